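"""The full iterative motion-artifact correction loop.

Each iteration: (1) compute the entropy-unbalance report; (2) identify the
most contaminated R-optode, its worst channel, and the implicated T-optode;
(3) wavelet-decompose the channel and train the corrector against the mean
of its clean-side (R-optode) neighbors; (4) transfer the trained weights to
the siblings sharing the implicated T-optode, fine-tuning briefly on each
sibling's own neighbor mean; (5) smooth the corrected channels with the
hemodynamic kernel.  The loop repeats on the updated recording until the
mean absolute deviation of the unbalanced indices falls below a threshold,
no optode stands out any more, or an iteration cap is reached.

Only corrected channels are ever modified: untouched channels leave the
pipeline bit-identical to their input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .baselines import hrf_smooth
from .corrector import DEFAULT_HIDDEN, build_target, train_corrector, transfer_correct
from .mra import DEFAULT_LEVELS, DEFAULT_WAVELET, decompose
from .probe import ProbeLayout
from .synth import BlockDesign
from .unbalance import (
    DEFAULT_WINDOW,
    IdentifiedTriple,
    UnbalanceReport,
    identify_contaminated,
    mean_abs_deviation,
    stop_criterion,
    unbalance_report,
)

__all__ = ["PipelineConfig", "IterationRecord", "CorrectionRun", "run_correction"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the correction loop."""

    window_n: int = DEFAULT_WINDOW
    normalized_gamma: bool = False
    scan_kind: str = "R"  # which optode type's UIs drive identification
    outlier_k: float = 8.0
    sigma_th: float | None = None  # absolute MAD stop threshold; None = relative
    sigma_th_rel: float = 0.1  # sigma_th = rel * initial MAD when sigma_th is None
    max_iter: int = 10
    wavelet: str = DEFAULT_WAVELET
    levels: int = DEFAULT_LEVELS
    hidden: tuple[int, ...] = DEFAULT_HIDDEN
    activation: str = "relu"
    epochs: int = 2000
    transfer_iters: int = 100
    learning_rate: float = 1e-3
    smooth_corrected: bool = True
    hrf_kernel_s: float = 30.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden"] = list(self.hidden)
        return d


@dataclass
class IterationRecord:
    iteration: int
    report: UnbalanceReport
    identified: IdentifiedTriple
    corrected_channels: list[int]
    model: object | None
    ui_mad: float


@dataclass
class CorrectionRun:
    """Audit trail and result of one correction run."""

    iterations: list[IterationRecord]
    final_recording: np.ndarray
    config: PipelineConfig
    seed: int
    sigma_th: float
    stopped_reason: str

    @property
    def corrected_channels(self) -> set[int]:
        out: set[int] = set()
        for it in self.iterations:
            out |= set(it.corrected_channels)
        return out

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "config": self.config.to_dict(),
            "sigma_th": self.sigma_th,
            "stopped_reason": self.stopped_reason,
            "iterations": [
                {
                    "iteration": it.iteration,
                    "identified": {
                        "r_optode": it.identified.r_optode,
                        "channel": it.identified.channel,
                        "t_optode": it.identified.t_optode,
                        "contaminated": it.identified.contaminated,
                    },
                    "corrected_channels": it.corrected_channels,
                    "ui_mad": it.ui_mad,
                }
                for it in self.iterations
            ],
        }


def run_correction(
    recording: np.ndarray,
    layout: ProbeLayout,
    design: BlockDesign,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> CorrectionRun:
    """Iteratively detect and correct contaminated channels.

    `recording` is channels x L ordered as `layout.channel_ids`; it is not
    modified.  All randomness (network initialization) derives from `seed`
    and the iteration number, so identical inputs give bit-identical output.
    """
    cfg = config if config is not None else PipelineConfig()
    state = np.array(recording, dtype=float, copy=True)
    iterations: list[IterationRecord] = []
    corrected_ud: dict[int, float] = {}  # UD at the time a channel was corrected
    sigma_th = cfg.sigma_th
    reason = "max_iter"
    for it in range(1, cfg.max_iter + 1):
        report = unbalance_report(
            state, layout, n=cfg.window_n, normalized=cfg.normalized_gamma, iteration=it
        )
        ui = report.ui_values(cfg.scan_kind)
        mad = mean_abs_deviation(ui.values())
        if sigma_th is None:
            sigma_th = cfg.sigma_th_rel * mad  # anchored to the initial spread
        report.sigma_th = sigma_th
        triple = identify_contaminated(report, layout, cfg.scan_kind, cfg.outlier_k)
        if not triple.contaminated:
            iterations.append(IterationRecord(it, report, triple, [], None, mad))
            reason = "no_contamination"
            break
        if it > 1 and stop_criterion(ui, sigma_th):
            iterations.append(IterationRecord(it, report, triple, [], None, mad))
            reason = "sigma_th"
            break
        ch = triple.channel
        if ch in corrected_ud and report.ud[ch] <= corrected_ud[ch]:
            # already corrected and not degrading again: nothing left to do
            iterations.append(IterationRecord(it, report, triple, [], None, mad))
            reason = "stable"
            break
        ch_idx = layout.channel_ids.index(ch)
        feats = decompose(state[ch_idx], cfg.levels, cfg.wavelet, channel=ch)
        target = build_target(state, layout, ch, triple.r_optode)
        model, corrected = train_corrector(
            feats,
            target,
            epochs=cfg.epochs,
            learning_rate=cfg.learning_rate,
            seed=(seed + 977 * it) % (2 ** 31),
            hidden=cfg.hidden,
            activation=cfg.activation,
        )
        done = [ch]
        corrected_ud[ch] = report.ud[ch]
        if cfg.smooth_corrected:
            corrected = hrf_smooth(corrected, design.fs, cfg.hrf_kernel_s,
                                   compensate_delay=True)
        state[ch_idx] = corrected
        # transfer to siblings sharing the implicated (faulty) optode
        for sib in sorted(layout.neighbor_channels(triple.t_optode, exclude=ch)):
            t_opt, r_opt = layout.optodes_of_channel(sib)
            clean_side = r_opt if cfg.scan_kind == "R" else t_opt
            sib_idx = layout.channel_ids.index(sib)
            sib_feats = decompose(state[sib_idx], cfg.levels, cfg.wavelet, channel=sib)
            sib_target = build_target(state, layout, sib, clean_side)
            _, sib_corr = transfer_correct(
                model, sib_feats, sib_target,
                iters=cfg.transfer_iters, learning_rate=cfg.learning_rate,
            )
            if cfg.smooth_corrected:
                sib_corr = hrf_smooth(sib_corr, design.fs, cfg.hrf_kernel_s,
                                      compensate_delay=True)
            state[sib_idx] = sib_corr
            done.append(sib)
            corrected_ud[sib] = report.ud[sib]
        iterations.append(IterationRecord(it, report, triple, done, model, mad))
    return CorrectionRun(iterations, state, cfg, seed, float(sigma_th or 0.0), reason)
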