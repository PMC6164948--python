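"""Synthetic multi-channel fNIRS recordings with ground truth.

Generates block-design oxygenated-hemoglobin (HbO) concentration-change
series at 10 Hz: a canonical double-gamma hemodynamic response convolved
with the task boxcar on active channels, plus sinusoidal physiological
components (cardiac ~1.1 Hz, respiration ~0.25 Hz, Mayer waves ~0.1 Hz)
and white noise.  Optode-level motion artifacts (baseline jump, linear
drift, spike trains) are added to *every* channel incident to the affected
optode, mirroring how a displaced optode corrupts all of its channels.

Both the clean and the contaminated (observed) matrices are returned, so
detection and correction stages can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma_dist

from .probe import ProbeLayout, default_layout

__all__ = [
    "BlockDesign",
    "ArtifactSpec",
    "SyntheticRecording",
    "canonical_hrf",
    "simulate_recording",
    "NoiseSpec",
    "ROI_CHANNELS",
]

#: region-of-interest channels of the 5x5 montage (used for ROI-restricted
#: quality metrics; the generator's default activates *all* channels, since
#: the walking-task montage covers motor cortex throughout and the unbalance
#: detector assumes neighbor channels share features absent artifacts)
ROI_CHANNELS = frozenset({7, 11, 12, 16, 20, 21, 25})


@dataclass(frozen=True)
class BlockDesign:
    """Block task design: each block is pre-rest, task, post-rest.

    Defaults encode the 20 s / 20 s / 20 s walking-task protocol at 10 Hz.
    """

    fs: float = 10.0
    pre_rest_s: float = 20.0
    task_s: float = 20.0
    post_rest_s: float = 20.0
    n_blocks: int = 3

    def __post_init__(self) -> None:
        if min(self.pre_rest_s, self.task_s, self.post_rest_s) <= 0:
            raise ValueError("block durations must be positive")
        if self.fs <= 0 or self.n_blocks < 1:
            raise ValueError("fs must be positive and n_blocks >= 1")

    @property
    def block_s(self) -> float:
        return self.pre_rest_s + self.task_s + self.post_rest_s

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.block_s * self.n_blocks))

    def task_boxcar(self) -> np.ndarray:
        """Boolean array, True during task periods."""
        t = np.arange(self.n_samples) / self.fs
        phase = np.mod(t, self.block_s)
        return (phase >= self.pre_rest_s) & (phase < self.pre_rest_s + self.task_s)


@dataclass(frozen=True)
class ArtifactSpec:
    """One optode-level motion artifact.

    kind:
        "baseline_jump"  - step of `amplitude` from `onset_s` onward
                           (rapid head movement);
        "linear_drift"   - ramp reaching `amplitude` over `duration_s`,
                           held afterwards (slow optode slippage);
        "spike_train"    - Gaussian-shaped transients of height `amplitude`
                           every ~2 s within [onset_s, onset_s+duration_s]
                           (cable sway).
    """

    optode: str
    kind: str
    amplitude: float
    onset_s: float
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("baseline_jump", "linear_drift", "spike_train"):
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if not np.isfinite(self.amplitude):
            raise ValueError("artifact amplitude must be finite")

    def waveform(self, n_samples: int, fs: float) -> np.ndarray:
        t = np.arange(n_samples) / fs
        if self.onset_s < 0 or self.onset_s >= n_samples / fs:
            raise ValueError(f"artifact onset {self.onset_s}s outside recording")
        if self.kind == "baseline_jump":
            return np.where(t >= self.onset_s, self.amplitude, 0.0)
        if self.kind == "linear_drift":
            dur = max(self.duration_s, 1.0 / fs)
            ramp = np.clip((t - self.onset_s) / dur, 0.0, 1.0)
            return self.amplitude * ramp
        # spike_train: one transient every 2 s, width 0.2 s
        w = np.zeros(n_samples)
        dur = max(self.duration_s, 1.0 / fs)
        for center in np.arange(self.onset_s, self.onset_s + dur, 2.0):
            w += self.amplitude * np.exp(-0.5 * ((t - center) / 0.2) ** 2)
        return w


@dataclass
class NoiseSpec:
    """Physiological + instrument noise amplitudes (signal units) and Hz."""

    sigma_white: float = 0.02
    cardiac_amp: float = 0.01
    cardiac_freq: float = 1.1
    mayer_amp: float = 0.01
    mayer_freq: float = 0.1
    resp_amp: float = 0.01
    resp_freq: float = 0.25

    def __post_init__(self) -> None:
        if min(self.sigma_white, self.cardiac_amp, self.mayer_amp, self.resp_amp) < 0:
            raise ValueError("noise scales must be non-negative")


@dataclass
class SyntheticRecording:
    """Ground-truth recording: `observed = clean + optode artifacts`."""

    clean: np.ndarray  # channels x L
    observed: np.ndarray  # channels x L
    design: BlockDesign
    layout: ProbeLayout
    artifact_specs: list[ArtifactSpec] = field(default_factory=list)
    seed: int = 0

    @property
    def n_channels(self) -> int:
        return self.clean.shape[0]

    def channel_index(self, channel_id: int) -> int:
        return self.layout.channel_ids.index(channel_id)

    def contaminated_channels(self) -> set[int]:
        out: set[int] = set()
        for spec in self.artifact_specs:
            out |= self.layout.neighbor_channels(spec.optode)
        return out


def canonical_hrf(t: np.ndarray, a1: float = 6.0, a2: float = 16.0,
                  b: float = 1.0, c: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, normalized to peak 1.

    h(t) = g(t; a1, b) - c * g(t; a2, b) with gamma probability densities g,
    the standard positive response peaking near (a1-1)*b = 5 s with a late
    undershoot.  `t` is a non-negative time grid in seconds.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time grid must be non-negative")
    h = _gamma_dist.pdf(t, a1, scale=b) - c * _gamma_dist.pdf(t, a2, scale=b)
    peak = np.max(np.abs(h))
    if peak > 0:
        h = h / peak
    return h


def _hemodynamic_response(design: BlockDesign, amp: float) -> np.ndarray:
    """Boxcar convolved with the canonical HRF, scaled to `amp` at plateau."""
    kernel_t = np.arange(0, 30.0, 1.0 / design.fs)
    kernel = canonical_hrf(kernel_t)
    s = kernel.sum()
    if s != 0:
        kernel = kernel / s  # unit-sum: plateau of a long boxcar ~= amp
    box = design.task_boxcar().astype(float)
    return amp * np.convolve(box, kernel)[: design.n_samples]


def simulate_recording(
    layout: ProbeLayout | None = None,
    design: BlockDesign | None = None,
    active_channels: set[int] | frozenset[int] | None = None,
    response_amp: float = 0.1,
    noise: NoiseSpec | None = None,
    artifacts: list[ArtifactSpec] | None = None,
    seed: int = 0,
) -> SyntheticRecording:
    """Simulate a multi-channel HbO recording with known contamination.

    The clean signal is a linear superposition of the task-evoked response
    (on `active_channels`; by default every channel, emulating a task that
    engages the whole covered cortex), per-channel random-phase
    physiological sinusoids and white noise.  Each artifact's waveform is added to every channel
    incident to its optode; all other channels are bit-identical between
    `clean` and `observed`.  Fully reproducible per `seed`.
    """
    layout = layout if layout is not None else default_layout()
    design = design if design is not None else BlockDesign()
    noise = noise if noise is not None else NoiseSpec()
    artifacts = list(artifacts) if artifacts is not None else []
    if active_channels is None:
        active_channels = set(layout.channel_ids)
    unknown = set(active_channels) - set(layout.channel_ids)
    if unknown:
        raise ValueError(f"active channels not in layout: {sorted(unknown)}")
    for spec in artifacts:
        layout.optode(spec.optode)  # raises on unknown optode

    rng = np.random.default_rng(seed)
    L = design.n_samples
    t = np.arange(L) / design.fs
    hrf = _hemodynamic_response(design, response_amp)

    n_ch = len(layout.channels)
    clean = np.zeros((n_ch, L))
    for i, ch in enumerate(layout.channels):
        x = np.zeros(L)
        if ch.id in active_channels:
            x = x + hrf
        for amp, freq in (
            (noise.cardiac_amp, noise.cardiac_freq),
            (noise.resp_amp, noise.resp_freq),
            (noise.mayer_amp, noise.mayer_freq),
        ):
            if amp > 0:
                x = x + amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
        if noise.sigma_white > 0:
            x = x + rng.normal(0.0, noise.sigma_white, size=L)
        clean[i] = x

    observed = clean.copy()
    for spec in artifacts:
        w = spec.waveform(L, design.fs)
        for cid in layout.neighbor_channels(spec.optode):
            observed[layout.channel_ids.index(cid)] += w

    return SyntheticRecording(clean, observed, design, layout, artifacts, seed)
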