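"""Dyadic wavelet multiresolution decomposition (Daubechies-6, 10 levels).

A J-level discrete wavelet transform splits a signal into J detail sub-bands
D1..DJ (finest to coarsest) plus one approximation AJ; with J = 10 this is
the 11-sub-band representation used as the corrector network's input.  Each
*MRA component* here is the full-length time-domain contribution of one
sub-band — the inverse transform of the coefficient tree with every other
sub-band zeroed — so the components sum samplewise to the input signal.

Periodized boundaries with an orthogonal wavelet make the decomposition
energy-preserving (Parseval) and the reconstruction exact.  Signals whose
length is not a multiple of 2^J are reflect-padded before the transform and
the components cropped back, which preserves additivity on the original
support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = ["MRADecomposition", "decompose", "reconstruct"]

DEFAULT_WAVELET = "db6"  # 6 vanishing moments, filter length 12
DEFAULT_LEVELS = 10


@dataclass
class MRADecomposition:
    """Additive sub-band components of one channel.

    `components` maps sub-band names "D1".."D{J}" and "A{J}" to full-length
    arrays; `coefficients` holds the underlying DWT coefficient arrays
    (approximation first, then coarsest-to-finest details, as returned by
    the transform).
    """

    channel: int
    wavelet: str
    levels: int
    length: int
    components: dict[str, np.ndarray]
    coefficients: list[np.ndarray] = field(repr=False)
    boundary_mode: str = "periodization"

    @property
    def band_names(self) -> list[str]:
        return [f"D{j}" for j in range(1, self.levels + 1)] + [f"A{self.levels}"]

    def stack(self) -> np.ndarray:
        """(levels+1) x L matrix, rows ordered D1..DJ, AJ."""
        return np.stack([self.components[b] for b in self.band_names])


def _pad_reflect(x: np.ndarray, multiple: int) -> tuple[np.ndarray, int]:
    L = x.size
    target = -(-L // multiple) * multiple
    if target == L:
        return x, 0
    extra = target - L
    if extra > L - 1:
        # reflect repeatedly for very short signals
        reps = []
        need = extra
        flip = True
        cur = x
        while need > 0:
            seg = cur[::-1][1:] if cur.size > 1 else cur
            reps.append(seg[: need])
            need -= seg.size
        return np.concatenate([x] + reps)[:target], extra
    return np.concatenate([x, x[-2 : -2 - extra : -1]]), extra


def decompose(
    signal,
    levels: int = DEFAULT_LEVELS,
    wavelet: str = DEFAULT_WAVELET,
    channel: int = 0,
    mode: str = "periodization",
) -> MRADecomposition:
    """Decompose a signal into levels+1 additive sub-band components.

    If the signal is too short for the requested depth (fewer than 2^levels
    samples after padding considerations), the depth is reduced to the
    maximum feasible level with a warning.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    L = x.size
    if L < 2:
        raise ValueError("signal too short to decompose")
    feasible = int(np.floor(np.log2(L)))
    if levels > feasible:
        warnings.warn(
            f"signal of length {L} supports at most {feasible} levels; "
            f"reducing from {levels}",
            stacklevel=2,
        )
        levels = feasible
    xp, pad = _pad_reflect(x, 2 ** levels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # pywt boundary-effect note
        coeffs = pywt.wavedec(xp, wavelet, level=levels, mode=mode)
    components: dict[str, np.ndarray] = {}
    for idx, name in enumerate(["A%d" % levels] + ["D%d" % j for j in range(levels, 0, -1)]):
        sel = [c if i == idx else np.zeros_like(c) for i, c in enumerate(coeffs)]
        comp = pywt.waverec(sel, wavelet, mode=mode)
        components[name] = comp[:L]
    return MRADecomposition(channel, wavelet, levels, L, components, coeffs, mode)


def reconstruct(decomp: MRADecomposition, keep=None) -> np.ndarray:
    """Samplewise sum of the kept components; keep=None keeps all (identity)."""
    names = decomp.band_names
    if keep is None:
        keep = names
    keep = list(keep)
    unknown = set(keep) - set(names)
    if unknown:
        raise ValueError(f"unknown sub-bands {sorted(unknown)}")
    if not keep:
        warnings.warn("empty keep set: returning the zero signal", stacklevel=2)
        return np.zeros(decomp.length)
    return np.sum([decomp.components[b] for b in keep], axis=0)
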