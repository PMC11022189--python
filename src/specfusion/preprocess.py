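"""Spectral pre-treatments: SNV, MSC, Savitzky-Golay smoothing, min-max
range normalization for fusion, and composable fitted chains.

Scatter corrections (SNV, MSC) remove the multiplicative/additive effects of
uneven particle distribution in diffuse-reflectance powder spectra; SG
smoothing suppresses high-frequency instrument noise.  Steps that learn
state (MSC reference, range bounds) are fitted on calibration data only and
frozen for prediction data — no information flows back from held-out
samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_coeffs

from .spectra import SpectraSet, SpectraValidationError


class DegenerateSpectrumError(ValueError):
    """A spectrum has no usable spread (constant row, zero MSC slope)."""


def snv(s: SpectraSet) -> SpectraSet:
    """Standard normal variate: per-row centering and scaling.

    Each spectrum x is mapped to (x - mean(x)) / sd(x) with the n-1 sample
    standard deviation, removing per-sample multiplicative scatter and
    baseline offsets.
    """
    block = s.absorbance
    mean = block.mean(axis=1, keepdims=True)
    sd = block.std(axis=1, ddof=1, keepdims=True)
    # relative threshold: a numerically constant row has sd ~ eps * |level|
    bad = np.flatnonzero(
        sd.ravel() <= 1e-12 * np.maximum(np.abs(mean).ravel(), 1.0))
    if bad.size:
        raise DegenerateSpectrumError(
            f"constant spectrum (zero spread) for sample "
            f"{s.meta[bad[0]].sample_id!r}"
        )
    return s.with_absorbance((block - mean) / sd)


@dataclass(frozen=True)
class MSCReference:
    """Frozen reference spectrum for multiplicative scatter correction."""

    reference: np.ndarray
    source: str = "calibration_mean"  # or "supplied"

    def __post_init__(self):
        ref = np.asarray(self.reference, dtype=float)
        if not np.all(np.isfinite(ref)):
            raise SpectraValidationError("MSC reference must be finite")
        object.__setattr__(self, "reference", ref)


def msc_fit(cal: SpectraSet) -> MSCReference:
    """Learn the MSC reference as the column-wise mean calibration spectrum."""
    if cal.n_samples < 2:
        warnings.warn(
            "MSC reference fitted on a single sample; using that spectrum",
            stacklevel=2,
        )
    return MSCReference(cal.absorbance.mean(axis=0))


def msc_apply(s: SpectraSet, ref: MSCReference) -> SpectraSet:
    """Regress each spectrum on the reference (x = a + b*ref) and invert.

    Rows are replaced by (x - a) / b, collapsing multiplicative scatter
    families onto the reference shape.
    """
    r = ref.reference
    if r.size != s.n_wavelengths:
        raise SpectraValidationError("MSC reference length does not match axis")
    rc = r - r.mean()
    denom = rc @ rc
    if denom == 0:
        raise DegenerateSpectrumError("MSC reference is constant")
    block = s.absorbance
    b = (block - block.mean(axis=1, keepdims=True)) @ rc / denom
    bad = np.flatnonzero(np.abs(b) < 1e-12)
    if bad.size:
        raise DegenerateSpectrumError(
            f"MSC slope ~ 0 for sample {s.meta[bad[0]].sample_id!r}"
        )
    a = block.mean(axis=1) - b * r.mean()
    return s.with_absorbance((block - a[:, None]) / b[:, None])


def _sg_edge_kernel(offsets: np.ndarray, polyorder: int, at: float) -> np.ndarray:
    """Least-squares polynomial smoothing weights over arbitrary offsets.

    Row of the hat matrix evaluated at position ``at``: the fitted
    polynomial's value there as a linear combination of the window samples.
    Order is capped so the local system stays overdetermined or square.
    """
    order = min(polyorder, offsets.size - 1)
    V = np.vander(offsets.astype(float), order + 1, increasing=True)
    # value at `at` = [1, at, at^2, ...] @ pinv(V) @ window values
    return np.polynomial.polynomial.polyvander(at, order)[0] @ np.linalg.pinv(V)


def sg_smooth(s: SpectraSet, window: int = 5, polyorder: int = 3) -> SpectraSet:
    """Savitzky-Golay least-squares polynomial smoothing (0th derivative).

    Interior points use the standard symmetric convolution kernel; at the
    spectrum edges the local polynomial is refitted on the truncated
    one-sided window so no samples are fabricated and the axis length is
    preserved (required for downstream fusion concatenation).
    """
    p = s.n_wavelengths
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if window > p:
        raise ValueError(f"window {window} exceeds axis length {p}")
    if not 0 <= polyorder < window:
        raise ValueError(f"polyorder must be in [0, window), got {polyorder}")
    half = window // 2
    block = s.absorbance
    out = np.empty_like(block)
    # savgol_coeffs returns weights for x[i-half..i+half] in reversed order
    kernel = savgol_coeffs(window, polyorder)[::-1]
    windows = np.lib.stride_tricks.sliding_window_view(block, window, axis=1)
    out[:, half : p - half] = windows @ kernel
    for i in range(half):
        offs = np.arange(0, i + half + 1)
        out[:, i] = block[:, : i + half + 1] @ _sg_edge_kernel(offs, polyorder, i)
        offs = np.arange(p - 1 - (i + half), p)
        out[:, p - 1 - i] = block[:, p - 1 - (i + half) :] @ _sg_edge_kernel(
            offs - (p - 1 - i), polyorder, 0.0
        )
    return s.with_absorbance(out)


@dataclass(frozen=True)
class RangeNorm:
    """Per-modality global min/max learned on calibration data.

    Maps x -> (x - min) / (max - min).  Prediction values may fall outside
    [0, 1] and are deliberately not clipped; the point is to put both
    modalities on a common scale so concatenated fused blocks have no
    artificial jump at the seam.
    """

    vmin: float
    vmax: float

    def __post_init__(self):
        if not self.vmax > self.vmin:
            raise SpectraValidationError("range normalization needs max > min")


def range_normalize_fit(cal: SpectraSet) -> RangeNorm:
    return RangeNorm(float(cal.absorbance.min()), float(cal.absorbance.max()))


def range_normalize_apply(s: SpectraSet, norm: RangeNorm) -> SpectraSet:
    return s.with_absorbance((s.absorbance - norm.vmin) / (norm.vmax - norm.vmin))


_STATELESS = {"snv": snv, "sg": sg_smooth}
_STATEFUL_FIT = {"msc": msc_fit, "range": range_normalize_fit}
_STATEFUL_APPLY = {"msc": msc_apply, "range": range_normalize_apply}
KNOWN_STEPS = sorted(set(_STATELESS) | set(_STATEFUL_FIT))


class PreprocessChain:
    """Ordered pre-treatment steps with calibration-frozen state.

    ``fit`` runs the steps in order on calibration data, freezing any
    learned state (MSC reference, range bounds) as it goes; ``apply``
    replays the frozen states on new data.  Applying to the calibration
    data reproduces the fitting pass output exactly.
    """

    def __init__(self, steps: list[tuple[str, dict]] | list[str]):
        self.steps: list[tuple[str, dict]] = []
        for step in steps:
            name, params = step if isinstance(step, tuple) else (step, {})
            if name not in KNOWN_STEPS:
                raise ValueError(
                    f"unknown preprocessing step {name!r}; known: {KNOWN_STEPS}"
                )
            self.steps.append((name, dict(params)))
        self._state: list[object] | None = None

    @property
    def fitted(self) -> bool:
        return self._state is not None

    def fit(self, cal: SpectraSet) -> SpectraSet:
        """Fit stateful steps on calibration data; return the transformed set."""
        self._state = []
        out = cal
        for name, params in self.steps:
            if name in _STATEFUL_FIT:
                state = _STATEFUL_FIT[name](out, **params)
                self._state.append(state)
                out = _STATEFUL_APPLY[name](out, state)
            else:
                self._state.append(None)
                out = _STATELESS[name](out, **params)
        return out

    def apply(self, s: SpectraSet) -> SpectraSet:
        if self._state is None:
            raise RuntimeError("chain must be fitted before apply")
        out = s
        for (name, params), state in zip(self.steps, self._state):
            if name in _STATEFUL_APPLY:
                out = _STATEFUL_APPLY[name](out, state)
            else:
                out = _STATELESS[name](out, **params)
        return out

    def state_snapshot(self) -> list:
        """Frozen learned state, for leakage checks and audit."""
        snap = []
        for state in self._state or []:
            if isinstance(state, MSCReference):
                snap.append(("msc", state.reference.copy()))
            elif isinstance(state, RangeNorm):
                snap.append(("range", state.vmin, state.vmax))
            else:
                snap.append(None)
        return snap


def chain(steps) -> PreprocessChain:
    """Build an (unfitted) preprocessing chain from an ordered step spec."""
    return PreprocessChain(steps)
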