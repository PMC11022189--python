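"""Piecewise direct standardization (PDS) calibration transfer.

PDS maps spectra measured in a "slave" domain (here: coarser powder
particle sizes, 80/100-mesh) onto a "master" domain (120-mesh) one
wavelength at a time: master wavelength i is regressed on the small slave
window [i-j .. i+k] using a handful of paired standard samples, and the
resulting banded coefficient matrix transfers any slave spectrum.  Local
regressions are PLS with few latent variables, mean-centered on the
standard samples so additive baseline lifts are absorbed by an intercept.

Exposed as a statsmodels-style pair: :class:`PDSTransfer` (model, built
from paired standard sets) whose ``fit()`` returns :class:`PDSResults`
(the transform, with ``transform()`` and ``summary()``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import _nipals_pls1, _pls_coefficients, kennard_stone_order
from .spectra import SpectraSet, SpectraValidationError


@dataclass(frozen=True)
class WindowSpec:
    """Slave-side window geometry: j columns left, k right of wavelength i."""

    j: int
    k: int

    def __post_init__(self):
        if self.j < 0 or self.k < 0:
            raise ValueError("window half-widths must be nonnegative")

    @property
    def width(self) -> int:
        return self.j + self.k + 1

    @classmethod
    def symmetric(cls, width: int) -> "WindowSpec":
        if width < 1 or width % 2 == 0:
            raise ValueError("symmetric window width must be odd and >= 1")
        return cls(width // 2, width // 2)


def _batch_local_pls(X: np.ndarray, y: np.ndarray, n_lv: int) -> np.ndarray:
    """NIPALS PLS1 run simultaneously for many local regressions.

    ``X`` is (n_windows, n_std, width) centered, ``y`` is (n_windows, n_std)
    centered.  Returns the (n_windows, width) coefficient block.  Same
    recursion as the scalar NIPALS, with degenerate latent variables zeroed
    per window instead of stopping.
    """
    P_, n, w = X.shape
    x_scale = np.maximum(np.sqrt(np.einsum("pnw,pnw->p", X, X)), 1e-300)
    Xd, yd = X.copy(), y.copy()
    Ws = np.zeros((P_, w, n_lv))
    Ps = np.zeros((P_, w, n_lv))
    qs = np.zeros((P_, n_lv))
    act_all = np.zeros((P_, n_lv), dtype=bool)
    for a in range(n_lv):
        W = np.einsum("pnw,pn->pw", Xd, yd)
        wn = np.linalg.norm(W, axis=1)
        W = W / np.maximum(wn, 1e-300)[:, None]
        t = np.einsum("pnw,pw->pn", Xd, W)
        tt = np.einsum("pn,pn->p", t, t)
        active = tt > (1e-8 * x_scale) ** 2
        tt_safe = np.maximum(tt, 1e-300)
        Pl = np.einsum("pnw,pn->pw", Xd, t) / tt_safe[:, None]
        q = np.einsum("pn,pn->p", yd, t) / tt_safe
        W[~active] = 0.0
        Pl[~active] = 0.0
        q[~active] = 0.0
        act_all[:, a] = active
        Xd = Xd - t[:, :, None] * Pl[:, None, :]
        yd = yd - q[:, None] * t
        Ws[:, :, a], Ps[:, :, a], qs[:, a] = W, Pl, q
    # B = W (P^T W)^-1 q per window; inactive LVs patched to the identity row
    PtW = np.einsum("pwa,pwb->pab", Ps, Ws)
    for a in range(n_lv):
        dead = ~act_all[:, a]
        PtW[dead, a, :] = 0.0
        PtW[dead, :, a] = 0.0
        PtW[dead, a, a] = 1.0
    sol = np.linalg.solve(PtW, qs[:, :, None])[:, :, 0]
    return np.einsum("pwa,pa->pw", Ws, sol)


def select_standard_samples(master_cal: SpectraSet, n_std: int) -> np.ndarray:
    """Most space-filling n_std calibration samples: the Kennard-Stone prefix.

    Standards must span the instrumental (particle-size) differences; the
    KS prefix is the deterministic subset that best covers the calibration
    spectra space.
    """
    n = master_cal.n_samples
    if not 1 <= n_std <= n:
        raise ValueError(f"n_std must be in [1, {n}], got {n_std}")
    order = kennard_stone_order(master_cal.absorbance)
    return np.sort(order[:n_std])


@dataclass
class PDSResults:
    """Fitted per-wavelength transfer coefficients.

    ``coefficients[i]`` applies to slave columns ``lo[i]:hi[i]`` (the window
    truncated at the spectrum edges); ``intercepts[i]`` carries the
    centering offset.  ``transform`` maps a slave SpectraSet onto the master
    axis.
    """

    window: WindowSpec
    master_axis: object
    lo: np.ndarray
    hi: np.ndarray
    coefficients: list[np.ndarray]
    intercepts: np.ndarray
    n_lv_local: int
    standard_indices: np.ndarray | None = None

    def transform(self, slave: SpectraSet) -> SpectraSet:
        if slave.n_wavelengths != self.intercepts.size:
            raise SpectraValidationError(
                "slave axis length does not match the fitted transform"
            )
        block = slave.absorbance
        out = np.empty_like(block)
        for i, (lo, hi, f) in enumerate(zip(self.lo, self.hi, self.coefficients)):
            out[:, i] = self.intercepts[i] + block[:, lo:hi] @ f
        return SpectraSet(self.master_axis, out, list(slave.meta))

    def summary(self) -> str:
        widths = self.hi - self.lo
        return "\n".join([
            "PDS transfer results",
            "=" * 40,
            f"window (j, k)      : ({self.window.j}, {self.window.k})",
            f"wavelengths        : {self.intercepts.size}",
            f"effective widths   : {widths.min()}..{widths.max()}",
            f"local latent vars  : {self.n_lv_local}",
            f"standard samples   : "
            f"{'-' if self.standard_indices is None else self.standard_indices.size}",
        ])


class PDSTransfer:
    """Piecewise direct standardization model from paired standard samples.

    Parameters
    ----------
    master_std, slave_std : the same standard samples measured in the master
        and slave domains, same order and axis length.
    window : :class:`WindowSpec` or odd integer width (symmetric window).
    n_lv_local : latent variables of each local PLS regression, capped at
        min(n_std - 1, effective window width).  Small windows and few
        standards demand heavy regularization; pass ``None`` for the
        feasibility cap itself (exact least squares where one exists).
    """

    def __init__(self, master_std: SpectraSet, slave_std: SpectraSet,
                 window: WindowSpec | int, n_lv_local: int | None = 2):
        if isinstance(window, int):
            window = WindowSpec.symmetric(window)
        if master_std.n_samples != slave_std.n_samples:
            raise SpectraValidationError("standard sets must be paired (same samples)")
        if master_std.n_wavelengths != slave_std.n_wavelengths:
            raise SpectraValidationError("master and slave axes must have equal length")
        if master_std.n_samples < 2:
            raise ValueError(
                "PDS with centering needs at least 2 standard samples (n_std >= 2)"
            )
        if window.width > master_std.n_wavelengths:
            raise ValueError("window wider than the spectral axis")
        self.master_std = master_std
        self.slave_std = slave_std
        self.window = window
        self.n_lv_local = n_lv_local

    def fit(self, standard_indices: np.ndarray | None = None) -> PDSResults:
        M = self.master_std.absorbance
        S = self.slave_std.absorbance
        n_std, p = S.shape
        j, k = self.window.j, self.window.k
        lo = np.maximum(np.arange(p) - j, 0)
        hi = np.minimum(np.arange(p) + k + 1, p)
        coefs: list[np.ndarray] = [np.empty(0)] * p
        intercepts = np.empty(p)

        interior = [i for i in range(p) if hi[i] - lo[i] == j + k + 1]
        edges = [i for i in range(p) if hi[i] - lo[i] != j + k + 1]
        if self.n_lv_local is not None and interior:
            # all interior windows share a width: batch the local PLS fits
            idx = np.asarray(interior)
            Xw = np.lib.stride_tricks.sliding_window_view(S, j + k + 1, axis=1)
            Xw = np.transpose(Xw[:, idx - j, :], (1, 0, 2))  # (p_int, n, w)
            Y = M[:, idx].T                                   # (p_int, n)
            n_lv = min(self.n_lv_local, n_std - 1, j + k + 1)
            F = _batch_local_pls(Xw - Xw.mean(axis=1, keepdims=True),
                                 Y - Y.mean(axis=1, keepdims=True), n_lv)
            for row, i in enumerate(idx):
                coefs[i] = F[row]
                intercepts[i] = Y[row].mean() - Xw[row].mean(axis=0) @ F[row]
        else:
            edges = list(range(p))
        for i in edges:
            Xw = S[:, lo[i]:hi[i]]
            yw = M[:, i]
            xm = Xw.mean(axis=0)
            ym = yw.mean()
            cap = min(n_std - 1, hi[i] - lo[i])
            n_lv = cap if self.n_lv_local is None else min(self.n_lv_local, cap)
            W, P, q, _ = _nipals_pls1(Xw - xm, yw - ym, n_lv)
            f = _pls_coefficients(W, P, q)
            coefs[i] = f
            intercepts[i] = ym - xm @ f
        return PDSResults(
            window=self.window,
            master_axis=self.master_std.axis,
            lo=lo,
            hi=hi,
            coefficients=coefs,
            intercepts=intercepts,
            n_lv_local=-1 if self.n_lv_local is None else self.n_lv_local,
            standard_indices=standard_indices,
        )


def fit_pds(master_std: SpectraSet, slave_std: SpectraSet,
            window: WindowSpec | int, n_lv_local: int | None = 2) -> PDSResults:
    """Functional wrapper over :class:`PDSTransfer`."""
    return PDSTransfer(master_std, slave_std, window, n_lv_local).fit()


def apply_pds(t: PDSResults, slave: SpectraSet) -> SpectraSet:
    """Transfer slave-domain spectra onto the master axis."""
    return t.transform(slave)


@dataclass
class TransferSearchResult:
    """Grid-search surface over (window width, number of standards).

    ``grid[(width, n_std)]`` holds the downstream RMSE of the transferred
    internal-validation spectra (NaN where the cell is infeasible); ``best``
    is the argmin with ties broken toward fewer standards, then narrower
    windows.
    """

    grid: dict = field(default_factory=dict)
    best: tuple[int, int] | None = None
    best_rmse: float = float("nan")


def optimize_pds(
    master_cal: SpectraSet,
    slave_cal: SpectraSet,
    y_cal: np.ndarray,
    downstream,
    widths=(3, 5, 7, 9, 11),
    n_std_range=range(1, 18),
    n_lv_local: int | None = 2,
) -> TransferSearchResult:
    """Grid-search window width x standard-sample count.

    ``downstream`` is a scorer ``f(transferred: SpectraSet, y) -> rmse``
    wrapping the frozen master-domain model.  Standards are the KS prefix of
    the master calibration spectra; the remaining calibration samples form
    the internal validation subset, so the held-out prediction set is never
    touched.  Cells infeasible for a centered local PLS (n_std < 2) are
    recorded as missing, not fatal.
    """
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    if master_cal.n_samples != slave_cal.n_samples or y_cal.size != master_cal.n_samples:
        raise SpectraValidationError("calibration sets and y must be paired")
    order = kennard_stone_order(master_cal.absorbance)
    result = TransferSearchResult()
    for width in sorted(widths):
        for n_std in n_std_range:
            if n_std < 2 or n_std >= master_cal.n_samples:
                result.grid[(width, n_std)] = float("nan")
                continue
            std_idx = np.sort(order[:n_std])
            val_idx = np.sort(order[n_std:])
            t = PDSTransfer(
                master_cal.take(std_idx), slave_cal.take(std_idx),
                WindowSpec.symmetric(width), n_lv_local,
            ).fit(standard_indices=std_idx)
            transferred = t.transform(slave_cal.take(val_idx))
            rmse = float(downstream(transferred, y_cal[val_idx]))
            result.grid[(width, n_std)] = rmse
    feasible = {k: v for k, v in result.grid.items() if np.isfinite(v)}
    if feasible:
        # argmin; ties -> smaller n_std, then smaller width
        best_key = min(feasible, key=lambda k: (feasible[k], k[1], k[0]))
        result.best = best_key
        result.best_rmse = feasible[best_key]
    return result
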