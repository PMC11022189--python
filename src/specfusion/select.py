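"""Wavelength-subset selection: uninformative variable elimination (UVE),
the successive projections algorithm (SPA), synergy-interval PLS (SiPLS),
and the UVE -> SPA cascade.

UVE removes wavelengths whose regression-coefficient stability across
leave-one-out refits is no better than that of appended random-noise
columns; SPA then prunes collinearity by forward selection of maximally
orthogonal columns; SiPLS instead scores combinations of contiguous
spectral intervals by cross-validated PLS error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .model import PLSCalibration, _cv_fold_assignment, _nipals_pls1, _pls_coefficients, kennard_stone_split


class EmptySelectionError(ValueError):
    """Every variable was eliminated; suggests lowering the cutoff."""


@dataclass(frozen=True)
class FeatureIndexSet:
    """Selected wavelength-column indices for one modality.

    ``diagnostics`` carries per-variable scores: UVE reliability c for UVE,
    selection order for SPA, interval CV-RMSE for SiPLS; the cascade keeps
    both stages.
    """

    modality: str
    indices: np.ndarray
    provenance: str  # UVE | SPA | SiPLS | UVE_SPA
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        if idx.size == 0:
            raise EmptySelectionError("empty feature index set")
        if np.unique(idx).size != idx.size:
            raise ValueError("duplicate indices in feature set")
        if not np.all(np.diff(idx) > 0):
            raise ValueError("indices must be strictly increasing")
        if idx.min() < 0:
            raise ValueError("negative index")

    def __len__(self) -> int:
        return self.indices.size


def save_feature_table(fs: FeatureIndexSet, axis_values: np.ndarray, path) -> None:
    """Two-column audit file: axis value, column index."""
    with open(path, "w") as fh:
        fh.write("axis_value,column_index\n")
        for i in fs.indices:
            fh.write(f"{axis_values[i]!r},{i}\n")


# ---------------------------------------------------------------------------
# UVE
# ---------------------------------------------------------------------------

def uve_select(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    n_noise: int | None = None,
    cutoff_factor: float = 1.0,
    seed: int | None = None,
    modality: str = "NIR",
) -> FeatureIndexSet:
    """Uninformative variable elimination.

    X is augmented with ``n_noise`` uniform random columns spanning the data
    range; leave-one-out PLS refits at ``n_lv`` latent variables collect the
    per-variable coefficient sequences b_j, and the reliability
    c_j = mean(b_j)/sd(b_j) of each real variable is compared against the
    noise block: variables with |c_j| <= cutoff_factor * max|c_noise| are
    eliminated.
    """
    if seed is None:
        raise ValueError("uve_select requires an explicit seed")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n_noise is None:
        n_noise = max(p, 300)
    rng = np.random.default_rng(seed)
    lo, hi = float(X.min()), float(X.max())
    # noise drawn uniformly over the data range, then scaled down so the
    # artificial block cannot perturb the PLS fit: the reliability ratio
    # c_j = mean/sd is scale-invariant per column, the model fit is not
    noise = 1e-10 * rng.uniform(lo, hi, size=(n, n_noise))
    Xa = np.hstack([X, noise])
    coefs = np.empty((n, p + n_noise))
    for i in range(n):
        keep = np.arange(n) != i
        Xt, yt = Xa[keep], y[keep]
        xm, ym = Xt.mean(axis=0), yt.mean()
        W, P, q, _ = _nipals_pls1(Xt - xm, yt - ym, n_lv)
        coefs[i] = _pls_coefficients(W, P, q)
    mean = coefs.mean(axis=0)
    sd = coefs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(sd > 0, mean / sd, np.inf * np.sign(mean))
    c = np.nan_to_num(c, nan=0.0)
    cutoff = cutoff_factor * np.abs(c[p:]).max()
    kept = np.flatnonzero(np.abs(c[:p]) > cutoff)
    if kept.size == 0:
        raise EmptySelectionError(
            "UVE eliminated every variable; consider a lower cutoff_factor"
        )
    return FeatureIndexSet(
        modality=modality,
        indices=kept,
        provenance="UVE",
        diagnostics={"reliability": c[:p], "cutoff": float(cutoff)},
    )


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------

def _spa_chain(Xc: np.ndarray, start: int, m_max: int) -> list[int]:
    """Forward orthogonal-projection chain from a start column.

    At each step the candidate whose component orthogonal to the span of the
    already-selected columns has maximal norm is added; the chain stops
    early on rank collapse (all orthogonal components numerically zero).
    """
    P = Xc.copy()
    n, p = P.shape
    scale = np.linalg.norm(Xc, axis=0).max()
    chain = [start]
    selected = np.zeros(p, dtype=bool)
    selected[start] = True
    for _ in range(m_max - 1):
        v = P[:, chain[-1]]
        nv = np.linalg.norm(v)
        if nv <= 1e-12 * scale:
            break
        v = v / nv
        P = P - np.outer(v, v @ P)
        norms = np.linalg.norm(P, axis=0)
        norms[selected] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] <= 1e-10 * scale:
            break
        chain.append(nxt)
        selected[nxt] = True
    return chain


def _ols_rmse(X: np.ndarray, y: np.ndarray, cols, tr, va) -> float:
    A = np.column_stack([np.ones(len(tr)), X[np.ix_(tr, cols)]])
    coef, *_ = np.linalg.lstsq(A, y[tr], rcond=None)
    Av = np.column_stack([np.ones(len(va)), X[np.ix_(va, cols)]])
    return float(np.sqrt(np.mean((y[va] - Av @ coef) ** 2)))


def _cv_rmse(X: np.ndarray, y: np.ndarray, cols, cv_folds: int = 10) -> float:
    folds = _cv_fold_assignment(y, min(cv_folds, y.size))
    sse, n = 0.0, y.size
    for f in range(folds.max() + 1):
        hold = folds == f
        A = np.column_stack([np.ones((~hold).sum()), X[np.ix_(~hold, cols)]])
        coef, *_ = np.linalg.lstsq(A, y[~hold], rcond=None)
        Ah = np.column_stack([np.ones(hold.sum()), X[np.ix_(hold, cols)]])
        sse += float(np.sum((y[hold] - Ah @ coef) ** 2))
    return np.sqrt(sse / n)


def spa_select(
    X: np.ndarray,
    y: np.ndarray,
    m_min: int = 1,
    m_max: int = 15,
    modality: str = "NIR",
    rescore_top: int = 20,
) -> FeatureIndexSet:
    """Successive projections algorithm (classic form).

    For every candidate start column a chain of maximally orthogonal columns
    is grown to length ``m_max``; every (start, length) combination with
    length in [m_min, m_max] is scored by the RMSE of an ordinary
    multilinear fit on an internal Kennard-Stone validation split.  Because
    the argmin over thousands of single-split scores rewards lucky chains,
    the ``rescore_top`` best candidates are re-scored by deterministic
    10-fold cross-validation and the CV argmin is returned.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    m_max = min(m_max, n - 1, p)
    m_min = max(1, min(m_min, m_max))
    if p == 1:
        return FeatureIndexSet(modality, np.array([0]), "SPA", {"order": [0]})
    # internal 2:1 KS re-split: never touches the held-out prediction set
    if n >= 6:
        split = kennard_stone_split(X, 2.0 / 3.0)
        tr, va = split.calibration_indices, split.prediction_indices
    else:
        tr = va = np.arange(n)
    Xc = X - X.mean(axis=0)
    scored: list[tuple[float, list[int]]] = []
    for start in range(p):
        chain = _spa_chain(Xc, start, m_max)
        for m in range(m_min, len(chain) + 1):
            cols = chain[:m]
            scored.append((_ols_rmse(X, y, cols, tr, va), cols))
    scored.sort(key=lambda t: (t[0], t[1]))
    finalists = scored[: max(1, rescore_top)]
    best = min(
        ((_cv_rmse(X, y, cols), rmse, cols) for rmse, cols in
         ((r, c) for r, c in finalists)),
        key=lambda t: (t[0], t[2]),
    )
    order = best[2]
    idx = np.sort(np.asarray(order, dtype=int))
    return FeatureIndexSet(
        modality, idx, "SPA",
        {"order": list(order), "val_rmse": best[1], "cv_rmse": best[0]},
    )


# ---------------------------------------------------------------------------
# SiPLS
# ---------------------------------------------------------------------------

def sipls_select(
    X: np.ndarray,
    y: np.ndarray,
    n_intervals: int = 20,
    combo_size: int = 2,
    max_lv: int = 6,
    cv_folds: int = 10,
    modality: str = "NIR",
) -> FeatureIndexSet:
    """Synergy-interval PLS: best combination of contiguous intervals.

    The axis is cut into ``n_intervals`` near-equal contiguous intervals;
    every combination of ``combo_size`` intervals is scored by the
    cross-validated RMSE of a PLS fit on the concatenated columns, and the
    winning combination's column indices are returned.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n_intervals > p:
        raise ValueError("more intervals than wavelengths")
    if combo_size not in (1, 2, 3, 4):
        raise ValueError("combo_size must be in {1, 2, 3, 4}")
    from math import comb

    if comb(n_intervals, combo_size) > 10**5:
        raise ValueError("combinatorial budget exceeded (>1e5 interval combinations)")
    bounds = np.linspace(0, p, n_intervals + 1).astype(int)
    intervals = [np.arange(bounds[i], bounds[i + 1]) for i in range(n_intervals)]
    if n_intervals == 1:
        return FeatureIndexSet(modality, np.arange(p), "SiPLS",
                               {"intervals": [0], "cv_rmse": {}})
    results: dict[tuple, float] = {}
    best: tuple[float, tuple] | None = None
    for combo in combinations(range(n_intervals), combo_size):
        cols = np.concatenate([intervals[i] for i in combo])
        lv = min(max_lv, cols.size, n - int(np.ceil(n / cv_folds)))
        model = PLSCalibration(X[:, cols], y, max_lv=lv, cv_folds=cv_folds)
        res = model.fit()
        score = float(res.cv_rmse.min())
        results[combo] = score
        if best is None or score < best[0] - 1e-15:
            best = (score, combo)
    assert best is not None
    cols = np.concatenate([intervals[i] for i in best[1]])
    return FeatureIndexSet(
        modality, np.sort(cols), "SiPLS",
        {"intervals": list(best[1]),
         "cv_rmse": {"+".join(map(str, k)): v for k, v in results.items()}},
    )


# ---------------------------------------------------------------------------
# UVE -> SPA cascade
# ---------------------------------------------------------------------------

def uve_spa_select(
    X: np.ndarray,
    y: np.ndarray,
    uve_params: dict,
    spa_params: dict | None = None,
    modality: str = "NIR",
) -> FeatureIndexSet:
    """UVE elimination followed by SPA de-collinearization.

    SPA runs on the UVE-retained columns only; its selected positions are
    mapped back to the original axis indices.  This is the selector behind
    the best-performing feature-level fusion model.
    """
    spa_params = dict(spa_params or {})
    uve = uve_select(X, y, modality=modality, **uve_params)
    kept = uve.indices
    m_min = spa_params.get("m_min", 1)
    if kept.size <= max(1, m_min):
        spa = None
        final = kept
        order = list(range(kept.size))
    else:
        spa = spa_select(X[:, kept], y, modality=modality, **spa_params)
        final = kept[spa.indices]
        order = [int(kept[i]) for i in spa.diagnostics["order"]]
    return FeatureIndexSet(
        modality, np.sort(final), "UVE_SPA",
        {
            "uve": uve.diagnostics,
            "uve_kept": kept,
            "spa": None if spa is None else spa.diagnostics,
            "order": order,
        },
    )
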