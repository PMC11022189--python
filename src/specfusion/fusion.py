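"""NIR-MIR fusion strategies.

Three levels of fusion are supported:

* full-spectrum — range-normalized absorbance blocks of both modalities
  concatenated column-wise (normalization is mandatory so the two
  instruments' scales meet without a jump at the seam);
* feature-level — only the selected wavelength columns of each modality are
  concatenated, NIR block first;
* decision-level — the per-modality model predictions are combined, either
  by entropy-weighted TOPSIS weights (y = n*y_NIR + m*y_MIR) or by a small
  multiple linear regression (y = b + k1*y_NIR + k2*y_MIR) fitted on
  calibration-side predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import RangeNorm, range_normalize_apply
from .select import FeatureIndexSet
from .spectra import SpectraSet, SpectraValidationError


def _check_aligned(nir: SpectraSet, mir: SpectraSet) -> None:
    if nir.n_samples != mir.n_samples:
        raise SpectraValidationError("sample counts differ between modalities")
    for a, b in zip(nir.meta, mir.meta):
        if a.concentration is not None and b.concentration is not None:
            if (a.concentration, a.replicate) != (b.concentration, b.replicate):
                raise SpectraValidationError(
                    "modalities are not metadata-aligned; run align_by_meta first"
                )


def fuse_full_spectrum(
    nir: SpectraSet,
    mir: SpectraSet,
    norms: tuple[RangeNorm, RangeNorm],
) -> np.ndarray:
    """Concatenate range-normalized full spectra: [NIR_norm | MIR_norm].

    ``norms`` must be the per-modality range normalizations fitted on the
    calibration set; passing None is refused because un-normalized blocks
    from different instruments would join with an arbitrary scale step.
    """
    if norms is None or norms[0] is None or norms[1] is None:
        raise ValueError("full-spectrum fusion requires fitted range normalizations")
    _check_aligned(nir, mir)
    nir_n = range_normalize_apply(nir, norms[0])
    mir_n = range_normalize_apply(mir, norms[1])
    return np.hstack([nir_n.absorbance, mir_n.absorbance])


def fuse_feature_level(
    nir: SpectraSet,
    mir: SpectraSet,
    f_nir: FeatureIndexSet,
    f_mir: FeatureIndexSet,
) -> np.ndarray:
    """Concatenate only the selected columns, NIR block first.

    Columns duplicated across modalities are kept (no cross-modality
    dedup); column provenance is positional: the first len(f_nir) columns
    are NIR.
    """
    _check_aligned(nir, mir)
    if f_nir.indices.max() >= nir.n_wavelengths:
        raise ValueError("NIR feature index out of bounds")
    if f_mir.indices.max() >= mir.n_wavelengths:
        raise ValueError("MIR feature index out of bounds")
    return np.hstack(
        [nir.absorbance[:, f_nir.indices], mir.absorbance[:, f_mir.indices]]
    )


# ---------------------------------------------------------------------------
# Decision-level fusion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictionSet:
    """Aligned per-modality predictions (and optional reference) in %."""

    y_nir: np.ndarray
    y_mir: np.ndarray
    y_true: np.ndarray | None = None

    def __post_init__(self):
        y_nir = np.asarray(self.y_nir, dtype=float).ravel()
        y_mir = np.asarray(self.y_mir, dtype=float).ravel()
        object.__setattr__(self, "y_nir", y_nir)
        object.__setattr__(self, "y_mir", y_mir)
        if y_nir.size != y_mir.size:
            raise ValueError("per-modality prediction lengths differ")
        if self.y_true is not None:
            y_true = np.asarray(self.y_true, dtype=float).ravel()
            object.__setattr__(self, "y_true", y_true)
            if y_true.size != y_nir.size:
                raise ValueError("reference length differs from predictions")


@dataclass(frozen=True)
class TopsisWeights:
    """Decision weights for the NIR and MIR models; n + m = 1."""

    n: float
    m: float

    def __post_init__(self):
        if self.n < 0 or self.m < 0:
            raise ValueError("weights must be nonnegative")
        if abs(self.n + self.m - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")


@dataclass(frozen=True)
class CriteriaMatrix:
    """Model-by-criterion evaluation matrix for entropy-weighted TOPSIS.

    Rows are the candidate modality models (NIR first), columns the
    criteria (typically R^2 and RMSE); ``benefit`` flags whether larger is
    better for each criterion.
    """

    values: np.ndarray
    benefit: tuple[bool, ...]

    def __post_init__(self):
        vals = np.atleast_2d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", vals)
        if vals.shape[0] < 2:
            raise ValueError("need at least 2 candidate models")
        if vals.shape[1] != len(self.benefit):
            raise ValueError("one orientation flag per criterion required")


def entropy_topsis_weights(c: CriteriaMatrix) -> TopsisWeights:
    """Entropy-weighted TOPSIS closeness scores, normalized to decision weights.

    Steps: (i) weight each criterion by its information content,
    w proportional to 1 - entropy of the oriented min-max share distribution
    (0*log 0 = 0); (ii) vector-normalize each raw criterion column (the
    classic TOPSIS normalization — with only two candidate models a min-max
    normalized matrix is binary, which would collapse the weights to 0/1
    whenever one model dominates); (iii) compute each model's weighted
    Euclidean distances d+ / d- to the ideal and anti-ideal points (max of a
    benefit column, min of a cost column) and its closeness d- / (d+ + d-);
    (iv) normalize the closeness values to sum to 1.  Identical rows degrade
    gracefully to equal weights.
    """
    vals = c.values
    n_models = vals.shape[0]
    if np.allclose(vals, vals[0], atol=1e-15):
        warnings.warn("identical criteria rows: falling back to equal weights",
                      stacklevel=2)
        return _equal_weights(n_models)
    shares, norm_cols, benefits = [], [], []
    for j, benefit in enumerate(c.benefit):
        col = vals[:, j]
        rng = col.max() - col.min()
        if rng == 0:
            warnings.warn(f"criterion {j} is constant; dropped", stacklevel=2)
            continue
        oriented = (col - col.min()) / rng if benefit else (col.max() - col) / rng
        shares.append(oriented)
        scale = np.linalg.norm(col)
        norm_cols.append(col / scale if scale > 0 else col)
        benefits.append(benefit)
    if not norm_cols:
        return _equal_weights(n_models)
    # entropy weights from the oriented share distribution per criterion
    M = np.column_stack(shares)
    colsum = M.sum(axis=0)
    P = np.divide(M, colsum, out=np.full_like(M, 1.0 / n_models), where=colsum > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    entropy = -plogp.sum(axis=0) / np.log(n_models)
    d = 1.0 - entropy
    w = d / d.sum() if d.sum() > 0 else np.full(M.shape[1], 1.0 / M.shape[1])
    V = np.column_stack(norm_cols) * w
    ideal = np.where(benefits, V.max(axis=0), V.min(axis=0))
    anti = np.where(benefits, V.min(axis=0), V.max(axis=0))
    d_plus = np.linalg.norm(V - ideal, axis=1)
    d_minus = np.linalg.norm(V - anti, axis=1)
    closeness = d_minus / (d_plus + d_minus)
    weights = closeness / closeness.sum()
    if n_models != 2:
        raise ValueError("TopsisWeights is defined for the two-modality case")
    return TopsisWeights(float(weights[0]), float(weights[1]))


def _equal_weights(n_models: int) -> TopsisWeights:
    if n_models != 2:
        raise ValueError("TopsisWeights is defined for the two-modality case")
    return TopsisWeights(0.5, 0.5)


def combine_topsis(p: PredictionSet, w: TopsisWeights) -> np.ndarray:
    """Elementwise weighted sum n*y_NIR + m*y_MIR."""
    return w.n * p.y_nir + w.m * p.y_mir


@dataclass(frozen=True)
class MLRCombiner:
    """Decision-level MLR combiner y = b + k1*y_NIR + k2*y_MIR."""

    b: float
    k1: float
    k2: float

    def __post_init__(self):
        if not np.all(np.isfinite([self.b, self.k1, self.k2])):
            raise ValueError("combiner coefficients must be finite")


def fit_mlr_combiner(p: PredictionSet) -> MLRCombiner:
    """Ordinary least squares of y_true on [1, y_NIR, y_MIR].

    Must be fitted on calibration-side predictions only.  Exactly collinear
    predictors fall back to the minimal-norm solution with a warning.
    """
    if p.y_true is None:
        raise ValueError("fit_mlr_combiner needs reference values")
    n = p.y_true.size
    if n < 3:
        raise ValueError("need at least 3 samples to fit the combiner")
    A = np.column_stack([np.ones(n), p.y_nir, p.y_mir])
    if np.linalg.matrix_rank(A) < 3:
        warnings.warn(
            "collinear modality predictions: minimal-norm combiner returned",
            stacklevel=2,
        )
    coef, *_ = np.linalg.lstsq(A, p.y_true, rcond=None)
    return MLRCombiner(b=float(coef[0]), k1=float(coef[1]), k2=float(coef[2]))


def combine_mlr(p: PredictionSet, c: MLRCombiner) -> np.ndarray:
    """Elementwise b + k1*y_NIR + k2*y_MIR."""
    return c.b + c.k1 * p.y_nir + c.k2 * p.y_mir
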