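"""Spectral data containers and delimited-text I/O.

The central object is :class:`SpectraSet`: an aligned sample-by-wavelength
absorbance block with a typed axis and per-sample metadata (adulterant mass
fraction in %, sieve mesh, replicate index).  Every stage of the pipeline —
pre-treatment, partitioning, calibration, fusion, calibration transfer —
consumes and produces this one currency.

Tables are plain CSV: the first column holds sample ids, optional reserved
columns ``concentration``/``mesh``/``replicate`` hold metadata, and the
remaining (numeric) headers are the wavelength/wavenumber axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODALITIES = ("NIR", "MIR")
UNITS = ("nm", "cm-1")
META_COLUMNS = ("concentration", "mesh", "replicate")


class SpectraFormatError(ValueError):
    """Raised when a spectra table cannot be parsed."""


class SpectraValidationError(ValueError):
    """Raised when spectral data violate a structural invariant."""


@dataclass(frozen=True)
class SpectralAxis:
    """Ordered wavelength (nm) or wavenumber (cm^-1) grid for one modality.

    The axis must be strictly monotone with no duplicates.  Near-infrared
    axes in nm must increase; mid-infrared axes in cm^-1 may run in either
    direction (acquisition order is typically 4000 -> 400 cm^-1).
    """

    modality: str
    unit: str
    values: np.ndarray

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise SpectraValidationError(f"unknown modality {self.modality!r}")
        if self.unit not in UNITS:
            raise SpectraValidationError(f"unknown unit {self.unit!r}")
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise SpectraValidationError("axis needs at least 2 values")
        if not np.all(np.isfinite(values)):
            raise SpectraValidationError("axis values must be finite")
        diffs = np.diff(values)
        if np.any(diffs == 0):
            raise SpectraValidationError("axis contains duplicate values")
        if self.unit == "nm":
            if not np.all(diffs > 0):
                raise SpectraValidationError("nm axis must be strictly increasing")
        elif not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise SpectraValidationError("cm-1 axis must be strictly monotone")

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SpectralAxis)
            and self.modality == other.modality
            and self.unit == other.unit
            and self.values.shape == other.values.shape
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata; missing fields are ``None`` (prediction-only use)."""

    sample_id: str
    concentration: float | None = None  # adulterant mass fraction, %
    mesh: int | None = None
    replicate: int | None = None

    def __post_init__(self):
        if self.concentration is not None and not (0.0 <= self.concentration <= 100.0):
            raise SpectraValidationError(
                f"sample {self.sample_id!r}: concentration {self.concentration} "
                "outside [0, 100] %"
            )


@dataclass
class SpectraSet:
    """Absorbance block (n_samples x n_wavelengths) with axis and metadata."""

    axis: SpectralAxis
    absorbance: np.ndarray
    meta: list[SampleMeta] = field(default_factory=list)

    def __post_init__(self):
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.absorbance.shape[0] < 1:
            raise SpectraValidationError("SpectraSet needs at least one sample")
        if self.absorbance.shape[1] != len(self.axis):
            raise SpectraValidationError(
                f"absorbance has {self.absorbance.shape[1]} columns, "
                f"axis has {len(self.axis)}"
            )
        if len(self.meta) != self.absorbance.shape[0]:
            raise SpectraValidationError(
                f"{len(self.meta)} metadata rows for "
                f"{self.absorbance.shape[0]} spectra"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise SpectraValidationError("absorbance contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]

    @property
    def concentrations(self) -> np.ndarray:
        """Concentration vector (%), requiring metadata on every sample."""
        vals = [m.concentration for m in self.meta]
        if any(v is None for v in vals):
            raise SpectraValidationError("concentration metadata missing")
        return np.asarray(vals, dtype=float)

    def take(self, indices: Sequence[int]) -> "SpectraSet":
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(self.axis, self.absorbance[idx], [self.meta[i] for i in idx])

    def with_absorbance(self, block: np.ndarray) -> "SpectraSet":
        return SpectraSet(self.axis, block, list(self.meta))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SpectraSet)
            and self.axis == other.axis
            and np.array_equal(self.absorbance, other.absorbance)
            and self.meta == other.meta
        )


def read_spectra_table(path, modality: str, unit: str) -> SpectraSet:
    """Read a CSV spectra table into a validated :class:`SpectraSet`.

    Header layout: ``sample_id`` first, optional reserved metadata columns,
    then numeric axis values.  Raises :class:`SpectraFormatError` on
    malformed headers or ragged rows.
    """
    # parse the header ourselves: pandas silently renames duplicate column
    # labels, which would let a duplicated axis value slip past validation
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split(",")
    if len(header) < 2:
        raise SpectraFormatError(f"{path}: header needs sample ids and an axis")
    meta_cols = [c for c in header[1:] if c in META_COLUMNS]
    axis_cols = [c for c in header[1:] if c not in META_COLUMNS]
    try:
        axis_values = np.asarray([float(c) for c in axis_cols])
    except ValueError as exc:
        raise SpectraFormatError(f"{path}: non-numeric axis header: {exc}") from exc
    axis = SpectralAxis(modality, unit, axis_values)
    try:
        df = pd.read_csv(path, header=None, skiprows=1,
                         names=list(range(len(header))), dtype={0: str},
                         float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SpectraFormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[0] == 0:
        raise SpectraFormatError(f"{path}: no data rows")
    if df.shape[1] != len(header):
        raise SpectraFormatError(f"{path}: ragged rows")

    positions = {name: i for i, name in enumerate(header)}
    axis_idx = [i for i, name in enumerate(header)
                if i > 0 and name not in META_COLUMNS]
    try:
        block = df.iloc[:, axis_idx].to_numpy(dtype=float)
    except ValueError as exc:
        raise SpectraFormatError(f"{path}: non-numeric absorbance: {exc}") from exc
    meta = []
    for _, row in df.iterrows():
        def field(name):
            return row.iloc[positions[name]] if name in meta_cols else None

        conc, mesh, rep = field("concentration"), field("mesh"), field("replicate")
        meta.append(
            SampleMeta(
                sample_id=str(row.iloc[0]),
                concentration=None if pd.isna(conc) else float(conc),
                mesh=None if pd.isna(mesh) else int(mesh),
                replicate=None if pd.isna(rep) else int(rep),
            )
        )
    return SpectraSet(axis, block, meta)


def write_spectra_table(s: SpectraSet, path) -> None:
    """Write a SpectraSet as CSV, re-readable to an equal object (full precision)."""
    cols: dict[str, object] = {"sample_id": [m.sample_id for m in s.meta]}
    if any(m.concentration is not None for m in s.meta):
        cols["concentration"] = [m.concentration for m in s.meta]
    if any(m.mesh is not None for m in s.meta):
        cols["mesh"] = [m.mesh for m in s.meta]
    if any(m.replicate is not None for m in s.meta):
        cols["replicate"] = [m.replicate for m in s.meta]
    df = pd.DataFrame(cols)
    axis_df = pd.DataFrame(
        s.absorbance, columns=[repr(float(v)) for v in s.axis.values],
        index=df.index,
    )
    pd.concat([df, axis_df], axis=1).to_csv(path, index=False, float_format=None)


def _meta_key(m: SampleMeta) -> tuple:
    return (m.concentration, m.replicate)


def align_by_meta(a: SpectraSet, b: SpectraSet) -> tuple[SpectraSet, SpectraSet]:
    """Reorder two sets so row i of each refers to the same
    (concentration, replicate) design point; unmatched samples are dropped.

    Needed before any fusion step: concatenation and decision combination
    are only meaningful on metadata-matched rows.
    """
    for s, name in ((a, "first"), (b, "second")):
        if any(m.concentration is None or m.replicate is None for m in s.meta):
            raise SpectraValidationError(
                f"{name} set lacks concentration/replicate metadata for alignment"
            )
    keys_a = {}
    for i, m in enumerate(a.meta):
        keys_a.setdefault(_meta_key(m), i)
    pairs = []
    for j, m in enumerate(b.meta):
        i = keys_a.get(_meta_key(m))
        if i is not None:
            pairs.append((_meta_key(m), i, j))
    if not pairs:
        raise SpectraValidationError("no metadata-matched sample pairs")
    pairs.sort(key=lambda t: t[0])
    dropped = (a.n_samples - len(pairs)) + (b.n_samples - len(pairs))
    if dropped:
        logger.info("align_by_meta dropped %d unmatched samples", dropped)
    ia = [p[1] for p in pairs]
    ib = [p[2] for p in pairs]
    return a.take(ia), b.take(ib)


def average_replicates(s: SpectraSet) -> SpectraSet:
    """Average absorbance across replicates of each (concentration, mesh) group.

    Mirrors the acquisition protocol in which repeated measurements of a
    sample are averaged into one final spectrum; the output carries
    replicate index 0.
    """
    if any(m.replicate is None for m in s.meta):
        raise SpectraValidationError("replicate metadata required for averaging")
    if any(m.concentration is None for m in s.meta):
        raise SpectraValidationError("concentration metadata required for averaging")
    groups: dict[tuple, list[int]] = {}
    for i, m in enumerate(s.meta):
        groups.setdefault((m.concentration, m.mesh), []).append(i)
    keys = sorted(groups, key=lambda k: (k[0], -1 if k[1] is None else k[1]))
    rows = np.vstack([s.absorbance[groups[k]].mean(axis=0) for k in keys])
    meta = [
        replace(s.meta[groups[k][0]], replicate=0, sample_id=s.meta[groups[k][0]].sample_id)
        for k in keys
    ]
    return SpectraSet(s.axis, rows, meta)
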