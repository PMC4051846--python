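"""Darroch–Mosimann log-shape ratios: isometric size removal.

For a specimen's positive measurement vector x = (x_1 .. x_p) the log-shape
ratios are ln x_i - mean_k(ln x_k), i.e. the log of each measurement over
the geometric mean.  Multiplying all measurements by a common factor leaves
the vector unchanged exactly, so what remains is shape.  The vector sums to
zero by construction, which makes the p ratios rank-deficient (rank p-1);
downstream ordinations must account for that.

The default measurement subset is the eight variables preserved on the
Trinil fossil (total length excluded), so the fossil itself is projectable
into the shape space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .morphodata import FOSSIL_SUBSET, Clade, MeasurementRecord, ValidationError

__all__ = ["ShapeVector", "ShapeMatrix", "log_shape_ratios", "shape_matrix"]


@dataclass(frozen=True)
class ShapeVector:
    """One specimen's log-shape ratios over a declared measurement subset."""

    specimen_id: str
    clade: Clade
    subset: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (len(self.subset),):
            raise ValidationError("shape vector length must match its subset")


@dataclass(frozen=True)
class ShapeMatrix:
    """Stacked shape vectors with row metadata; fossil rows are flagged.

    ``values`` is (n, p) in input row order; ``is_fossil`` marks rows that
    must be excluded from any model fitting and only ever projected.
    """

    subset: tuple[str, ...]
    specimen_ids: tuple[str, ...]
    clades: tuple[Clade, ...]
    values: np.ndarray

    @property
    def is_fossil(self) -> np.ndarray:
        return np.array([c is Clade.FOSSIL for c in self.clades])

    @property
    def comparative(self) -> np.ndarray:
        return self.values[~self.is_fossil]

    @property
    def comparative_clades(self) -> list[Clade]:
        return [c for c in self.clades if c is not Clade.FOSSIL]

    def __len__(self) -> int:
        return self.values.shape[0]


def log_shape_ratios(
    record: MeasurementRecord, subset: Sequence[str] = FOSSIL_SUBSET
) -> ShapeVector:
    """Compute ln x_i - mean(ln x) over *subset* (p >= 2, all present)."""
    subset = tuple(subset)
    if len(subset) < 2:
        raise ValidationError("log-shape ratios need at least two measurements")
    x = record.vector(subset)  # raises naming any missing measurement
    logs = np.log(x)
    return ShapeVector(
        specimen_id=record.specimen_id,
        clade=record.clade,
        subset=subset,
        values=logs - logs.mean(),
    )


def shape_matrix(
    records: Iterable[MeasurementRecord], subset: Sequence[str] = FOSSIL_SUBSET
) -> ShapeMatrix:
    """Stack per-record shape vectors in input order.

    Requires at least two computable records; fossil rows are kept but
    flagged so downstream fits exclude them.
    """
    subset = tuple(subset)
    vecs = [log_shape_ratios(r, subset) for r in records]
    if len(vecs) < 2:
        raise ValidationError("need at least two records for a shape matrix")
    return ShapeMatrix(
        subset=subset,
        specimen_ids=tuple(v.specimen_id for v in vecs),
        clades=tuple(v.clade for v in vecs),
        values=np.vstack([v.values for v in vecs]),
    )
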