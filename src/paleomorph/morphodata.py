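"""Domain types, validation and I/O for femoral measurement and landmark tables.

The measurement scheme is the nine-variable femoral protocol used for
comparing the Trinil 5703 fossil femur with extant Southeast Asian primates:
two neck lengths (LNW, UNW), the antero-posterior neck width (ANW), the
minimum proximo-distal neck height (NH), the antero-posterior and
medio-lateral shaft widths just below the lesser trochanter (ATW, MTW), the
maximum antero-posterior shaft width and its medio-lateral counterpart
(ADW, MDW), and the total femoral length (TL).  All values are millimetres.

Specimens belong to one of four natural clades of extant comparators —
small apes (Hylobatidae), langurs, odd-nosed monkeys, macaques — or are a
fossil under attribution.  Fossil records never enter any model fit.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MEASUREMENTS",
    "FOSSIL_SUBSET",
    "Clade",
    "AgeClass",
    "MeasurementRecord",
    "CladeSummary",
    "CurveLandmarks",
    "CurveState",
    "ValidationError",
    "DEFAULT_CLADE_MAP",
    "clade_of_taxon",
    "read_measurements",
    "write_measurements",
    "read_landmarks",
    "write_landmarks",
    "summarize_clade",
]

#: Canonical column order of the nine linear measurements (mm).
MEASUREMENTS: tuple[str, ...] = (
    "LNW", "UNW", "ANW", "NH", "ATW", "MTW", "ADW", "MDW", "TL",
)

#: The eight measurements preserved on the Trinil fossil (TL is not
#: measurable on the broken shaft); default subset for shape analysis.
FOSSIL_SUBSET: tuple[str, ...] = MEASUREMENTS[:-1]

MISSING_TOKEN = "-"


class ValidationError(ValueError):
    """A record or table violates a domain invariant."""


class Clade(str, Enum):
    SMALL_APES = "small_apes"
    LANGURS = "langurs"
    ODD_NOSED = "odd_nosed"
    MACAQUES = "macaques"
    FOSSIL = "fossil"

    @classmethod
    def comparative(cls) -> tuple["Clade", ...]:
        """The four extant clades, in canonical (tie-breaking) order."""
        return (cls.SMALL_APES, cls.LANGURS, cls.ODD_NOSED, cls.MACAQUES)


class AgeClass(str, Enum):
    ADULT = "adult"
    SUBADULT = "subadult"
    JUVENILE = "juvenile"
    UNKNOWN = "unknown"


class CurveState(str, Enum):
    RAW3D = "raw3d"
    PLANAR2D = "planar2d"
    BOOKSTEIN2D = "bookstein2d"


#: Genus -> clade grouping of the comparative sample.  Pygathrix is grouped
#: with the odd-nosed monkeys (as in the study's species list); Nasalis and
#: Rhinopithecus are classical odd-nosed genera and map there as well.
DEFAULT_CLADE_MAP: dict[str, Clade] = {
    "Bunopithecus": Clade.SMALL_APES,
    "Hylobates": Clade.SMALL_APES,
    "Nomascus": Clade.SMALL_APES,
    "Symphalangus": Clade.SMALL_APES,
    "Presbytis": Clade.LANGURS,
    "Trachypithecus": Clade.LANGURS,
    "Nasalis": Clade.ODD_NOSED,
    "Pygathrix": Clade.ODD_NOSED,
    "Rhinopithecus": Clade.ODD_NOSED,
    "Macaca": Clade.MACAQUES,
    "Trinil": Clade.FOSSIL,
}


def clade_of_taxon(taxon: str, clade_map: Mapping[str, Clade] | None = None) -> Clade:
    """Resolve a taxon name to its clade by its genus (first word).

    Raises :class:`ValidationError` if the genus has no mapping.
    """
    cmap = DEFAULT_CLADE_MAP if clade_map is None else clade_map
    genus = taxon.split()[0] if taxon.strip() else ""
    if genus in cmap:
        return Clade(cmap[genus])
    raise ValidationError(
        f"taxon {taxon!r} has no clade mapping (genus {genus!r}); "
        f"known genera: {sorted(cmap)}"
    )


@dataclass(frozen=True)
class MeasurementRecord:
    """One specimen's linear femoral measurements in mm.

    Any measurement may be missing (``None``); present values must be
    positive, and TL, when present, must exceed every other measurement.
    """

    specimen_id: str
    taxon: str
    clade: Clade
    age_class: AgeClass = AgeClass.UNKNOWN
    LNW: float | None = None
    UNW: float | None = None
    ANW: float | None = None
    NH: float | None = None
    ATW: float | None = None
    MTW: float | None = None
    ADW: float | None = None
    MDW: float | None = None
    TL: float | None = None

    def __post_init__(self) -> None:
        for name in MEASUREMENTS:
            v = getattr(self, name)
            if v is None:
                continue
            if not math.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"specimen {self.specimen_id!r}: measurement {name} = {v!r} "
                    "must be a positive finite number"
                )
        tl = self.TL
        if tl is not None:
            for name in FOSSIL_SUBSET:
                v = getattr(self, name)
                if v is not None and v >= tl:
                    raise ValidationError(
                        f"specimen {self.specimen_id!r}: TL = {tl} must exceed "
                        f"{name} = {v}"
                    )

    @property
    def is_fossil(self) -> bool:
        return self.clade is Clade.FOSSIL

    def get(self, name: str) -> float | None:
        if name not in MEASUREMENTS:
            raise KeyError(name)
        return getattr(self, name)

    def vector(self, subset: Sequence[str]) -> np.ndarray:
        """Measurement values over *subset*; raises if any is missing."""
        out = np.empty(len(subset))
        for i, name in enumerate(subset):
            v = self.get(name)
            if v is None:
                raise ValidationError(
                    f"specimen {self.specimen_id!r}: measurement {name} is "
                    "missing but required by the requested subset"
                )
            out[i] = v
        return out

    def has(self, subset: Sequence[str]) -> bool:
        return all(self.get(name) is not None for name in subset)


@dataclass(frozen=True)
class CladeSummary:
    """Per-measurement descriptive statistics of one clade (mm)."""

    clade: Clade
    n: int
    median: dict[str, float]
    mean: dict[str, float]
    sd: dict[str, float]
    min: dict[str, float]
    max: dict[str, float]
    n_present: dict[str, int] = field(default_factory=dict)


def summarize_clade(
    records: Iterable[MeasurementRecord],
    clade: Clade,
    measurements: Sequence[str] = MEASUREMENTS,
) -> CladeSummary:
    """Descriptive statistics (sample sd, n-1) over non-missing values.

    Raises :class:`ValidationError` if the clade has no records.
    """
    group = [r for r in records if r.clade is Clade(clade)]
    if not group:
        raise ValidationError(f"no records in clade {Clade(clade).value!r}")
    med, mean, sd, mn, mx, npres = {}, {}, {}, {}, {}, {}
    for name in measurements:
        vals = np.array([r.get(name) for r in group if r.get(name) is not None])
        npres[name] = len(vals)
        if len(vals) == 0:
            continue
        med[name] = float(np.median(vals))
        mean[name] = float(np.mean(vals))
        sd[name] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        mn[name] = float(np.min(vals))
        mx[name] = float(np.max(vals))
    return CladeSummary(
        clade=Clade(clade), n=len(group),
        median=med, mean=mean, sd=sd, min=mn, max=mx, n_present=npres,
    )


@dataclass(frozen=True)
class CurveLandmarks:
    """An ordered 10-landmark chain along the anterior femoral shaft.

    ``points`` is a (10, k) array, k = 3 for raw digitized coordinates or
    k = 2 after flattening / baseline registration; ordering is
    proximal -> distal.  In the ``bookstein2d`` state the first landmark is
    exactly (0, 0) and the last exactly (1, 0).
    """

    specimen_id: str
    taxon: str
    clade: Clade
    points: np.ndarray
    state: CurveState = CurveState.RAW3D

    N_LANDMARKS = 10

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[0] != self.N_LANDMARKS:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: expected exactly "
                f"{self.N_LANDMARKS} landmarks, got array of shape {pts.shape}"
            )
        expected_dim = 3 if self.state is CurveState.RAW3D else 2
        if pts.shape[1] != expected_dim:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: state {self.state.value} "
                f"requires {expected_dim}-D points, got {pts.shape[1]}-D"
            )
        if not np.all(np.isfinite(pts)):
            raise ValidationError(
                f"specimen {self.specimen_id!r}: landmark coordinates must be finite"
            )
        if self.state is CurveState.BOOKSTEIN2D:
            if not (np.array_equal(pts[0], [0.0, 0.0]) and np.array_equal(pts[-1], [1.0, 0.0])):
                raise ValidationError(
                    f"specimen {self.specimen_id!r}: bookstein2d endpoints must "
                    "be exactly (0,0) and (1,0)"
                )

    @property
    def free_y(self) -> np.ndarray:
        """Off-baseline coordinates of the eight interior landmarks."""
        if self.state is not CurveState.BOOKSTEIN2D:
            raise ValidationError("free_y is defined only for bookstein2d curves")
        return self.points[1:-1, 1].copy()


# ---------------------------------------------------------------------------
# I/O

MEASUREMENT_HEADER = (
    "specimen_id", "taxon", "clade", "age_class", *MEASUREMENTS,
)
LANDMARK_HEADER = (
    "specimen_id", "taxon", "clade", "landmark_index", "x", "y", "z",
)


def _parse_cell(value, specimen: str, column: str) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    s = str(value).strip()
    if s in ("", MISSING_TOKEN, "NA", "nan"):
        return None
    try:
        return float(s)
    except ValueError:
        raise ValidationError(
            f"specimen {specimen!r}, column {column}: cannot parse {value!r} as mm"
        ) from None


def _read_table(path: str | Path, delimiter: str) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xls", ".xlsx"):
        return pd.read_excel(path, dtype=object)
    return pd.read_csv(path, sep=delimiter, dtype=object, keep_default_na=False)


def read_measurements(
    path: str | Path,
    *,
    delimiter: str = ",",
    column_map: Mapping[str, str] | None = None,
    clade_map: Mapping[str, Clade] | None = None,
) -> list[MeasurementRecord]:
    """Read a measurement table (CSV or spreadsheet) into validated records.

    ``column_map`` maps file headers to canonical names (e.g.
    ``{"Neck height": "NH"}``); unmapped canonical headers are used as-is.
    Missing cells (empty or ``-``) become missing values, never zeros.  A
    record's clade comes from its ``clade`` column when present, otherwise
    from the genus of its taxon via ``clade_map``.
    """
    df = _read_table(path, delimiter)
    if column_map:
        df = df.rename(columns=dict(column_map))
    records: list[MeasurementRecord] = []
    for _, row in df.iterrows():
        sid = str(row.get("specimen_id", "")).strip()
        taxon = str(row.get("taxon", "")).strip()
        clade_cell = str(row.get("clade", "") or "").strip()
        if clade_cell:
            try:
                clade = Clade(clade_cell)
            except ValueError:
                raise ValidationError(
                    f"specimen {sid!r}: unknown clade {clade_cell!r}"
                ) from None
        else:
            clade = clade_of_taxon(taxon, clade_map)
        age_cell = str(row.get("age_class", "") or "").strip()
        age = AgeClass(age_cell) if age_cell else AgeClass.UNKNOWN
        values = {
            name: _parse_cell(row.get(name), sid, name) for name in MEASUREMENTS
        }
        records.append(
            MeasurementRecord(
                specimen_id=sid, taxon=taxon, clade=clade, age_class=age, **values
            )
        )
    return records


def write_measurements(
    records: Iterable[MeasurementRecord],
    path: str | Path,
    *,
    delimiter: str = ",",
) -> None:
    """Write records as CSV with ``-`` for missing cells (round-trip safe)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(MEASUREMENT_HEADER)
        for r in records:
            row = [r.specimen_id, r.taxon, r.clade.value, r.age_class.value]
            for name in MEASUREMENTS:
                v = r.get(name)
                row.append(MISSING_TOKEN if v is None else repr(float(v)))
            w.writerow(row)


def read_landmarks(path: str | Path, *, delimiter: str = ",") -> list[CurveLandmarks]:
    """Read a long-format landmark table into raw 3-D curves.

    Expects columns ``specimen_id, taxon, clade, landmark_index, x, y, z``
    with landmark_index 1..10 proximal->distal.  Specimens are returned in
    first-appearance order; a specimen with other than 10 landmarks is an
    error naming the specimen.
    """
    df = _read_table(path, delimiter)
    curves: list[CurveLandmarks] = []
    # preserve input order of specimen blocks
    seen: dict[str, int] = {}
    for sid in df["specimen_id"].astype(str):
        seen.setdefault(sid, len(seen))
    for sid, block in sorted(df.groupby("specimen_id", sort=False), key=lambda kv: seen[str(kv[0])]):
        block = block.copy()
        block["landmark_index"] = block["landmark_index"].astype(int)
        block = block.sort_values("landmark_index")
        idx = block["landmark_index"].to_numpy()
        if len(idx) != CurveLandmarks.N_LANDMARKS or not np.array_equal(
            idx, np.arange(1, CurveLandmarks.N_LANDMARKS + 1)
        ):
            raise ValidationError(
                f"specimen {sid!r}: expected landmark_index 1..10, got {list(idx)}"
            )
        taxon = str(block["taxon"].iloc[0])
        clade_cell = str(block.get("clade", pd.Series([""])).iloc[0] or "").strip()
        clade = Clade(clade_cell) if clade_cell else clade_of_taxon(taxon)
        pts = block[["x", "y", "z"]].astype(float).to_numpy()
        curves.append(
            CurveLandmarks(
                specimen_id=str(sid), taxon=taxon, clade=clade,
                points=pts, state=CurveState.RAW3D,
            )
        )
    return curves


def write_landmarks(
    curves: Iterable[CurveLandmarks], path: str | Path, *, delimiter: str = ","
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(LANDMARK_HEADER)
        for c in curves:
            if c.state is not CurveState.RAW3D:
                raise ValidationError(
                    f"specimen {c.specimen_id!r}: only raw3d curves are serialized"
                )
            for i, (x, y, z) in enumerate(c.points, start=1):
                w.writerow(
                    [c.specimen_id, c.taxon, c.clade.value, i,
                     repr(float(x)), repr(float(y)), repr(float(z))]
                )
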