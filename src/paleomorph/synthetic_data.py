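"""Synthetic measurement tables and shaft-landmark curves.

The generator reproduces the statistical structure the analysis chain
assumes, so every downstream stage can be exercised without the study's raw
spreadsheets:

* measurement vectors are multivariate log-normal per clade — drawn as a
  correlated Gaussian on the natural-log scale and exponentiated, which
  guarantees positivity and makes log-shape ratios exactly normal;
* total length follows the clade's log-log allometry on neck height,
  ln TL = a + b ln NH + N(0, sigma);
* shaft landmark chains are ten points evenly spaced along the chord of a
  quadratic arc with mid-chord bow kappa * scale, optionally noised and
  rigidly posed in 3-D.

Calibration to the published clade summary statistics is by moment matching
on the log scale: the log-sd is the raw coefficient of variation sd/mean
and the log-mean is ln(mean) - log_sd^2 / 2 (the small-CV log-normal
approximation).  The published tables give no inter-measurement
correlations, so a single exchangeable correlation (default 0.7, a strong
common size factor) is used and is overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .allometry import AllometricModel
from .morphodata import (
    FOSSIL_SUBSET,
    AgeClass,
    Clade,
    CurveLandmarks,
    CurveState,
    MeasurementRecord,
    ValidationError,
)

__all__ = [
    "AllometrySimSpec",
    "CladeSimSpec",
    "CurveSimSpec",
    "clade_spec_from_reference",
    "gen_measurements",
    "gen_allometric_pairs",
    "gen_curve",
    "random_rotation",
]

#: Typical taxon name used on generated records, per clade.
_SIM_TAXON = {
    Clade.SMALL_APES: "Hylobates sim",
    Clade.LANGURS: "Presbytis sim",
    Clade.ODD_NOSED: "Nasalis sim",
    Clade.MACAQUES: "Macaca sim",
    Clade.FOSSIL: "Trinil sim",
}


@dataclass(frozen=True)
class AllometrySimSpec:
    """ln TL = intercept + slope * ln NH + N(0, sigma) for generation."""

    slope: float
    intercept: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("allometric residual sd must be >= 0")


@dataclass(frozen=True)
class CladeSimSpec:
    """Log-scale moments and allometry defining one clade's population.

    ``log_mean``, ``log_sd`` are per-measurement over ``subset`` (natural
    logs of mm); ``log_corr`` is the exchangeable-or-explicit correlation of
    the log measurements (unit diagonal, PSD).
    """

    clade: Clade
    n: int
    log_mean: np.ndarray
    log_sd: np.ndarray
    log_corr: np.ndarray
    allometry: AllometrySimSpec
    subset: tuple[str, ...] = FOSSIL_SUBSET

    def __post_init__(self) -> None:
        p = len(self.subset)
        lm = np.asarray(self.log_mean, dtype=float)
        ls = np.asarray(self.log_sd, dtype=float)
        lc = np.asarray(self.log_corr, dtype=float)
        object.__setattr__(self, "log_mean", lm)
        object.__setattr__(self, "log_sd", ls)
        object.__setattr__(self, "log_corr", lc)
        if lm.shape != (p,) or ls.shape != (p,):
            raise ValidationError("log_mean and log_sd must match the subset length")
        if np.any(ls < 0):
            raise ValidationError("log_sd must be non-negative")
        if lc.shape != (p, p) or not np.allclose(lc, lc.T):
            raise ValidationError("log_corr must be a symmetric p x p matrix")
        if not np.allclose(np.diag(lc), 1.0):
            raise ValidationError("log_corr must have unit diagonal")
        if np.min(np.linalg.eigvalsh(lc)) < -1e-8:
            raise ValidationError("log_corr must be positive semi-definite")
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if "NH" not in self.subset:
            raise ValidationError("subset must include NH (drives the allometry)")


def exchangeable_corr(p: int, rho: float) -> np.ndarray:
    c = np.full((p, p), rho)
    np.fill_diagonal(c, 1.0)
    return c


#: Fallback allometry for the clade with no published equation (odd-nosed):
#: isometric slope 1, intercept matched to the clade's mean TL/NH ratio,
#: residual sd a little under the clade's raw TL coefficient of variation.
_ODD_NOSED_ALLOMETRY = AllometrySimSpec(
    slope=1.0, intercept=math.log(233.6 / 18.26), sigma=0.07
)


def clade_spec_from_reference(
    clade: Clade,
    n: int | None = None,
    rho: float = 0.7,
    subset: Sequence[str] = FOSSIL_SUBSET,
) -> CladeSimSpec:
    """Moment-matched simulation spec for one extant clade.

    Location/scale come from the published per-clade means and standard
    deviations; sample size defaults to the published clade n.
    """
    from .reference import CLADE_STATS, PUBLISHED_ALLOMETRY  # local: avoid cycle

    clade = Clade(clade)
    if clade not in CLADE_STATS:
        raise ValidationError(f"no reference statistics for clade {clade.value!r}")
    stats = CLADE_STATS[clade]
    subset = tuple(subset)
    mean = np.array([stats["mean"][m] for m in subset])
    sd = np.array([stats["sd"][m] for m in subset])
    cv = sd / mean
    if clade in PUBLISHED_ALLOMETRY:
        pub = PUBLISHED_ALLOMETRY[clade]
        allo = AllometrySimSpec(slope=pub.slope, intercept=pub.intercept, sigma=pub.see)
    else:
        allo = _ODD_NOSED_ALLOMETRY
    return CladeSimSpec(
        clade=clade,
        n=int(n) if n is not None else int(stats["n"]),
        log_mean=np.log(mean) - cv**2 / 2,
        log_sd=cv,
        log_corr=exchangeable_corr(len(subset), rho),
        allometry=allo,
        subset=subset,
    )


def gen_measurements(
    spec: CladeSimSpec,
    seed: int,
    *,
    drop_tl: bool = False,
    id_prefix: str | None = None,
    clade_label: Clade | None = None,
) -> list[MeasurementRecord]:
    """Draw ``spec.n`` records; reproducible given ``seed``.

    ``clade_label`` relabels the output records (e.g. to mint a synthetic
    fossil from a known clade's generator) without changing the generating
    distribution.  ``drop_tl`` omits total length, mimicking a broken shaft.
    """
    rng = np.random.default_rng(seed)
    p = len(spec.subset)
    chol = np.linalg.cholesky(spec.log_corr + 1e-12 * np.eye(p))
    z = rng.standard_normal((spec.n, p))
    logs = spec.log_mean + (z @ chol.T) * spec.log_sd
    x = np.exp(logs)
    nh = x[:, spec.subset.index("NH")]
    a = spec.allometry
    log_tl = a.intercept + a.slope * np.log(nh) + a.sigma * rng.standard_normal(spec.n)
    tl = np.exp(log_tl)
    out_clade = Clade(clade_label) if clade_label is not None else spec.clade
    prefix = id_prefix if id_prefix is not None else f"{out_clade.value}"
    records = []
    for i in range(spec.n):
        values = dict(zip(spec.subset, (float(v) for v in x[i])))
        if not drop_tl:
            values["TL"] = float(tl[i])
        records.append(
            MeasurementRecord(
                specimen_id=f"{prefix}_{i:04d}",
                taxon=_SIM_TAXON.get(out_clade, f"{out_clade.value} sim"),
                clade=out_clade,
                age_class=AgeClass.ADULT,
                **values,
            )
        )
    return records


def gen_allometric_pairs(
    a: float,
    b: float,
    sigma: float,
    n: int,
    nh_range: tuple[float, float],
    seed: int,
) -> list[tuple[float, float]]:
    """(NH, TL) pairs with ln NH uniform on log(nh_range) and log-normal TL."""
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    if n < 3:
        raise ValidationError("n must be >= 3")
    lo, hi = nh_range
    if not (0 < lo <= hi):
        raise ValidationError("nh_range must be positive with lo <= hi")
    rng = np.random.default_rng(seed)
    ln_nh = rng.uniform(math.log(lo), math.log(hi), size=n)
    ln_tl = a + b * ln_nh + sigma * rng.standard_normal(n)
    return list(zip(np.exp(ln_nh).tolist(), np.exp(ln_tl).tolist()))


# ---------------------------------------------------------------------------
# Curves


@dataclass(frozen=True)
class CurveSimSpec:
    """A posed, noised quadratic landmark arc.

    ``kappa`` is the dimensionless mid-chord bow (sagitta over chord
    length); ``scale`` is the chord length in mm; ``pose`` an optional
    (rotation, translation) pair — when omitted a uniformly random rotation
    and a modest translation are drawn from the generation seed.
    """

    kappa: float
    noise_sd: float = 0.0
    scale: float = 100.0
    pose: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValidationError("kappa must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.scale <= 0:
            raise ValidationError("scale must be > 0")
        if self.pose is not None:
            rot, trans = self.pose
            rot = np.asarray(rot, dtype=float)
            trans = np.asarray(trans, dtype=float)
            if rot.shape != (3, 3) or trans.shape != (3,):
                raise ValidationError("pose must be a (3,3) rotation and (3,) translation")
            if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-8) or np.linalg.det(rot) < 0:
                raise ValidationError("pose rotation must be proper orthogonal")
            object.__setattr__(self, "pose", (rot, trans))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def gen_curve(
    spec: CurveSimSpec,
    seed: int,
    *,
    specimen_id: str = "sim_curve",
    taxon: str = "synthetic",
    clade: Clade = Clade.SMALL_APES,
) -> CurveLandmarks:
    """Ten landmarks on a quadratic arc, noised then rigidly posed (raw 3-D).

    Landmarks sit at chord fractions t = 0, 1/9, ..., 1 with off-chord
    height 4 * kappa * scale * t * (1 - t), so the arc's apex (at mid-chord,
    between landmarks 5 and 6) has sagitta kappa * scale.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, CurveLandmarks.N_LANDMARKS)
    pts = np.column_stack([
        t * spec.scale,
        4.0 * spec.kappa * spec.scale * t * (1.0 - t),
        np.zeros_like(t),
    ])
    if spec.noise_sd > 0:
        pts = pts + rng.normal(0.0, spec.noise_sd, size=pts.shape)
    if spec.pose is not None:
        rot, trans = spec.pose
    else:
        rot = random_rotation(rng)
        trans = rng.uniform(-50.0, 50.0, size=3)
    pts = pts @ rot.T + trans
    return CurveLandmarks(
        specimen_id=specimen_id, taxon=taxon, clade=clade,
        points=pts, state=CurveState.RAW3D,
    )
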