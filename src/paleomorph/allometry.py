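"""Per-clade log-log allometry of total femoral length on neck height.

The model is ordinary least squares on natural logs,

    ln TL = a + b * ln NH + eps,   eps ~ N(0, sigma^2),

fitted separately within each extant clade (the comparative sample is too
heterogeneous for a pooled fit, and the taxonomic question is precisely
which clade's scaling the fossil follows).  A fossil's total length is then
estimated by back-transforming the fitted log prediction at its preserved
neck height; the uncertainty band is the multiplicative one-SEE band
exp(prediction +/- SEE), which is asymmetric in mm as a log-scale band
must be.

Also provides the platymeric index, 100 * MTW / ATW below the lesser
trochanter: values well below 100 indicate an antero-posteriorly deep
(platymeric) shaft.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm

from .morphodata import Clade, MeasurementRecord, ValidationError

__all__ = [
    "AllometricModel",
    "LengthEstimate",
    "fit_loglog",
    "fit_clade_models",
    "estimate_length",
    "platymeric_index",
]


@dataclass(frozen=True)
class AllometricModel:
    """A fitted (or published) clade-specific log-log length model."""

    clade: Clade | None
    n: int
    slope: float
    intercept: float
    r: float
    see: float
    slope_ci95: tuple[float, float]
    intercept_ci95: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValidationError("an allometric model needs n >= 3")
        if not -1.0 <= self.r <= 1.0:
            raise ValidationError(f"correlation r = {self.r} outside [-1, 1]")
        if self.see < 0:
            raise ValidationError("SEE must be non-negative")
        lo, hi = self.slope_ci95
        if not lo <= self.slope <= hi:
            raise ValidationError("slope must lie inside its own 95% CI")

    def predict_log(self, nh: float) -> float:
        return self.intercept + self.slope * math.log(nh)


@dataclass(frozen=True)
class LengthEstimate:
    """Back-transformed fossil length estimate with one-SEE band (mm)."""

    tl_hat: float
    band_low: float
    band_high: float
    model_clade: Clade | None

    def __post_init__(self) -> None:
        if not (0 < self.band_low <= self.tl_hat <= self.band_high):
            raise ValidationError("length band must satisfy 0 < low <= hat <= high")


def fit_loglog(
    pairs: Sequence[tuple[float, float]], clade: Clade | None = None
) -> AllometricModel:
    """OLS of ln TL on ln NH with Pearson r, SEE and t-based 95% CIs.

    ``pairs`` are (NH, TL) in mm, all positive, at least three of them.
    SEE is the residual standard error sqrt(RSS / (n - 2)) on the log scale.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValidationError("need at least 3 (NH, TL) pairs")
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValidationError("all NH and TL values must be positive and finite")
    x = np.log(arr[:, 0])
    y = np.log(arr[:, 1])
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in ln NH: slope undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    n = len(x)
    see = float(np.sqrt(res.ssr / (n - 2)))
    ci = res.conf_int(alpha=0.05)
    # guard against r slightly outside [-1, 1] on perfectly collinear input
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0)) if np.ptp(y) > 0 else 0.0
    return AllometricModel(
        clade=clade,
        n=n,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r=r,
        see=see,
        slope_ci95=(float(ci[1, 0]), float(ci[1, 1])),
        intercept_ci95=(float(ci[0, 0]), float(ci[0, 1])),
    )


def fit_clade_models(
    records: Iterable[MeasurementRecord],
    clades: Sequence[Clade] = (Clade.SMALL_APES, Clade.LANGURS, Clade.MACAQUES),
) -> dict[Clade, AllometricModel]:
    """Fit one log-log model per requested clade from records with NH and TL.

    Fossil records never enter a fit.  By default the odd-nosed clade is not
    modelled: the fossil lies outside its morphometric range, so a length
    prediction from that clade would be an extrapolation without support.
    """
    records = list(records)
    out: dict[Clade, AllometricModel] = {}
    for clade in clades:
        clade = Clade(clade)
        if clade is Clade.FOSSIL:
            raise ValidationError("fossil records are never used to fit models")
        pairs = [
            (r.NH, r.TL)
            for r in records
            if r.clade is clade and r.NH is not None and r.TL is not None
        ]
        out[clade] = fit_loglog(pairs, clade=clade)
    return out


def estimate_length(model: AllometricModel, nh: float) -> LengthEstimate:
    """Estimate total length (mm) at neck height *nh* with exp(+/-SEE) band."""
    if not (nh > 0 and math.isfinite(nh)):
        raise ValidationError(f"neck height must be positive, got {nh}")
    log_hat = model.predict_log(nh)
    return LengthEstimate(
        tl_hat=math.exp(log_hat),
        band_low=math.exp(log_hat - model.see),
        band_high=math.exp(log_hat + model.see),
        model_clade=model.clade,
    )


def platymeric_index(atw: float, mtw: float) -> float:
    """Platymeric index 100 * MTW / ATW (dimensionless percent, unrounded)."""
    if not (atw > 0 and mtw > 0):
        raise ValidationError("ATW and MTW must both be positive")
    return 100.0 * mtw / atw
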