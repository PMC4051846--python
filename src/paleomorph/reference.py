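"""Published reference values for the Trinil 5703 attribution study.

These constants are inputs to the pipeline, transcribed from the study's
printed tables: the fossil's own calliper measurements, descriptive
statistics of the four-clade extant comparative sample (49 small apes,
18 langurs, 6 odd-nosed monkeys, 28 macaques), and the per-clade log-log
allometric regressions of total femoral length on neck height.  They
calibrate the synthetic-data generator and supply the coefficients for the
fossil length estimates when the raw comparative spreadsheets are not at
hand.
"""

from __future__ import annotations

from .allometry import AllometricModel
from .morphodata import MEASUREMENTS, AgeClass, Clade, MeasurementRecord

__all__ = [
    "TRINIL_RECORD",
    "CLADE_STATS",
    "PUBLISHED_ALLOMETRY",
    "PUBLISHED_LENGTH_ESTIMATES",
    "PUBLISHED_PLATYMERIC_INDEX",
    "PUBLISHED_PC12_VARIANCE_PCT",
    "PUBLISHED_LD1_VARIANCE_PCT",
    "PUBLISHED_CONFUSION_ROW_PCT",
    "PUBLISHED_CURVE_DISTANCES",
]

#: The fossil femur: eight preserved measurements (mm); total length is not
#: measurable on the broken shaft.
TRINIL_RECORD = MeasurementRecord(
    specimen_id="Trinil 5703",
    taxon="Trinil",
    clade=Clade.FOSSIL,
    age_class=AgeClass.UNKNOWN,
    LNW=9.93, UNW=10.44, ANW=7.53, NH=9.86,
    ATW=11.15, MTW=9.97, ADW=7.53, MDW=7.18, TL=None,
)

# Descriptive statistics of the comparative sample, mm, in canonical
# measurement order (LNW, UNW, ANW, NH, ATW, MTW, ADW, MDW, TL).
_ORDER = MEASUREMENTS

_RAW_STATS = {
    Clade.SMALL_APES: dict(
        n=49,
        mean=(10.60, 6.27, 8.96, 10.93, 12.71, 10.26, 9.72, 10.06, 190.9),
        sd=(2.072, 1.350, 1.332, 1.361, 1.532, 1.394, 1.369, 1.441, 20.096),
        min=(6.68, 3.95, 6.5, 8.57, 10.11, 7.95, 7.11, 6.93, 145.7),
        max=(15.02, 9.79, 11.66, 13.35, 15.19, 13.15, 12.02, 12.57, 221.1),
    ),
    Clade.LANGURS: dict(
        n=18,
        mean=(8.89, 5.04, 9.47, 13.31, 11.91, 11.29, 9.84, 10.32, 196.8),
        sd=(2.47, 1.596, 1.834, 1.519, 2.1, 1.9, 1.72, 1.662, 19.478),
        min=(4.46, 1.86, 7.12, 11.01, 7.78, 7.7, 6.35, 6.99, 175.6),
        max=(13.96, 8.0, 14.32, 15.64, 14.52, 13.77, 11.89, 12.78, 220.8),
    ),
    Clade.ODD_NOSED: dict(
        n=6,
        mean=(12.67, 7.335, 14.25, 18.26, 15.16, 15.38, 13.43, 13.87, 233.6),
        sd=(1.56, 1.230, 2.822, 2.186, 1.578, 1.595, 1.246, 1.316, 18.136),
        min=(11.18, 6.0, 10.68, 15.97, 13.1, 14.15, 12.35, 12.52, 217.0),
        max=(14.44, 8.95, 17.66, 20.54, 17.33, 17.65, 15.14, 15.91, 249.6),
    ),
    Clade.MACAQUES: dict(
        n=28,
        mean=(10.05, 7.06, 9.91, 11.54, 11.69, 11.12, 10.4, 10.84, 158.0),
        sd=(1.928, 1.273, 1.546, 1.847, 2.029, 1.685, 2.08, 1.934, 29.637),
        min=(6.77, 3.95, 7.5, 8.67, 8.53, 8.09, 7.29, 7.3, 117.4),
        max=(13.37, 11.66, 12.98, 15.17, 15.85, 14.05, 14.28, 13.95, 209.3),
    ),
}

#: clade -> {"n": int, "mean"/"sd"/"min"/"max": {measurement: mm}}
CLADE_STATS: dict[Clade, dict] = {
    clade: {
        "n": d["n"],
        **{
            stat: dict(zip(_ORDER, d[stat]))
            for stat in ("mean", "sd", "min", "max")
        },
    }
    for clade, d in _RAW_STATS.items()
}

#: Published per-clade allometric models, ln TL = intercept + slope * ln NH
#: (no model is published for the odd-nosed clade: the fossil falls outside
#: its morphometric range and no regression was reported for it).
PUBLISHED_ALLOMETRY: dict[Clade, AllometricModel] = {
    Clade.SMALL_APES: AllometricModel(
        clade=Clade.SMALL_APES, n=49, slope=0.709, intercept=3.554,
        r=0.796, see=0.091,
        slope_ci95=(0.524, 0.894), intercept_ci95=(3.112, 3.996),
    ),
    Clade.MACAQUES: AllometricModel(
        clade=Clade.MACAQUES, n=28, slope=1.110, intercept=2.344,
        r=0.94, see=0.234,
        slope_ci95=(0.910, 1.31), intercept_ci95=(1.857, 2.831),
    ),
    Clade.LANGURS: AllometricModel(
        clade=Clade.LANGURS, n=18, slope=0.549, intercept=3.859,
        r=0.64, see=0.095,
        slope_ci95=(0.011, 1.088), intercept_ci95=(2.467, 5.251),
    ),
}

#: Published point estimates (mm) of the fossil's total femoral length under
#: each clade model, evaluated at the fossil's neck height (9.86 mm).  The
#: langur value as printed (171) is not reproduced by its own printed
#: coefficients (which give 166.5); the small-ape and macaque rows are.
PUBLISHED_LENGTH_ESTIMATES: dict[Clade, float] = {
    Clade.SMALL_APES: 177.0,
    Clade.MACAQUES: 132.0,
    Clade.LANGURS: 171.0,
}

#: Published platymeric index of the fossil (100 * MTW / ATW below the
#: lesser trochanter).
PUBLISHED_PLATYMERIC_INDEX = 89.4

#: Published share of total shape variance on PC1+PC2 of the log-shape-ratio
#: ordination, percent.
PUBLISHED_PC12_VARIANCE_PCT = 64.57

#: Published share of discriminating variance on the first discriminant
#: function, percent.
PUBLISHED_LD1_VARIANCE_PCT = 88.82

#: Published cross-validated confusion matrix (row percent; rows = true
#: clade, columns = predicted), clade order macaques, small apes, langurs,
#: odd-nosed.
PUBLISHED_CONFUSION_ROW_PCT = {
    Clade.MACAQUES: {
        Clade.MACAQUES: 71, Clade.SMALL_APES: 14,
        Clade.LANGURS: 11, Clade.ODD_NOSED: 4,
    },
    Clade.SMALL_APES: {
        Clade.MACAQUES: 8, Clade.SMALL_APES: 88,
        Clade.LANGURS: 4, Clade.ODD_NOSED: 0,
    },
    Clade.LANGURS: {
        Clade.MACAQUES: 28, Clade.SMALL_APES: 0,
        Clade.LANGURS: 72, Clade.ODD_NOSED: 0,
    },
    Clade.ODD_NOSED: {
        Clade.MACAQUES: 50, Clade.SMALL_APES: 0,
        Clade.LANGURS: 17, Clade.ODD_NOSED: 33,
    },
}

#: Published fossil-to-taxon mean shaft-curvature distances in baseline
#: units, ascending.
PUBLISHED_CURVE_DISTANCES: dict[str, float] = {
    "Presbytis": 0.010,
    "Hylobates": 0.014,
    "Trachypithecus": 0.037,
    "Nomascus": 0.064,
    "Macaca fascicularis": 0.073,
    "Macaca nemestrina": 0.126,
}
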