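# paleomorph

Morphometric attribution of fragmentary primate femora.

When a fossil femur preserves only its proximal end — no total length, no
distal epiphysis — which clade did it belong to? This package implements
the full quantitative chain used to answer that question for partial
femora compared against extant Southeast Asian primates (small apes,
langurs, odd-nosed monkeys, macaques), with the Trinil 5703 gibbon femur
as the motivating case:

- **Allometry** — per-clade log-log regressions `ln TL = a + b·ln NH`
  estimate total femoral length from the preserved neck height, with
  multiplicative `exp(±SEE)` uncertainty bands, plus the platymeric index
  `100·MTW/ATW`.
- **Size-free shape** — Darroch–Mosimann log-shape ratios
  (`ln xᵢ − mean ln x`) remove isometric size; PCA ordination and
  cross-validated canonical LDA classify the fossil as a hold-out
  specimen, with the leave-one-out confusion matrix quantifying the risk
  of misattribution.
- **Shaft curvature** — ten-landmark 3-D chains are flattened per specimen
  and registered to a two-point (Bookstein) baseline at (0,0)–(1,0);
  fossil-to-taxon mean distances in baseline units rank the candidate
  taxa.
- **Synthetic data** — a generator calibrated to the published clade
  summary statistics (multivariate log-normal measurements, allometric TL,
  posed quadratic landmark arcs) makes the entire chain testable without
  the original specimen spreadsheets.

See `docs/methods.md` for the models, assumptions and design choices.

## Layout

Library in `src/paleomorph/` (measurement/landmark I/O and validation,
allometry, log-shape ratios, PCA/LDA classification, curvature, pipeline);
narrative drivers in `analysis/01_simulate.py` … `05_full_report.py`, each
writing its tables under `results/`; a `paleomorph` CLI with subcommands
`simulate | allometry | shape | classify | curvature | run`.

## Worked example

```
$ python analysis/01_simulate.py
$ python analysis/02_allometry.py
fossil platymeric index: 89.4

fossil length estimates from the published coefficients:
  small_apes   177.1 mm [162, 194]
  macaques     132.2 mm [105, 167]
  langurs      166.6 mm [151, 183]  (published table prints 171; its own coefficients give this)
...
```

The platymeric index of the fossil (ATW 11.15 mm, MTW 9.97 mm) is 89.4 —
a relatively rounded shaft, as in gibbons. Under the small-ape model the
fossil's neck height (9.86 mm) predicts a 177 mm femur; under the macaque
model, 132 mm — implausibly short given that the preserved fragment alone
approaches that length, which is one line of evidence against the macaque
attribution.

```
$ python analysis/03_shape_classification.py
PC1+PC2 share of shape variance: 67.36%
LD1 share of discriminating variance: 78.19%

leave-one-out confusion matrix (row %):
            small_apes  langurs  odd_nosed  macaques
small_apes          86        0          0        14
langurs              0       72         28         0
odd_nosed            0       17         67        17
macaques            29        0          7        64

fossil 'Trinil 5703' post-classified as: small_apes

$ python analysis/04_curvature.py
fossil-to-taxon mean-curve distances (ascending, baseline units):
  Hylobates sim    d = 0.008   (taxon mean bow 0.008)
  Presbytis sim    d = 0.009   (taxon mean bow 0.014)
  Nasalis sim      d = 0.015   (taxon mean bow 0.030)
  Macaca sim       d = 0.029   (taxon mean bow 0.052)
```

On the simulated dataset (seed 42) the held-out synthetic fossil — drawn
from the small-ape generator with its total length withheld — is
post-classified as a small ape, and its nearly straight shaft (bow 0.012
in baseline units) ranks the straight-shafted taxa nearest. The confusion
matrix shows where attributions of this kind are fragile: macaques and
small apes overlap most in size-free shape.

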