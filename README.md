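# replisort

Cell-cycle sorting of single nuclei from replication-foci images, and
per-nucleus colocalization by image cross-correlation spectroscopy (ICCS).

## The problem

DNA replication proceeds through S phase in a stereotyped spatial program:
euchromatin replicates early, heterochromatin later.  Labelling nascent DNA
with EdU produces punctate replication foci whose number, brightness and
arrangement change characteristically through S phase, so a *single optical
section* of the EdU channel is enough to stage each cell — no 3-D stack or
total-DNA quantification needed.  `replisort` implements this staging and
then measures, per nucleus, how strongly the replication foci colocalize
with a second channel (for example elongating RNA polymerase II marking
transcription), using ICCS, which needs no object pre-segmentation.

It is aimed at microscopists analysing confocal or STED images of cultured
cells: images in, per-cell CSV out.

## The method

For every nucleus *j* of a labelled count mask, two statistics are measured
on the binarized and raw EdU channel:

```
rho_RF(j) = N_RF / N_nuc            foci pixel density
I_RF(j)   = <I(x,y)>_foci pixels    mean foci intensity
```

Population-derived thresholds then sort the cells:

* **G1/G2**  if `rho_RF < rho_min`, with `rho_min = N_min / <N_nuc>`
* **Middle-S** if `rho_RF > rho_thr`, with `rho_thr = k_rho * max(rho_RF)`
* otherwise **Early-S** if `I_RF < I_thr`, **Late-S** if `I_RF > I_thr`,
  with `I_thr = k * min(I_RF)` over the Early-or-Late subgroup

and Early cells larger than `k_size * <N_nuc>` are excluded (they are very
late cells entering G2 that would masquerade as Early).  Defaults:
`N_min = 10` px, `k_rho = 0.4`, `k = 3`, `k_size = 1.2`.

For each S-phase nucleus, ICCS computes masked spatial auto-correlation
functions of the two channels and their cross-correlation function,

```
G_ab(xi, eta) = <dI_a(x,y) dI_b(x+xi, y+eta)> / (mu_a mu_b)
```

fits `G(r) = B exp(-r^2/w^2) + G_inf` to each radial profile (zero lag
excluded), and reports the colocalization fractions

```
f1 = B_cc / B_22      f2 = B_cc / B_11
```

which run from 1 (maximal cross-correlation) through 0 (independence) to
negative values (anti-correlation).

A synthetic-scene generator (disk nuclei, phase-specific Gaussian foci, PSF
blur, Poisson + Gaussian noise, controllable ground-truth colocalized
fraction φ) makes the whole pipeline testable without microscopy data.

## Worked example

Simulate a 20-nucleus scene, segment it, sort it, and run ICCS (ground-truth
colocalized fraction φ = 0.5 for every phase):

```
$ replisort simulate --seed 1 --n-nuclei 20 --out scene
$ replisort segment --dna scene/dna.tif --out mask.tif
20 nuclei -> mask.tif
$ replisort sort --mask mask.tif --rf scene/rf.tif --out cells.csv
phase
MIDDLE      6
G1G2        5
LATE        4
EARLY       3
EXCLUDED    2
$ replisort iccs --cells cells.csv --mask mask.tif --rf scene/rf.tif \
      --tf scene/tf.tif --out cells_iccs.csv
$ replisort report --cells cells_iccs.csv
   phase  n     mean      sem   median      iqr
   EARLY  3 0.494290 0.073325 0.500225 0.126898
    LATE  4 0.382186 0.063183 0.326532 0.077211
  MIDDLE  6 0.290427 0.058346 0.268140 0.052877
EARLY vs MIDDLE: U=16.0 p=0.0952 (exact, n=3/6)
```

The sorter recovered all four groups (two oversized Early candidates were
excluded by the size guard), and with φ = 0.5 everywhere the group-mean f1
values all sit near 0.3–0.5, as they should: the per-group differences here
reflect focus-density differences, not a built-in colocalization contrast.
The `run` subcommand executes the same steps for a whole multi-frame batch
from a YAML config, pooling all frames before deriving thresholds and
writing `cells.csv`, `summary.csv`, `scatter.png` and a reproducible
`manifest.yaml`.

From Python the same pipeline is three calls: `generate_scene` /
`read_image_set` → `analyze_frames` → `records_frame`; the sorter itself is
a scikit-learn estimator (`CellCycleSorter().fit_predict(measurements)`).

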