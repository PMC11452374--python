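# Methods

## Scope and data model

`replisort` analyses single 2-D optical sections of multi-channel
fluorescence images: a DNA counterstain (segmentation), a replication-foci
channel (EdU; staging and ICCS channel 1) and optionally a transcription-
foci channel (ICCS channel 2).  The unit of iteration is the nucleus,
carried as an integer-labelled count mask; every per-cell quantity becomes
one row of the output table.  Mitotic cells are not detected automatically;
they are removed via a user-supplied `excluded_labels` list on the mask.

## Pre-processing

* **Segmentation.**  Global isodata (iterative intermeans) threshold on the
  DNA channel, optional hole filling (nucleoli would otherwise fragment
  masks), 8-connected components, minimum area 500 px at the default 45 nm
  pixel size (~1 µm²).  Pixels exactly at a threshold are foreground
  throughout the package.
* **Foci binarization.**  The raw replication-foci image is thresholded at
  `factor x background_level`, default factor 1.5.  The background level is
  the median raw foci-channel intensity over pixels of EdU-negative (G1/G2)
  reference nuclei of the first frame; the median is robust to residual
  foci.  Reference nuclei can be given explicitly; otherwise the dimmest
  quartile of first-frame nuclei (ranked by mean foci-channel intensity) is
  used as a first-pass G1/G2 set.  An absolute threshold override exists
  because the 1.5 factor is a per-experiment calibration, not a universal
  constant; within a batch one threshold is used for all frames.
* **Background subtraction.**  Rolling-ball (radius 10 px) background is
  subtracted from intensity images before intensity averaging and ICCS;
  output clipped at 0.

## Sorting rules

Measurements per nucleus: `N_nuc` (mask pixels), `N_RF` (binary-foci pixels
inside the mask), `rho_RF = N_RF/N_nuc`, `I_RF` = mean background-subtracted
foci intensity over the foci pixels (0 when there are none).

Thresholds are statistics of one analysis batch (all frames pooled, all
non-excluded nuclei) and are never reused across batches:

| constant | default | meaning |
|---|---|---|
| `N_min` | 10 px | minimum foci pixels to count as containing foci; `rho_min = N_min/<N_nuc>` |
| `k_rho` | 0.4 | `rho_thr = k_rho * max(rho_RF)` separates Middle |
| `k` | 3 | `I_thr = k * min(I_RF)` over the Early-or-Late subgroup |
| `k_size` | 1.2 | Early cells with `N_nuc > k_size * <N_nuc>` are excluded |

Tie handling (the defining inequalities are strict on both sides, so
equality needs a convention): a density exactly at `rho_min` enters the
S-phase subgroup, exactly at `rho_thr` is Middle, an intensity exactly at
`I_thr` is Early — each boundary is assigned to the group whose threshold
was derived from that side's extremum.  A single-cell subgroup is
necessarily Early (its own intensity is the subgroup minimum) and is
flagged `singleton-subgroup`.  The subgroup minimum for `I_thr` is taken
before the size exclusion is applied.  `<N_nuc>` averages all non-excluded
nuclei of the batch — the staging literature does not restrict it to one
group, and the mixed-population mean keeps `rho_min` stable across batches
with different phase composition.  Because `rho_thr` depends on the
observed maximum density, a single outlier can shift it; an optional
absolute cap `rho_thr_max` is available but off by default.

The sorter is deliberately unable to split G1 from G2 (that needs total DNA
content from a z-stack) and defines Early/Late narrowly as the low-density
tails of S phase.  The `total_content` operation provides the z-stack
cross-validation table (per-nucleus summed EdU and DNA over sections) for
checking the sorted groups against the conventional staging axis.

## ICCS

Correlations are computed per nucleus on a bounding-box crop padded by 8 px.
Masked normalization: means are taken inside the nucleus mask, fluctuation
products are summed per lag by FFT, and each lag is divided by the number
of in-mask pixel pairs at that lag (the autocorrelation of the mask
indicator) and by `mu_a*mu_b`.  This keeps G unbiased for irregular nuclear
shapes, unlike zero-padding with global means.  Lags with fewer than
`min_overlap` (default 200) pairs are dropped; default maximum lag 32 px.

The zero lag is excluded from fitting because uncorrelated shot noise
inflates only the ACF there.  The radial profile (integer-rounded bins,
weighted by bin counts) is fitted with `G(r) = B exp(-r^2/w^2) + G_inf`,
width bounded to [0.5, max_lag] px, amplitude free in sign; initialisation
`B = G(1) - tail`, `w = 2` px, `G_inf` = mean of the outermost three bins.
A 1-D radial fit is used rather than a 2-D elliptical one: the simulated
and biological spot correlations are close to isotropic and the radial
average is more stable at the per-nucleus pixel counts involved.

Fractions use fitted amplitudes (not raw zero-lag values):
`f1 = B_cc/B_22`, `f2 = B_cc/B_11` — the classical fraction-colocalized
convention, which keeps f1 and f2 distinct; a symmetric Pearson-style
option `B_cc/sqrt(B_11 B_22)` is provided, and at raw zero lag that form
reduces exactly to the Pearson coefficient over mask pixels (a property the
test suite pins to 1e-12).  Negative cross-amplitudes propagate into
negative fractions; nothing is clamped, and |f| > 1 from fit noise is
flagged `out-of-range` rather than altered.  Nuclei with fewer than
`N_min` foci pixels are skipped (`insufficient-foci`); border-touching
nuclei are processed with their available pixels and flagged; any
per-nucleus failure becomes a qc flag, never a batch abort.

## Synthetic scenes

The generator emulates the pipeline's input structure: non-overlapping disk
nuclei (radius 24 ± 2 px by default — compact stand-ins for ~10 µm nuclei,
chosen to keep default scenes fast rather than to match 45 nm sampling),
phase-specific replication foci as isotropic Gaussian spots, a second foci
channel with ground-truth colocalized fraction φ (that fraction of its foci
is placed exactly on replication-focus coordinates,
`round(phi*min(n_RF, n_TF))` per nucleus), Gaussian PSF blur (σ = 1 px),
then Poisson noise over signal plus background (100 counts) and additive
Gaussian read noise (σ = 2).  The background is set high enough that its
Poisson fluctuations stay well below the 1.5x binarization threshold —
mimicking the high-background-SNR regime real staging operates in; with a
low-count background the threshold would sit ~1σ above the mean and
EdU-negative nuclei would accumulate false foci pixels.

Focus archetypes (amplitudes in multiples of a 300-count base):

| phase | foci | σ (px) | amplitude |
|---|---|---|---|
| G1/G2 | 0 | – | – |
| Early | 15 | 1.5 | 1x |
| Middle | 120 | 1.5 | 2x |
| Late | 6 | 2.0 | 6x |

These are simulator defaults, not biological measurements.  The Late
archetype is kept sparse enough that its binarized footprint
(≈ n·2πσ_eff²·ln(peak/threshold)) stays below `k_rho` times the Middle
coverage — with many large bright spots the Late density would cross the
Middle boundary for any nucleus size, because footprint area grows with
the logarithm of the amplitude-to-threshold ratio.  Middle and Late foci
are biased toward the nuclear rim (radial placement weight), Early foci are
uniform, approximating the euchromatin/heterochromatin disposition without
modelling chromatin texture.  Foci are sampled out to the full nuclear
radius: confining them to an inner disk would imprint a shared dark rim on
both channels and fake positive cross-correlation between independent
patterns.

One RNG sub-stream per nucleus (plus one for placement, one for detection
noise) is spawned from the scene seed, so scenes are bit-reproducible and
adding nuclei does not perturb earlier ones.

What the scenes do *not* model: chromatin texture, 3-D structure, realistic
PSF physics (resolution enters only through σ_PSF), spectral bleed-through,
spatially varying background, nucleus shape variability.  Passing tests
therefore demonstrate the correctness and calibration of the algorithms on
their stated model, not performance on any particular microscope's data.

## Numerical and degenerate-input choices

* All operations are deterministic; identical inputs give bit-identical
  outputs, and the batch manifest (YAML) reproduces a run exactly.
* Correlation requires ≥ 100 mask pixels, a nonzero in-mask mean and
  nonzero in-mask variance; violations raise per-nucleus errors that the
  batch layer converts to qc flags.
* Gaussian fits need ≥ 5 usable radial bins; non-convergence yields missing
  fractions, never exceptions.
* Mann–Whitney comparisons use the exact null when `min(n) <= 8` with no
  ties, else the normal approximation with tie and continuity correction;
  zero-variation inputs short-circuit to p = 1 with a `no-variation` flag.
  Group summaries report mean ± s.e.m. plus median and IQR; p-values are
  raw (no multiple-testing correction), which is stated here rather than
  silently assumed.
* Problem sizes in the test and acceptance runs (60-nucleus scenes, 20-seed
  averages, 200-foci nuclei) are the package's default study conditions;
  they were chosen as the smallest populations at which the population
  thresholds and correlation averages are stable.

## Known limitations

* The sorter cannot distinguish G1 from G2, and medium-density nuclei are
  all "Middle" — the Early/Late windows are deliberately narrow.
* `rho_thr` tracks the densest nucleus in the batch; heavily censored or
  tiny batches can make the subgroup empty or a singleton.
* ICCS assumes approximately isotropic, roughly Gaussian spot correlations;
  strongly anisotropic structures would call for a 2-D elliptical fit.
* The 1.5x binarization factor is a per-experiment calibration; the package
  exposes it (and an absolute override) instead of guessing a tuning rule.
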