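# Methods

## The generative model

Each well starts with `n_cells` (default 850; imaging benchmarks use 25 —
see *Problem sizes*) independent cells and evolves in discrete 0.5 h steps
from 4 h to 72 h post-transfection, matching a 30-min imaging interval.
Per step an interphase cell:

- enters mitosis with probability `r·m(t)·dt`, where `r` is the baseline
  division rate (default 0.03 /cell/h, i.e. a ~23 h doubling time typical
  of HeLa) and `m(t)` the phenotype's rate multiplier;
- dies with probability `d·dt` (background interphase death,
  default 0.001 /h).

A mitosis normally lasts 1 h and ends in division (two daughters). Under
a `mitotic_arrest` phenotype, an entering cell instead arrests with the
phenotype's probability; arrest durations are uniform on (2, 10] h — the
biology gives only the ~10 h cap, so the simplest law consistent with it
is used — and resolve into mitotic death, mitotic exit or cytokinesis
failure according to the fate mixture. A `viability` phenotype multiplies
the entry rate by `1 − effect`. Phenotypes act only after a penetration
delay (default 12 h post-transfection, consistent with knockdown
phenotypes peaking late in the movie); the delay is measured from
transfection, not from the start of imaging.

The default fate mixture is 42% arrest→mitotic death, 28% arrest→mitotic
exit, 5% arrest→cytokinesis failure and 25% direct apoptosis (interphase
death at 12–24 h, no prior arrest). `assign_fates` draws standalone
phenotypic cell histories from this mixture with arrest entries uniform
on [12, 60] h so that every arrest resolves within the movie.

Two execution paths share this law exactly:

- **fast path** (`simulate_well_counts`): tracks only per-well cell
  counts, with a delay line for the 1 h mitosis; cells that arrest leave
  the proliferating pool and never contribute a track split. Lognormal
  well-to-well variability (log-sd 0.1, a typical high-content-screening
  plate CV) multiplies the division rate. A whole 9-plate screen
  simulates in under a second.
- **per-cell path** (`simulate_well`): full event logs with positions.
  A test verifies the per-cell division count falls inside the fast
  path's 99% band.

### Spatial model and rendering

Cells are seeded at ≥2 nucleus radii spacing (nuclei are 8 µm by
default), random-walk with 2 µm/frame Brownian steps inside a reflective
margin, and softly repel below 2 radii with a capped push (≤0.3 radius
per frame) so no cell ever moves further between frames than a tracker
could follow. Mitotic cells stop moving — real cells round up — which
also pins the parent's last observed position at the division site.
Daughters appear 1.4 radii either side of the parent along the
least-crowded of eight candidate axes (out-of-bounds placements
penalized), with a final ≤0.5-radius nudge off any crowding neighbour:
divisions stay resolvable by the segmenter. The event log carries the
exact per-frame trajectory (`log.tracks`), so the renderer and all ground
truth share one geometry.

Rendering: nuclei are Gaussian blobs (σ = 0.5 radius) in the H2B channel;
mitotic cells condense (0.7σ, 2× brighter), dying cells shrink over their
last hour and fragment into four dim blobs for an hour after death, cells
that failed cytokinesis render 1.25× enlarged (binucleate), and a division
replaces one blob with two separating blobs. Tubulin renders as a broad
dim halo and is decorative — it is not segmented. Gaussian read noise
(σ = 5) rides on a background of 100 counts.

## Imaging analysis

Segmentation per frame: Gaussian smoothing (σ = 2 px) → global Otsu
threshold (synthetic illumination is uniform, so local thresholding adds
nothing) → watershed seeded at smoothed-intensity maxima ≥5 px apart →
area filter at 25% of the nominal nucleus area (50 px²). Intensity maxima
are used as markers rather than distance-transform maxima because for
Gaussian-profile nuclei the distance transform of a merged three-cell
cluster has a single central peak, while the intensity still shows one
mode per nucleus. A frame whose thresholding keeps >25% of pixels is
treated as object-free (Otsu on pure noise splits the noise
distribution). An all-constant frame yields an empty mask. Coordinates
are 0-based pixels, x = column.

Tracking: greedy mutual-nearest-neighbour linking with a deliberately
tight gate of 1 nucleus radius (8 px) — frame-to-frame motion is a few
pixels while daughters appear ~1.4 radii away, so a division ends the
parent track instead of linking through a daughter. A track claimed as
nearest by ≥2 objects within twice the gate is left unlinked (division
ambiguity). Tracks tolerate one missed frame. A mitosis is then detected
when a track ends at frame f and ≥2 unconsumed tracks begin within 2
frames and 2 radii of its last position; the two nearest (ties by
distance, then track id) become the daughters. MitosisCount is the number
of such events per well. Apoptotic terminations are track ends (away from
the last frame) whose area collapsed by >50% over the final two
observations with no split.

## Screen scoring

Primary screen: `z = (median − x)/(1.4826·MAD)` per plate with median and
MAD taken over **sample wells only** (the normalization is defined
against the sample-well median, and the duplicated controls would
otherwise contaminate their own reference). The numerator is inverted so
reduced MitosisCounts score positive; z ≥ 2 is inclusive. MAD = 0 raises
an error unless the caller opts into an SD fallback (logged). Hit rules:
bioinformatic = ≥2 siRNAs at z ≥ 2; manual = ≥3 siRNAs scoring ≥3 or ≥2
scoring ≥4. Manual scores are synthesized from the latent effect as
`clamp(round(1 + 4·effect + N(0, 0.5)), 1, 5)` — the real scores are
human judgements; this ordinal link is the package's own choice and only
its monotonicity matters downstream.

Validation screen: wells are normalized as raw MitosisCount over the
median of the plate's negative controls (raw/mnc; the re-arrayed plate
median is not a null reference). A target validates when ≥2 of the
siRNAs *that had a primary effect* (counted toward either primary rule —
z ≥ 2 or manual ≥ 3) show raw/mnc ≤ 0.8 **or** manual ≥ 3; the OR is
applied per siRNA.

`mitoscreen.fixtures` packages synthetic reference candidate tables whose
call arithmetic reproduces the screen bookkeeping this package targets
(27 bioinformatic + 35 manual hits, overlap 13, union 49; 26 validated,
of which 16 by each criterion and 6 by both). The values in those tables
are constructed, not measured; only the combinatorial structure is
meaningful.

In fully simulated screens the bioinformatic and manual hit sets overlap
more than in a real screen, because both readouts derive from the same
latent effect; real manual scoring detects phenotype classes (late
arrests, nuclear morphology) the MitosisCount misses.

## Fate analysis

A mitosis longer than 2 h (2× the ~1 h normal duration; the biology gives
no numeric cutoff, so the threshold is exposed in `FateThresholds`)
counts as prometaphase arrest, and the first arrest's resolution labels
the cell. Interphase death with no prior arrest is direct apoptosis.
Cells whose mitoses all complete normally — or with no events at all —
are `normal`; anything unresolved (e.g. a mitosis censored by the end of
the movie) is `other`. Fate profiles divide by phenotypic cells only
(`normal`/`other` excluded), matching a quantification "among phenotypic
cells". Time courses report, at each requested time, the fraction of
alive cells currently in mitosis and cumulative deaths over the initial
cell number.

## Pulldown proteomics

iBAQ = Σ(peptide intensities)/n_theoretical per protein. Enrichment uses
log2((target + 1)/(mean(controls) + 1)) with a detected-in-target
requirement and a ≥1 log2 threshold; the pseudocount and threshold are
package choices (no published rule exists for this step) and are
configurable. The two control pulldowns are averaged with the mean, not
the median, as two values have no useful median distinct from their mean.
Term over-representation is the exact hypergeometric upper tail with
Benjamini–Hochberg FDR across tested terms; terms with no members in the
universe are skipped.

## Problem sizes and verification

- Screen-level statistics run on full-size plates (384 wells, 850
  cells/well, 9 plates for the default library; 20 plates for the control
  performance metrics) via the fast path.
- Imaging benchmarks use 25 seed cells in a 256 px field over 4–28 h
  (≈100 cells and 30–40 divisions by the end). The nominal 850-cell well
  cannot be rendered in this field at 8 µm nuclei (the nuclei would cover
  ~2.6× the field area); the chosen density is the package's benchmark
  operating point. At it, pooled over three seeds, split detection
  reaches ≈0.98 recall and ≈1.00 precision against the rendering ground
  truth, per-frame object counts match the true alive-cell count in ≈98%
  of frames, and the imaging-path MitosisCount agrees with the event-log
  count within ~2%.
- Brute-force oracles back the statistics: exhaustive truth tables for
  the hit-calling rules, enumeration of all draws for the hypergeometric
  tail (N ≤ 12), hand-recomputed robust-z examples, and an independent
  count-recursion for the branching model.

## What the synthetic data does not capture

No off-target seed effects, no photobleaching or illumination drift, no
cell migration out of the field, no 3D structure, no segmentation-relevant
debris, and nuclei interact only by soft exclusion. Manual scores are a
noisy monotone link to a scalar latent effect, not a human judgement over
distinct phenotype classes. Passing tests therefore demonstrate the
*analysis* is correct under a faithful-but-idealized image formation
model; they do not certify performance on real microscope data, where
segmentation and tracking errors dominate.
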