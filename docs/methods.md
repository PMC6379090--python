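# Methods

`notchtrack` quantifies Notch-reporter dynamics in *Drosophila* type I
neuroblast (NB) lineages from two-channel time-lapse movies: a ubiquitous
nuclear histone marker (red, His2Av-RFP-like) used for segmentation and
tracking, and a Notch-target transcriptional reporter (green,
E(spl)mγ-GFP-like) whose per-cell levels are the scientific read-out.  This
note documents the model behind the synthetic-data generator, the analysis
chain, the numerical choices, and what the validation suite does and does
not demonstrate.

## Biological model encoded by the simulator

Type I NB lineages follow a stereotyped program:

* the NB divides asymmetrically every few hours, self-renewing as the larger
  daughter and producing a smaller ganglion mother cell (GMC);
* each GMC divides exactly once, ~4 h after birth, into two equal-sized
  post-mitotic neurons;
* reporter expression is high in the NB, modulated over the cell cycle with
  peaks immediately after mitosis (early G1) and just before the next
  mitosis (late G2), and decays exponentially in newly born GMCs;
* under constitutively active Notch (condition `NACT`), progeny older than
  8 h can re-acquire the stem-cell programme: they grow to a size
  intermediate between GMC and NB, re-express the reporter (the size change
  precedes the expression change), and then divide asymmetrically with only
  the larger daughter keeping expression;
* under additional Mi-2/NuRD depletion (condition `NACT_MI2I`), a
  configurable fraction of lineages (default 0.278) shows persistent GMC
  expression: GMCs hold the reporter from birth and, if they divide within
  the movie, both daughters retain it.

Because a 10–14 h movie is too short for a cell born during imaging to pass
the 8 h age gate *and* divide again before the end, reactivation-competent
progeny are seeded at negative birth times (they exist at movie start).
This mirrors the observation that reactivation occurs only in progeny born
before the onset of imaging, and it means reactivating cells are roots of
their own measured trees — their true birth time is only known to the
simulator, which is why the reactivation age-gate checks compare detected
onsets against ground-truth births.

### Generator parameters (defaults)

| parameter | default | unit | rationale |
|---|---|---|---|
| `duration_hours` | 12 | h | middle of the 10–14 h imaging window |
| `frame_interval_min` | 10 | min | resolves mitoses at 61–85 frames per movie |
| `nb_cycle_hours` ± jitter | 2.0 ± 0.25 | h | several NB divisions per movie |
| `gmc_division_delay_hours` | 4.0 | h | GMC divides ~4 h after birth |
| `reactivation_min_age_hours` | 8.0 | h | progeny age gate for re-expression |
| `persistence_fraction` | 0.278 | – | fraction of persistent lineages under Mi-2 depletion |
| `nb/gmc/neuron/nb_like_radius_px` | 7 / 4.5 / 3.5 / 6 | px | NB > NB-like > GMC > neuron ordering |
| `gmc_decay_rate_per_hour` | 0.5 | 1/h | visible decay within one GMC lifetime |
| `nb_baseline_green` | 50 | a.u. | arbitrary units; only ratios matter |
| `cycle_amplitude`, `cycle_bump_width` | 0.8, 0.1 | – | raised-cosine peaks at phase < 0.1 and > 0.9 |
| noise | offset 10, read-noise SD 5, Poisson gain 1, PSF σ 0.8 px | a.u. | read noise = 5 % of the nuclear red density (100) |

Intensities are arbitrary units throughout: no absolute reporter brightness
or camera calibration is modelled, so only ratios, shapes and
classifications are meaningful — which is exactly why traces are normalised
to the movie average before any thresholding.

Mitosis is rendered as an abrupt replacement of the mother by the two
daughters at a frame boundary, preceded by mitotic rounding (the mother's
radius swells ×1.2 in its last frame).  No cleavage furrow, polarity
crescents, photobleaching, stage drift or z-anisotropy in the rendering are
simulated; voxels are isotropic by default and anisotropy enters the
analysis only through the `z_scale` distance factor.  Cells perform a small
random walk (σ 0.25 px/frame) with soft repulsion maintaining a centre
separation of `separation_factor` × mean radius (default 3 ×, i.e. 1.5 × the
sum of radii); daughters are placed within the tracking radius of the
mother's last position, as real daughters are.  These are the regimes in
which the acceptance guarantees hold; real movies with dense tissue,
z-anisotropic PSFs, fluctuating focus or cell deaths are harder than
anything the generator emulates, so the passing suite demonstrates
correctness of the computations, not performance on arbitrary microscopes.

## Segmentation

Per frame, on the red channel: cubic median filter (radius 1) → per-frame
Otsu threshold (fixed-threshold escape hatch available) → morphological
Chan–Vese refinement (two-phase, piecewise-constant, fixed iteration budget,
run per connected component inside a padded bounding box — identical for
separated nuclei and much faster than whole-volume evolution) → 3D watershed
on the negated anisotropy-scaled Euclidean distance transform, seeded at its
h-maxima (depth 2 px) → components below `min_volume_voxels` removed (default
90 ≈ half the volume of the smallest simulated neuron) and labels renumbered.

Numerical choices worth knowing:

* **Curvature smoothing is off by default** (`contour_smoothing = 0`): the
  sup-inf smoothing sweeps of morphological Chan–Vese shave one to two voxel
  layers off nuclei of radius ≤ 4 px, enough to push neurons below the
  volume filter.  With bright nuclei on dark background the region energy
  alone is stable.
* **Otsu collapse guard**: on a frame without nuclei, Otsu splits the
  background noise in half and the "foreground" percolates into one giant
  component.  A mask covering more than `max_foreground_fraction` (default
  25 %) of the volume — nuclei are sparse — is treated as an empty frame
  with a warning.  A truly constant frame raises a degenerate-input error.
* **Seeding depth vs geometry**: h-maxima depth must lie below the
  distance-transform saddle depth of the most-overlapping pair to be split;
  the default 2 px separates touching nuclei but deliberately does not split
  deeply interpenetrating spheres (which real nuclei cannot form).

Per-label measurements: centroid, voxel volume, equivalent spherical
diameter (6V/π)^{1/3}, and the mean of each channel over exactly the label's
voxels.

## Tracking

Greedy nearest-neighbour linking with gap closing: frames in increasing
order; at frame t the candidate predecessors are open track ends at frames
t−1 … t−5 (`max_gap_frames`), nearer gaps exhausted before farther ones;
within a gap level, pairs are assigned greedily in ascending distance (ties:
lower label).  Distances are Euclidean on (z·`z_scale`, y, x) centroids with
an inclusive 12 px radius.  The radius is a fixed length in pixel units, not
scaled by gap length, and is interpreted in 3D with `z_scale` (whether the
original analysis worked in 2D projections is unknowable from the published
description; the 3D reading is the package's choice).  Consequence of the
window arithmetic: a hole of k missing detections produces a link spanning
k+1 frames, so holes up to 4 frames are bridged and a 5-frame hole splits
the track — this is the literal reading of "search in the five previous
frames" and matches the link-table invariant gap ≤ 5.

A validation-only exhaustive linker (`link_frames_exhaustive`) enumerates
all feasible assignments per gap level and keeps a maximum-cardinality,
minimum-total-distance assignment; on physically sensible instances
(non-interpenetrating nuclei, ≤ ~1.5 px/frame drift) the greedy linker
reproduces its track partition essentially always, bounding the cost of
greediness.

**Division detection.**  Nuclei round up before mitosis and the daughters
are distinctly smaller, so a mitosis has a size signature.  Two cases are
recognised, each requiring every daughter to lie within the search radius
and window of the mother's last observation and to satisfy
daughter diameter ≤ `division_size_ratio_max` (default 0.95) × mother
diameter:

1. an unmatched track end with ≥ 2 orphan candidates — the two nearest
   orphans become daughters;
2. a track end whose forward link shows the mitotic size drop, with at least
   one additional size-qualifying orphan — the link is reinterpreted as a
   division (replaced by two division edges).

Case 2 is essential, not cosmetic: daughters are born within the search
radius of the mother, so plain nearest-neighbour linking always links the
mother's end to the nearest daughter first; without the reinterpretation no
division could ever be detected by an orphan-pair rule alone.

Manual corrections enter as an ordered edit list (`add_link`, `remove_link`,
`set_division`); each edit is validated against every link-table invariant
(gap window, radius, in/out-degree discipline) and rejected with an error
naming the violated invariant.

**Normalisation.**  `mean_green_norm = mean_green / M`, with M the movie-wide
arithmetic mean of the per-cell green means.  Using the per-cell mean (not
the mean over all voxels) makes the normalisation invariant to how much
empty background is in the field of view; either way the normalised values
average exactly 1 and all downstream classifications are invariant to global
intensity scaling between movies.

## Lineage analysis

Tracks become tree nodes; division events become mother→daughter edges;
daughter birth times are the mitosis frame.  Role classification: a root
whose initial diameter (median of its first 3 samples) reaches the
GMC/NB-midpoint is the NB; at each division of an NB/NB-like node, the
larger-median-diameter daughter inherits the stem identity and the smaller
is a GMC; a GMC whose two daughters are terminal and similar-sized
(diameter ratio ≥ 0.8) produced neurons; a non-NB node whose (3-sample
rolling-median) diameter rises above the midpoint of the configured GMC and
NB diameters and that later divides asymmetrically is NB-like.  Small roots
(pre-existing progeny) start UNKNOWN so that they remain eligible for the
NB-like upgrade — with reactivation restricted to progeny born before
imaging, NB-like cells are necessarily roots of their own measured trees.

Trace read-outs (thresholds are explicit parameters; the corresponding
published scoring was done by eye, so these are the package's documented
decisions, not fidelity claims):

* **GMC decay**: log-linear least squares on samples above a floor (default:
  the trace's 5th percentile), giving a decay rate (1/h), half-life ln2/k
  (reported as none when the rate is ≤ 0 within 1e-9), and r².  Log-linear
  rather than nonlinear fitting keeps the estimate deterministic and
  initialisation-free.
* **Cell-cycle profile**: samples in each complete inter-division interval
  (t_prev, t_next] map to phase (t−t_prev)/(t_next−t_prev); per-bin means
  over all complete cycles (default 20 bins); incomplete first/last cycles
  excluded.
* **Persistence**: a lineage is persistent iff some GMC born during the
  movie holds `mean_green_norm` ≥ θ × (median level along its NB chain) for
  at least τ after birth, with θ = 0.5 and τ = 4 h (one GMC lifetime).  A
  GMC not observed to within one frame interval of birth+τ cannot qualify.
* **Reactivation onset**: first sample at/above `reactivation_on_theta`
  (default 0.3, normalised units) following an observed quiet period of
  ≥ 2 h below `reactivation_off_theta` (0.15).  Monotone-decaying traces and
  traces high from birth (persistence) return none — the two phenotypes are
  disjoint by construction.  The on/off defaults assume the usual movie
  composition (NB normalised level ≈ 3–5, decayed progeny ≪ 0.15); they are
  per-movie tunables, not constants of nature.

## Count statistics

Box summaries use linear-interpolation percentiles (the IQR depends on the
method, so it is fixed and documented), SEM with the n−1 sample SD, whiskers
at q1 − 1.5·IQR and q3 + 1.5·IQR clipped to the data range.  Group
comparisons use Welch's unequal-variance two-sided t-test (group sizes in
this kind of data are rarely equal) with conventional nested star bands
(\*p<0.05, \*\*p<0.01, \*\*\*p<0.001, \*\*\*\*p<0.0001); published figure
legends sometimes print the second band as "0.001 < P < 0.05", which
overlaps the first — the conventional nesting is used here and the
discrepancy is noted rather than resolved.  Fold changes are ratios of
condition means presented at one decimal.  Wet-lab counts are inputs to this
module; nothing in the package claims to regenerate them.

## Determinism and problem sizes

All randomness flows from explicit seeds: a lineage is a pure function of
`(config, lineage_seed)`, rendering of `config.rng_seed`, and the pipeline
derives per-stage seeds from the single run seed, so identical config + seed
give byte-identical outputs.  The validation suite runs at desk scale by
choice: the full-resolution noiseless end-to-end check uses one 5-lineage,
12 h, 73-frame movie (28×256×256 voxels); seed-sweep properties use smaller
volumes (single frames for count recovery over 100 seeds; 2-lineage 6 h
movies for tracking recovery); trace-level statistics (decay, persistence,
reactivation) run on simulator-generated observation tables with 5 %
multiplicative noise, which isolates the estimators from segmentation error.

## Known limitations

* The generator's geometry (spheres, soft repulsion, sparse fields) is far
  cleaner than brain explants; segmentation guarantees do not transfer to
  dense tissue.
* Division detection relies on the mitotic size signature; a detector that
  misses the rounded mitotic frame or a movie without visible rounding would
  need manual `set_division` edits, as the original analysis used.
* Under constitutive Notch the published description notes GMC decay with
  "slightly slower kinetics"; no number is published, so the per-condition
  decay rate (`gmc_decay_rate_nact_per_hour`) defaults to the wild-type
  value and is exposed rather than guessed.
* Tree node counts follow track semantics: a mitosis ends the mother track,
  so a cycling NB is a chain of one node per cycle, not a single node.
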