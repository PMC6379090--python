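# notchtrack

Quantification of Notch-reporter dynamics in *Drosophila* neural-stem-cell
(neuroblast, NB) lineages from two-channel time-lapse movies, for groups
studying how stem-cell programmes are shut down in progeny and re-awakened
under pathological Notch activity.

Type I NB lineages are a stereotyped system: the NB divides asymmetrically
every few hours, self-renewing as the larger daughter and producing a
smaller ganglion mother cell (GMC) that divides once, ~4 h after birth, into
two neurons.  A Notch-target reporter (green channel, E(spl)mγ-GFP-like) is
high in the NB — peaking just after mitosis (early G1) and just before the
next one (late G2) — and decays exponentially in newly born GMCs,

  I(t) = I₀ · e^(−k·(t − t_birth)),

fit per GMC by log-linear least squares (half-life ln 2 ⁄ k).  Under
constitutively active Notch, progeny older than 8 h can re-express the
reporter and revert to NB-like behaviour; under additional Mi-2/NuRD
depletion a fraction of lineages shows *persistent* GMC expression from
birth.  The package measures all of this from raw movies:

* **simulate** — a ground-truth generator: NB lineages with programmed
  division schedules, reporter kinetics, reactivation and persistence,
  rendered into noisy two-channel 4D movies (PSF blur, background, Poisson +
  Gaussian noise), so every downstream stage is testable without external
  data;
* **segment** — per-frame 3D nuclear segmentation of the histone channel:
  median filter → Otsu threshold → morphological Chan–Vese refinement → 3D
  watershed on the distance transform;
* **track** — nearest-neighbour linking within a 12 px radius searching up
  to five previous frames (gap closing), division detection from the mitotic
  size signature, manual-correction edits, and normalisation of green means
  to the movie average;
* **lineage** — tree reconstruction, NB/GMC/neuron/NB-like role
  classification from size and division pattern, GMC decay fits,
  cell-cycle-aligned NB profiles, persistence and reactivation calls;
* **stats** — box-plot summaries (median, IQR, ±1.5 × IQR whiskers), Welch
  t-tests with star bands, fold changes, hyperplasia fractions;
* **io / CLI** — OME-TIFF movies, CSV tables, JSON/Newick trees, a YAML
  config, and a `notchtrack` command chaining the stages end to end.

## Worked example

Simulate two wild-type lineages (6 h, 15-min frames, no image corruption),
run the full chain, and read off the biology:

```python
import notchtrack as nt

cfg = nt.SimulationConfig(duration_hours=6.0, frame_interval_min=15.0,
                          condition="WT", n_lineages=2,
                          volume_shape_zyx=(24, 200, 200),
                          noise=nt.NoiseParams.off(), rng_seed=1)
lineages = nt.simulate_movie(cfg)
movie, truth = nt.render_movie(lineages, cfg)

labels, obs = nt.segment_movie(movie, nt.SegmentationParams())
params = nt.TrackingParams()
links = nt.detect_divisions(nt.link_frames(obs, params), obs, params)
obs = nt.normalize_green(obs)
forest = nt.build_trees(links, obs)
for tree in forest:
    nt.classify_roles(tree)

print(f"observations: {len(obs)} nuclei over {movie.n_frames} frames")
tracks = links.track_ids(obs)
print(f"tracks: {tracks['track_id'].nunique()}, "
      f"divisions: {len(links.divisions(tracks))}")
nb_tree = max(forest, key=lambda t: len(t.nodes()))
gmc = next(n for n in nb_tree.nodes() if nb_tree.role(n) == "GMC"
           and len(nb_tree.trace(n)) >= 8)
fit = nt.fit_gmc_decay(nb_tree.trace(gmc))
print(f"GMC decay: k = {fit.rate_per_h:.3f}/h, "
      f"half-life = {fit.half_life_h:.2f} h, r2 = {fit.r2:.3f}")
flags, pct = nt.classify_gmc_persistence(forest)
print(f"persistent lineages: {pct:.1f}%")
print(f"fold change 1322/485: {nt.fold_change(1322, 485)}")
```

prints

```
observations: 102 nuclei over 25 frames
tracks: 14, divisions: 6
GMC decay: k = 0.500/h, half-life = 1.39 h, r2 = 1.000
persistent lineages: 0.0%
fold change 1322/485: 2.7-fold
```

Every segmented nucleus was tracked into 14 tracks with all 6 mitoses
assigned; the fitted GMC decay rate recovers the programmed k = 0.5/h
exactly on noiseless data; no wild-type lineage is called persistent; and
the ratio of the two mean cell counts (1322 vs 485 marker-positive cells per
nerve cord) presents as the published 2.7-fold enhancement.

The same pipeline runs from a config file:

```sh
notchtrack all --config examples/wt_movie.yaml --seed 4 --out run1
```

writing observations/links/traces as CSV, trees as JSON and Newick, the
movie and label volumes as OME-TIFF, and the resolved config (with content
hash) next to the outputs.  Identical config + seed reproduce identical
bytes.

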