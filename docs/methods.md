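# Methods

This note records the models, conventions and numerical choices behind
`mitosocial`, in the order data flows through the package.

## Trajectory model and calibration

The unit of input is a spot table: one row per detection with a track
id, a 0-based frame index and an x/y position. A track id names one
mitochondrion (at trajectory granularity) for the whole video; splits
and merges are not resolved. Positions are analysed in µm; pixel-unit
exports are divided by the calibration (default 5 px/µm). z is ignored:
the hypocotyl cells this analysis targets are quasi-2D. The frame
interval in seconds is not stored in tracker exports and must be
supplied as metadata; the default analysis window is 233 s.

Gap closing: upstream trackers may link a trajectory across up to
`max_frame_gap` (default 2) missed frames. Positions inside a gap are
**never interpolated** — a track contributes nothing to any statistic in
frames where it has no spot. Interpolating would fabricate encounter
evidence; the cost is a slight undercount of co-localization frames
during gaps. The one place gaps are smoothed is speed: a step spanning a
g-frame gap contributes displacement/g per frame, treating the closed
gap as continuous motion, which matches the tracker's linking
assumption.

Cell area `A` is required metadata for enrichment. When absent, the
convex hull of all mitochondrial positions is used as a documented
fallback; it underestimates the true outline because organelles do not
visit the full cytoplasm.

## Physical statistics

- **Speed** (µm/frame): per-track mean of step speeds; the cell value is
  the mean over tracks, with the median over tracks and the pooled
  per-step median also exposed (summaries of "typical speed" differ and
  no single convention is canonical; all three are emitted).
- **Inter-mitochondrial distance** (µm): nearest-neighbour distances are
  averaged *within* each frame first, then across frames, so crowded
  frames do not dominate. Frames with fewer than two spots are skipped;
  if all frames are skipped the statistic is flagged undefined.
- **Co-localization time** (frames): per unordered pair, frames both are
  present at distance ≤ threshold (closed comparison; default 1.6 µm,
  just over one mitochondrion's length). The headline cell value is the
  mean over pairs that ever co-localize — on the tens-of-frames scale
  that per-cell co-localization is reported on — and the mean spread
  over *all* pairs is emitted alongside, since "average co-localization"
  is ambiguous between the two.

## Chloroplast enrichment

Per frame, `E = (Nc/Ac) / ((N−Nc)/(A−Ac))` with `d = 3 µm` (twice the
typical 1.5 µm chloroplast radius) and `Ac = π d²` summed over the
chloroplasts present that frame. Adjacency is to the *nearest*
chloroplast centre, so a mitochondrion counts once even in overlap
zones. `Ac` deliberately ignores disc overlaps and boundary clipping for
fidelity to the printed estimate — an exact union-of-discs correction is
available via `correct_overlap=True` — so under spatial randomness the
per-cell mean scatters around 1 with a modest downward bias in narrow
cells. Frames where every mitochondrion is adjacent (infinite
enrichment), or where no chloroplast or mitochondrion is present, are
flagged undefined and excluded from the mean with a warning.

## Encounter networks

An edge (i, j) exists in window [0, c] iff tracks i and j were
simultaneously within the threshold in ≥ 1 frame of the window; one
sustained contact of k frames is one edge of weight k. Edges are binary
for all network statistics (weights are annotation only), a single
contact frame suffices, and networks only accumulate — edge sets are
nested across both thresholds and windows, which the tests assert.
Isolated tracks are real nodes: a mitochondrion that never meets anyone
still dilutes mean degree and efficiency (an `include_isolated=False`
mode exists for comparison with pipelines that drop them).

Network statistics follow the standard conventions: global efficiency
with 1/d = 0 for disconnected pairs; diameter reported on the largest
connected component (with the component count always emitted alongside,
so disconnection is never hidden); betweenness with endpoints excluded
and fractional credit for tied shortest paths, reported both raw
(headline) and (n−1)(n−2)/2-normalized since no single normalization is
canonical. Undefined cases (empty or edgeless graphs, n < 2) raise a
typed signal that cohort summaries convert to NaN.

## Group comparison

Cells are the unit of observation. Two groups: two-sided
Wilcoxon/Mann–Whitney, exact null when combined n ≤ 25 and tie-free,
otherwise the tie-corrected normal approximation; the path taken is
recorded. Three or more: Kruskal–Wallis (tie-corrected, χ² p) with
post-hoc Dunn z-tests on the shared ranks,
`z = (R̄_i − R̄_j)/√((N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_i + 1/n_j))`,
and Benjamini–Hochberg adjustment across the pairwise set. FDR
correction is applied only within a Dunn set, never across the summary
statistics, matching the per-statistic reporting convention of this kind
of cohort analysis; a global correction remains available but off.

## Synthetic cells

The generator emulates the phenomenology the analysis assumes, not
images: per cell, `n_mito` point organelles in a bounded elongated
quasi-2D domain with reflecting walls, each assigned one motion class by
largest-remainder apportionment of the configured fractions (so realised
counts match the fractions exactly and the static fraction is
recoverable exactly).

| parameter | default | why |
|---|---|---|
| domain | 15 × 100 µm | epidermal hypocotyl cells are elongated, several times longer than wide; area 1500 µm² puts 100 mitochondria at ~2 µm nearest-neighbour spacing |
| n_frames, Δt | 120, 233/120 s | 120 frames spanning exactly the 233 s analysis window |
| fractions (static/diff./ball.) | 0.3 / 0.5 / 0.2 | the observed mixture: some organelles static, most diffusive, a minority streaming |
| D | 0.01 µm²/s | within the measured range for plant mitochondria; makes a contact at the 1.6 µm threshold persist ~1.6²/(8D) ≈ 32 s, the tens-of-frames scale of wild-type co-localization times |
| v, persistence | 0.6 µm/s, 0.9/frame | cytoplasmic-streaming-like runs of ~10 µm |

Diffusive steps are Gaussian with per-axis variance 2·D·Δt (the tests
verify the 4·D·Δt mean-squared-displacement law to 5%); ballistic steps
advance v·Δt along a persistent heading and reflect off walls
heading-wise, preserving the step length exactly. All randomness flows
from one integer seed through numpy's PCG64, so output is reproducible
across platforms.

**Clustering** (off by default; used for mutant-like genotypes): pairs
of distinct clusters within `attraction_radius` (1.5 µm) stick with
`sticking_prob` per frame. A cluster moves jointly — one displacement,
drawn from its lowest-id member's motion class — and coheres: members
relax toward the cluster centroid by a fraction 0.2 per frame with
0.15 µm Gaussian jitter, so aggregates are compact blobs whose members
keep rearranging. Shared displacement alone was found insufficient as a
model of aggregation: it freezes relative geometry, so stuck organelles
stop encountering new partners, whereas real clustered mitochondria
jostle within the aggregate and accumulate encounter cliques — the
defining network signature of the clustering phenotype. Release
(`unsticking_prob` per frame, per member of a multi-member cluster) is a
fission event: the member is ejected just outside the aggregate's
capture zone in a random direction, so it genuinely resumes independent
motion rather than re-sticking in place; escaped itinerants are what
bridge separate cliques. Chloroplasts are static 1.5 µm discs placed
uniformly without overlap (bounded rejection sampling).

**What the generator does not emulate** — and hence what passing tests
do not show about real data: detection noise and track fragmentation
(simulated tracks span every frame), fission/fusion as topology changes,
cytoskeletal track geometry, organelle size and shape, mito–chloroplast
interaction (enrichment is null by construction), and any calibrated
genotype effect sizes. Group-level conclusions from synthetic cohorts
are directional and mechanistic, not quantitative predictions. Under the
default conditions the free-motion baseline already builds a
well-connected encounter network within 233 s, so sticky cohorts show
the spacing and co-localization signatures of clustering mutants
clearly, while their *global* efficiency sits below the baseline rather
than above it — sparser, more locally-mixing baselines would be needed
to reproduce that aspect of the mutant phenotype.

## Numerical and interface choices

- Distance comparisons are closed (≤ threshold) in calibrated µm.
- Canonical trajectory files print positions via `repr`, so round trips
  are bit-exact and repeated writes byte-identical; reading uses
  pandas' `round_trip` float parser.
- TrackMate dialects: single-header CSVs and the newer exports with
  descriptive sub-header rows, auto-detected by sniffing leading rows
  with non-numeric frame fields; unassigned-track spots are dropped and
  counted.
- Per-cell analysis failures inside cohort summaries are logged and
  flagged in the output table, never fatal to the cohort.
- The package is a library: the functions above plus the narrative
  scripts in `examples/` are the interface, and network exports
  (edge-list text, GraphML) cover interoperability; no shell CLI is
  shipped.
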