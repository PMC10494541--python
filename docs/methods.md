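# Methods

## Scope and model

`fcnet` implements a two-group comparison of resting-state functional
connectomes built from parcellated time series. For each subject with a
T×N time-series matrix (T volumes, N parcels), the functional
connectivity (FC) matrix is the N×N matrix of pairwise Pearson
correlations, Fisher z-transformed:

    z_ij = atanh(r_ij),   z_ii = 0.

The diagonal is fixed at 0 rather than atanh(1) = ∞ so matrices can be
averaged and thresholded (the convention of the standard connectome
toolboxes). No variance normalization by √(T−3) is applied: z values
are used directly as connectivity. No nuisance regression or partial
correlation is performed — the package consumes already-preprocessed
parcel time series.

Groups are compared at three levels:

1. **Network level.** Each subject contributes, per named network, the
   mean z over unordered parcel pairs with *both* endpoints inside the
   network (cross-network edges excluded; the alternative reading —
   all edges touching a network — is not implemented). Values are
   rank-based inverse-normal transformed across the pooled subjects per
   network, compared with a pooled two-sample t-test, and
   Bonferroni-corrected over the number of networks (7 for the
   canonical atlas: threshold 0.05/7 ≈ 0.007).
2. **Edge level.** All N(N−1)/2 unique pairs (79,800 for N = 400),
   same transform and test per edge, Benjamini–Hochberg FDR correction.
3. **Whole-graph level.** Per group, `n_boot` bootstrap resamples of
   subjects (with replacement, same size) are averaged into group
   z-matrices. Each averaged matrix is proportionally thresholded and
   binarized over a density grid, four binary metrics are computed per
   density, and each metric's curve is integrated (trapezoidal rule
   over the fractional-density axis) into an AUC. The two per-group AUC
   samples are compared with a pooled two-sample t-test per metric and
   Bonferroni-corrected over the metric family.

## Graph construction and metrics

**Proportional thresholding.** At target density d, exactly
k = round(d·n(n−1)/2) edges with the largest *signed* z-weights are
retained (round-half-to-even; ties at the cutoff broken by
lexicographic (i,j) order). Signed ranking means negative correlations
enter only when positive edges are exhausted — at ≤34% density on
Fisher-z FC this never happens in practice; ranking by |z| is available
as an explicit choice at call sites that construct weight matrices, but
the pipeline's fidelity claim is for signed ranking. The fixed
deterministic rule makes edge sets nested across densities and runs
bit-reproducible. A density that rounds to k = 0 is an error, not an
empty graph.

**Metrics** (t_i = triangles through node i, k_i = degree):

- mean nodal clustering: C̄ = (1/n) Σ_i 2t_i/(k_i(k_i−1)), with
  C_i = 0 when k_i < 2 (nodes are not excluded from the mean);
- transitivity: T = Σ_i 2t_i / Σ_i k_i(k_i−1); NaN when the graph has
  no connected triple;
- global efficiency: E = (1/(n(n−1))) Σ_{i≠j} 1/d_ij with 1/d = 0 for
  unreachable pairs; distances are unweighted shortest paths computed
  by a level-synchronous breadth-first search (dense boolean matrix
  products, O(diameter) multiplications — faster than sparse-graph
  routines at these sizes and verified against them);
- degree assortativity: Pearson correlation of endpoint degrees over
  the orientation-doubled edge list; NaN when endpoint degrees have
  zero variance (ring, complete graph).

Degenerate values are NaN, never silently 0: a coerced 0 would bias the
AUC. NaN propagates through the trapezoidal integral and is excluded
(with a logged count) from the bootstrap t-test; a metric whose AUC is
NaN in every replicate is an error.

## Statistical choices

- **Pooled Student t** (df = n₁+n₂−2), not Welch: with equal group
  sizes the statistics coincide, and the summary-statistics entry point
  (`two_sample_t_from_summary`) reproduces published demographic
  comparisons exactly.
- **Inverse normal transform** uses the Blom offset c = 3/8:
  y_i = Φ⁻¹((r_i − 3/8)/(n + 1/4)), average ranks for ties; the offset
  is a parameter for users who prefer c = 0 or c = 1/2.
- **Bonferroni family for the graph metrics defaults to 3** with a
  config override to 4. Four metrics are always computed and reported;
  which metrics form the inferential family is a reporting decision the
  package leaves to the user, defaulting to the three-segregation/
  integration/resilience summary conventional in this literature.
- **Bootstrap t caveat (deliberate).** Replicate AUCs within a group
  are resamples of the same subjects, so their spread reflects
  resampling noise around that group's fixed sample, not
  between-subject variability of independent groups. Under a fixed true
  effect the t statistic therefore grows ≈ √n_boot without bound. This
  mechanism — which explains the very large t values such pipelines
  print — is reproduced faithfully, asserted by a test (|t| monotone in
  n_boot ∈ {50, 200, 800}), and surfaced in the run metadata (df and an
  explanatory note) rather than "corrected".

## Synthetic data generator

The generator emulates two groups of 15 subjects, 640 volumes each,
with parcels partitioned into 7 modules (named after the seven
canonical resting-state networks). Time series are i.i.d. zero-mean
multivariate normal draws whose correlation matrix is
compound-symmetric per block: `within_r` on same-module pairs,
`between_r` across modules. Positive semi-definiteness is checked at
construction and violations are rejected, not clipped — clipping would
silently change the requested effect size. Per-subject seeds are
counter-based (`SeedSequence([master, group, index])`), so enlarging a
design never perturbs earlier subjects.

**Default group effect.** Control: within_r = 0.23; case:
within_r = 0.08 (a 0.15 reduction); shared between_r = 0.05, N = 100
parcels. The magnitude of these defaults is necessarily arbitrary — no
published effect sizes exist for this contrast — but their *placement*
is principled: proportional thresholding binarizes by rank order of
edge weights, so a group whose within/between z-gap far exceeds the
sampling noise of a group-averaged matrix (per-edge sd ≈
(1−r²)/√(T·n) ≈ 0.01 here) produces the same ranked edge list as any
other such group, and *no* within_r reduction would survive
binarization. The case group therefore sits near that noise margin
(z-gap atanh(0.08) − atanh(0.05) ≈ 0.03): cross-module edges genuinely
displace within-module edges at threshold, which is what weakened
functional segregation means for a binary connectome. Consequences, by
construction: lower transitivity and clustering, lower assortativity,
and higher global efficiency (cross-module shortcuts) in the case
group.

**What the generator does not model:** temporal autocorrelation,
hemodynamics, motion or physiological noise, heterogeneous per-network
correlation levels, negative modular structure. Passing recovery tests
therefore demonstrate that the *pipeline* recovers effects that operate
through rank reordering of edges; they do not certify sensitivity to
every alteration real scans could show.

## Problem sizes and numerical choices

- Density grid default 0.10–0.34 in steps of 0.01 (25 densities); the
  AUC is the raw integral over that axis (span 0.24), not normalized —
  only group contrasts of AUC are interpreted, so the scale is inert
  but fixed.
- Validation experiments use N = 100 parcels and n_boot = 200 with 20
  master seeds; full-scale runs (N = 400, n_boot = 1000) use the same
  code paths and remain practical on a workstation.
- Matrix symmetry tolerance 1e−12; |r| ≥ 1 − 1e−12 off-diagonal is
  treated as a duplicated signal and rejected; constant columns are
  detected exactly (max = min), not via a floating-point std.
- End-to-end runs are byte-identical under a fixed seed and config; the
  configuration hash (SHA-256 of the analysis parameters, excluding the
  output path) is stamped into every output file.

## Known limitations

- The bootstrap AUC t-test inherits the inflation caveat above; its
  p-values should be read as descriptive of the resampling experiment,
  not as subject-level inference.
- Network-level averaging assumes the within-network reading of
  "connections within regions of each network"; results under the
  incident-edge reading would differ.
- The binary-metric pipeline is blind to group differences that leave
  edge rank order unchanged (uniform FC scaling, or modular effects far
  above the noise floor at fixed topology); this is a property of
  proportional thresholding itself, documented here because the
  synthetic defaults were chosen with it in mind.
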