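# Methods

## Causal model and prediction profiles

The knowledge base is a multiset of signed directed statements
(source, ±1, target, target-layer, provenance). Duplicate statements are
retained (parallel edges); parallel edges of opposing sign are legal and are
the graph-level source of ambiguity. A hypothesis (node n, direction d ∈
{+1, −1}) predicts downstream transcripts by signed propagation:

- Propagation radius (`depth`) defaults to **1** — the statement model
  encodes direct perturbation experiments, so direct transcript edges are
  the best-attested predictions. The radius is configurable for exploratory
  multi-step propagation.
- At depth > 1, the sign of a transcript t is d times the product of edge
  signs along a *shortest* path; if shortest paths disagree the prediction
  is ambiguous. Nearest causal evidence dominates; longer paths never
  override shorter ones.
- Same-sign parallel edges count once for sign determination; a
  +1/−1 parallel pair makes the target ambiguous.
- The hypothesis node's own transcript is excluded from its profile: a
  driver does not get credit for "explaining" itself.

## Correctness score and its exact null

Against ternary observations (N measured transcripts, n⁺ up, n⁻ down) a
profile with q⁺ predicted-up, q⁻ predicted-down and q⁰ ambiguous transcripts
yields counts (correct, incorrect, ambiguous) over *changed* transcripts
only, and the score S = correct − incorrect. Ambiguous predictions
contribute to neither the score nor the null margins: they are reported as
a separate column, counting changed transcripts only.

The null re-assigns the n⁺ and n⁻ change labels uniformly without
replacement across the N transcripts. With (a, b) the up/down labels in the
q⁺ set and (c, d) those in the q⁻ set, S = (a − b) + (d − c) and

P(a, b, c, d) = C(q⁺,a) C(q⁺−a,b) · C(q⁻,c) C(q⁻−c,d) ·
C(r, n⁺−a−c) C(r−(n⁺−a−c), n⁻−b−d) / [C(N,n⁺) C(N−n⁺,n⁻)],  r = N−q⁺−q⁻.

Two equivalent implementations are provided and cross-checked to 1e−12:

- a reference summation in exact integer arithmetic (`method="exact"`),
  used by default below ~20,000 terms — its masses are exact rationals cast
  to float once, so the distribution sums to 1 up to a single rounding;
- a log-space broadcast evaluation (`method="vectorized"`) for large
  margins, using gammaln-based log-binomials.

Reported p-values are the upper tail P(S ≥ s_obs), clipped to [0, 1]
against float drift. Useful identities used as test oracles: total mass 1;
E[S] = (q⁺ − q⁻)(n⁺ − n⁻)/N; swapping the hypothesis direction mirrors the
distribution (S → −S).

The enrichment p-value is the one-sided hypergeometric tail for drawing
≥ correct + incorrect changed transcripts in q⁺ + q⁻ draws from N containing
n⁺ + n⁻ changed. The draw is the *non-ambiguous* downstream set by default,
because correct/incorrect counts can only arise there; an
`include_ambiguous` switch widens both the draw and the overlap for the
reading in which ambiguous targets also count as "found".

## Ranking, thresholds, networks

Hypotheses failing either threshold (defaults: correctness p ≤ 10⁻⁵ and
enrichment p ≤ 10⁻⁵) are removed; survivors sort by score descending, then
enrichment p ascending, then node id, then Up before Down — a total,
deterministic order. p-values are deliberately *not* multiplicity-adjusted
(the method applies raw thresholds); an optional Benjamini–Hochberg column
can be attached but is off by default.

The driver network takes hypotheses with correctness p < 10⁻⁴ (the p-field
is switchable to enrichment) as nodes and any knowledge-base statement
between two retained entities as an undirected edge — sign and orientation
express regulation, not connectivity. Component ties break toward the
component containing the lexicographically smallest node. The explained
fraction uses union-of-correct semantics: a changed transcript counts once
if at least one hypothesis predicts its observed sign, and a correct
explanation is not cancelled by another hypothesis's wrong one (conflicts
between drivers are reported by the shared-target table instead).

The universe N for the null is the measured-transcript universe (the
observation set after the detection filter), not the full knowledge-base
transcript set; a caller can widen it by supplying wider observations.

## Preprocessing layers

- **Normalization**: log2 then rank-mean quantile normalization across
  samples. Idempotent; ties receive the mean of the values they span.
- **Detection filter**: features detected in fewer than 3 samples are
  excluded (boundary: exactly 3 is kept); the removal log is returned.
- **Ternary calls**: log2 FC = mean(t_j) − mean(t_i) over all samples of a
  timepoint (biological and technical replicates pooled); per-feature
  Welch t; Benjamini–Hochberg across features. Presets: `headline`
  (|FC| ≥ 2 and adjusted P < 0.01) and `toptable` (|FC| > 1.5 and raw
  P < 0.01). Welch-t + BH stands where the original analysis used limma's
  moderated t: the moderated statistic borrows variance across features and
  will not reproduce identical call counts, so absolute counts are not a
  contract of this module — the calling rules and thresholds are.
- **H3K4me3**: RPKM in 5,000 bp windows centred on the TSS (strand picks
  the TSS coordinate; the window itself is symmetric, hence effectively
  strand-neutral). A read overlapping ≥ 1 bp counts once, implemented with
  sorted-endpoint counting so duplicate reads keep their multiplicity.
  Coordinates are 0-based half-open (BED) throughout. The background level
  is the median RPKM over user-supplied control windows (a control track
  column or shuffled windows); no formula-level claim is made beyond that.
- **Correlations**: level matrices correlate per-timepoint mean vectors
  across shared features; change matrices correlate consecutive-interval
  differences. Per-gene correlations use matched samples when the two
  layers share a sample layout and timepoint means otherwise; zero-variance
  tracks give NaN and are excluded from distributions.
- **Peak overlap**: asymmetric query fraction (share of set-A intervals
  touching ≥ 1 bp of set B).

## miRNA integration

Assembly keeps curated pairs plus pairs predicted by ≥ 2 of targetscan,
PicTar, miRBase (provenance preserved). The anti-correlation filter keeps
pairs with Pearson R ≤ −0.5 across timepoint means — the method prescribes
anti-correlation but no numeric cut; −0.5 demands the correct sign with a
moderate effect and is configurable. Epigenetic parsimony: tier B if the
gene's expression–mark correlation is ≥ 0.5 ("adequately explained" by the
mark, likewise a configurable quantification of a qualitative rule),
tier A if below or undefined (flat mark, e.g. below background throughout).
Tier B candidates are labelled, not discarded — a strong mark correlation
argues the miRNA effect is small, not absent. Ranking: tier A first, then
ascending R, then (mirna, gene) lexicographic.

## Synthetic data: what it emulates, what it does not

The generators produce every input the pipeline reads, with planted truth:

- **Knowledge base**: uniform random signed multigraph (out-degree
  Binomial(m, 1/n)), all targets transcript-layer; optionally a hub node
  with a fixed number of distinct targets to host a planted regulator.
  Defaults 200 nodes / 2,000 statements — a desk-scale model of a curated
  KB orders of magnitude larger.
- **Observations**: planted-hypothesis targets change in the predicted
  direction with probability `fidelity` (default 0.9), flip with
  (1 − fidelity) × `flip_share` (default 0.5), else stay; all other
  transcripts change at `background_rate` (default 0.05), sign uniform.
- **Tri-omics**: 6 timepoints (labelled D0–D11 after the emulated
  differentiation design) × 3 replicates. Latent trajectories are random
  combinations of a linear ramp and the first two cosine/sine harmonics,
  standardized to sd 2 on the log2 scale — smooth ramp/burst shapes with
  enough effective degrees of freedom (~5) that independent trajectories
  are not spuriously correlated. Coupled genes get a promoter mark of
  0.8 × their latent plus noise; decoupled genes (10% of background genes,
  plus all planted-pair genes) get a flat mark at a below-background level.
  Planted repressive pairs give the miRNA the mirrored gene trajectory.
  Replicate noise is i.i.d. N(0, 0.2) everywhere.
- **Catalogs**: planted pairs enter as curated or as two-database
  predictions (both survive assembly); 100 decoy pairs with
  assembly-passing evidence and 20 single-database pairs (dropped by the
  ≥ 2 rule) model catalog noise.
- **Reads**: per-window counts Poisson with mean rpkm × kb × (reads/10⁶),
  uniform placement inside the window — RPKM recovery is unbiased by
  construction.

Not emulated: probe/array effects, sequence-level reads, miRNAs with
activating effects, entity synonymy, dependence between the omics layers
beyond the planted couplings. Passing the recovery tests therefore shows the
*inference machinery* is sound under the assumed generative structure, not
that real catalogs or real ChIP-seq would yield these recall/precision
levels.

## Numerical choices and degenerate inputs

- Degenerate null (q⁺ = q⁻ = 0 or no changed transcripts): S ≡ 0, so
  P(S ≥ 0) = 1 and P(S ≥ s) = 0 for s > 0.
- Empty survivor sets are results (with a warning), not errors; an
  explained fraction over zero changed transcripts is an error.
- Tie-breaks everywhere are lexicographic and documented, so reruns are
  byte-identical given a seed.
- Problem sizes in the test-suite recovery studies — 100 seeded
  knowledge-base runs and 50 seeded time courses at 1,000 genes ×
  100 miRNAs — are the package's chosen desk-scale study conditions, large
  enough for the binomial bands the checks assert.

## Known limitations

Richer statement typing (phosphorylation contexts, compound exposure) is
not modelled — statements are bare signed edges. Shortest-path-only sign
propagation discards longer corroborating or conflicting paths. Welch-t
calls diverge from moderated-t counts on small replicate numbers. The
miRNA thresholds (−0.5, 0.5) quantify qualitative rules and should be
treated as tunable screening cuts, not calibrated error rates.
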