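# cretools

Causal reasoning on signed regulatory graphs, with tri-omic (mRNA / miRNA /
H3K4me3) time-course integration.

Given a knowledge base of curated causal statements — "A increases B",
"A decreases B", each from a published perturbation experiment — and a set of
ternary differential-expression calls (up / down / unchanged), `cretools`
asks: *which upstream regulators, in which direction of activity change, best
explain what was observed?* It is aimed at systems biologists analysing
time-course transcriptomics (the package's synthetic study emulates a
6-timepoint hESC-to-pancreatic-endocrine differentiation design), and at
anyone who wants exact, permutation-free significance for upstream-regulator
scoring.

## The statistic at the core

A *hypothesis* h = (entity, direction) predicts, through signed shortest
paths in the knowledge base, a ternary change for each downstream transcript:
q⁺ predicted up, q⁻ predicted down, q⁰ ambiguous (conflicting path signs).
Scored against observed calls over a universe of N transcripts (n⁺ up,
n⁻ down), the **correctness score** is

    S = #correct − #incorrect

counting only non-ambiguous predictions of transcripts that actually changed.
Under the null of re-assigning the n⁺ + n⁻ change labels uniformly at random
across the N transcripts, write (a, b) for the up/down labels landing in the
predicted-up set and (c, d) for those landing in the predicted-down set; then
S = (a − b) + (d − c) and (a, b, c, d) follow a multivariate hypergeometric
law. The package sums this law exactly — O(n⁺²·n⁻²), no simulation — to give
the **correctness p-value** P(S ≥ s_obs). A direction-blind **enrichment
p-value** (one-sided Fisher/hypergeometric tail for finding
#correct + #incorrect changed transcripts among q⁺ + q⁻ draws) is reported
alongside. Significant hypotheses (default: both p ≤ 10⁻⁵) are ranked by
score; drivers with p < 10⁻⁴ are linked through knowledge-base edges into a
driver network and summarised by the fraction of observed changes they
jointly explain.

The integration layers: ternary calls from fold-change + Welch-t/BH rules
(|FC| ≥ 2 & adj-P < 0.01, or |FC| > 1.5 & P < 0.01), H3K4me3 quantified as
RPKM in 5 kb windows centred on TSSs, level/change correlation matrices and
per-gene expression–mark correlations, and a three-stage miRNA filter:
catalog assembly (curated ∪ predicted-by-≥2-databases), expression
anti-correlation (R ≤ −0.5), and epigenetic parsimony (genes whose expression
already tracks their promoter mark, R ≥ 0.5, are tier B; decoupled genes are
the primary tier-A candidates).

## Worked example

Everything runs on synthetic data with planted ground truth:

```bash
cre simulate --out demo --seed 1 --n-genes 300 --n-mirnas 60
cre score --statements demo/statements.tsv \
          --observations demo/observations.tsv --out demo/score
head -3 demo/score/results.tsv
```

```text
node  direction  correct  incorrect  ambiguous  score  correctness_p  enrichment_p  q_up  q_down  q_ambig
G000  Up         50       2          0          48     5.62487e-41    3.50523e-35   26    28      0
```

The simulated knowledge base (200 nodes, 2,000 statements) contains a hub
regulator `G000` with 50 dedicated targets; observations were generated with
sign fidelity 0.9 over a 5% background change rate (`demo/truth.json` records
the plant). The score run recovers it: `G000 Up` explains 50 observed changes
correctly and 2 incorrectly (score 48) and is the only hypothesis passing the
default 10⁻⁵ thresholds — its correctness p-value, computed from the exact
null, is ≈ 6 × 10⁻⁴¹.

The miRNA filter on the same directory:

```bash
cre integrate-mirna --curated demo/catalog_curated.tsv \
    --predicted mirbase demo/catalog_mirbase.tsv \
    --predicted pictar demo/catalog_pictar.tsv \
    --predicted targetscan demo/catalog_targetscan.tsv \
    --mirna demo/mirna.tsv --genes demo/mrna.tsv --h3k4 demo/h3k4me3.tsv \
    --out demo/mirna
head -3 demo/mirna/mirna_candidates.tsv
```

```text
mirna   gene     r_mirna_gene  r_gene_h3k4  tier  sources
miR-12  GENE012  -0.9995       0.3133       A     curated
miR-08  GENE008  -0.9992       -0.0886      A     curated
```

Of 120 assembled associations, 51 survive anti-correlation and 21 land in
tier A; the top candidates are planted repressive pairs (miRNA mirrors the
gene trajectory, R ≈ −1) whose genes are decoupled from their promoter mark
(|R_gene,H3K4me3| small). `cre report --dir demo --out demo/report` runs the
whole pipeline (score, network, miRNA, epigenome correlations, calls) in one
step.

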