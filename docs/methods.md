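# Methods

This document records the statistical model behind each module, the
default parameter choices, the simulator's scope, and the places where a
published description was ambiguous and the package had to commit to one
reading.

## Consensus aggregation

Inputs are `J ≥ 2` ranked gene lists. Each list is normalized to
`GeneN_ij = (M_j − r_ij + 1)/M_j` (rank mode) or min–max scaled (score
mode; constant score vectors saturate to 1 with a warning). A gene seen
by `n_i` lists with mean normalized score `m_i` receives

```
Gene_i = sqrt( (n_i − 1)/(J − 1) · m_i )
```

The square root compresses the product of the two agreement terms; any
single-source gene scores exactly zero. Ties in `Gene_i` are broken by
the symmetric mean `((n_i − 1)/(J − 1) + m_i)/2` and then by gene id, so
the table is a deterministic function of its inputs. Ranks use
competition ranking (tied genes share the minimal position) and
`ConsenScore_i = (N − rank_i + 1)/N`.

Assumptions: lists are exchangeable evidence sources; missingness is
informative (absence from a list counts against a gene, which is why the
`(n−1)/(J−1)` factor exists); within-list order is the only information
used in rank mode.

## Rational cutoff

Against a reference set, the index at table position `i` is
`I_i = TP_i/(FP_i + 1) · ConsenScore_i` with `TP_i`/`FP_i` the
reference/non-reference counts in the top `i`. The selected rank is the
first argmax. A rate variant `TPR/(FPR + 1) · ConsenScore` is computed
alongside (`variant="rate"`): the count form is scale-dependent, the rate
form is not, and neither is canonical, so both are reported and the count
form is the default. This is an open design decision: the source
description of this index admits both readings and its printed example
value is not reproducible from either, so the package exposes the two
defensible forms rather than tuning toward a number it cannot verify.

## Early-recognition benchmarking

Detection percentage in the top fraction `f` uses a window of
`w = ceil(f · N)` rows. Enrichment factor, RIE and BEDROC follow the
standard early-recognition definitions; BEDROC uses the closed-form best
and worst placements for its extremes and `alpha = 1/f` pairs the two
parameterizations (`f ∈ {0.01, 0.05, 0.1, 0.2}` ↔
`alpha ∈ {100, 20, 10, 5}`). All primitives are validated against
independent brute-force oracles, exhaustively on small placements and on
random instances.

Stability is assessed by leave-`n`-out bootstrap over the reference set
and paired rankings are compared with the exact Wilcoxon signed-rank test
(≥ 6 informative pairs required; identical tables report p = 1 with a
"none" direction marker).

## Network communities

Edge tables are confidence-filtered (inclusive cutoff, default 0.9;
integer scores on a 0–1000 scale are divided by 1000). Communities are
k-clique percolation communities: maximal components of the clique graph
where two k-cliques connect when they share k − 1 nodes. Detection uses
the maximal-clique formulation (equivalent to direct percolation; the
test suite proves equality against a direct enumeration oracle on
hundreds of random graphs). The clique size is chosen by minimizing the
size-balance index `S^k = |mean − median| / n_communities` over
`k ∈ [k_min, k_max]`, breaking ties toward smaller k. Because heavily
overlapping planted structures can merge into one giant community at
small k (driving `S^k` to zero), `k_override` is always available and the
scan table reports every k.

## Pathway scoring

Communities link to pathways by hypergeometric over-representation of the
community's genes against the universe, BH-adjusted, linking at
`q < 0.05`. For a pathway linked to communities `K`:

- `PathRankScore = mean_{k∈K} (mean consensus rank of community k)` —
  the per-community means are averaged, not pooled over genes. This is a
  deliberate reading: the alternative (pooling all member genes) is not
  consistent with the published community summaries this package
  reproduces, so the per-community mean is used throughout.
- `PathGeneScore = sqrt( ⟨ConsenScore⟩_pathway · n_in_network / size )`.
- `PathScore = sqrt( PathGeneScore · (P_max + 1 − P)/(P_max + 1) )` where
  `P_max` is the worst linked pathway's rank score. The `+1` keeps the
  worst pathway's term strictly positive; this normalization was chosen
  because it reproduces the published combined scores to three decimals
  across an entire 32-row fixture, which a plain `(P_max − P)/P_max`
  does not.

## Monte-Carlo significance

`component_significance` measures the largest group of input genes
mutually reachable in a reference network; with `allow_missing d ∈ {1,2}`
two input genes also connect through at most `d` non-input intermediates
(paths of ≤ d + 1 edges avoiding other input genes). The null redraws
equally sized gene sets uniformly from the network. Two p-values are
returned: the conservative `(1 + #{sim ≥ obs})/(n_mc + 1)`, and a
tie-randomized variant that is exactly Uniform(0,1) under the null.
Because the test statistic is a small integer, the conservative p is
necessarily super-uniform; the randomized variant exists so calibration
can be verified, and it never exceeds the conservative one.
`overlap_significance` applies the same construction to set overlap and
reports the exact hypergeometric tail alongside.

## Microarray consensus

Within each study, significant genes are ranked by ascending adjusted p
(ties by gene id) and normalized to `GeneS = (M − r + 1)/M`. Across `S`
studies, `GeneAS = sqrt((Narray − 1)/(S − 1) · mean GeneS)`. Direction is
called up- or down-regulated only on a unanimous vote; any conflict marks
the gene ambiguous rather than resolved by majority — with few studies a
majority vote would overstate confidence. Community weights divide the
sum of member `GeneAS` by the full community size, so sparsely covered
communities are penalized.

## Synthetic data

The generators emulate the statistical structure the analysis assumes,
not any specific biological dataset:

- **Ranked lists** — positives draw latent quality from Beta(`signal_a`,
  1) (`signal_a = inf` means quality 1), negatives from U(0,1); each
  source includes a gene by an independent Bernoulli (`coverage_pos` /
  `coverage_neg`) and ranks `quality + N(0, noise_sd²)`.
- **Network** — consecutive planted cliques of `community_size` genes
  sharing `community_overlap` nodes, intra-clique confidences drawn above
  the filtering threshold; Bernoulli background edges scored below it.
- **Studies** — a DE pool with a true direction per gene; each study
  includes pool genes with `study_inclusion_prob` and flips signs with
  `sign_flip_prob`.
- **Pathways** — set m holds `planted_fraction` of community m plus
  random fillers; optional purely random sets.

Defaults (`n_genes=2000`, `n_positives=35`, `n_methods=12`,
`coverage_pos=0.9`, `coverage_neg=0.5`, `signal_a=4`, `noise_sd=0.2`,
9 communities of 10 sharing 2, 5 studies, 300 DE genes) mirror the
problem sizes of the prioritization study this package models: a dozen
heterogeneous sources over a ~2000-gene candidate space with a ~35-gene
pathogenic reference and a 9-community network. They are study
conditions, not tuned values.

Not emulated: correlated errors between sources, gene–gene correlation
within lists, realistic degree distributions in the background network,
batch structure in the study tables.

## Determinism and numerics

All randomness flows from integer seeds through `numpy.random.SeedSequence`
(per-generator streams; per-pipeline-stage spawned children reduced mod
2³¹). Sorting is mergesort with explicit gene-id tie-breaks everywhere a
tie could occur, so every output is a pure function of config and seed,
and pipeline reruns are byte-identical (SHA-256-checksummed in the
manifest). Trapezoid areas use `numpy.trapezoid`; the RIE denominator
uses `expm1` to stay accurate at small `alpha/N`; BH adjustment comes
from statsmodels, hypergeometric tails from scipy, clique enumeration
from networkx.

## Limitations

- The cutoff index has two defensible forms (count vs rate); results near
  the selected rank should be read with that ambiguity in mind.
- `S^k`-based clique-size selection degenerates when a single giant
  community exists at several k (all `S^k = 0`); inspect the scan table
  or set `k_override`.
- One row of the shipped 32-row pathway fixture is internally
  inconsistent with its own community list (its printed rank score cannot
  be recomputed from the printed communities); the regression test
  asserts 31 of 32 rather than hiding the discrepancy.
- Monte-Carlo p-values are resolution-limited by `n_mc`; the conservative
  form never reports below `1/(n_mc + 1)`.
- The microarray module consumes already-thresholded study tables
  (adjusted p < 0.05 with a direction); it does not model the upstream
  differential-expression analysis.
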