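# Methods

## Differential expression

Input is a probe × sample intensity matrix with exactly two sample groups.
Linear intensities are floored at 1.0 and log2-transformed (the floor keeps
the transform finite for zero or negative background-corrected values; a
guard refuses to double-transform a matrix already on the log2 scale).
Quantile normalization then forces every sample onto the common reference
distribution given by the row means of the column-sorted matrix; within each
column the original rank order is preserved, with ties resolved by stable
sort order. Missing values are rejected rather than imputed.

The test statistic is the two-sample t. Three variants are available:

* `student_pooled` (default) — pooled-variance Student t;
* `welch` — unequal-variance;
* `paired` — for before/after designs with aligned sample order.

Zero-variance (degenerate) probes never propagate NaN: equal group means
give t = 0, unequal means a signed large sentinel (1e9); degenerate probes
with t = 0 are assigned p = 1 and are never selected.

**Permutation p-values.** The two-tailed criterion is realized on |t|: the
p-value of a probe is the fraction of group-label permutations whose |t| is
at least the observed |t|. Monte-Carlo permutations (default m = 10,000) are
drawn uniformly with replacement and the identical permutation stream is
applied to every probe in an iteration, preserving the across-probe
correlation of the null. An exhaustive mode enumerates all C(n, n1) label
splits, which includes the observed split, so exhaustive p ≥ 1/C(n, n1).
The plain estimator count/m matches the stated procedure and can return 0;
an add-one estimator (count+1)/(m+1) is available. Counting uses the
threshold |t_obs| − 1e-9·max(|t_obs|, 1): a drawn permutation that happens
to reproduce the observed split recomputes t with a different column order,
and summation-order rounding would otherwise drop it from the ≥ count.
Distinct label splits of continuous data differ by far more than the
tolerance, so it cannot overcount.

**Storey q-values.** With a single fixed λ (default 0.5, no spline
smoothing), π0 = min(1, #{p > λ} / ((1 − λ)·m)); q-values follow the
step-up recursion q_(m) = min(1, π0·p_(m)),
q_(i) = min(q_(i+1), π0·m·p_(i)/i). When π0 caps at 1 this reduces exactly
to Benjamini–Hochberg, which is used as an independent cross-check in the
tests. Probes with q ≤ the FDR threshold (default 0.20, boundary inclusive)
are selected; no fold-change filter is applied at any stage. Probes collapse
to genes by the any-probe rule — a gene is significant if at least one of
its probes is — with unmapped probes dropped and counted.

## Evidence intersection

Gene symbols are uppercased on ingest; alias resolution is deliberately out
of scope (identity mapping). Sources intersect on gene symbols only —
protein-complex entries (DNA-PK, HSP70, MRN(95), RAS in the packaged
literature table) are carried through I/O but excluded from intersections,
since they are not gene symbols. The default rule keeps genes present in
every source; a k-of-n generalization is exposed (`min_sources`). For two
or three sources the full 2^s − 1 Venn region counts are reported and sum
to the union size.

## Network ranking

The interaction network is a simple digraph; each edge carries an integer
reference count ≥ 1 (the number of publications supporting the interaction)
and an effect label (inhibitory / stimulatory / unspecified) that is
preserved by I/O but ignored by scoring. Duplicate edges merge at ingest by
summing reference counts; self-loops are rejected; an absent reference
count defaults to 1 (minimum evidence, never 0).

A Floyd–Warshall pass with unit edge weights computes, for every ordered
pair, the hop-minimal path; among equally short paths the one with the
maximal total reference count is chosen (strongest-evidence path — this
tie rule also makes every score monotone in edge evidence). Both the hop
count and the reference total are additive along paths, so the
lexicographic relaxation is exact. The pass yields N (node count of the
chosen path, endpoints included, so a direct edge has n = 2; diagonal 1)
and R (its reference total; diagonal 0); unreachable pairs are marked and
score 0.

Pair and protein scores follow the power-law form described in the README:
rs = w_r·r^α with α = 0.5 (concave — additional references help, with
diminishing returns) and ns = w_n·n^(−β) with β = 2.0 (node count decays
super-linearly, so indirectness dominates evidence, the intended ordering
of influences; a warning is emitted if β ≤ α). All four constants are
configurable. A flag switches n to intermediate-only counting, in which
case a direct edge contributes the full node weight w_n.

Ranking tables are sorted by descending score with lexicographic
tie-breaking, so output bytes are deterministic and invariant to node
insertion order.

## Synthetic data

The expression generator draws i.i.d. Gaussian log2 intensities
(baseline mean 8.0 — a typical mid-range microarray log-intensity — and
σ = 1.0) for `n_probes` probes over two groups of `n_per_group` samples
(default 8 vs 8, the size of a paired before/after irradiation design);
the first `n_de` probes are shifted by `effect_size` log2 units in the
second group and the truth vector is returned for power and FDR
evaluation. The generator is seed-deterministic and omits realistic
microarray artifacts (dye bias, spatial effects, probe-level correlation),
so a green calibration test establishes correctness of the statistics, not
robustness to such artifacts. One consequence worth knowing: quantile
normalization assumes mostly unchanged distributions, so strongly
one-directional spike-ins shift null probes slightly in the opposite
direction and inflate the realized FDR above the nominal threshold — a
property of the procedure itself, visible in the README example.

The network generator produces directed Erdős–Rényi (independent ordered
pairs at `edge_prob`) or preferential-attachment digraphs; reference counts
are Geometric(`ref_p`) with support ≥ 1.

## Numerical and design notes

* Exhaustive and Monte-Carlo permutation modes agree in expectation; the
  test suite checks 10,000 draws against the 20-split enumeration at
  n1 = n2 = 3 within 3 binomial standard errors per probe.
* The published equations behind the two power-law scores are available
  only in prose ("a power law", with node influence dominating reference
  influence); the constants fixed here honor that constraint but published
  absolute score values on proprietary networks are not reproducible and
  are not targets.
* In a bidirectional star with unit references, leaves outrank the hub:
  leaf-to-leaf two-hop paths accumulate r = 2 (score √2 + 1/9 ≈ 1.53 per
  pair versus 1.25 for a direct edge). Hub dominance holds in a directed
  out-star where leaves are mutually unreachable. This is a direct
  consequence of summing reference counts along paths.
* Permutations are drawn with replacement (duplicate label splits allowed);
  the t-test variant and the |t| reading of "two-tailed" are configuration
  choices with the defaults above.

## Limitations

* No GEO download, probe-annotation retrieval, batch correction,
  missing-value imputation, or SAM-style moderated statistics.
* Probe-to-gene maps are always user-supplied.
* Network retrieval from curated commercial databases is out of scope; the
  ranking operates on whatever edge list is provided.
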