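# Methods

`sigmatch` implements connectivity-map-style matching of a query phenotype
(two disjoint lists of up- and down-regulated gene symbols) against a
database of ranked gene-expression signatures, for generating drug-
repositioning hypotheses: a perturbation whose signature *opposes* a
disease phenotype is a candidate for reverting it.

## Signature construction

A signature is built from one two-class comparison of a genes × samples
log-scale expression matrix.  For every experimental variable in the sample
metadata, every unordered pair of its class labels yields one comparison
(k classes → k·(k−1)/2 signatures; variables with more than `max_classes`
classes, default 10, are skipped as unlikely to encode a clean contrast).
The reference class of a pair is chosen by, in order:

1. a control-vocabulary regex match on exactly one label (defaults:
   control, untreated, vehicle, dmso, wild-type, baseline, normal, none,
   mock — configurable, since public metadata vocabularies vary);
2. time ordering, when the variable name looks like a time series and both
   labels parse as times (units s/min/h/d/w);
3. otherwise the lexicographically smaller label, with
   `direction_known=False` recorded on the signature — the comparison
   direction is arbitrary and downstream consumers can see that.

Genes are ranked by a two-sample statistic of (test − reference).  The
default is a **moderated t**: per-gene pooled variances are shrunk toward
an empirical-Bayes prior — a scaled inverse-chi-square fitted by matching
the moments of the log sample variances, the posterior variance being
(d₀s₀² + df·s²)/(d₀ + df).  With 2–3 replicates per class the raw per-gene
variance estimate is so noisy that the ordinary t statistic's heavy null
tails (t with ~4 df) let genes with accidentally tiny variances outrank
genuinely shifted genes; shrinkage restores a ranking dominated by effect
size.  `method="pooled"` and `"welch"` are available for comparison; the
moderated fit needs at least 10 genes and otherwise reduces to the pooled
t.  With fewer than 2 replicates in either class the statistic falls back
to the difference of class means — a log fold-change, flagged via
`stat_kind="fold_change"`.  A gene with zero variance estimate but nonzero
mean difference falls back to the mean difference (logged); constant,
equal classes give statistic 0.  Probe-level duplicates of a symbol are
collapsed case-insensitively, keeping the entry with the largest |stat|
(ties toward the larger stat): rank-based matching consumes only the most
extreme signal per gene.

## Matching statistic

For a gene set against a ranked signature of N genes with n_hits overlap,
the enrichment score (ES) is the signed maximum-absolute-deviation value of
a running sum walked from the top: a hit at position i adds w_i/N_R (w_i =
|stat_i| when weighted — the default — or 1 unweighted; N_R = Σ hit
weights) and a miss subtracts 1/(N − n_hits).  ES ∈ [−1, 1]; +1 means all
hits sit at the very top.  The implementation evaluates the walk as
(cumulative hit weight)/N_R − (cumulative miss count)/(N − n_hits), which
is algebraically identical to the step walk but float-exact at the
extremes (a packed top block reaches exactly +1).  When the maximum
absolute deviation is attained more than once (possible exactly in
unweighted mode, where the walk takes rational steps), the earliest
position within 1e−12 of the peak is used — an explicit tie-break rather
than whatever float noise argmax would pick.  If every hit has zero
weight, the weighted walk degenerates and falls back to unweighted.  A set
with no overlap is excluded (and logged), and a set covering the whole
signature is an error (no misses to walk).

The combined score is c = (es_up − es_down)/2, nulled to 0 when both
enrichment scores carry the same strict sign — the two query halves then
disagree about the signature's direction (Connectivity-Map convention;
`nulling=False` disables it).  A half with no overlap contributes 0.  The
similarity score on the 0–100 scale is the affine map 50·(1 + c) in direct
mode and 50·(1 − c) in inverse mode, so a perfect mimic scores 100 direct
and a perfect opposer scores 100 inverse.  The two symmetries this buys —
swapping the query's up/down lists maps score → 100 − score, and
inverse-mode results equal direct-mode results of the swapped query —
are asserted in the test suite row for row.

## Significance

Each (signature, query) pair gets a permutation p-value: B random query
surrogates — disjoint gene sets of the observed overlap sizes, drawn
uniformly without replacement from the signature's genes — are rescored
and p = (1 + #{|c_b| ≥ |c_obs|})/(B + 1), add-one corrected so p is never
0. B defaults to 1000.  Because |c| depends only on the *unordered* pair
of surrogate sets, the surrogates are drawn in a canonical order (larger
set first), making the p-value exactly invariant under swapping the
query's up/down lists — this is what makes the mode-duality symmetry hold
including p- and q-values, not just scores.

Calibration: for the raw (un-nulled) statistic the p-values of random
queries against random signatures are uniform on (0, 1] up to the B+1
grid; the test suite checks an empirical-CDF KS distance < 0.05 over
2,000 replicates.  With nulling enabled the p-value is still exactly
calibrated below 1 − P(c = 0) but has a deliberate conservative atom at
p = 1: every discordant query (roughly half of null draws) is sent to
c = 0 and hence p = 1.  That is a feature of the discordance rule, not a
calibration error, which is why the uniformity check is run with nulling
off.

q-values are Benjamini–Hochberg over all signatures retained in a run
(statsmodels' step-up implementation).  Result rows are ordered by score
descending, ties by p ascending then signature id, so identical inputs
and seed give a byte-identical table.

## miRNA translation

miRNA-level queries are inverted into mRNA queries through tables of
experimentally verified miRNA→target edges, each edge carrying a support
count (number of source databases).  Since essentially all verified
miRNA–mRNA interactions are inhibitory, targets of up-regulated miRNAs
become the down-gene list and vice versa.  Names are first normalized to
canonical miRBase-style identifiers via a case-insensitive alias
dictionary; unmapped names are reported, never silently dropped.  A gene
implied in both directions is removed from both lists, keeping the output
a valid (disjoint) query; `min_support` (default 1) lets users demand
multi-database confirmation and is monotone — raising it never adds genes.

## Annotation aggregation and experts

Signatures carry precomputed drug/disease terms from sidecar files (term
extraction from dataset descriptions is outside this package's scope; a
plain substring tagger exists for fixture generation only and is labelled
non-NLP).  Terms pass a case-insensitive stoplist.  Over a ranked result
table, the rows counted as "matched" are the union of rows with q ≤ 0.05
and the top 200 by score (both configurable).  Term tables report the
union of terms tagging the top `top_n_by_score` (default 30) rows and
terms with count ≥ `min_count` (default 4), counts taken over all matched
rows — mirroring a "best scorers plus most abundant" reading habit.
Drug–disease edges count signatures co-tagged with both terms.  Expert
scores give an author one point per matched signature whose source
dataset cites at least one paper with that author (capped at one per
signature); author names are normalized to case-folded surname + initials,
with no homonym disambiguation.

## Synthetic data

The generators exist so every statistical claim in the test suite is
checked against planted ground truth:

- `simulate_expression` draws i.i.d. Gaussian noise (σ = 1 by default)
  around a log-scale baseline of 8 and shifts `n_de` planted genes by ±δ
  in the test class (δ = 3 by default, first half up, second half down),
  with a "control"-labelled reference class.  Defaults are a desk-scale
  fixture: 200 genes, 3 vs 3 replicates, 20 planted.  The genome size is
  deliberately small: the weakest of ~10 planted effects is typically
  δ − ~1.5·σ·√(2/3) while null exceedances above that level grow linearly
  with genome size, so a compact fixture is what makes planted-gene
  recovery a sharp, informative check of the ranking machinery (measured:
  ~98% of planted genes land in the extreme 20 ranks over 100 seeds).  A
  Student-t noise option (`heavy_tail`, variance-standardized) exists for
  robustness checks.
- `make_synthetic_store` builds `n_decoys` (default 200) random-order
  signatures over a shared universe (default 500 genes) plus one planted
  signature whose query up-genes sit in the top block and down-genes in
  the bottom block, each with probability |ρ|; ρ < 0 swaps the blocks to
  plant an anti-match and ρ = 0 is an honest null.  Truth manifests record
  the planted id and all parameters.

What these fixtures do *not* emulate: probe structures, batch and
platform effects, correlated genes, realistic genome sizes, or the messy
label vocabularies of real public metadata.  Passing tests demonstrate
the correctness and calibration of the machinery, not performance on any
real corpus.

## Numerical and design notes

- Scores are clamped to [−1, 1] only against ≤1e−9 float drift; a larger
  excursion raises, since it would indicate a real bug.
- Stat ordering within a signature breaks ties by gene symbol; all output
  tables have fixed column orders, floats in shortest round-trip form,
  and trailing newlines, so reruns are byte-comparable.
- Seeds: every stochastic step takes an explicit seed; the CLI derives one
  from a hash of the configuration when omitted, and logs it.  Per-
  signature permutation streams are spawned from a root SeedSequence in
  sorted signature-id order, so results are independent of store layout.
- The score normalization is absolute (fixed affine map), not rank-
  relative within a run — scores are comparable across runs, at the cost
  of not spreading a run's results over the full scale.
- Signatures with arbitrary comparison direction are reported once with
  `direction_known=false` exposed, not mirrored at query time; users who
  care can query the swapped list themselves.

## Known limitations

- No ortholog or probe-to-symbol mapping: gene identity is upper-cased
  symbol equality.
- The expert score counts citations at the dataset level; it cannot
  distinguish homonymous authors, and datasets without citation records
  contribute nothing.
- Permutation cost is O(B·N) memory and time per signature; desk-scale
  databases (hundreds of signatures, B = 1000) run in seconds to minutes,
  but corpus-scale runs would want batching.
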