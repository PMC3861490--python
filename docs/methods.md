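# Methods

`crossgsea` implements a cross-study pathway analysis for case/control
expression compendia: several independent microarray-style studies of one
disease are each reduced to a gene-level matrix, scored pathway-by-pathway
with a permutation test, combined into a cross-study consensus, and — in a
parallel gene-level track — meta-analysed with Fisher's method, with the
resulting gene list fed to an over-representation test. This note records
the statistical model of each stage, the tunable parameters, the design
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Preprocessing

Input is a probes × samples matrix of normalized log2 intensities with an
explicit probe→gene column (normalization itself is upstream of this
package). Three row-wise rules produce one row per pathway-mappable gene:

1. **Pathway-mapping filter.** Probes whose gene occurs in no set of the
   collection are removed; downstream stages only ever look at pathway
   members, so unmapped probes carry no information for them.
2. **IQR filter.** Probes whose interquartile range across *all* samples
   (cases and controls pooled) is strictly below `iqr_threshold` (default
   0.5 log2 units) are removed. Pooled IQR is the standard nonspecific
   variance filter: it needs no labels, so it cannot bias the later
   label-permutation null. Exclusion is strict `<`: a probe exactly at the
   threshold survives. Quantiles use linear interpolation between order
   statistics at positions 1 + (n−1)q (the default convention of the
   mainstream numeric stacks); the convention is fixed and tested because
   threshold decisions depend on it.
3. **Probe collapse.** Where several probes hit one gene, the probe with
   the largest IQR is retained and the row re-keyed by the gene symbol.
   Ties (identical IQRs) go to the lexicographically smallest probe id so
   output is deterministic.

The mapping and IQR rules are row-independent and therefore commute; the
composed operation is idempotent, and both properties are asserted by
tests. Whether the IQR filter should run before or after collapse is not
determined by the procedure itself; this package filters first, which can
only remove candidate probes before the per-gene maximum is taken.

## Per-dataset gene-set analysis

Each gene g gets the equal-variance two-sample Student statistic

    t_g = (mean_case − mean_control) / (s_p · sqrt(1/n1 + 1/n2)),

with s_p the pooled standard deviation. The equal-variance form (rather
than Welch) matches the plain "Student's t-test" convention of the
spreadsheet-era microarray literature this pipeline descends from.
Degenerate rows: s_p = 0 with equal means gives t = 0; s_p = 0 with
unequal means has no finite t and the gene is dropped with a warning
(measure-zero under the continuous model, but reachable with constructed
or quantised data). Zero-variance detection uses a relative tolerance
(pooled sum of squares ≤ 1e-12 × the row's squared scale).

A set's score is the mean t over its member genes present in the dataset;
sets with fewer than `min_set_size` (default 10) present genes are
excluded. Significance comes from permuting the case/control labels
preserving group sizes, `n_permutations` times (default 1000, seeded):
label permutation regenerates every gene's t per shuffle and preserves the
inter-gene correlation that makes mean-t null distributions heavy. One
shared shuffle stream scores all sets, for consistency and speed.

Directional p-values count ties and are add-one corrected:

    p_up   = (#{b : mean_t_b ≥ observed} + 1) / (B + 1)
    p_down = (#{b : mean_t_b ≤ observed} + 1) / (B + 1)

so p ∈ (0, 1] always, p_up + p_down ≥ 1, and the estimator stays valid
under the null. Per-tail (rather than two-sided) decisions are used
because up- and down-regulated pathways are reported separately; the call
at level α (default 0.05, inclusive ≤) is the smaller-p tail if both pass.
A numerical subtlety: the observed set means are evaluated as column 0 of
the very same batched matrix computation as the permutations, because BLAS
gives last-bit-different results for single-column and batched products —
without this, a re-drawn observed labeling would not tie with itself
exactly and tie counting (hence exactness against enumeration on tiny
samples) would fail.

Exclusion counts member genes *present after preprocessing*, not
"dysregulated" ones; where the procedure's wording is ambiguous, presence
is the reading that keeps exclusion independent of the test outcome.

## Cross-study consensus

Per-dataset calls are tallied per set: n_up, n_down, n_ns, n_excluded sum
to the number of datasets tested. Consensus-at-k in a direction means at
least k datasets called that direction; a dataset where the set was
excluded still counts in the denominator but cannot contribute a call.
The default report uses k = n and k = n−1 (all studies, and all-but-one).
Consensus is monotone in k and invariant to the order of dataset results.
A set called up in ≥1 dataset and down in ≥1 other is flagged as a
conflict; conflicts do not block consensus accounting (a 3-up/3-down set
simply reaches neither direction at k = 4).

## Gene-level meta-analysis

Each dataset contributes a two-sided p from the same equal-variance t
(df = n1 + n2 − 2). For a gene observed in k datasets,

    χ² = Σᵢ (−2 ln pᵢ),   df = 2k,

and the combined p is the upper chi-square tail — Fisher's method, exactly
chi-square distributed under the null for continuous data. Genes are
combined over the datasets in which they survived preprocessing, with
`k_min = 2` required (different platforms measure different gene subsets;
requiring presence everywhere would discard most of the universe). A gene
present in fewer than k_min datasets is reported with an empty combined p
and never selected. Selection is combined p < α (default 0.05).

An optional screening variant (`prefilter_p`) keeps only per-dataset
p-values below a threshold before combining. Screening on significance
biases Fisher's null toward small combined p-values, so the default is
off; the flag exists because two-stage screening is common practice and
reproducing it must be possible. p-values are floored at 1e-300
(configurable) before the log so χ² stays finite.

Closed-form identity used in testing: for even df = 2k the upper tail is
e^{−χ²/2} · Σ_{j<k} (χ²/2)^j / j!, which an independent oracle evaluates
against the implementation to 1e-10.

## Over-representation of the selected genes

The selected gene list is tested against each set by the hypergeometric
upper tail: with background size M, set size K within the background, list
size N and overlap x, p = P(X ≥ x). The EASE variant — the conservative
score popularised by the DAVID service — recomputes the tail after
removing one gene from the observed overlap (floored at 0), so
p_ease ≥ p_hyper with equality only at x = 0; EASE is the default,
matching the DAVID-style annotation convention. The background defaults to the
union of genes surviving preprocessing across all datasets — the universe
the meta-analysis actually tested — not the whole genome; it is
configurable. Benjamini–Hochberg q-values are available but off by
default, matching the uncorrected reporting convention of the workflow
this implements. At desk-checkable sizes (background ≤ 12) both tails are
verified exactly against rational brute-force enumeration of all draws.

Note the discreteness of the hypergeometric: at small backgrounds the
achievable rejection rate at α = 0.05 is well below 0.05. The null
calibration test therefore uses background 1000, sets of 60 and lists of
100, where the step size is small enough for the empirical rate to sit
near the nominal level.

## Synthetic compendia

The generator emulates a multi-study compendium with known truth, all on
the log2 scale:

* gene baseline means ~ Normal(8, 2²) once per compendium (RMA-like
  intensity range);
* 1..`probes_per_gene_max` probes per measured gene, probe offsets
  ~ Normal(0, 0.25²);
* sample value = baseline + probe offset + group effect + Normal(0, σ²);
* planted sets: member genes (a fixed fraction `affected_fraction`,
  default 1.0) get a ±δ mean shift in cases; the affected subsets are
  drawn once per compendium and shared across datasets so consensus is
  learnable by design. Sets are sampled independently and may overlap; a
  gene affected in both directions nets to zero shift;
* each dataset measures a `gene_coverage` fraction of the universe but
  always includes every affected gene of each planted set.

Defaults — 6 datasets of 10 vs 10, 800 genes, 40 sets of 10–40 genes,
δ = 1.5, σ = 0.5, coverage 0.8 — describe a regime where single-study
calls are strong but not saturated, so cross-study consensus is the
interesting quantity. Randomness is organised as fixed-offset substreams
of one seed (collection / compendium-level draws / each dataset), so
adding datasets never perturbs earlier ones and every output is
bit-reproducible.

What the generator does *not* model: batch effects, probe
cross-hybridization, heavy-tailed or missing values, correlated gene-gene
noise beyond set-level mean shifts, and platform-specific normalization
artifacts. Passing the benchmark therefore shows the machinery is correct
and calibrated under a clean Gaussian shift model — not that real
compendia, where those nuisances dominate, will yield equally clean
consensus. Note also that because sets overlap, planted genes inflate the
scores of overlapping *null* sets; the recovery benchmark scores planted
sensitivity, and null-set specificity is instead measured on fully null
(δ = 0) compendia, where the per-tail false-positive rate is checked
against its binomial band.

## Problem sizes used in validation

The statistical checks run at: type-I calibration on a δ = 0 compendium of
200 sets × 3 datasets (≈600 set-dataset pairs, B = 1000); recovery on 50
replicate compendia at the default conditions; permutation exactness on
3v3 toys against all-20-assignment enumeration with B = 10000; Fisher
uniformity on 500 null genes × 4 datasets; ORA exactness on every count
configuration with background ≤ 12 (1819 configurations). These sizes give
binomial/KS resolution well inside the asserted bands while keeping the
whole validation fast.

## Pipeline determinism

`run_all` derives each dataset's permutation seed from the global seed by
a fixed stride, writes all tables with a fixed float format (`%.10g`), LF
newlines and stable column order, and keeps wall-clock timings out of the
output files; re-running the same configuration reproduces every output
byte for byte, which is asserted end-to-end in the tests.
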