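# Methods

## Scope and data model

The package analyzes droplet scRNA-seq of dermal fibroblasts from young
and old donors at the stage *after* alignment and clustering: the inputs
are a cells × genes UMI count matrix (10x Matrix Market convention),
per-cell annotations (donor, age group as the dichotomy young/old,
cluster label), gene-signature lists, and a stem-vs-fibroblast
differential-expression reference table. Upstream steps — read alignment,
graph clustering, embedding — are out of scope; cluster labels are inputs
(the synthetic generator provides ground-truth labels).

## QC and normalization

Cells are removed when their number of expressed genes (raw count > 0)
is < 200 or > 7,500, or their mitochondrial UMI fraction is > 5%. All
three inequalities are strict: cells at exactly 200 genes, exactly 7,500
genes or exactly 5% mitochondrial content are retained. Mitochondrial
genes are those whose symbol starts with `MT-` (case-sensitive, the human
HGNC convention). The mitochondrial fraction is computed on UMI counts
(the natural unit of droplet data); an all-zero cell has fraction 0 by
definition and is removed by the minimum-genes rule rather than raising a
division error. Filtering is idempotent and genes are never removed.

Normalization is counts-per-scale with a log1p transform:
`value(c,g) = ln(1 + count(c,g)/total(c) × scale)`, scale defaulting to
10⁶. This is the "TPM" layer appropriate for 3′ UMI data, where no
gene-length term exists. Natural log with pseudocount 1 avoids log(0) and
follows dominant single-cell practice; both choices are recorded on the
output object. Two identities pin the implementation: the zero pattern is
preserved exactly, and per cell Σ_g (e^value − 1) = scale.

## Marker statistics

One-vs-rest testing per cluster: genes expressed in ≥ 10% of either group
(configurable) get a two-sided Wilcoxon rank-sum p-value and a log
fold-change `ln((mean_in(e^v−1)+1)/(mean_out(e^v−1)+1))` — de-logged
means with pseudocount 1, natural log. The rank-sum test uses the normal
approximation with midrank tie correction and continuity correction
(count data are tie-heavy); when the two groups together have ≤ 25 cells
and the values are tie-free it switches to the exact null distribution,
which coincides with full enumeration over group assignments. A gene with
identical values in both groups is defined to have p = 1. Multiple
testing within a marker table uses Bonferroni (the convention of the
standard one-vs-rest marker workflow); the over-representation test uses
BH, which keeps multi-term enrichment scans usable.

Signature scores are per-cell means of normalized values over the
signature genes present in the matrix (missing genes are reported, never
silently dropped). Dot-plot summaries report percent expressed (count >
0; for signatures, score > 0) and mean expression per cluster.
Over-representation of a query set in a term is the hypergeometric upper
tail P(X ≥ overlap) with fold enrichment
`(overlap/|query|)/(|term|/|universe|)`.

## Stemness score

From the reference table (one row per gene: symbol, signed effect —
positive = up in stem cells — and adjusted p), rows with p_adj < 0.05 are
eligible; the stem list is the top 250 by effect descending, the
fibroblast list the top 250 ascending. Boundary ties break
deterministically by (p_adj ascending, symbol); a direction with fewer
than 250 significant genes returns what exists, with a warning. Whether
the original selection ranked by effect or by significance is not
documented anywhere authoritative; ranking by effect size is this
package's choice, and planted-truth tests only require that the reference
generator and selector agree.

Per cell and per list, `identity = n + Σ logTPM` with n = number of list
genes with raw count > 0, and `stemness = (stem identity + 1)/(fibroblast
identity + 1)`. Σ logTPM is computed as the sum of ln(1 + counts-per-
scale) over **all** list genes present in the matrix — zero-count genes
contribute 0 — rather than ln of raw TPM over expressed genes only. The
published formula says only "log TPM"; summing ln TPM over expressed
genes admits negative contributions from genes with TPM < 1 and is
sensitive to the expression threshold, so the bounded variant is the
default; the expressed-only variant is available via `expressed_only=True`
and the mode is recorded on the result. Consequences worth knowing: the
score is strictly positive, equals exactly 1 when a cell expresses no
listed gene, never decreases when an up-list count is raised and never
increases when a down-list count is raised.

Group comparisons use the unpaired Wilcoxon rank-sum test with the stated
sidedness; "highest among populations" is a set of one-vs-each-other-
population one-sided tests.

## Composition analysis

Each cluster is tested against all remaining cells pooled. The 2×2 table
(a = old in cluster, b = old out, c = young in, d = young out) gets the
two-sided Fisher's exact p under the point-probability scan rule (sum of
all tables with point probability ≤ the observed one — the convention of
mainstream exact-test implementations), computed via scipy and verified
against direct hypergeometric-support enumeration. The odds ratio is the
cross-product ad/bc in an explicit orientation: old-enriched reports
odds(old)/odds(young), young-enriched the reciprocal, because the
direction of reporting flips between populations that grow and shrink
with age. The 95% CI is Woolf's logit interval ln OR ± 1.96·√(1/a + 1/b +
1/c + 1/d); when any cell is zero the Haldane 0.5 correction is applied
to all four cells for both the estimate and the interval, keeping OR
finite and inside its CI. The original report's CI method is unreported
(and one printed interval is internally inconsistent), so no attempt is
made to match CI bounds — only the ORs, which the point-probability and
cross-product conventions fully determine.

Per-donor analysis: each donor's fraction of cells in the cluster, young
vs old by a two-tailed unpaired Student t-test (equal variances pooled;
Welch behind a flag), reported with group means ± SEM.

## Synthetic cohort generator

The generator emulates the study design this pipeline targets: 3 young
and 4 old donors by default, five fibroblast populations (reticular F1,
papillary F2, pro-inflammatory F3, and the mesenchymal subpopulations
F4a = dermal sheath and F4b). Counts are negative binomial, parameterized
by mean and a single cohort-wide size parameter (default 2.0), with
gene-level baselines drawn log-normal (σ = 1) around a mean of 0.5
counts/gene/cell — a realistic sparsity for whole-skin droplet data.
Each cell's mean vector is baseline × its population's program
fold-changes × a per-donor log-normal library-size factor (σ = 0.15,
donor effects limited to depth so composition recovery stays
unconfounded by default). Genes named `MT-*` (13 by default, the size of
the human mitochondrial proteome) are rescaled so the expected
mitochondrial fraction is 2%.

Membership is drawn per cell from its age group's population
probabilities. The default design encodes the published composition odds
ratios exactly: young probabilities (0.300, 0.486, 0.150, 0.034, 0.030)
and old probabilities (0.419328, 0.466444, 0.095781, 0.004935, 0.013512)
for (F1, F2, F3, F4a, F4b), giving true ORs 1.685 (old-enriched), ~1.08,
1.666, 7.097 and 2.258 (young-enriched). The published work gives cluster
sizes only as totals, so the absolute probabilities are free parameters
chosen once to be realistic (reticular largest, DS a few percent of young
fibroblasts) under the printed OR constraints.

Age-dependent expression uses a global `aging_effects` list — (gene,
fold-change) applied to every old cell — the minimal mechanism for an
age-attenuated program. The stemness demo design plants a 40-gene stem
program at fold-change 6 in F4a and attenuates those genes to 0.35× in
old cells, over a near-balanced composition so each population has
hundreds of cells per age group for rank tests. A companion generator
emits the emulated stem-vs-fibroblast DE reference: planted up/down sets
with well-separated effects and p_adj ≤ 10⁻⁵, the rest null (|effect| ≲
0.15, p_adj ≥ 0.2), optionally forcing named genes (the planted stem
program) into the up set so end-to-end recovery is checkable.

Seeding: one master `SeedSequence`; per-donor substreams are spawned
deterministically, so output is bit-identical for a fixed spec + seed and
independent of donor evaluation order.

What the generator does **not** emulate: hair-follicle spatial structure,
doublets, ambient RNA, batch effects beyond donor depth, spliced/
unspliced layers, or donor-specific composition noise (available behind
no flag by default — composition varies across donors only through
sampling). Passing tests therefore demonstrate correctness of the
statistics and recovery of planted effects under a clean NB model, not
robustness to real-data artifacts.

## Problem sizes and numerical choices

Test and demo cohorts use 300–850 cells/donor and 900–2,000 genes, sizes
at which every planted effect is comfortably detectable while the full
suite runs in well under a minute per module. Odds-ratio parameter
recovery runs at the published cohort size (19,139 young / 31,010 old
fibroblasts) through the isolated binomial membership layer, 200
replicates per population; the mean estimated OR carries a small upward
Jensen bias of order var(ln OR)/2 (< 0.5% even for the smallest
population), well inside the 2% recovery tolerance. Exact-oracle
equivalence for Fisher's test is checked exhaustively over all tables
with every cell ≤ 5 and on seeded random tables with totals up to 60.
Degenerate inputs are defined, not special-cased: all-tied rank tests
return p = 1, identical-fraction t-tests return (t = 0, p = 1), zero
cells in a 2×2 trigger Haldane, empty margins raise.

## Limitations

- The stemness score depends on the normalization scale through Σ logTPM;
  scores are comparable only within one scale choice (recorded on the
  result).
- Fisher one-vs-rest tests treat cells as independent, ignoring donor
  structure; the per-donor t-test is the complementary donor-level view,
  and compositional mixed models are deliberately out of scope.
- The DE reference here is always synthetic-with-planted-truth; nothing
  validates the score against a real iPS-reprogramming contrast.
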