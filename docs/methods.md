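# Methods

## Scope and model

The package quantifies synonymous codon usage bias in bacterial CDS sets
and attributes it to mutational pressure versus translational selection.
All statistics are computed from 64-dimensional codon count vectors under
the bacterial/plastid genetic code (standard assignments: 61 sense
codons; stops TAA/TAG/TGA; Met and Trp are the only single-codon
families; Leu, Ser and Arg are treated as undivided 6-fold families).

## Inclusion filter

Genome-scale codon statistics are sensitive to fragmentary or
mis-annotated CDS, so sequences pass an inclusion filter before
counting: length ≥ 100 codons, initiation codon in a configurable start
set (default {ATG}; GTG/TTG can be admitted), length divisible by 3, no
in-frame internal stop, and at most 5% ambiguous triplets. Each
rejected CDS is charged to the **first** failing rule in that fixed
order, making filter reports reproducible and additive
(n_input = n_passing + Σ rejections). ATG-only initiation is the
conservative default: admitting GTG/TTG starts is common in bacterial
annotation but changes only the margins of the filtered set. Triplets
containing N are skipped during counting rather than rejecting the whole
gene; the 5% cap bounds the distortion this salvage can introduce.

The terminal stop codon is counted (stop codons have well-defined RSCU
as a 3-member family) but never enters ENc, CAI, GC3s or P1–P3.

## Index definitions and numerical choices

**RSCU.** `RSCU(c) = n_c · k / N` within each family. Families with
N = 0 are *missing* (NaN), not zero — a zero would be indistinguishable
from observed avoidance.

**GC partitions.** P1/P2/P3 exclude ATG, TGG, ATA and stops; GC3s
excludes ATG, TGG and stops but keeps ATA (Ile retains synonymous
choice, so its third position is informative); GC runs over all counted
codons. All values are proportions in [0, 1] internally; writers can
emit percentages.

**ENc.** Wright's estimator with the 9/1/5/3 class decomposition. A
family is scorable when it has n ≥ 2 observations and F̂ > 0 (F̂ = 0,
e.g. a 2-fold family observed exactly once per codon, carries no usable
homozygosity signal and would blow up the reciprocal). When Ile is
unscorable, F̄3 = (F̄2 + F̄4)/2; when any other class is empty its mean
is estimated as the unweighted mean of the available class means. These
imputations follow the usual practice for short genes and are noted on
the returned value. The estimate is capped to [20, 61]: the
finite-sample estimator exceeds 61 under near-uniform usage, and 61 is
the no-bias ceiling by construction. The expected-ENc curve
`2 + s + 29/(s² + (1−s)²)` takes its extreme values 31 at s = 0, 32 at
s = 1 and ≈ 60.5 near s = 0.5 (the exact maximum, 60.5011, sits at
s ≈ 0.5022 because of the linear term).

**CAI.** Weights come from the pooled ribosomal-protein reference.
Zero-count codons in an observed family get the floor w = 0.5/(max
family count), the standard pseudocount that prevents a single rare
codon from annihilating the geometric mean; families absent from the
reference altogether are scored neutrally (w = 1, equivalent to giving
every member the 0.5 pseudocount) and flagged. Both flags are carried
on the model for transparency. CAI is the count-weighted geometric mean
of w, so it is invariant to gene length at fixed codon proportions.

**Optimal codons.** The high/low contrast groups default to the top and
bottom 10% of genes by CAI — the test itself is grouping-agnostic, and
CAI grouping matches the translational-optimality framing; ENc- or
axis-based grouping can be substituted by passing different groups. χ²
is computed on the 2×2 codon-vs-rest-of-family table without Yates
continuity correction, two-sided, for determinism and cross-codon
comparability (recorded in the result metadata). Tables with a zero
margin are skipped and flagged.

**Correspondence analysis** operates on the gene × 59-codon RSCU matrix
(not raw counts): RSCU removes amino-acid composition so axes reflect
synonymous choice. Families a gene never uses are imputed at RSCU = 1
(neutral) and the imputation count is reported — zeros would fabricate
avoidance signal for short genes. CA is the standard SVD of the
chi-square-standardized residual matrix; per-axis inertia is σ², total
inertia equals table χ²/N. The SVD sign ambiguity is fixed by orienting
each axis so its largest-magnitude codon coordinate is positive.

**Neutrality plot.** OLS of P12 on P3 (with Spearman ρ), rather than
reduced-major-axis regression: the slope is read as the mutational
(neutral) share of compositional covariation, 1 − slope as the selection
share. Constant P3 leaves the slope undefined (flagged); constant P12
leaves ρ undefined.

**Clustering.** Pairwise squared Euclidean distances between pooled
genome RSCU vectors, average linkage (configurable); genomes are sorted
by label before linkage so ties resolve deterministically. Average
linkage on a fixed dissimilarity is monotone, so merge heights are
non-decreasing; the Newick export uses height differences as branch
lengths.

**Highly expressed genes.** Per-strain ribosomal reference (product
contains "ribosomal protein", or gene symbol rpl*/rps*/rpm*; or an
explicit list file), top-⌈5%⌉ by CAI with ties broken by gene id, and
cross-strain comparison by shared gene symbol only. Sequence-based
orthology inference is deliberately out of scope; symbol intersection
reproduces the structure of ortholog tables without external tools.

## Synthetic data: what it emulates and what it does not

`simulate_genome` draws amino acids i.i.d. from a fixed frequency vector
(uniform over the 18 variable amino acids, Met/Trp at 1%), then encodes
each residue either with its designated optimal codon (probability s,
the class's selection strength) or from the family under the mutational
model: third-position G/C probability θ, A/T probability 1 − θ, uniform
within each subset. First/second positions are fixed by the amino-acid
draw, so θ controls GC3s in isolation — the contrast the neutrality plot
measures. Defaults are the AT-rich study conditions: θ = 0.266,
500 genes of 100–300 codons, a 5% highly expressed class at s = 0.9 over
a background at s = 0.1, and a T-ending (else A-ending) optimal codon
per family, mirroring the A/U-ending preference of AT-rich genomes.
Part of the highly expressed class carries ribosomal annotations so
reference selection and symbol intersection work end to end.

One consequence of this construction: selection dilutes GC3s, since
optimal codons are A/T-ending — a gene class with selection strength s
has E[GC3s] = (1 − s)·θ. GC3s therefore estimates θ only in the
mutation-dominated condition (s = 0), and the parameter-recovery checks
(mean GC3s → θ as codon totals grow; per-strain mean GC3s within
[0.25, 0.29] at θ = 0.266; dendrogram recovery of planted θ regimes) are
run with selection off, while planted-class recovery by CAI runs under
the default s = 0.9 vs 0.1 contrast. `simulate_strain_set` jitters θ
and the selection strengths per strain by N(0, divergence) and can plant
two regimes at θ ∓ 0.01 — a shift chosen so that, at 500 genes × 300
codons, between-group RSCU distances exceed within-group sampling noise
several-fold while both regimes keep GC3s within the AT-rich band.

The simulator does **not** model phylogenetically correlated evolution,
amino-acid composition differences between genes, gene length/expression
correlations, strand or positional effects, or indels. Passing tests on
synthetic data therefore demonstrate the correctness of the statistics
and the recoverability of planted parameters, not that real genomes meet
the generator's assumptions.

All randomness flows from one master seed through named substreams
(strain index, gene index), so a single gene can be regenerated in
isolation and FASTA output is byte-identical across runs.

## Problem sizes

The test suite exercises cohorts of up to 12 strains × 500 genes × 300
codons (≈1.8 M codons), the scale at which planted-regime recovery and
the GC3s band are asserted; unit and property tests use tens to hundreds
of genes. The full suite runs in a few seconds on one CPU.

## Known limitations

- "Optimal codon" detection depends on the contrast grouping; different
  groupings (ENc-based, axis-1-based) can flag different marginal codons.
- The symbol-keyed ortholog report inherits annotation inconsistencies
  between genomes; unnamed genes are reported but not matched.
- ENc for very short or compositionally extreme genes relies on the
  class-imputation rules above; such genes carry a note and are best
  excluded from fine comparisons.
- The real-data integration check (per-strain summary statistics against
  published per-genome values) requires locally downloaded CDS sets and
  is skipped when they are absent.
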