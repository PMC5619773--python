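# Methods

## Model and assumptions

`gst` treats each genotyped exome site as a Bernoulli-style trial per
contributing family member: the member is either *consistent* with a
causative variant segregating with the disease (indicator 0) or not
(indicator 1). The method assumes a single-family, highly penetrant,
effectively monogenic architecture: every affected member carries the
causal genotype, every unaffected member does not, and the causal variant
is family-specific (absent from the reference). No recombination model,
allele-frequency prior, or population panel is used — the statistic is a
pure within-family contrast, which is what makes it applicable when only
one small pedigree exists.

Two family configurations choose the indicator equations:

* **Condition 1 — both parents genotyped.** Offspring (C = V − 2
  contributors) are compared against the reference, the unaffected
  parents (required to be homozygous reference) and the affected parents
  (whose genotype an affected offspring must share). The published
  equations reference one parent of each disease state; when both parents
  share a state the clause for the absent state is dropped, which
  degrades gracefully to "offspring matches like-state parents and the
  reference rule".
* **Condition 2 — at most one parent genotyped.** All V members count as
  offspring. Affected members are compared against the modal affected
  genotype MSNV (ties broken by allele-sorted string; computed over
  non-missing calls). An affected member with a non-modal, non-reference
  genotype scores 0.5 — partial support, allowing for genotyping error
  in the patient pool. An affected member that is homozygous reference
  scores 1 even though the published case chain is ambiguous there: the
  method's stated premise is that patients differ from the reference.

Genotypes are unordered allele multisets — phase is ignored and zygosity
matters (A/G ≠ G/G). Missing genotypes score 1 by default (conservative:
missingness pushes LF away from 0 and cannot create candidates); the
`skip` policy instead removes the member from that site's sum and
decrements the site-local denominator.

## Window statistic

The pattern frequency LF_j (sum of contributing indicators) is averaged
over a window of 2n+1 consecutive markers and normalized to the
proportion PR ∈ [0, 1]. PR is tested one-tailed against the null PR ≥ 0.5
with a lower-tail normal approximation at effective sample size
m = C·(2n+1) — each member-site cell is one trial. The approximation is
the default because Condition 2's half-unit indicators make success
counts non-integer; `--test z-cc` adds a continuity correction and
`--test exact` offers a binomial fallback for integer (Condition 1)
counts. No multiple-testing correction is applied by default (the
selection rule is a fixed per-window α = 0.05 threshold); `--fdr` applies
Benjamini–Hochberg across all windows for users who want it.

The p-value is multiplied by the span weight w = (L_max − L_min)/(t·10⁶):
two windows with equal PR are distinguished by how tightly their markers
cluster, and the tuning parameter t (default 1 Mb) sets the span at which
the weight is neutral. The score is −ln(w·p) — natural log, the only base
under which the selection threshold −log(0.05) prints as 2.996. Scores
can be negative when w·p > 1; they are reported unclamped since selection
uses only the upper threshold (the plot clips them at 0, the "trimmed
score").

Window centers run over i = n+1 .. U−n−1 per chromosome (1-based), so the
first and last n sites are unscored, windows never span chromosomes, and
a chromosome needs at least 2n+2 sites to yield any window. The
vectorized scan (cumulative sums) is tested against a naive per-window
recomputation at 1e-12 relative tolerance.

## Parameters

| parameter | default | meaning |
|---|---|---|
| n | from formula | markers each side of the window center |
| t | 1 Mb | span at which the weight is 1 |
| α | 0.05 | selection level; threshold −ln(α) = 2.996 |
| E | 0.05 | margin of error in the window-size formula |
| z | 1.645 | one-sided 5% normal critical value |
| splice-bp | 2 | intronic bases flanking CDS boundaries counted as splice site |
| missing-policy | one | missing genotype scores 1 (`skip`: drop from the sum) |

n = round((((z·0.5)²/(C·E²)) − 1)/2), half-up, floored at 1. For C = 7
this gives 19; C = 2 gives 67 — small families need wide windows because
each site carries few trials.

## Input handling

Per-member variant lists are outer-joined on (chromosome, position,
reference allele); a site absent from a member's VCF is a
homozygous-reference call, since the indicators compare every member
against the reference at every merged site. Records whose REF conflicts
across inputs at one position are dropped and logged to an audit TSV.
Multi-allelic records are kept as one site record carrying the full
genotype multisets (splitting them per ALT would duplicate loci without
changing any multiset comparison). Chromosome naming is normalized to
the dialect of the first input. A plain TSV genotype table is accepted
as an alternate input for pre-made SNV matrices.

Splice sites are the ±2 intronic bases at each internal CDS boundary of a
transcript (canonical donor/acceptor), configurable via `--splice-bp`.
When a position is both CDS (one transcript) and splice (another), CDS
wins; among overlapping genes the lexicographically first name is
returned for determinism. The report keeps one row per gene (its
best-scoring SNV) with every supporting SNV in a detail file; the primary
sort is by score, with phenotype annotation used as a tie-break and as a
separate grouped view (`report_by_phenotype.tsv`) that lists annotated
genes first.

## Synthetic families

The simulator emulates the regime the scan targets: a small family whose
members share most variants regardless of affection (shared heterozygous
background sites at rate 0.35), occasional private variants (rate 0.05),
and a planted causal cluster — patient-specific heterozygous SNVs,
identical in all affected members and absent in the unaffected, inside
the CDS of a designated gene. Defaults are seven data-bearing members
(two affected) with no genotyped parents, so Condition 2 with C = 7 and
n = 19 by the formula; the cluster holds 2·19+1 = 39 SNVs in 50 kb so at
least one full window fits inside it; two 60 Mb chromosomes carry 260
sites each, enough for several hundred scanned windows per replicate
while keeping a 10-seed recovery experiment under a few seconds.
Background loci are excluded from the cluster interval so the planted
pattern is contiguous in marker space. Genotyping error replaces a call
with a uniformly random different genotype over {ref, alt}; missing noise
blanks calls.

What the simulator does **not** model: linkage disequilibrium and
recombination, realistic exome site density (sites are uniform per
chromosome), allele-frequency spectra, sequencing-depth-dependent error,
and Mendelian transmission for Condition 1 trios. Passing recovery tests
therefore demonstrate the statistic's behavior under its own model — a
clean co-segregating cluster against exchangeable background noise — not
calibration on real exomes.

## Numerical choices and edge cases

* p-values are clipped below at 1e-300 before the log so extreme windows
  score finitely.
* Half-up rounding for the window size (`floor(x + 0.5)`).
* Modal-genotype ties break lexicographically on the allele-sorted
  genotype string; all-missing affected calls yield a missing sentinel
  and indicator 1 for affected members at that site.
* Duplicate loci are deduplicated upstream, so window spans are strictly
  positive and the weight never degenerates.
* Report floats print at 6 decimals, making re-runs byte-identical.

## Known limitations

* The proportion test treats member-site cells as independent trials;
  adjacent exome sites are correlated in real data, so the nominal α is
  approximate and the LF = 0 center filter carries much of the
  specificity burden.
* Condition 1 assumes parental genotypes are reliable; a missing parent
  call at a site forces all offspring indicators to 1 there.
* Gene attribution at overlapping loci is deterministic but arbitrary
  (first name in lexicographic order).
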