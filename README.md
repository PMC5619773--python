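# gst — gene selection tool for small-family exome linkage

`gst` prioritizes candidate disease genes from whole-exome sequencing of a
single small family (2–10 members). In families, most called variants are
shared among members regardless of affection status, so single-variant
filters leave long candidate lists. `gst` instead scores **multilocus
co-segregation**: it quantifies, at every genotyped site, how cleanly the
family's genotypes split patients from unaffected members, aggregates that
signal over a sliding window of neighboring markers, and reports genes
whose coding or splice-site variants sit in significant, tightly clustered
windows.

## The statistic

For site *j* and member *v*, an indicator *I(SNV<sub>jv</sub>)* is 0 when
the member's genotype is consistent with a causative variant segregating
with disease and 1 when it is not:

* **Condition 1** (both parents genotyped): offspring are compared against
  the reference allele and both parents' genotypes; only the C = V − 2
  offspring contribute.
* **Condition 2** (at most one parent genotyped): all C = V members count
  as offspring. An unaffected member scores 0 iff homozygous reference; an
  affected member scores 0 iff it carries the modal affected genotype
  *MSNV<sub>j</sub>* and that genotype is non-reference (0.5 for a
  different non-reference genotype).

The pattern frequency LF<sub>j</sub> = Σ<sub>v</sub> I(SNV<sub>jv</sub>)
is 0 exactly when patients and unaffected members separate perfectly.
Over the window ℶ(i, n) of 2n + 1 consecutive markers,

```
PR = Σ_{j∈ℶ(i,n)} LF_j / (C·(2n+1))
p  = Φ( (PR − 0.5) / √(0.25 / (C·(2n+1))) )        one-tailed, H0: PR ≥ 0.5
w  = (L_max − L_min) / (t·10⁶)                      span weight, t in Mb
Score = −ln(w · p)
```

Sites with Score > −ln(0.05) = 2.996, LF = 0 at the window center, and a
CDS or splice-site location are reported, ranked by score. The half-width
n comes from the proportion-test sample-size formula
n = ((((1.645·0.5)² / (C·0.05²)) − 1) / 2, rounded; for C = 7 contributing
members this gives n = 19.

## Worked example

Simulate a seven-member family (two affected, no genotyped parents) with
39 patient-specific coding SNVs planted in a 50 kb gene, then scan it:

```
$ gst simulate --out demo --seed 42
$ gst run --vcf demo/family.vcf --ped demo/family.ped \
          --gff demo/genes.gff3 --out demo/out
1 candidate gene(s) written to demo/out/report.tsv
$ gst window-size --members 7
19
$ head -2 demo/out/report.tsv
rank  chromosome  locus     gene         score       region  ...
1     chr1        30026309  GENE_CAUSAL  143.315942  CDS
```

The scan auto-derived n = 19 from C = 7 (see `demo/out/manifest.json`),
slid the 39-marker window over each chromosome, and the only window
passing all three filters centers in the planted gene: its PR is 0 (every
member consistent at all 39 sites), giving a vanishing p-value, and the
50 kb span gives weight w ≈ 0.05, hence the large score 143.3. Background
windows have PR near the shared-variant load of the family and never
combine Score > 2.996 with a perfectly segregating (LF = 0) center.

Other outputs: `windows.tsv` (every window's PR, p, span, weight, score),
`report_detail.tsv` (all supporting SNVs per gene), `plot.tsv` / `plot.png`
(Manhattan-style trimmed-score plot, autosomes alternating red/blue), and
`indicators.tsv.gz` (the full per-member indicator matrix for audit).

Real data go in the same way: one multi-sample VCF or one VCF per member
(`--vcf` repeatable), a PED-like pedigree, a GFF3/GTF gene model, and
optional annotation TSVs (`--annot` gene/description/phenotype,
`--variant-annot` chrom/pos/SIFT/PolyPhen-2) joined into the report.

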