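# exotier

Assessment and prioritisation of variants in small exome cohorts.

Researchers studying a cohort that shares a phenotype — a Mendelian disease
family, a small case series — usually receive a multi-sample VCF annotated
with ANNOVAR or VEP and then face two problems: turning those annotations
into defensible ACMG/AMP classifications, and finding variants enriched in
the cohort without having sequenced controls. `exotier` does both. It
assigns every ACMG/AMP evidence criterion that annotations can support,
converts each variant's criteria set into a continuous posterior probability
of pathogenicity, tests cohort enrichment against public population
frequencies, handles parent–offspring trios, and writes filtered, by-sample
and gene-burden reports.

## The model in brief

Criteria are combined two ways. The categorical ACMG class follows the
Richards et al. (2015) rules. The continuous posterior follows the
Tavtigian et al. (2018) Bayesian framework: evidence strengths form a
geometric ladder in the exponent of the combined odds of pathogenicity,

    OddsPath  = O_PVSt ^ (n_PP/8 + n_PM/4 + n_PS/2 + n_PVS − n_BP/8 − n_BS/2)
    posterior = OddsPath · Prior / ((OddsPath − 1) · Prior + 1)

with defaults Prior = 0.10, O_PVSt = 350 and scaling X = 2 (hence the
denominators 8/4/2/1). BA1 is stand-alone: it forces the posterior to 0.

Cohort enrichment (criterion PS4) needs integer control counts, so a control
minor allele frequency MAF_c = y × 10⁻ˣ (1 ≤ y < 10) is extrapolated to
n_c = ⌈y⌉ affected and N_c = 10ˣ/2 − n_c unaffected control individuals —
for MAF_c = 3.23 × 10⁻⁵, n_c = 4 and N_c = 49 996. A one-sided Fisher exact
test on [cohort carriers/non-carriers vs n_c/N_c] assigns PS4 when OR ≥ 20,
p ≤ 0.001 and at least 2 cohort individuals carry the variant. The ceiling
deliberately overestimates the control frequency, making this test uniformly
more stringent than the naive calculation.

Per-gene prioritisation uses the burden score Σ P_i · N_i over the gene's
variants with P_i > 0.80 (P_i = posterior, N_i = carriers), with advisory
warnings for FLAGS genes, very long genes and excess-carrier artifacts.

See `docs/methods.md` for the full model description, thresholds and
limitations. The bundled gene/pathway lookup tables are small synthetic
stand-ins (marked `.synthetic.` in their filenames) and are user-replaceable.

## Worked example

Generate a synthetic 10-sample cohort (one trio plus seven unrelated cases,
12 variants with known ground truth), then classify it:

```
$ exotier make-fixtures -o cohort --seed 1
$ exotier sort -i cohort/cohort.annovar.tsv -o reports --tab \
      --trio cohort/pedigree.tsv --by-gene --by-sample
12 variants classified (5 above the pathogenic threshold)
```

The main report (first columns shown):

```
Chr  Pos        Ref   Alt  Gene   ACMG_criteria   ACMG_class         Posterior_probability  Probability_verdict
2    166245425  C     T    SCN1A  PS3, PM1, PP2   likely_pathogenic  0.9492358517894096     pathogenic
2    178528000  C     G    TTN    BP1, BP4        likely_benign      0.02504522570204682    benign
3    37047000   A     G    MLH1   PS4, PM2        likely_pathogenic  0.8999100280514164     pathogenic
7    5530600    A     G    ACTB   BP6, BP7        likely_benign      0.02504522570204682    benign
7    117559500  T     C    CFTR   BS1, BS2, BS3   benign             1.6968679799491277e-05 benign
10   87933000   G     T    PTEN   PVS1, PS2, PM2  pathogenic         0.999682323240033      pathogenic
12   111803000  G     A    ALDH2  BA1             benign             0.0                    benign
13   32338000   C     T    BRCA2  PVS1, PM2       likely_pathogenic  0.9940900584647195     pathogenic
14   23424000   TCTG  T    MYH7   PM2, PM4        VUS                0.6751874260043591     unknown
17   7675088    G     A    TP53   PS1, PP3, PP5   likely_pathogenic  0.8999100280514164     pathogenic
17   7675100    G     T    TP53   PM2, PM5        VUS                0.6751874260043591     unknown
19   8950000    A     ACAG MUC16  BP3             VUS                0.050716016942268675   benign
```

Reading it: the PTEN stop-gain is de novo in the trio (PS2) on top of loss
of function in a LOF-intolerant gene (PVS1) and absence from population
databases (PM2) — posterior 0.9997. The MLH1 variant is carried by 5 of the
8 samples that remain after the two unaffected parents are removed, against
a control MAF of 3.23 × 10⁻⁵: odds ratio 20 832 and p = 2.7 × 10⁻¹⁸ earn
PS4. The ALDH2 variant at 12% population frequency is stand-alone benign
(BA1, posterior forced to 0). With zero criteria the posterior would equal
the prior, 0.10; the two VUS here sit at 0.675 because two moderate criteria
give OddsPath = 350^(1/2).

The gene-burden report (`--by-gene`) ranks MLH1 first — one confident
variant times five carriers:

```
Gene   Burden              N_variants_counted  Warnings
MLH1   4.499550140257082   1
PTEN   0.999682323240033   1
BRCA2  0.9940900584647195  1
SCN1A  0.9492358517894096  1
TP53   0.8999100280514164  1
```

The same cohort is also emitted as ANNOVAR-annotated and VEP-annotated VCFs;
`exotier sort` classifies all three renderings identically (`--vep` selects
the VEP dialect). Filtering options: `--list brca2,mlh1` (or a file),
`--kegg "Pathways in cancer"` (bundled pathway snapshot), `--disease
"autosomal dominant"` (gene-description search), `--enrichr [library]`
(online pathway analysis of the pathogenic gene list; default library
GO_Biological_Process_2018).

Everything is also available as a library:

```python
from exotier import read_annovar_table, classify_cohort, gene_burden, Pedigree

cohort = read_annovar_table("cohort/cohort.annovar.tsv")
result = classify_cohort(cohort, pedigree=Pedigree.from_tsv("cohort/pedigree.tsv"))
print(result.report.head())
print(gene_burden(result.report))
```

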