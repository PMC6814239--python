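# Methods

## Scope and model

`exotier` assesses variants in small exome cohorts that share a phenotype.
It consumes files already annotated by ANNOVAR (tab/comma tables or VCF) or
VEP (VCF with a `CSQ` INFO field) and performs four computations per variant:

1. **ACMG/AMP criteria assignment.** Nineteen of the 28 evidence criteria can
   be derived from annotations plus small lookup tables: PVS1, PS1, PS3,
   PM1, PM2, PM4, PM5, PP2, PP3, PP5, BA1, BS1, BS2, BS3, BP1, BP3, BP4,
   BP6, BP7. Two more come from cohort structure: PS2 (trio de novo) and PS4
   (case enrichment). The criteria that require segregation, phase,
   phenotype-specificity or de-novo-without-confirmed-parentage evidence
   (PM3, PM6, PP1, PP4, BS4, BP2, BP5) are never assigned, because an
   annotated variant file cannot carry that evidence.
2. **Categorical class** via the Richards et al. (2015) combining rules
   (pathogenic / likely pathogenic / VUS / likely benign / benign).
3. **Posterior probability of pathogenicity** via the Tavtigian et al.
   (2018) Bayesian reading of the same framework (below).
4. **Reports**: a main table, gene-list / pathway / disease-term filtered
   subsets, a per-sample ranking, and a per-gene burden score.

## The posterior model

Evidence strengths form a geometric ladder. With scaling factor X (default
X = 2) a supporting criterion is worth an exponent of 1/X³ = 1/8, moderate
1/X² = 1/4, strong 1/X = 1/2 and very strong 1, so

    OddsPath  = O_PVSt ^ (n_PP/8 + n_PM/4 + n_PS/2 + n_PVS
                          − n_BP/8 − n_BS/2)
    posterior = OddsPath · prior / ((OddsPath − 1) · prior + 1)

with defaults prior = 0.10 and O_PVSt = 350. Benign evidence enters the same
exponent with negative sign — the symmetric extension of the pathogenic
ladder — so net-benign evidence pulls the posterior below the prior. BA1
(stand-alone benign, population AF > 5%) overrides everything: the posterior
is forced to 0 and the class to benign, with a conflict note when pathogenic
evidence was present. No cap is applied to per-strength criterion counts.

Verdict thresholds on the posterior are inclusive and configurable; the
recommended pairs are lenient (pathogenic ≥ 0.80, benign ≤ 0.35, the
default) and strict (0.85 / 0.20).

Numerical choices: the exponent is computed in log space; `exp()` overflow
(log-odds > 700) saturates the posterior at 1.0. With zero evidence the odds
are exactly 1 and the posterior equals the prior bit-for-bit. Because the
posterior saturates near 1 in double precision, strict monotonicity in the
evidence counts is guaranteed (and tested) on the log-odds; the posterior
itself is monotone non-strict, and strict away from saturation.

A known friction between the two outputs: the combining rules ignore benign
evidence too weak to fire a benign rule (a single BS alongside two PS still
combines to "pathogenic"), while the posterior subtracts it. Mixed-evidence
variants can therefore be categorically pathogenic with a posterior well
below a clean likely-pathogenic variant. This is inherent to running both
models side by side; the probability is the recommended ranking key.

## Criteria predicates and their thresholds

Each predicate is a pure function of (variant, reference tables,
configuration); missing annotations simply prevent the criteria that need
them. Tunable cut-offs (defaults in parentheses): `rare_threshold` — PM2
population AF ceiling (1e-4); `bs1_threshold` (0.01); `ba1_threshold`
(0.05); `bs2_hom_count` — reported homozygotes tolerated before BS2 (0);
`pp3_fraction` / `bp4_fraction` — fraction of available in-silico predictors
that must agree (0.5), with at least `min_predictors` (2) non-missing calls;
`splice_threshold` — splice-impact score below which a synonymous variant
keeps BP7 (0.6, the conventional dbscSNV cut-off). All are overridable via a
`key=value` config file. With predictors split exactly 50/50, PP3 and BP4
both fire and cancel in the exponent, which is the neutral outcome.

ClinVar assertions are split by review status: assertion-backed statuses
("criteria provided", "reviewed by expert panel", "practice guideline") feed
the strong criteria PS3/BS3; "no assertion" statuses (or a missing status)
feed the supporting PP5/BP6. Significance strings containing "conflicting"
fire nothing.

PS1/PM5 consult a pathogenic amino-acid-change table keyed by (gene,
residue). PS1 requires the same residue substitution from a *different*
nucleotide change; when either cDNA annotation is unknown the change is
assumed different (the optimistic reading; a curated table with cDNA columns
removes the ambiguity). PM5 requires a different substitution at the same
residue and yields to PS1.

## Control-free enrichment (PS4)

The cohort carrier count is tested against pseudo-counts extrapolated from a
public control MAF. Writing MAF_c = y × 10⁻ˣ (1 ≤ y < 10, decimal string
normalization so 3.23e-5 splits into y = 3.23, x = 5 exactly):

    n_c = ⌈y⌉   affected controls,   N_c = 10ˣ/2 − n_c   unaffected

(3.23e-5 → n_c = 4, N_c = 49996). The ceiling overestimates the control
carrier frequency, so the resulting odds ratio is never larger — and the
one-sided Fisher p never smaller — than the naive calculation from unrounded
expected counts; the test is deliberately the more stringent of the two
(property-tested across a MAF × carrier-fraction grid). The approximation
assumes MAF_c < 0.05 and rare variants mostly heterozygous; variants with
control MAF outside (0, 0.05) are not tested (they meet BA1/BS1 instead),
and a variant absent from the chosen control database is treated as
minimally observed (n_c = 1 of 50 000 controls, configurable).

PS4 requires all three gates: OR ≥ 20 (plain cross-product ratio, no
continuity correction; infinity passes), p ≤ 0.001 (one-sided Fisher,
upper-tail hypergeometric sum via scipy), and ≥ 2 cohort carriers. Carriers
are counted at the individual level (a homozygote counts once); genotypes
with any missing allele count as neither carrier nor non-carrier.
Single-sample cohorts skip the test. No multiple-testing correction is
applied across variants.

## Trio analysis (PS2)

A pedigree TSV (`sample`, `trio_id`, `role`, `affected`) defines trios. A
variant is de novo in a trio when the child carries it and both parents are
homozygous reference; a missing parental genotype blocks the call for that
trio (conservative against genotype dropout). PS2 is assigned if any trio
qualifies, with qualifying trios listed per variant. De-novo detection runs
on the full cohort; afterwards unaffected parents are removed from all
downstream analysis (carrier counts, PS4, reports), so they cannot dilute
case frequencies. PS2 counts as an ordinary strong criterion.

## Reports

The by-gene burden is Σ P_i · N_i over the gene's variants with
P_i strictly greater than 0.80 (a variant at exactly 0.80 is excluded),
N_i = carriers after parent removal. Advisory warnings — never score
adjustments — mark FLAGS genes, genes whose bundled coding length reaches
the 99th percentile of the length table, and variants carried by more than
90% of genotyped samples (poorly mapped or pseudo-autosomal artifacts).

The by-sample report ranks each sample's carried variants by descending
posterior (ties by chromosome then position); by default it keeps variants
at or above the pathogenic threshold, or the top k when requested. Filters
(gene list, bundled pathway snapshot, gene-description substring) return
row-subsets of the main report with identical columns. The EnrichR pathway
analysis submits only genes with a variant above the pathogenic threshold
(default library GO_Biological_Process_2018); it is the package's only
network call, has an injectable transport, and degrades to a warning.

## Input normalization

Column names are mapped through an alias table covering common ANNOVAR
spellings and VEP CSQ fields (frequencies: ExAC/gnomAD exome+genome/1000G/
ESP variants; predictors: SIFT, PolyPhen2 HDIV/HVAR, MutationTaster, LRT,
FATHMM, PROVEAN, MetaSVM/LR). Unmapped columns are passthrough. The
sentinels `.`, empty and `NA` mean absent. Coordinates are 1-based
inclusive; indels are taken as given without re-normalization (criteria
assignment never needs it). Multi-allelic VCF records are decomposed per alt
allele with genotypes re-expressed against that allele; the alias table is
config-extensible since no fixed list of required databases exists.

## Synthetic cohorts and what the tests show

The fixture generator realizes blueprint variants whose annotations trigger
exactly the intended criteria, with deterministic genotypes (no sampling
noise, so the truth object is exact) and byte-identical output for a given
spec and seed. The default cohort is 10 samples — one trio with two
unaffected parents plus seven unrelated cases — and 12 variants that jointly
cover all 21 assignable criteria, including a de-novo PTEN stop-gain and an
MLH1 variant at 5/8 post-stripping carriers against a control MAF of
3.23e-5 (the enrichment worked example). Rare non-enriched pathogenic
variants are singletons, because in an 8-sample cohort a second carrier of a
variant that is rare in controls is already genuine enrichment. The same
cohort is emitted in ANNOVAR-table, ANNOVAR-VCF and VEP-VCF renderings, and
the end-to-end tests require all three to reproduce the truth object
identically.

The generator emulates annotation structure, not biology: no linkage,
no sequencing error, no realistic site-frequency spectrum, and one variant
per blueprint intent. Passing tests therefore demonstrate correctness of
parsing, criteria logic, arithmetic and report plumbing on well-formed
inputs — not calibration of the classifier on real clinical data. The
bundled lookup tables (LOF-intolerant, missense-constrained,
truncating-mechanism, FLAGS and benign-domain lists; pathogenic AA changes;
pathway, description and length snapshots) are small synthetic stand-ins,
marked `.synthetic.` in their filenames, and should be replaced with curated
equivalents for production use.

## Known limitations

- Criteria definitions are restricted to evidence an annotated file can
  carry; curators can and should override individual calls.
- The PS4 extrapolation ignores control cohort size heterogeneity and tests
  carriers, not alleles.
- ClinVar-based criteria (PS3/BS3/PP5/BP6) inherit ClinVar's curation
  quality and use substring matching on significance strings.
- BP7's splice check consults a single splice-impact score column; exotic
  splice annotations are not integrated.
- Workbook output is plain multi-sheet; no styling or interactive browsing.
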