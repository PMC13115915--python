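# Methods

## Data model and conventions

Variant records follow VCF 4.2 semantics: 1-based positions, one record
per decomposed ALT allele (each allele carries its own AD entry), and
`chr`-prefixed and bare chromosome labels accepted interchangeably.
Protein positions are 1-based residue indices; domain intervals are
closed on both ends, matching the way domain boundaries are quoted in
annotation databases ("amino acids 1292–1467" includes both residues).

Absent annotations are represented as `None`, never as sentinel numbers.
Filters treat an absent value as failing any criterion that gates on it
— a conservative policy, since a threshold that cannot be checked cannot
be certified — with one deliberate exception: an absent population
allele frequency *passes* the frequency filter, because genuinely novel
variants have no frequency entry, and failing them would discard exactly
the variants a de novo analysis exists to find.

Because plain VCF does not carry exonic/splice annotations or
cohort-recurrence counts, the pipeline transports them in the INFO
fields `REGION` and `RECUR`; readers map their absence to `None`.

## Filter dialects

Two cascades are implemented, reflecting the two variant-calling
pipelines that trio cohorts of this kind combine.

Common block: region ∈ {exonic, splice-site}; total depth ≥ 10 reads in
all three trio members; population MAF ≤ 4 × 10⁻⁴.

`yale` dialect: (i) proband alternate reads ≥ 5; (ii) proband alternate
allele fraction ≥ 0.28 when alternate reads < 10, and ≥ 0.20 when ≥ 10;
(iii) alternate allele fraction ≤ 3.5% in each parent (checked
per-parent). The published wording of criterion (ii) phrases the
high-support clause as "≤ 20%", which would reject every confident
heterozygous call; we interpret it as the *minimum* allele fraction at
higher read support, the standard direction for allele-balance filters.
The literal reading remains available
(`FilterConfig(high_support_fraction_is_minimum=False)`).

`genedx` dialect, criteria i–xi with the published strictness: GQ > 40 in
all members; VQSLOD > −10; FS < 30; proband alternate count > 4;
alternate ratio > 0.1; ratio > 0.15 for equal-length alleles; ratio >
0.25 when lengths differ; ratio < 0.9 on autosomes (sex-chromosome
records skip this ceiling but are otherwise evaluated; a config flag
drops them entirely); both alleles < 100 bp; not (VQSLOD < 7 and ratio <
0.3); carried by ≤ 2 unrelated individuals in the cohort. A proband with
zero sequenced reads makes the allele fraction undefined and raises an
evaluation error rather than silently passing or failing.

Every rejected record names each criterion it failed, and the cohort
filter report reconciles: input = passed + failed + unjoinable +
unevaluable. Boundary behaviour on both sides of every threshold is unit
tested, and both cascades are checked against an independent
per-criterion brute-force evaluator on randomized records.

Visual inspection and Sanger confirmation of individual calls are manual
steps outside this package's scope (a limitation: the cascades model
only the automatable criteria).

## Classification

LoF: stop-gain, stop-loss, frameshift, canonical splice-site (the two
intronic bases flanking an exon), start-loss. Damaging missense (misD):
MetaSVM deleterious **or** MPC ≥ 2 — an inclusive OR, so either
predictor alone suffices; a missense variant with neither predictor
available cannot meet the rule and falls back to `mis`. Composite groups
are derived, never stored: protein-altering = lof + misD + mis,
protein-damaging = lof + misD, so the group identities hold by
construction.

## Burden testing

Expected counts are E_{g,c} = 2·N·p_{g,c}; class-resolved probabilities
compose additively into the composite groups. The Poisson upper tail
P(X ≥ k) is computed through the survival function (regularized
incomplete gamma), which is accurate far into the tail; tests verify
agreement with an independent log-space series summation to 10⁻¹²
relative error over λ ∈ [0.01, 50], k ≤ 100. Degenerate cases: P(X ≥ 0)
= 1 for any rate; a zero rate with a positive observed count yields
probability 0.

Gene-level significance uses α = 0.05 / (3 × 19,347) ≈ 8.6 × 10⁻⁷ by
default (three class groups across the genome-wide gene universe; both
factors configurable). Results carry the raw Poisson p and a Bonferroni-
adjusted p = min(1, p · n_tests); results sort by ascending p with gene
name as the tie-break, so rankings are deterministic. Genes absent from
the rate table raise by default; a "zero" policy substitutes p = 0 for
exploratory runs. Case/control comparison is expressed as two
independent burden runs plus their rate ratios; no additional test
statistic is invented.

### Calibration

The Poisson test is discrete. At exome-realistic per-gene rates
(λ = 2Np_g ≈ 0.05) the achievable p-values are coarse and the test is
strongly conservative: the fraction of null genes with p < 0.05 is
P(X ≥ 2) ≈ 10⁻³, far below nominal — conservatism the suite asserts
directly. Calibration *at* the nominal level is therefore evaluated
where the null has support near it: at λ = 10 per gene the achieved size
is ≈ 0.049, and 200 replicates of a 2,000-gene null cohort recover the
nominal 0.05 within ±0.015 with essentially no genome-wide false
positive. Power against a single 20-fold-enriched gene (baseline
p_g = 10⁻⁵, N = 2,697) is low by the same discreteness arithmetic — the
enriched gene's true mean is only ≈ 1.08 events — and is pinned as a
measured regression value (strict top-rank fraction ≈ 0.09–0.15
depending on seed, genome-wide power ≈ 0.02) rather than asserted as
high.

## Protein density mapping

Per-residue counts increment once per variant *report* (recurrent
variants count their multiplicity; the alternative — once per distinct
variant — can be had by deduplicating upstream). The density is the mean
count over residues i−w … i+w with w = 10 by default. At the protein
ends the window truncates and the denominator is the truncated window's
actual length; a fixed-denominator (2w+1) mode reproduces plots made
with zero padding. A single variant cluster yields a plateau of tied
densities, so the reported peak breaks ties toward the residue with the
highest raw count, then the smallest index — this makes the recurrent
residue of a cluster (e.g. Glu1299 in the bundled example) the peak
rather than the plateau's left edge.

## Kinship QC

The IBS→IBD method-of-moments estimator: per-site expected IBS-class
probabilities under IBD states 0/1/2 are computed from the site allele
frequencies (the classical genotype-based relatedness algebra), state
proportions are estimated by moment matching, negative estimates are
clamped to zero before renormalization, and π̂ = P(IBD1)/2 + P(IBD2).
Parent–offspring pairs are accepted at π̂ ∈ [0.45, 0.55]. The estimator
is validated by simulation (duplicates ≈ 1, parent–offspring ≈ 0.5,
unrelated ≈ 0, with the expected ordering against full siblings), not by
matching any external tool's output bit-for-bit. Sites need frequencies
strictly inside (0, 1) to be informative; fewer than a configurable
minimum (default 100) raises rather than returning a noisy estimate.

Mendelian errors: a proband dosage is impossible when it falls outside
[min transmissible, max transmissible] given the parental dosages (the
possible set is always a contiguous range). De novo candidates are
single-site "errors" by construction, so the genome-wide *rate* is the
QC signal, not any individual site.

## Synthetic cohorts

The generator is the analysis model run forward: per trio, gene-g event
counts are Poisson(2·p_g·multiplier_g) with p_g from a real or
log-uniform-synthesized rate table and multipliers expressing risk-gene
enrichment (1 under the null). Events draw a consequence class
(defaults: lof 0.08, misD 0.17, mis 0.50, synonymous 0.25 — a mix
resembling coding de novo spectra), an annotation consistent with the
class (misD draws receive MPC ≥ 2 or a deleterious MetaSVM call), and
sequencing evidence from the noise model: negative-binomial depths
(mean 60, dispersion 8), Beta(25, 25) heterozygous allele fractions,
clipped-normal GQ (85 ± 12), VQSLOD ~ N(12, 4), FS ~ Exp(3), and 2%
parental contamination at a 1% fraction. Artifact sites are spiked at a
configurable rate (default 1 per trio) with distributions typical of
failed calls: VQSLOD ~ N(−5, 6), skewed Beta(2, 8) allele fractions,
GQ ~ N(45, 20), FS ~ Exp(20), and elevated cohort recurrence. These
distributions are modelling choices of this package — the analysis
thresholds constrain only what passes — chosen so that every filter
criterion sees a non-degenerate pass/fail mix; all are exposed on
`SimulationConfig`, and the seed is mandatory, making every output
bit-reproducible.

What the generator does *not* emulate: mapping and calling artifacts
correlated along the genome, batch effects between sequencing centres,
trinucleotide-context rate structure within genes, mosaicism, and
population structure. Passing tests therefore certify the statistical
machinery and the filter logic, not performance on any particular real
cohort.

Pedigree panels draw parents from Hardy–Weinberg at given site
frequencies and transmit one allele per parent; unrelated/duplicate/
full-sibling modes support the kinship validation. Genotyping noise
replaces calls with a uniform random dosage at a configurable rate, and
the induced Mendelian-error rate is checked against a brute-force
enumeration of the error channel.

## Problem sizes

Simulation-based checks use 2,000-gene cohorts at N = 2,697 with 100–400
replicates, 10,000-site kinship panels with 200 replicates, and a
400-trio cohort for the filter operating point — sizes at which the
Monte-Carlo standard errors are small compared to every asserted
tolerance while the full suite runs in seconds. End-to-end pipeline
tests use smaller, denser cohorts (tens of trios, hundreds of genes,
inflated p_g) so that every stage sees non-trivial counts.

## Known limitations

- The filter cascades model only the automatable criteria; manual review
  and Sanger validation whitelists are out of scope.
- The burden framework is one-sided enrichment; depletion and
  case/control exact tests beyond paired burden runs are not provided.
- Mutation probabilities are consumed as inputs; the package does not
  implement a sequence-context mutation-rate model.
- The IBD estimator targets within-family verification; it is not a
  substitute for robust between-family kinship estimation under
  population structure.
- Multi-allelic handling decomposes sites before filtering; criteria are
  evaluated per decomposed allele, which can differ from pipelines that
  filter whole sites.
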