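# Methods

This note documents the statistical models, parameter choices and known
limitations of `hybridogen`, stage by stage.

## Biological model

The package assumes a two-genome hybrid system: a hybrid taxon carrying
one haploid genome from each of two parental species (here L =
*P. lessonae*, R = *P. ridibundus*), reproducing hemiclonally
(hybridogenesis: one genome excluded from the germline, the other
transmitted clonally), with diploid (LR) and possibly triploid (LLR,
LRR) hybrid forms.  Sex determination is XY with the Y restricted to
the L genome: primary hybridizations pair LL males with RR females, so
the R genome is strictly X-linked, hybrid males are LyRx and hybrid
females LxRx.  Hemiclonally derived homotypic offspring (RR from two R
hemiclones, or LL likewise) carry accumulated deleterious load.

## Diagnostic-locus discovery

A locus is species-diagnostic when the LL reference panel is fixed for
one allele and the RR panel for a different allele — an
allele-frequency difference of 1.0.  Fixation is evaluated on
non-missing reference calls only, with a per-group floor
`min_ref_called` (default 3) so that a single called reference cannot
anoint a locus.  Sites are biallelic-only by default
(`require_biallelic`), matching SNP-matrix practice; multiallelic sites
can be admitted and are accepted when the two panels are fixed for
distinct alleles.  Hybrid and unlabelled samples are ignored during
discovery because they are the inference targets.  The panel is sorted
by locus id for reproducible reports.

## Dosage from allele depths

For a hybrid individual, each usable panel locus contributes the depth
pair (d_L, d_R) of the oriented alleles.  Usability requires the called
genotype to contain both alleles and both depths to reach
`min_depth_per_allele` (default 3): a heterozygote with a zero-depth
allele is indistinguishable from allelic dropout, so such loci are
excluded rather than imputed.  Three summaries are computed:

* `mean_ratio` — mean over loci of max(d_L, d_R)/min(d_L, d_R), the
  statistic as conventionally reported;
* `pooled_ratio` — max/min of the depths summed over loci;
* `mean_log2_lr` — mean of log2(d_L/d_R), whose sign distinguishes LLR
  (L excess, positive) from LRR (negative).

**Finite-depth bias.** max/min is bounded below by 1, so sampling noise
only inflates it: for a true diploid at per-locus depth n the per-locus
expectation is ≈ 1 + 2·E|D|/n with D ~ Binomial(n, ½) centred, giving
≈ 1.16 at n = 100 — which is why published diploid surveys report mean
ratios near 1.1 rather than 1.0, and why the statistic is
depth-dependent.  The pooled ratio aggregates depth before the max/min
and suppresses this bias to O(1/√(total depth)); both are reported, and
both per-locus-then-individual and pooled orderings appear in the
detail output.

**Classification.** `mean_ratio ≤ diploid_max` (default 1.4) calls
DIPLOID_LR; `mean_ratio ≥ triploid_min` (default 1.7) calls
TRIPLOID_LLR or TRIPLOID_LRR by the sign of `mean_log2_lr`; the band in
between is UNDETERMINED, as are profiles with fewer than `min_loci`
(default 20) usable loci.  The thresholds bracket the observed diploid
range (up to ~1.3 at depth ~100) against the triploid expectation of 2;
they are deliberately conservative, and at mean depths below ~50 the
heuristic leaves true diploids UNDETERMINED because of the bias above —
by design, since a borderline call is worse than none.

**Likelihood companion.** For the three hybrid classes the L-read
fraction is p_L ∈ {½, ⅔, ⅓}, shifted by the symmetric sequencing-error
mass ε as p = p_L(1−ε) + (1−p_L)ε.  The per-class log-likelihood sums
Binomial(d_L; d_L+d_R, p) over usable loci; the ML class is reported
alongside the heuristic call and never overrides it.  Unlike the ratio,
the likelihood is unbiased at any depth and resolves ploidy reliably at
mean depth 20 with a few hundred panel loci.

## Microsatellite peak-height ratios

At a co-amplifying L/R diagnostic microsatellite, peak height scales
with allele copy number, modulated by allele-specific amplification
efficiency.  With exactly one L-specific and one R-specific peak,

    PHR = log10(H_R / H_L).

The base is 10 (configurable): it puts the copy-number-2 signal at
±log10 2 ≈ ±0.301, commensurate with the published calibration ranges
shipped in `data/phr_calibration.tsv` (RICA1b5-type genotypes; diploid
LR −0.23–0.00, LLR −0.54 – −0.29 with mean −0.39, LRR 0.09–0.25 with
mean 0.17; the 120/136 calibration is applied unchanged to the
analogous 122/137 and 123/137 genotypes, and users can supply their own
file).  Ranges are closed intervals and must be pairwise disjoint,
checked at load.  Patterns with ≥ 3 distinct peaks are flagged
tri-allelic (direct triploid evidence) and get no PHR; single-peak
patterns (possible null allele) are reported uninformative rather than
quantified.

## Population summaries

Observed heterozygosity H_o is the fraction of heterozygous genotypes
among an individual's called loci (genotype-call basis, not depth
basis), averaged within (population × taxon) groups of at least
`min_n = 5`; smaller groups are omitted with a logged note.  H_o is
computed over all loci by default (the genome-wide figure), with an
optional locus restriction.  All called loci are included, monomorphic
or not.

The hybrid index classifies each sample from its called panel loci:
fractions of L/R-heterozygous, homozygous-L and homozygous-R genotypes.
Thresholds `pure_min = het_min = 0.9` (tolerating genotyping error and
missing data; these are implementation constants, not field-calibrated
values) map the fractions to LL / RR / LR, else AMBIGUOUS.  This is an
intentionally transparent stand-in for Bayesian admixture assignment —
sufficient here because panel loci are fixed between the parental
genomes — and triploids appear as LR at this stage; ploidy is refined
by the dosage stage.

## Cross models

Genome copies are (lineage, sex chromosome) pairs; genotypes are
multisets of 2–3 copies; sex is male iff a Y is present, and Y-bearing
R copies are rejected unless explicitly allowed (logged).
Gametogenesis rules: ELIMINATE_L / ELIMINATE_R (drop that lineage,
segregate the remainder — clonal for one copy, Mendelian ½/½ for two),
AMPHI (transmit L with probability q, R with 1−q; q defaults to 0.5 as
the symmetric minimal assumption, and q ∈ {0, 1} mixtures across
individuals express coexisting L- and R-eliminating lineages),
DIPLOID_LR (unreduced LR gamete), MENDELIAN, and a configurable
per-composition TRIPLOID_RULE table (encoded preset: LLR → recombined
haploid L, males also unreduced LL sperm; LRR → haploid R).  Crosses
multiply the two gamete distributions and union gametes into offspring;
distributions are validated to sum to 1.  Gamete unions outside ploidy
2–3 (diploid egg meeting diploid sperm) raise an error by default or,
in generation recursion, are dropped as inviable with renormalization.

Viability weights act per offspring class (LL / RR / hybrid).  In the
all-hybrid presets w_LL = w_RR = 0 (full hybridogenetic load); in the
L-E preset only w_RR = 0, because there LL offspring arise from the
sexual parental species, not from hemiclones — the load attaches to
hemiclone-derived homotypes, so zeroing w_LL would contradict the
system being modelled.  R_E mirrors this.  Weights are overridable,
e.g. small positive w_RR to model rare surviving hemiclonal RR adults.
`generation_step` iterates genotype frequencies under random mating
within sex; it is a deterministic recursion with no ecology (no
carrying capacity, mate choice or dispersal).

## Synthetic cohorts

The generator emulates the marker structure the analysis assumes, with
defaults set to the study system it was built around: 2521 SNPs of
which 376 diagnostic; a cohort of 20 LL, 5 RR and 30 LR frogs split
over two demes; negative-binomial per-locus depth (mean 20, dispersion
5 — RAD depth is overdispersed; "poisson" is available as the limiting
option); sequencing error ε = 0.01 as symmetric cross-allele depth mass
at diagnostic loci; missing rate 0.1 (the matrix emulated retained SNPs
present in ≥ 80% of individuals).  Diagnostic loci are fixed L/R;
allele depths are multinomial with L-probability equal to the genome
dosage (1, 0, ½, ⅔, ⅓ for LL, RR, LR, LLR, LRR) perturbed by ε.
Genotype calls are diploid-coded (heterozygous iff both alleles
present), with an option to emit triploid GT strings for truth files.

Non-diagnostic loci share one major allele across groups and model
diversity as a single per-class heterozygosity probability: hemiclonal
RR `residual_het = 0.02`, sexual LL `parental_het = 0.07`, hybrids
`hybrid_het = 0.05` off-panel (their genome-wide H_o is dominated by
the always-heterozygous diagnostic loci; with the default geometry this
lands near 0.19).  The three defaults reproduce the observed ordering
and magnitudes of heterozygosity in hemiclones, parentals and hybrids.
This design guarantees that no non-diagnostic locus can satisfy the
fixed-difference criterion, so the planted panel is exactly
identifiable — at the cost of realism: there is no allele-frequency
spectrum, no linkage disequilibrium, no shared hemiclonal haplotype
structure beyond the het-rate scalar, and no read-level error model.
Passing tests therefore demonstrate correctness of the statistics under
the stated sampling models, not robustness to artifacts of real RAD
libraries (allelic dropout covariance, paralog collapse, batch effects).

Microsatellite peaks: each genome copy draws an allele from its
lineage's pool; allele *a* with copy number c gets height
`base · e_a · c · exp(N(0, σ²))` (defaults base 1000, σ = 0.1), with
per-record dropout probability `null_prob` modelling null alleles.  LLR
frogs whose two L copies drew distinct alleles yield tri-allelic
patterns.

## Numerical and testing choices

Problem sizes in the test and acceptance suites are scaled so the whole
suite exercises every claim on one CPU in seconds: convergence checks
use 30–50 loci at depth 10⁴ (law-of-large-numbers regime), dosage-limit
checks use 20 individuals × 376 loci at Poisson(100) depth, and
parameter recovery uses 100 individuals × 500 loci at depth 20.  The
dosage-limit assertions use a 0.01 absolute tolerance on the pooled
ratio, the concentration bound appropriate to that statistic at that
total depth (≈ 37 600 reads per individual).  Distribution sums are
validated to 1e-9; panel and report orderings are lexicographic for
byte-reproducibility; every report file carries the package version,
seed and a parameter digest in its header.

## Known limitations

* The dosage heuristic's thresholds (1.4 / 1.7) are depth-sensitive in
  the regime below ~50× and leave true diploids UNDETERMINED there; use
  the likelihood call at low depth.
* The PHR calibration transfers a published range between analogous
  genotypes; laboratories should calibrate their own markers.
* The hybrid index is not an admixture model and will mislabel
  backcrossed or introgressed individuals that a Bayesian clustering
  would flag as intermediate.
* The cross module enumerates genotype distributions; it does not
  estimate gametogenesis parameters (e.g. q) from offspring data.
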