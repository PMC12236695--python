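# Methods

## The analysis

`mitoscan` scans admixed diploid populations for mitonuclear genetic
incompatibilities using local-ancestry posteriors at ancestry-informative
markers (AIMs). The genetic input is a sites × individuals matrix of
posterior dosages of major-parent ancestry: each entry is read as the
posterior-weighted fraction of the individual's two alleles at that site
descending from the major parent (0, 0.5, 1 for hard calls). A single
designated mitochondrial AIM represents the non-recombining mitogenome;
the per-individual mito haplotype is called from it by thresholding.

Low-confidence posteriors are removed before any statistic is computed:
entries strictly between `lo = 0.2` and `hi = 0.8` become missing.
Values exactly equal to a threshold are retained — the rule is stated as
"below"/"above", and the boundary convention is explicit and
configurable.

For each nuclear AIM *A* against the mitogenome *B* we estimate, over
pairwise-complete individuals,

    pA  = mean dosage at A
    pB  = fraction of major mito calls
    pAB = mean of (dosage × 1[mito = major])

and derive

    D    = pAB − pA·pB
    Dmax = min(pA(1−pB), (1−pA)pB)   if D > 0
           min(pA·pB, (1−pA)(1−pB))  if D < 0
    D′   = D / Dmax                  (0 when D = 0)
    r²   = D² / (pA(1−pA)·pB(1−pB))

Alleles at both loci are labelled by the same parent, so D′ > 0 means
parental (matched) mitonuclear combinations are in excess. The pAB
estimator is chosen so that its marginals are exactly consistent
(summing over mito states returns pA) and so that it reduces to plain
haplotype counting when dosages are hard 0/1 calls — the acceptance
suite verifies this equivalence to 1e−12 against a counting oracle.

Per-AIM statistics are averaged (unweighted) within each gene to limit
pseudo-replication; genes are 1-based inclusive intervals carrying one
of three functional classes: interacting n-mt (nuclear-encoded proteins
in physical contact with mitochondrially encoded gene products),
non-interacting n-mt (mitochondrially targeted, no contact), non-n-mt.
Downstream tests operate on these gene-level values:

* **One-way ANOVA** of gene values on class (fixed effects, scipy's
  implementation; validated in tests against a from-scratch
  sums-of-squares decomposition).
* **Permutation test** on T = mean(class X) − mean(class Y), default
  one-sided upper on (interacting − non-n-mt) since the scientific
  hypothesis is directional; values are reassigned across all genes
  (class sizes fixed); p = (#{T\* ≥ T} + 1)/(n_perm + 1), the add-one
  estimator, which is valid and never returns 0. Two-sided |T| by flag.
* **Top-fraction enrichment**: the ⌈f·N⌉ largest gene values (all
  cutoff ties included), per class an exact upper-tail hypergeometric
  p-value.
* **Z-score outliers**: per gene, (value − genome mean)/sd with the
  n−1 denominator; a gene is an outlier iff Z > 2, strictly and
  one-sided.
* **Cross-population correlation**: Pearson r (two-sided t-test p) of
  gene-level values for a focal gene list shared by two populations.

Statistics at AIMs with a monomorphic marginal (pA or pB in {0, 1}) are
reported missing and excluded from gene means and class tests rather
than set to 0, which would bias class means toward 0. Individuals
missing either member of a pair are dropped for that AIM only
(pairwise-complete deletion). When the filtered mito AIM is monomorphic
the LD scan is undefined; the pipeline switches to the per-gene
matched-allele-frequency analysis (the fixed-mito regime) and says so.

## The simulator

Because the motivating datasets cannot be bundled, the package carries a
forward-in-time simulator whose emissions have the statistical shape the
analysis expects, with ground truth for recovery tests.

**Founding.** Generation 0 consists of pure parental individuals. By
default a founder's mitogenome matches its nuclear species
(`founder_mito_coupling = True`): founding females are major-parent with
probability `mito_init_freq`, founding males with probability
`2·admixture_prop − mito_init_freq`, so mothers realize the requested
mito frequency while the population-wide nuclear proportion stays
`admixture_prop`. This coupling is what gives a fresh hybrid swarm its
maximal mitonuclear admixture LD, which then decays by half each
generation because the mitogenome is unlinked to every nuclear locus.
Setting the flag to False draws nuclear species and mito haplotype
independently (no founding LD).

**Transmission.** Discrete generations, two sexes (equal ratio), random
mating with replacement; gametes receive Poisson(L) crossovers at
uniform positions on each chromosome of genetic length L Morgans;
ancestry is tracked as half-open tracts in genetic coordinates. The
mitogenome is copied strictly from the mother. Physical coordinates for
output files come from a fixed linear map, 1 Morgan = 25 Mb; the
analysis only needs a monotone coordinate convention.

**Selection.** Offspring survive with probability
w = Π over incompatibility loci of (1 − s·g(d)), where d is the
fraction of the individual's two alleles at the locus whose ancestry
does not match the nuclear parent matched to its mitogenome, and
g(0) = 0, g(0.5) = h, g(1) = 1. A locus's `matched_parent` field names
which nuclear parent matches the *major* mitogenome there ("minor"
models inverted pairings such as historically introgressed alleles).
Census size is held constant by drawing offspring until n survive; if
500·n candidates die in one generation the simulator raises an
extinction error naming the generation.

**Migration.** Optionally (`migration_rate`, default 0) a
Binomial(n, m) share of each generation's census is fresh pure-parental
immigrants whose mitogenome matches their species, with species drawn
at `admixture_prop`. This is the minimal representation of the ongoing
replenishment that real hybrid zones experience. It matters more than
it may look: each generation of mitonuclear viability selection changes
the mito haplotype frequency by roughly s·D (the selected locus drags
the maternally co-transmitted mitogenome), so in a *closed* population
any selection strong enough to produce detectable mitonuclear LD fixes
one mito haplotype within a few dozen generations. Persistent
mito polymorphism alongside strong selection — the situation observed
in young natural hybrid zones — requires an inflow term of this kind.
The package does not simulate explicit spatial demes.

**Emission.** True dosages t ∈ {0, 0.5, 1} at a uniform AIM grid are
perturbed to Beta(κt + ½, κ(1−t) + ½) draws — supported on [0, 1],
centered near t, collapsing onto t as the concentration κ → ∞ (κ = inf
emits the truth exactly). A `lowconf_fraction` of entries is replaced
by Uniform(0.2, 0.8) draws, emulating the low-confidence calls that the
standard filter removes. Defaults κ = 50 (posterior noise small but
nonzero) and lowconf = 0.01 (about 1% of calls lost to filtering, the
order seen in practice).

All randomness flows from a single integer seed through separate
substreams for simulation, gene-map layout and emission; identical
configs give byte-identical outputs.

## Frozen study scenarios

`mitoscan.scenarios` pins the conditions used by the calibration and
sensitivity studies (and `scripts/acceptance.py`). The genome is 10
chromosomes × 2 Morgans with 400 AIMs each (4,000 AIMs) and 800 genes
(30 interacting : 170 non-interacting : 600 non-n-mt, ~4.5 AIMs per
gene). The interacting class is deliberately larger than a strict
proportional scale-down of a real genome would give, so that selecting
a ~7% subset of it is a meaningful experiment at this size; the
proportional scaling rule itself (round half up, non-n-mt absorbs the
remainder) is available as `scaled_class_counts`.

* **Segregating-mito hybrid zone** (`call_like_config`): admixture
  proportion 0.522, founding-mother major-mito frequency 0.637, 46
  generations, migration 0.25, n = 300 (n = 100 in the neutral
  calibration study). Incompatibilities are severe and mostly recessive
  (s = 0.9, h = 0.1): homozygous mismatches are embryonic-lethal-grade
  while most heterozygotes survive.
* **Fixed-mito old population** (`huex_like_config`): admixture 0.846,
  mito fixed for the major parent, 263 generations, closed (m = 0),
  n = 100, selection across the interacting class (all 30 genes) with
  moderate mostly-recessive effects (s = 0.3, h = 0.1). Stronger or
  more dominant multi-locus selection here would purge minor-parent
  ancestry genome-wide at the hybridization front — F1-type individuals
  are heterozygous at every selected locus at once — flattening the
  very class contrast the study measures.

Replicates of the segregating scenario are analyzed only when the
filtered mito AIM is still polymorphic (additional seeds are drawn
otherwise), since mitonuclear LD is undefined in a fixed population —
the same restriction natural studies apply.

## What passing tests do and do not show

The simulator emulates: admixture LD and its decay, maternal mito
co-transmission, viability selection with dominance, drift at realistic
desk-scale Ne, posterior noise, and confidence filtering. It does not
emulate: explicit spatial structure or assortative mating, mutation,
variable recombination maps, sex-biased migration, AIM ascertainment,
or HMM-correlated posterior errors along chromosomes (noise is
independent across sites, so real posterior data will be more
autocorrelated than the emissions). Calibration results (ANOVA type-I,
permutation uniformity) therefore speak to the statistics under this
generative model, not to robustness against structure-driven
confounding, which in real hybrid zones is the dominant caveat.

One sensitivity finding deserves emphasis. In the segregating-mito
scenario, increasing the number of strongly selected interacting genes
does **not** increase class-ANOVA power at this scale: each additional
strong incompatibility further couples every individual's hybrid index
to its mitogenome, inflating the genome-wide D′ baseline toward 1
("congealing" toward two reproductively isolated forms) faster than it
raises the interacting-class mean. Class-level tests are accordingly
flat-to-decreasing in power as the selected fraction rises, an
amplified version of the dilution-by-hitchhiking insensitivity that
motivates this package; the outlier Z-scan remains informative only
while the baseline sits clearly below its ceiling (sparse selection).

## Numerical choices

* D′ is defined as 0 when D = 0 (the piecewise Dmax is undefined
  there); r² inherits 0.
* Marginal monomorphism ⇒ all LD statistics missing, never 0.
* Gene means ignore missing AIMs; genes with no defined AIM are dropped.
* sd uses the n−1 denominator everywhere a sd is reported.
* Z > 2 is strict; Z exactly 2 is not an outlier.
* Permutation comparisons use a 1e−12 tolerance so ties count as
  "at least as extreme"; with all values equal the p-value is exactly 1.
* Top-fraction cutoff ties are all included; the realized set size is
  reported.
* The posterior parser rejects values outside [0, 1] naming the cell,
  duplicated (chrom, pos) rows, and missing headers; the sentinel is
  `NA`; `#`-prefixed lines are metadata.

## Problem sizes

The shipped studies use 200 replicates for the neutral ANOVA
calibration (n = 100 individuals each), 20 seeds per selection arm, 20
seed pairs for the fixed-mito study, 500 replicates × 999 permutations
for permutation calibration, 200 random populations for the counting
oracle and 10,000 triples for the invariant sweep — sizes chosen so the
full suite runs on a single CPU in minutes while keeping Monte-Carlo
error well inside the asserted bands.
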