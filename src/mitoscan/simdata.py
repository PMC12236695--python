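"""Forward-in-time simulator of admixed diploid populations with maternal
mitochondrial inheritance and mitonuclear viability selection.

The generative model behind the observed local-ancestry data: two parental
species hybridize once; the founding generation consists of pure parental
individuals (a founder's mitogenome matches its nuclear species).  Each
later generation is produced by random mating between a female and a male
drawn uniformly (with replacement), with gametes formed by Poisson
crossovers (rate = chromosome length in Morgans, positions uniform) and
the mitogenome copied strictly from the mother.  Offspring viability is

    w = prod over incompatibility loci of (1 - s * g(d)),

where d is the fraction of the individual's two alleles at the locus whose
ancestry does not match the nuclear parent matched to its mitogenome, and
g(0) = 0, g(0.5) = h, g(1) = 1.  Census size is held constant by drawing
offspring until n survive.

Ancestry is tracked as tracts in genetic coordinates (Morgans); output
base-pair coordinates come from a fixed linear map (1 Morgan = 25 Mb).
Emitted "posterior" dosages perturb the true dosage with a Beta
concentration-kappa noise kernel, plus a configurable fraction of
low-confidence entries forced into the (0.2, 0.8) band that the standard
confidence filter removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .ancestry_io import AimSite, GeneAnnotation

MORGAN_TO_BP = 25_000_000  # fixed monotone genetic->physical map
MITO_CHROM = "chrM"
MITO_POS = 1


class SimConfigError(ValueError):
    pass


class ExtinctionError(RuntimeError):
    pass


@dataclass(frozen=True)
class IncompatLocus:
    """A gene under mitonuclear viability selection.

    ``matched_parent`` names the nuclear parent whose allele matches the
    *major-parent* mitogenome at this locus; "major" is the ordinary
    coevolved case, "minor" models an inverted (introgressed) pairing.
    """

    gene_id: str
    s: float
    h: float = 0.5
    matched_parent: str = "major"

    def __post_init__(self):
        if not 0.0 <= self.s <= 1.0:
            raise SimConfigError(f"selection coefficient s={self.s} outside [0,1]")
        if not 0.0 <= self.h <= 1.0:
            raise SimConfigError(f"dominance h={self.h} outside [0,1]")
        if self.matched_parent not in ("major", "minor"):
            raise SimConfigError(f"matched_parent must be 'major' or 'minor'")


@dataclass(frozen=True)
class GeneMapConfig:
    """Counts and layout of the three gene classes.

    Genes are laid side by side (equal genetic width, covering ``coverage``
    of each chromosome) and class labels are interleaved at random unless
    ``clustering`` > 0, which places that fraction of interacting n-mt
    genes in consecutive slots on the first chromosome (mimicking genomes
    with dense n-mt clusters).
    """

    n_interacting: int
    n_noninteracting: int
    n_non_nmt: int
    coverage: float = 0.9
    clustering: float = 0.0

    def counts(self) -> tuple[int, int, int]:
        return (self.n_interacting, self.n_noninteracting, self.n_non_nmt)

    @property
    def n_genes(self) -> int:
        return sum(self.counts())


@dataclass(frozen=True)
class SimConfig:
    n_individuals: int = 200
    n_generations: int = 46
    admixture_prop: float = 0.5
    mito_init_freq: float = 0.5
    chromosomes: tuple[tuple[str, float], ...] = tuple(
        (f"chr{i+1}", 1.0) for i in range(5)
    )
    n_aims_per_chrom: int = 400
    gene_map: GeneMapConfig = field(
        default_factory=lambda: GeneMapConfig(30, 170, 600)
    )
    incompat_loci: tuple[IncompatLocus, ...] = ()
    posterior_noise_kappa: float = 50.0
    lowconf_fraction: float = 0.01
    founder_mito_coupling: bool = True
    migration_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 2:
            raise SimConfigError("need at least 2 individuals")
        for frac, name in (
            (self.admixture_prop, "admixture_prop"),
            (self.mito_init_freq, "mito_init_freq"),
            (self.lowconf_fraction, "lowconf_fraction"),
            (self.migration_rate, "migration_rate"),
        ):
            if not 0.0 <= frac <= 1.0:
                raise SimConfigError(f"{name}={frac} outside [0,1]")
        if not self.posterior_noise_kappa > 0:
            raise SimConfigError("posterior_noise_kappa must be > 0 (inf allowed)")
        for cid, L in self.chromosomes:
            if L <= 0:
                raise SimConfigError(f"chromosome {cid} has non-positive length")
        if self.founder_mito_coupling:
            pm = self.founding_male_major_prob()
            if not -1e-9 <= pm <= 1 + 1e-9:
                raise SimConfigError(
                    "admixture_prop and mito_init_freq are jointly infeasible: the "
                    f"implied founding-male major fraction {pm:.3f} is outside [0,1]"
                )

    def founding_male_major_prob(self) -> float:
        """Major-parent probability for founding males, chosen so founding
        females hit ``mito_init_freq`` while the population-wide nuclear
        proportion stays ``admixture_prop``."""
        return 2.0 * self.admixture_prop - self.mito_init_freq


@dataclass
class SimPopulation:
    """Final generation: per individual, two tract haplotypes per
    chromosome (arrays of right edges in Morgans + uint8 parent labels,
    1 = major), a mito label and a sex (0 = female)."""

    chromosomes: tuple[tuple[str, float], ...]
    haplotypes: list  # [individual][chrom] -> ((breaks, labels), (breaks, labels))
    mito: np.ndarray  # uint8, 1 = major-parent mitogenome
    sex: np.ndarray  # uint8, 0 = female

    @property
    def n(self) -> int:
        return len(self.haplotypes)


@dataclass
class SimTruth:
    """Ground truth for recovery tests: true diploid ancestry dosage at
    every AIM (the mito row carries the haplotype as 0/1), the selected
    gene ids, and realized population summaries."""

    sites: list[AimSite]
    dosages: np.ndarray  # (n_sites, n_individuals), values in {0, 0.5, 1}
    selected_genes: list[str]
    mean_ancestry: float
    mito_major_freq: float


# ---------------------------------------------------------------------------
# gene map and AIM layout


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Apportion ``total`` integer slots proportionally to ``weights``."""
    quota = total * weights / weights.sum()
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quota - base))
    base[order[:rem]] += 1
    return base


def scaled_class_counts(
    full_counts: tuple[int, int, int], scale: float
) -> tuple[int, int, int]:
    """Scale per-class gene counts by 1/scale with round-half-up, then
    adjust the non-n-mt count so the total matches the rounded scaled
    total."""
    import math

    def rhu(x: float) -> int:
        return int(math.floor(x + 0.5))

    ni = rhu(full_counts[0] / scale)
    nn = rhu(full_counts[1] / scale)
    total = rhu(sum(full_counts) / scale)
    return (ni, nn, total - ni - nn)


def build_gene_map(config: SimConfig) -> list[GeneAnnotation]:
    """Deterministic (seeded) non-overlapping gene layout with the exact
    class counts of ``config.gene_map``."""
    gm = config.gene_map
    n_genes = gm.n_genes
    if n_genes < 1:
        raise SimConfigError("gene map needs at least one gene")
    lengths = np.array([L for _, L in config.chromosomes])
    per_chrom = _largest_remainder(n_genes, lengths)
    # class label sequence
    labels = (
        ["interacting_nmt"] * gm.n_interacting
        + ["noninteracting_nmt"] * gm.n_noninteracting
        + ["non_nmt"] * gm.n_non_nmt
    )
    rng = np.random.default_rng([config.seed, 1])
    n_clustered = int(round(gm.clustering * gm.n_interacting))
    if n_clustered > per_chrom[0]:
        raise SimConfigError(
            f"cannot cluster {n_clustered} interacting genes on "
            f"{config.chromosomes[0][0]} ({per_chrom[0]} gene slots)"
        )
    rest = labels[n_clustered:] if n_clustered else list(labels)
    rest = [rest[i] for i in rng.permutation(len(rest))]
    ordered = labels[:n_clustered] + rest

    genes: list[GeneAnnotation] = []
    k = 0
    for (cid, L), cnt in zip(config.chromosomes, per_chrom):
        if cnt == 0:
            continue
        span_bp = int(L * MORGAN_TO_BP)
        width = gm.coverage * span_bp / cnt
        gap = (1.0 - gm.coverage) * span_bp / (cnt + 1)
        for j in range(cnt):
            start = int(gap + j * (width + gap)) + 1
            end = int(start + width) - 1
            if end > span_bp:
                end = span_bp
            if end < start:
                raise SimConfigError(
                    f"requested genes exceed available span on {cid}"
                )
            genes.append(GeneAnnotation(f"g{k:05d}", cid, start, end, ordered[k]))
            k += 1
    return genes


def build_aim_sites(config: SimConfig) -> tuple[list[AimSite], list[np.ndarray]]:
    """AIM positions: a uniform grid of ``n_aims_per_chrom`` nuclear AIMs
    along each chromosome plus one designated mito AIM.  Returns the site
    list (mito last) and per-chromosome genetic positions in Morgans."""
    sites: list[AimSite] = []
    genetic: list[np.ndarray] = []
    for cid, L in config.chromosomes:
        pos_m = (np.arange(config.n_aims_per_chrom) + 0.5) * L / config.n_aims_per_chrom
        genetic.append(pos_m)
        for p in pos_m:
            sites.append(AimSite(cid, int(p * MORGAN_TO_BP) + 1, "nuclear"))
    sites.append(AimSite(MITO_CHROM, MITO_POS, "mito"))
    return sites, genetic


def gene_genetic_midpoint(gene: GeneAnnotation) -> float:
    """Genetic (Morgan) coordinate of a gene's midpoint under the fixed
    1 Morgan = 25 Mb map."""
    return ((gene.start + gene.end) / 2.0 - 1.0) / MORGAN_TO_BP


def select_incompatibility_targets(
    genes: Sequence[GeneAnnotation],
    n_selected: int,
    s: float,
    h: float = 0.5,
    matched_parent: str = "major",
    seed: int = 0,
) -> tuple[IncompatLocus, ...]:
    """Choose ``n_selected`` interacting n-mt genes (seeded, without
    replacement) as viability-selection targets."""
    inter = [g.gene_id for g in genes if g.gene_class == "interacting_nmt"]
    if n_selected > len(inter):
        raise SimConfigError(
            f"asked for {n_selected} selected genes but only {len(inter)} interacting"
        )
    rng = np.random.default_rng([seed, 7])
    chosen = sorted(rng.choice(len(inter), size=n_selected, replace=False))
    return tuple(IncompatLocus(inter[i], s, h, matched_parent) for i in chosen)


# ---------------------------------------------------------------------------
# forward simulation


def _recombine(b1, l1, b2, l2, start, xs, L):
    """Merge two tract haplotypes through sorted crossover positions
    ``xs``, alternating source starting from ``start``; returns compressed
    (breaks, labels)."""
    k = len(xs)
    cap = len(b1) + len(b2) + k + 2
    ob = np.empty(cap)
    ol = np.empty(cap, dtype=np.uint8)
    cur = start
    prev = 0.0
    out = 0
    for i in range(k + 1):
        x = xs[i] if i < k else L
        b = b1 if cur == 0 else b2
        l = l1 if cur == 0 else l2
        j = np.searchsorted(b, prev, side="right")
        while j < len(b) and b[j] < x:
            if out > 0 and ol[out - 1] == l[j]:
                ob[out - 1] = b[j]
            else:
                ob[out] = b[j]
                ol[out] = l[j]
                out += 1
            j += 1
        # closing segment of this interval, ending exactly at x
        lab = l[j] if j < len(l) else l[len(l) - 1]
        if out > 0 and ol[out - 1] == lab:
            ob[out - 1] = x
        else:
            ob[out] = x
            ol[out] = lab
            out += 1
        prev = x
        cur = 1 - cur
    return ob[:out].copy(), ol[:out].copy()


try:  # JIT the tract-merge inner loop when numba is available
    from numba import njit as _njit

    _recombine = _njit(cache=True)(_recombine)
except Exception:  # pragma: no cover - numba is an optional accelerator
    pass


def _gamete(hap1, hap2, k, start, xs, L):
    """Recombinant gamete from a haplotype pair.

    ``k`` crossovers at sorted positions ``xs``; segments alternate between
    the two parental haplotypes starting from ``start``.  Haplotypes are
    immutable (breaks, labels) pairs, so the k = 0 case returns a parental
    haplotype by reference.
    """
    if k == 0:
        return hap1 if start == 0 else hap2
    return _recombine(hap1[0], hap1[1], hap2[0], hap2[1], start, xs, L)


def _allele_at(hap, pos_m: float) -> int:
    b, l = hap
    return int(l[np.searchsorted(b, pos_m, side="right")])


_G_BY_MISMATCHES = None  # placeholder for clarity; g computed inline


def simulate_population(config: SimConfig) -> tuple[SimPopulation, SimTruth]:
    """Run the forward model and return the final generation plus ground
    truth dosages at the AIM grid."""
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_individuals
    chroms = config.chromosomes
    n_chrom = len(chroms)
    lengths = np.array([L for _, L in chroms])

    genes = build_gene_map(config)
    gene_by_id = {g.gene_id: g for g in genes}
    chrom_index = {cid: i for i, (cid, _) in enumerate(chroms)}
    loci = []
    for il in config.incompat_loci:
        g = gene_by_id.get(il.gene_id)
        if g is None:
            raise SimConfigError(f"incompatibility locus references unknown gene {il.gene_id}")
        loci.append((chrom_index[g.chrom], gene_genetic_midpoint(g), il))

    # founders are pure parentals.  With founder_mito_coupling (default), a
    # founder's mito matches its nuclear species, giving the maximal
    # mitonuclear admixture LD of a fresh hybrid swarm; founding-female and
    # founding-male major fractions are then chosen so mothers hit
    # mito_init_freq while the population nuclear proportion stays
    # admixture_prop.  Without coupling, nuclear species and mito haplotype
    # are drawn independently (no founding LD) — emulating populations
    # whose mito polymorphism is maintained by processes outside the model,
    # such as ongoing structure.
    n_f = n // 2
    sex = np.ones(n, dtype=np.uint8)
    sex[:n_f] = 0
    if config.founder_mito_coupling:
        p_major = np.where(
            sex == 0,
            config.mito_init_freq,
            min(max(config.founding_male_major_prob(), 0.0), 1.0),
        )
        species = (rng.random(n) < p_major).astype(np.uint8)
        mito = species.copy()
    else:
        species = (rng.random(n) < config.admixture_prop).astype(np.uint8)
        mito = (rng.random(n) < config.mito_init_freq).astype(np.uint8)

    def pure_hap(lab, L):
        return (np.array([L]), np.array([lab], dtype=np.uint8))

    pure = [
        {lab: pure_hap(lab, L) for lab in (0, 1)} for _, L in chroms
    ]
    haps = [
        [(pure[c][int(species[i])], pure[c][int(species[i])]) for c in range(n_chrom)]
        for i in range(n)
    ]

    for gen in range(1, config.n_generations + 1):
        females = np.nonzero(sex == 0)[0]
        males = np.nonzero(sex == 1)[0]
        if len(females) == 0 or len(males) == 0:
            raise ExtinctionError(f"generation {gen}: a sex died out")
        new_haps, new_mito = [], []
        # hybrid-zone replenishment: a migration_rate fraction of each
        # census is fresh pure-parental immigrants (mito matching their
        # species), the mechanism that maintains mito polymorphism and
        # baseline mitonuclear LD in ongoing admixture
        if config.migration_rate > 0:
            n_imm = rng.binomial(n, config.migration_rate)
            imm_species = (rng.random(n_imm) < config.admixture_prop).astype(np.uint8)
            for spc in imm_species:
                new_haps.append(
                    [(pure[c][int(spc)], pure[c][int(spc)]) for c in range(n_chrom)]
                )
                new_mito.append(spc)
        attempts = 0
        max_attempts = 500 * n
        while len(new_haps) < n:
            batch = min(n, max_attempts - attempts)
            if batch <= 0:
                raise ExtinctionError(
                    f"population extinct at generation {gen}: viability too low "
                    f"after {attempts} attempted offspring"
                )
            attempts += batch
            moms = rng.choice(females, size=batch)
            dads = rng.choice(males, size=batch)
            ks = rng.poisson(lengths[None, None, :], size=(batch, 2, n_chrom))
            starts = rng.integers(0, 2, size=(batch, 2, n_chrom))
            accept_u = rng.random(batch)
            for b in range(batch):
                child = []
                for c in range(n_chrom):
                    L = lengths[c]
                    mh = haps[moms[b]][c]
                    ph = haps[dads[b]][c]
                    km, kp = ks[b, 0, c], ks[b, 1, c]
                    gm_ = _gamete(
                        mh[0], mh[1], km, starts[b, 0, c],
                        np.sort(rng.random(km) * L) if km else None, L,
                    )
                    gp_ = _gamete(
                        ph[0], ph[1], kp, starts[b, 1, c],
                        np.sort(rng.random(kp) * L) if kp else None, L,
                    )
                    child.append((gm_, gp_))
                m_label = mito[moms[b]]
                if loci:
                    w = 1.0
                    for (ci, pos_m, il) in loci:
                        match = m_label if il.matched_parent == "major" else 1 - m_label
                        mism = int(_allele_at(child[ci][0], pos_m) != match) + int(
                            _allele_at(child[ci][1], pos_m) != match
                        )
                        gval = (0.0, il.h, 1.0)[mism]
                        w *= 1.0 - il.s * gval
                    if accept_u[b] >= w:
                        continue
                new_haps.append(child)
                new_mito.append(m_label)
                if len(new_haps) == n:
                    break
        haps = new_haps
        mito = np.array(new_mito, dtype=np.uint8)
        sex = (rng.random(n) < 0.5).astype(np.uint8)
        if sex.sum() in (0, n):  # keep both sexes present
            sex[rng.integers(0, n)] ^= 1

    pop = SimPopulation(chromosomes=chroms, haplotypes=haps, mito=mito, sex=sex)

    sites, genetic = build_aim_sites(config)
    n_sites = len(sites)
    dos = np.empty((n_sites, n), dtype=float)
    row = 0
    for c in range(n_chrom):
        pos = genetic[c]
        block = np.empty((len(pos), n))
        for i in range(n):
            h1, h2 = haps[i][c]
            a1 = h1[1][np.searchsorted(h1[0], pos, side="right")]
            a2 = h2[1][np.searchsorted(h2[0], pos, side="right")]
            block[:, i] = (a1.astype(float) + a2) / 2.0
        dos[row : row + len(pos)] = block
        row += len(pos)
    dos[row] = mito.astype(float)

    truth = SimTruth(
        sites=sites,
        dosages=dos,
        selected_genes=[il.gene_id for il in config.incompat_loci],
        mean_ancestry=float(dos[: row].mean()),
        mito_major_freq=float(mito.mean()),
    )
    return pop, truth


# ---------------------------------------------------------------------------
# posterior emission


def emit_posteriors(pop: SimPopulation, truth: SimTruth, config: SimConfig):
    """Noisy posterior matrix from true dosages.

    Each entry is drawn from Beta(kappa*t + 1/2, kappa*(1-t) + 1/2), which
    is centered on the true dosage t and collapses onto it as kappa grows
    (kappa = inf emits the truth exactly).  A ``lowconf_fraction`` of
    entries is then replaced by draws from the open interval (0.2, 0.8),
    emulating low-confidence calls that the standard filter removes.
    """
    from .ancestry_io import PosteriorMatrix

    rng = np.random.default_rng([config.seed, 2])
    t = truth.dosages
    kappa = config.posterior_noise_kappa
    if np.isinf(kappa):
        emitted = t.copy()
    else:
        emitted = rng.beta(kappa * t + 0.5, kappa * (1.0 - t) + 0.5)
    if config.lowconf_fraction > 0:
        mask = rng.random(t.shape) < config.lowconf_fraction
        u = 0.2 + 0.6 * rng.random(int(mask.sum()))
        u[u <= 0.2] = 0.5
        emitted[mask] = u
    individuals = [f"ind{i:04d}" for i in range(t.shape[1])]
    return PosteriorMatrix(emitted, individuals, list(truth.sites)), list(truth.sites)


# ---------------------------------------------------------------------------
# presets (demographic summaries of the three hybrid populations)

TABLE_POPULATIONS = {
    # admixture proportion, founding-mother major-mito freq, generations
    "CALL": {"admixture_prop": 0.522, "mito_init_freq": 0.637, "n_generations": 46},
    "CHAF": {"admixture_prop": 0.682, "mito_init_freq": 0.936, "n_generations": 46},
    "HUEX-STAC": {"admixture_prop": 0.846, "mito_init_freq": 1.0, "n_generations": 263},
}

# unique genes per class genome-wide (interacting, non-interacting, non-n-mt)
FULL_CLASS_COUNTS = {
    "CALL": (148, 883, 19312),
    "CHAF": (148, 883, 19307),
    "HUEX-STAC": (162, 947, 20544),
}

# genes with prior evidence of mitonuclear incompatibility in this system
N_FOCAL_INCOMPATIBILITY_GENES = 10


def focal_fraction_of_interacting(population: str = "CALL") -> float:
    """Known incompatibility genes as a percentage of interacting n-mt genes."""
    return 100.0 * N_FOCAL_INCOMPATIBILITY_GENES / FULL_CLASS_COUNTS[population][0]


def focal_fraction_of_nmt(population: str = "CALL") -> float:
    """Known incompatibility genes as a percentage of all n-mt genes."""
    c = FULL_CLASS_COUNTS[population]
    return 100.0 * N_FOCAL_INCOMPATIBILITY_GENES / (c[0] + c[1])


def preset_config(name: str, **overrides) -> SimConfig:
    """Desk-scale scenario presets: "CALL-like", "CHAF-like",
    "HUEX-STAC-like".  Demography follows the population summaries above;
    genome size, AIM density and gene counts are scaled for workstation
    runs.  Any field may be overridden."""
    key = name.removesuffix("-like")
    if key not in TABLE_POPULATIONS:
        raise SimConfigError(f"unknown preset {name!r}")
    params = dict(TABLE_POPULATIONS[key])
    params.update(overrides)
    return SimConfig(**params)
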