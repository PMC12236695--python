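"""Frozen desk-scale study scenarios for power and sensitivity studies.

These fix the simulation conditions used by the package's calibration and
sensitivity studies (and by ``scripts/acceptance.py``): a 20-Morgan genome
(10 chromosomes x 2 M) carrying 4,000 AIMs and 800 genes in the three
functional classes (30 interacting n-mt : 170 non-interacting n-mt : 600
non-n-mt; the interacting class is kept large enough that selecting a ~7%
subset of it is meaningful at this scale).

Two demographic regimes:

* ``call_like_config`` — a young hybrid zone with segregating
  mitochondrial haplotypes (admixture proportion 0.522, founding-mother
  major-mito frequency 0.637, 46 generations) and ongoing replenishment
  by pure parental migrants (rate 0.25 per census).  The migration term
  is what maintains the mitochondrial polymorphism and the positive
  genome-wide mitonuclear LD baseline that mitonuclear viability
  selection would otherwise erase: every generation of selection
  transfers roughly s*D of frequency change onto the mitogenome, so a
  closed population either fixes its mito haplotype or congeals into two
  reproductively isolated forms well before generation 46.
  Incompatibility selection here is strong and mostly recessive
  (s = 0.9, h = 0.1), matching incompatibilities severe enough to kill
  homozygous-mismatched embryos while sparing most heterozygotes.

* ``huex_like_config`` — an older, closed hybrid population fixed for
  the major-parent mitogenome (admixture proportion 0.846, mito
  frequency 1.0, 263 generations, no migration).  Selection is applied
  across the interacting class (all 30 genes) with moderate, mostly
  recessive effects (s = 0.3, h = 0.1): stronger or more dominant
  multi-locus selection would purge minor-parent ancestry genome-wide
  at the hybridization front (F1-type individuals are heterozygous at
  every selected locus at once), leaving no class contrast to detect.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import ancestry_io as aio
from . import ld_stats as ld
from . import simdata as sd

DESK_CHROMOSOMES = tuple((f"chr{i + 1}", 2.0) for i in range(10))
DESK_N_AIMS_PER_CHROM = 400
DESK_GENE_MAP = sd.GeneMapConfig(30, 170, 600)

HYBRID_ZONE_MIGRATION = 0.25
SEGREGATING_S = 0.9
SEGREGATING_H = 0.1

FIXED_MITO_N_SELECTED = 30  # the whole interacting class
FIXED_MITO_S = 0.3
FIXED_MITO_H = 0.1


def call_like_config(
    seed: int,
    n_individuals: int = 300,
    n_selected: int = 0,
    s: float = SEGREGATING_S,
    h: float = SEGREGATING_H,
) -> sd.SimConfig:
    """Segregating-mito hybrid-zone scenario, optionally with viability
    selection at ``n_selected`` interacting n-mt genes."""
    cfg = sd.preset_config(
        "CALL-like",
        n_individuals=n_individuals,
        chromosomes=DESK_CHROMOSOMES,
        n_aims_per_chrom=DESK_N_AIMS_PER_CHROM,
        gene_map=DESK_GENE_MAP,
        migration_rate=HYBRID_ZONE_MIGRATION,
        seed=seed,
    )
    if n_selected:
        genes = sd.build_gene_map(cfg)
        loci = sd.select_incompatibility_targets(genes, n_selected, s=s, h=h, seed=seed)
        cfg = replace(cfg, incompat_loci=loci)
    return cfg


def huex_like_config(
    seed: int,
    n_individuals: int = 100,
    n_selected: int = FIXED_MITO_N_SELECTED,
    s: float = FIXED_MITO_S,
    h: float = FIXED_MITO_H,
) -> sd.SimConfig:
    """Fixed-mito old-hybrid-population scenario."""
    cfg = sd.preset_config(
        "HUEX-STAC-like",
        n_individuals=n_individuals,
        chromosomes=DESK_CHROMOSOMES,
        n_aims_per_chrom=DESK_N_AIMS_PER_CHROM,
        gene_map=DESK_GENE_MAP,
        migration_rate=0.0,
        seed=seed,
    )
    if n_selected:
        genes = sd.build_gene_map(cfg)
        loci = sd.select_incompatibility_targets(genes, n_selected, s=s, h=h, seed=seed)
        cfg = replace(cfg, incompat_loci=loci)
    return cfg


def run_ld_replicate(cfg: sd.SimConfig):
    """Simulate, emit, filter and scan one replicate.

    Returns a dict with per-gene D' statistics, the outlier table and the
    realized mito frequency, or None when the filtered mito AIM is
    monomorphic (mitonuclear LD is then undefined, as in real populations
    fixed for one haplotype; callers substitute further seeds)."""
    pop, truth = sd.simulate_population(cfg)
    if truth.mito_major_freq in (0.0, 1.0):
        return None
    genes = sd.build_gene_map(cfg)
    m, _ = sd.emit_posteriors(pop, truth, cfg)
    filt = aio.filter_posteriors(m)
    calls = ld.call_mito_haplotype(filt, m.sites[-1])
    called = calls[~np.isnan(calls)]
    if called.size == 0 or not 0.0 < called.mean() < 1.0:
        return None
    scan = ld.scan_mitonuclear_ld(filt, calls)
    mapping = aio.map_aims_to_genes(m.sites, genes)
    stats = ld.aggregate_per_gene(scan, mapping, genes, "Dprime")
    outliers = ld.zscore_outliers(stats, truth.selected_genes)
    return {
        "gene_stats": stats,
        "outliers": outliers,
        "truth": truth,
        "mito_major_freq": truth.mito_major_freq,
    }


def run_allele_freq_replicate(cfg: sd.SimConfig):
    """Simulate one fixed-mito replicate and return per-gene matched-allele
    frequencies."""
    pop, truth = sd.simulate_population(cfg)
    genes = sd.build_gene_map(cfg)
    m, _ = sd.emit_posteriors(pop, truth, cfg)
    filt = aio.filter_posteriors(m)
    mapping = aio.map_aims_to_genes(m.sites, genes)
    stats = ld.allele_freq_per_gene(filt, mapping, genes)
    return {"gene_stats": stats, "truth": truth}


def ld_replicates(base_seed: int, n_replicates: int, make_config, max_tries=None):
    """Yield ``n_replicates`` LD-analyzable replicates (segregating mito
    after filtering), drawing extra seeds for replicates where a haplotype
    was lost; seeds derive from ``base_seed``."""
    if max_tries is None:
        max_tries = 4 * n_replicates + 20
    got = 0
    for k in range(max_tries):
        rep = run_ld_replicate(make_config(base_seed + k))
        if rep is None:
            continue
        yield rep
        got += 1
        if got == n_replicates:
            return
    raise RuntimeError(
        f"only {got}/{n_replicates} replicates retained a segregating mito "
        f"haplotype after {max_tries} seeds"
    )
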