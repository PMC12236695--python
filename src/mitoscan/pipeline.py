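"""Config-driven end-to-end runs: simulate/load -> filter -> scan -> test
-> report, with TSV outputs, a machine-readable manifest, and data-first
figures (every figure has a TSV twin carrying exactly the plotted
numbers)."""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import ancestry_io as aio
from . import class_tests as ct
from . import ld_stats as ld
from . import simdata as sd

log = logging.getLogger("mitoscan")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Either file inputs (posterior_table + gene_table) or a simulation
    block, never both."""

    outdir: str
    posterior_table: str | None = None
    gene_table: str | None = None
    focal_genes: str | None = None
    sim: sd.SimConfig | None = None
    lo: float = 0.2
    hi: float = 0.8
    mito_aim: str | None = None  # "chrom:pos"; default: the unique mito site
    statistics: tuple[str, ...] = ("Dprime", "r2")
    n_perm: int = 9999
    seed: int = 0
    contrast: tuple[str, str] = ("interacting_nmt", "non_nmt")
    fraction: float = 0.01
    sided: str = "one"

    def __post_init__(self):
        has_files = self.posterior_table is not None or self.gene_table is not None
        if self.sim is not None and has_files:
            raise PipelineError("config: give file inputs or a sim block, not both")
        if self.sim is None and not (self.posterior_table and self.gene_table):
            raise PipelineError(
                "config: need posterior_table and gene_table, or a sim block"
            )

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        sim = raw.pop("sim", None)
        if sim is not None:
            preset = sim.pop("preset", None)
            if "gene_map" in sim:
                sim["gene_map"] = sd.GeneMapConfig(**sim["gene_map"])
            if "incompat_loci" in sim:
                sim["incompat_loci"] = tuple(
                    sd.IncompatLocus(**d) for d in sim["incompat_loci"]
                )
            if "chromosomes" in sim:
                sim["chromosomes"] = tuple((c, float(L)) for c, L in sim["chromosomes"])
            sim = sd.preset_config(preset, **sim) if preset else sd.SimConfig(**sim)
        if "contrast" in raw:
            raw["contrast"] = tuple(raw["contrast"])
        if "statistics" in raw:
            raw["statistics"] = tuple(raw["statistics"])
        return cls(sim=sim, **raw)


@dataclass
class ScanResult:
    matrix: aio.PosteriorMatrix
    genes: list
    mapping: dict
    mito_calls: np.ndarray
    summary: aio.PopulationSummary
    mode: str  # "ld" or "allele_freq"
    per_aim: pd.DataFrame | None
    gene_stats: dict  # statistic -> list[ld.GeneStat]
    class_results: dict  # statistic -> dict of test results
    outliers: dict  # statistic -> DataFrame
    enrichment: dict  # statistic -> list[ct.EnrichmentResult]
    truth: sd.SimTruth | None = None


def _find_mito_site(m: aio.PosteriorMatrix, selector: str | None):
    if selector:
        chrom, pos = selector.rsplit(":", 1)
        return m.sites[m.site_index(chrom, int(pos))]
    mito = [s for s in m.sites if s.compartment == "mito"]
    if len(mito) != 1:
        raise PipelineError(
            f"expected exactly one mito AIM (found {len(mito)}); use mito_aim"
        )
    return mito[0]


def run_scan(config: RunConfig) -> ScanResult:
    """Execute the full analysis and write all outputs under
    ``config.outdir``.  Deterministic given the config (incl. seeds)."""
    outdir = Path(config.outdir)

    # --- stage: input -----------------------------------------------------
    truth = None
    if config.sim is not None:
        log.info("[simulate] seed=%s", config.sim.seed)
        pop, truth = sd.simulate_population(config.sim)
        m, _ = sd.emit_posteriors(pop, truth, config.sim)
        genes = sd.build_gene_map(config.sim)
        focal = list(truth.selected_genes)
    else:
        for p in (config.posterior_table, config.gene_table, config.focal_genes):
            if p is not None and not os.path.exists(p):
                raise PipelineError(f"[input] missing input file: {p}")
        m, _ = aio.read_posterior_table(config.posterior_table)
        genes = aio.read_gene_table(config.gene_table)
        focal = (
            aio.read_focal_genes(config.focal_genes) if config.focal_genes else []
        )
    outdir.mkdir(parents=True, exist_ok=True)

    # --- stage: filter + mito call ---------------------------------------
    filt = aio.filter_posteriors(m, config.lo, config.hi)
    mito_site = _find_mito_site(filt, config.mito_aim)
    calls = ld.call_mito_haplotype(filt, mito_site, config.lo, config.hi)
    summary = aio.population_summaries(filt, calls)
    mapping = aio.map_aims_to_genes(filt.sites, genes)

    called = calls[~np.isnan(calls)]
    polymorphic = called.size > 0 and 0.0 < called.mean() < 1.0

    gene_stats: dict = {}
    class_results: dict = {}
    outliers: dict = {}
    enrichment: dict = {}
    per_aim = None

    if polymorphic:
        mode = "ld"
        log.info("[scan] mitonuclear LD at %d nuclear AIMs", int(filt.nuclear_mask().sum()))
        per_aim = ld.scan_mitonuclear_ld(filt, calls)
        stat_list = [s for s in config.statistics if s != "allele_freq"]
    else:
        mode = "allele_freq"
        log.info(
            "[scan] mito AIM monomorphic after filtering; skipping LD, "
            "running matched-allele-frequency analysis instead"
        )
        stat_list = ["allele_freq"]

    for stat in stat_list:
        if stat == "allele_freq":
            gs = ld.allele_freq_per_gene(filt, mapping, genes)
        else:
            gs = ld.aggregate_per_gene(per_aim, mapping, genes, stat)
        gene_stats[stat] = gs
        res: dict = {}
        try:
            res["anova"] = ct.one_way_anova(gs)
        except ct.ClassTestError as e:
            raise PipelineError(f"[class-test:{stat}] {e}") from e
        present = {s.gene_class for s in gs}
        if set(config.contrast) <= present:
            res["permutation"] = ct.permutation_class_test(
                gs,
                contrast=config.contrast,
                n_perm=config.n_perm,
                seed=config.seed,
                sided=config.sided,
            )
        else:
            log.warning(
                "[class-test:%s] permutation skipped: contrast class absent", stat
            )
            res["permutation"] = None
        class_results[stat] = res
        if len(gs) * config.fraction >= 1.0:
            enrichment[stat] = ct.top_fraction_enrichment(gs, config.fraction)
        else:
            log.warning(
                "[enrichment:%s] skipped: %d genes is too few for the top "
                "%.3g fraction", stat, len(gs), config.fraction,
            )
            enrichment[stat] = []
        outliers[stat] = ld.zscore_outliers(gs, focal)

    result = ScanResult(
        matrix=filt,
        genes=genes,
        mapping=mapping,
        mito_calls=calls,
        summary=summary,
        mode=mode,
        per_aim=per_aim,
        gene_stats=gene_stats,
        class_results=class_results,
        outliers=outliers,
        enrichment=enrichment,
        truth=truth,
    )
    _write_outputs(result, config, outdir)
    return result


def _write_outputs(result: ScanResult, config: RunConfig, outdir: Path):
    if result.per_aim is not None:
        result.per_aim.to_csv(outdir / "per_aim_stats.tsv", sep="\t", index=False)
    for stat, gs in result.gene_stats.items():
        ld.gene_stats_frame(gs).to_csv(
            outdir / f"per_gene_{stat}.tsv", sep="\t", index=False
        )
        result.outliers[stat].to_csv(
            outdir / f"outliers_{stat}.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            [dataclasses.asdict(e) for e in result.enrichment[stat]]
        ).to_csv(outdir / f"enrichment_{stat}.tsv", sep="\t", index=False)

    rows = []
    for stat, res in result.class_results.items():
        a, p = res["anova"], res["permutation"]
        for s in a.summaries:
            rows.append(
                dict(statistic=stat, gene_class=s.gene_class, n=s.n, mean=s.mean,
                     sd=s.sd, F=a.F, p_anova=a.p_anova,
                     p_perm=p.p_perm if p else float("nan"),
                     n_perm=p.n_perm if p else 0,
                     observed_diff=p.observed_diff if p else float("nan"),
                     contrast="-".join(p.contrast) if p else "",
                     sided=p.sided if p else "")
            )
    pd.DataFrame(rows).to_csv(outdir / "class_tests.tsv", sep="\t", index=False)

    s = result.summary
    pd.DataFrame(
        [dict(mean_nuclear_ancestry=s.mean_nuclear_ancestry,
              mito_major_freq=s.mito_major_freq, mito_minor_freq=s.mito_minor_freq,
              n_mito_called=s.n_mito_called, mode=result.mode)]
    ).to_csv(outdir / "population_summary.tsv", sep="\t", index=False)
    s.per_individual_ancestry.rename("mean_ancestry").to_frame().assign(
        mito_call=result.mito_calls
    ).to_csv(outdir / "per_individual_ancestry.tsv", sep="\t")

    manifest = {
        "mitoscan_version": __version__,
        "mode": result.mode,
        "seed": config.seed,
        "filter": {"lo": config.lo, "hi": config.hi},
        "n_perm": config.n_perm,
        "contrast": list(config.contrast),
        "fraction": config.fraction,
        "sided": config.sided,
        "statistics": list(config.statistics),
        "sim": dataclasses.asdict(config.sim) if config.sim else None,
        "inputs": {
            "posterior_table": config.posterior_table,
            "gene_table": config.gene_table,
            "focal_genes": config.focal_genes,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# report


def make_report(result: ScanResult, outdir) -> list[str]:
    """Figures (with TSV twins) for a finished scan: per-class distribution
    of the association statistic, per-individual ancestry histogram stacked
    by mito haplotype, and a per-class boxplot for allele-frequency runs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    for stat, gs in result.gene_stats.items():
        df = ld.gene_stats_frame(gs)
        df.to_csv(outdir / f"fig_class_distribution_{stat}.tsv", sep="\t", index=False)
        fig, ax = plt.subplots(figsize=(6, 4))
        for cls in aio.GENE_CLASSES:
            vals = df.loc[df["gene_class"] == cls, "value"].dropna()
            if len(vals) == 0:
                log.warning("report: gene class %s empty; omitted from figure", cls)
                continue
            if len(vals) > 1 and vals.std() > 0:
                ax.hist(vals, bins=30, density=True, alpha=0.45, label=cls)
            else:
                ax.axvline(vals.iloc[0], alpha=0.6, label=cls)
        ax.set_xlabel(stat)
        ax.set_ylabel("density")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(outdir / f"fig_class_distribution_{stat}.png", dpi=120)
        plt.close(fig)
        written.append(f"fig_class_distribution_{stat}")

        if stat == "allele_freq":
            fig, ax = plt.subplots(figsize=(5, 4))
            data = [
                df.loc[df["gene_class"] == cls, "value"].dropna()
                for cls in aio.GENE_CLASSES
            ]
            keep = [(c, d) for c, d in zip(aio.GENE_CLASSES, data) if len(d)]
            ax.boxplot([d for _, d in keep], tick_labels=[c for c, _ in keep])
            ax.set_ylabel("major-parent allele frequency")
            fig.tight_layout()
            fig.savefig(outdir / "fig_allele_freq_by_class.png", dpi=120)
            plt.close(fig)
            written.append("fig_allele_freq_by_class")

    anc = result.summary.per_individual_ancestry
    calls = result.mito_calls
    twin = anc.rename("mean_ancestry").to_frame().assign(mito_call=calls)
    twin.to_csv(outdir / "fig_ancestry_histogram.tsv", sep="\t")
    fig, ax = plt.subplots(figsize=(6, 4))
    bins = np.linspace(0, 1, 41)
    groups = [anc[calls == 1.0], anc[calls == 0.0], anc[np.isnan(calls)]]
    labels = ["major mito", "minor mito", "uncalled"]
    keep = [(g, l) for g, l in zip(groups, labels) if len(g)]
    ax.hist([g for g, _ in keep], bins=bins, stacked=True, label=[l for _, l in keep])
    ax.set_xlabel("proportion of nuclear genome from major parent")
    ax.set_ylabel("individuals")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "fig_ancestry_histogram.png", dpi=120)
    plt.close(fig)
    written.append("fig_ancestry_histogram")
    return written
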