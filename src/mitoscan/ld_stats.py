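"""Mitonuclear linkage-disequilibrium statistics.

Locus A is a nuclear AIM (allele = major-parent ancestry), locus B the
mitogenome, represented by a single mitochondrial AIM because the
mitogenome does not recombine.  With pA and pB the major-parent allele
frequencies and pAB the frequency of the matched (major nuclear on major
mito) combination:

    D    = pAB - pA*pB
    Dmax = min(pA*(1-pB), (1-pA)*pB)       if D > 0
           min(pA*pB, (1-pA)*(1-pB))       if D < 0
    D'   = D / Dmax                        (defined as 0 when D = 0)
    r^2  = D^2 / (pA*(1-pA)*pB*(1-pB))

Both alleles are labelled by the same parent, so D' > 0 means parental
(matched) mitonuclear combinations are in excess and D' < 0 means
recombinant combinations are.  Frequencies are estimated from posterior
dosages: pA is the mean per-individual dosage at the AIM, pB the fraction
of major mito calls, and pAB the mean of dosage x indicator(mito=major),
all over individuals with both values non-missing (pairwise-complete
deletion per AIM).  For hard 0/1 dosages with known haplotypes this
reduces exactly to haplotype counting.

Statistics are reported missing (NaN) whenever a marginal frequency is 0
or 1; monomorphic sites carry no association information and reporting 0
would bias per-gene and per-class means toward 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ancestry_io import AimSite, GeneAnnotation, PosteriorMatrix

STAT_NAMES = ("Dprime", "r2", "allele_freq")


class LdError(ValueError):
    pass


@dataclass(frozen=True)
class TwoLocusFreqs:
    """(pA, pB, pAB) with the Frechet bounds max(0, pA+pB-1) <= pAB <= min(pA, pB)."""

    pA: float
    pB: float
    pAB: float
    n_used: int = 0

    def validate(self, tol: float = 1e-9):
        if not (0 - tol <= self.pA <= 1 + tol and 0 - tol <= self.pB <= 1 + tol):
            raise LdError(f"marginal frequency outside [0,1]: {self}")
        lo = max(0.0, self.pA + self.pB - 1.0)
        hi = min(self.pA, self.pB)
        if not (lo - tol <= self.pAB <= hi + tol):
            raise LdError(f"pAB violates Frechet bounds: {self}")


@dataclass(frozen=True)
class LdValues:
    D: float
    Dprime: float
    r2: float
    n_used: int = 0


@dataclass(frozen=True)
class GeneStat:
    gene_id: str
    gene_class: str
    statistic: str  # one of STAT_NAMES
    value: float
    n_aims: int


def call_mito_haplotype(
    m: PosteriorMatrix, mito_site: AimSite | str, lo: float = 0.2, hi: float = 0.8
) -> np.ndarray:
    """Haplotype call per individual from the designated mito AIM:
    posterior >= hi -> major (1.0), <= lo -> minor (0.0), else missing (NaN).

    ``mito_site`` may be an AimSite or a "chrom:pos" selector.
    """
    if m.values.size == 0:
        raise LdError("empty posterior matrix")
    if isinstance(mito_site, str):
        chrom, pos = mito_site.rsplit(":", 1)
        idx = m.site_index(chrom, int(pos))
    else:
        idx = m.site_index(mito_site.chrom, mito_site.pos)
    site = m.sites[idx]
    if site.compartment != "mito":
        raise LdError(f"site {site.chrom}:{site.pos} is not a mito AIM")
    post = m.values[idx]
    calls = np.full(post.shape, np.nan)
    calls[post >= hi] = 1.0
    calls[post <= lo] = 0.0
    return calls


def allele_freq(dosages) -> float:
    """Major-parent allele frequency at one AIM: the mean non-missing
    dosage (equivalent to summing posteriors and normalizing).  NaN if all
    values are missing."""
    d = np.asarray(dosages, dtype=float)
    if np.all(np.isnan(d)):
        return float("nan")
    return float(np.nanmean(d))


def joint_freq(dosages, calls) -> TwoLocusFreqs | None:
    """Two-locus frequencies over pairwise-complete individuals.

    pAB is the mean of dosage x indicator(mito = major); summing over the
    two mito states returns pA, and for hard calls this is haplotype
    counting.  Returns None (flagged missing) with fewer than 2 complete
    individuals.
    """
    d = np.asarray(dosages, dtype=float)
    c = np.asarray(calls, dtype=float)
    if d.shape != c.shape:
        raise LdError("dosages and mito calls differ in length")
    ok = ~np.isnan(d) & ~np.isnan(c)
    n = int(ok.sum())
    if n < 2:
        return None
    d, c = d[ok], c[ok]
    return TwoLocusFreqs(
        pA=float(d.mean()), pB=float(c.mean()), pAB=float((d * c).mean()), n_used=n
    )


def ld_from_freqs(f: TwoLocusFreqs) -> LdValues:
    """D, D' and r^2 from two-locus frequencies (module docstring has the
    formulas).  All statistics are NaN when either marginal is 0 or 1."""
    f.validate()
    pA, pB, pAB = f.pA, f.pB, f.pAB
    denom = pA * (1.0 - pA) * pB * (1.0 - pB)
    if denom <= 0.0:
        return LdValues(float("nan"), float("nan"), float("nan"), f.n_used)
    D = pAB - pA * pB
    if D > 0:
        dmax = min(pA * (1.0 - pB), (1.0 - pA) * pB)
    elif D < 0:
        dmax = min(pA * pB, (1.0 - pA) * (1.0 - pB))
    else:
        return LdValues(0.0, 0.0, 0.0, f.n_used)
    return LdValues(float(D), float(D / dmax), float(D * D / denom), f.n_used)


def _ld_arrays(pA: np.ndarray, pB: np.ndarray, pAB: np.ndarray):
    """Vectorized ld_from_freqs used by the scan."""
    denom = pA * (1 - pA) * pB * (1 - pB)
    D = pAB - pA * pB
    with np.errstate(invalid="ignore", divide="ignore"):
        dmax = np.where(
            D > 0,
            np.minimum(pA * (1 - pB), (1 - pA) * pB),
            np.minimum(pA * pB, (1 - pA) * (1 - pB)),
        )
        dp = np.where(D == 0, 0.0, D / dmax)
        r2 = np.where(D == 0, 0.0, D * D / denom)
    bad = ~(denom > 0)
    D = np.where(bad, np.nan, D)
    dp = np.where(bad, np.nan, dp)
    r2 = np.where(bad, np.nan, r2)
    return D, dp, r2


def scan_mitonuclear_ld(m: PosteriorMatrix, calls) -> pd.DataFrame:
    """Per-AIM mitonuclear LD across all nuclear AIMs (the mito AIM itself
    is excluded).  Returns a DataFrame aligned with the nuclear rows of
    ``m``: chrom, pos, pA, pB, pAB, D, Dprime, r2, n_used; site_index
    refers back to rows of ``m``."""
    nuc = m.nuclear_mask()
    if not nuc.any():
        raise LdError("no nuclear AIMs to scan")
    c = np.asarray(calls, dtype=float)
    V = m.values[nuc]
    ok = ~np.isnan(V) & ~np.isnan(c)[None, :]
    n_used = ok.sum(axis=1)
    Vz = np.where(ok, V, 0.0)
    cz = np.where(np.isnan(c), 0.0, c)
    with np.errstate(invalid="ignore", divide="ignore"):
        pA = Vz.sum(axis=1) / n_used
        pB = (ok * cz[None, :]).sum(axis=1) / n_used
        pAB = (Vz * cz[None, :]).sum(axis=1) / n_used
    few = n_used < 2
    pA[few] = np.nan
    D, dp, r2 = _ld_arrays(pA, pB, pAB)
    idx = np.nonzero(nuc)[0]
    return pd.DataFrame(
        {
            "site_index": idx,
            "chrom": [m.sites[i].chrom for i in idx],
            "pos": [m.sites[i].pos for i in idx],
            "pA": pA,
            "pB": pB,
            "pAB": pAB,
            "D": D,
            "Dprime": dp,
            "r2": r2,
            "n_used": n_used,
        }
    )


def _per_site_series(per_aim: pd.DataFrame, statistic: str) -> pd.Series:
    if statistic not in per_aim.columns:
        raise LdError(f"unknown statistic {statistic!r}")
    return pd.Series(per_aim[statistic].values, index=per_aim["site_index"].values)


def aggregate_per_gene(
    per_aim: pd.DataFrame,
    mapping: Mapping[str, Sequence[int]],
    genes: Sequence[GeneAnnotation],
    statistic: str = "Dprime",
) -> list[GeneStat]:
    """Unweighted mean of a per-AIM statistic over each gene's non-missing
    AIMs (averaging within genes limits pseudo-replication from multiple
    AIMs per gene).  Genes whose AIMs are all missing are dropped."""
    vals = _per_site_series(per_aim, statistic)
    out = []
    for g in genes:
        idxs = mapping.get(g.gene_id)
        if not idxs:
            continue
        v = vals.reindex(idxs).dropna()
        if len(v) == 0:
            continue
        out.append(GeneStat(g.gene_id, g.gene_class, statistic, float(v.mean()), len(v)))
    return out


def allele_freq_per_gene(
    m: PosteriorMatrix,
    mapping: Mapping[str, Sequence[int]],
    genes: Sequence[GeneAnnotation],
) -> list[GeneStat]:
    """Per-gene mean major-parent allele frequency — the analysis used when
    the mito haplotype is fixed and LD is undefined.  Per-AIM frequencies
    are computed first, then averaged within the gene."""
    freq = np.nanmean(
        np.where(np.isnan(m.values), np.nan, m.values), axis=1
    ) if m.values.size else np.array([])
    per_aim = pd.DataFrame(
        {"site_index": np.arange(len(m.sites)), "allele_freq": freq}
    )
    nuclear = {i for i, s in enumerate(m.sites) if s.compartment == "nuclear"}
    nmap = {g: [i for i in idxs if i in nuclear] for g, idxs in mapping.items()}
    return aggregate_per_gene(per_aim, nmap, genes, "allele_freq")


def gene_stats_frame(stats: Sequence[GeneStat]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in stats],
            "gene_class": [s.gene_class for s in stats],
            "statistic": [s.statistic for s in stats],
            "value": [s.value for s in stats],
            "n_aims": [s.n_aims for s in stats],
        }
    )


def zscore_outliers(
    stats: Sequence[GeneStat], focal_genes: Sequence[str] = ()
) -> pd.DataFrame:
    """Standardize each gene's statistic against the genome-wide mean and
    sd (n-1 denominator) and flag outliers with Z > 2 (one-sided, strict).
    Returns all genes; ``is_focal`` highlights genes of prior interest."""
    if len(stats) < 2:
        raise LdError("need at least 2 genes with defined values")
    df = gene_stats_frame(stats)
    sd = df["value"].std(ddof=1)
    if sd == 0 or np.isnan(sd):
        raise LdError("degenerate distribution: zero standard deviation across genes")
    mean = df["value"].mean()
    df["zscore"] = (df["value"] - mean) / sd
    df["is_outlier"] = df["zscore"] > 2.0
    focal = set(focal_genes)
    df["is_focal"] = df["gene_id"].isin(focal)
    return df
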