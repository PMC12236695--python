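"""Population-level tests across the three gene classes.

Gene-level statistics (per-gene mean D', r^2 or matched-allele frequency)
are compared across the interacting n-mt / non-interacting n-mt /
non-n-mt partition with: a fixed-effects one-way ANOVA; a permutation
test on the difference in class means (labels fixed, values reassigned
across genes); an exact hypergeometric enrichment test on the top
fraction of ranked genes; and a Pearson correlation of focal-gene
statistics between two populations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ld_stats import GeneStat, gene_stats_frame


class ClassTestError(ValueError):
    pass


@dataclass
class ClassSummary:
    gene_class: str
    n: int
    mean: float
    sd: float


@dataclass
class ClassTestResult:
    statistic: str
    summaries: list[ClassSummary]
    F: float | None = None
    p_anova: float | None = None
    p_perm: float | None = None
    n_perm: int | None = None
    seed: int | None = None
    contrast: tuple[str, str] | None = None
    observed_diff: float | None = None
    sided: str = "one"


@dataclass
class EnrichmentResult:
    gene_class: str
    K_class: int
    n_top: int
    k_in_top: int
    p_hyper: float


def _frame(stats: Sequence[GeneStat] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(stats, pd.DataFrame):
        return stats
    return gene_stats_frame(stats)


def _summaries(df: pd.DataFrame) -> list[ClassSummary]:
    out = []
    for cls, grp in df.groupby("gene_class", sort=True):
        out.append(
            ClassSummary(cls, len(grp), float(grp["value"].mean()),
                         float(grp["value"].std(ddof=1)))
        )
    return out


def one_way_anova(stats: Sequence[GeneStat] | pd.DataFrame) -> ClassTestResult:
    """Fixed-effects one-way ANOVA of gene-level values on gene class.

    Requires at least two classes with at least two genes each; a smaller
    class is an error naming it.
    """
    df = _frame(stats)
    groups = {cls: grp["value"].to_numpy() for cls, grp in df.groupby("gene_class")}
    if len(groups) < 2:
        raise ClassTestError("need at least two gene classes")
    for cls, v in groups.items():
        if len(v) < 2:
            raise ClassTestError(f"gene class {cls!r} has fewer than 2 genes")
        if not np.all(np.isfinite(v)):
            raise ClassTestError(f"non-finite values in class {cls!r}")
    F, p = sps.f_oneway(*groups.values())
    stat_name = df["statistic"].iloc[0] if "statistic" in df and len(df) else ""
    return ClassTestResult(
        statistic=stat_name, summaries=_summaries(df), F=float(F), p_anova=float(p)
    )


def permutation_class_test(
    stats: Sequence[GeneStat] | pd.DataFrame,
    contrast: tuple[str, str] = ("interacting_nmt", "non_nmt"),
    n_perm: int = 9999,
    seed: int = 0,
    sided: str = "one",
    exhaustive: bool = False,
) -> ClassTestResult:
    """Permutation test on T = mean(class X) - mean(class Y).

    The null reassigns values across all genes (class sizes fixed) and the
    p-value uses the add-one estimator (#{T_perm >= T_obs} + 1) /
    (n_perm + 1), guaranteeing p > 0.  ``sided='two'`` compares |T|.
    ``exhaustive=True`` enumerates every value permutation (tiny inputs
    only) instead of sampling.
    """
    if n_perm < 1 and not exhaustive:
        raise ClassTestError("n_perm must be >= 1")
    if sided not in ("one", "two"):
        raise ClassTestError("sided must be 'one' or 'two'")
    df = _frame(stats)
    cx, cy = contrast
    labels = df["gene_class"].to_numpy()
    vals = df["value"].to_numpy(dtype=float)
    mx = labels == cx
    my = labels == cy
    if mx.sum() == 0 or my.sum() == 0:
        raise ClassTestError(f"contrast class missing from data: {contrast}")

    def T(v: np.ndarray) -> float:
        return float(v[mx].mean() - v[my].mean())

    obs = T(vals)
    key = (lambda t: abs(t) >= abs(obs) - 1e-12) if sided == "two" else (
        lambda t: t >= obs - 1e-12
    )
    if exhaustive:
        if len(vals) > 9:
            raise ClassTestError("exhaustive enumeration limited to <= 9 genes")
        perms = [np.asarray(p) for p in itertools.permutations(vals)]
        b = sum(key(T(p)) for p in perms)
        n_eff = len(perms)
    else:
        rng = np.random.default_rng(seed)
        perm = np.tile(vals, (n_perm, 1))
        perm = rng.permuted(perm, axis=1)
        Ts = perm[:, mx].mean(axis=1) - perm[:, my].mean(axis=1)
        b = int(np.sum(np.abs(Ts) >= abs(obs) - 1e-12)) if sided == "two" else int(
            np.sum(Ts >= obs - 1e-12)
        )
        n_eff = n_perm
    p = (b + 1) / (n_eff + 1)
    stat_name = df["statistic"].iloc[0] if "statistic" in df and len(df) else ""
    return ClassTestResult(
        statistic=stat_name,
        summaries=_summaries(df),
        p_perm=float(p),
        n_perm=n_eff,
        seed=seed,
        contrast=contrast,
        observed_diff=obs,
        sided=sided,
    )


def top_fraction_enrichment(
    stats: Sequence[GeneStat] | pd.DataFrame, fraction: float = 0.01
) -> list[EnrichmentResult]:
    """Class enrichment in the top ``fraction`` of genes ranked by value.

    The top set holds the ceil(fraction*N) largest values with all ties at
    the cutoff included, so it may exceed the nominal size.  Each class
    gets an upper-tail hypergeometric p-value P(X >= k) for its count in
    the top set.
    """
    if not 0.0 < fraction < 1.0:
        raise ClassTestError(f"fraction {fraction} outside (0,1)")
    df = _frame(stats)
    N = len(df)
    if N < 1.0 / fraction:
        raise ClassTestError(f"need at least {math.ceil(1/fraction)} genes")
    n_nominal = math.ceil(fraction * N)
    vals = df["value"].to_numpy(dtype=float)
    cutoff = np.sort(vals)[::-1][n_nominal - 1]
    top = vals >= cutoff
    n_top = int(top.sum())
    out = []
    for cls, grp in df.groupby("gene_class", sort=True):
        K = len(grp)
        k = int(top[df["gene_class"].to_numpy() == cls].sum())
        p = float(sps.hypergeom.sf(k - 1, N, K, n_top))
        out.append(EnrichmentResult(cls, K, n_top, k, min(p, 1.0)))
    return out


def cross_population_correlation(
    stats_a: Sequence[GeneStat] | pd.DataFrame,
    stats_b: Sequence[GeneStat] | pd.DataFrame,
    focal_genes: Sequence[str],
) -> tuple[float, float, int]:
    """Pearson correlation of a per-gene statistic between two populations
    over the focal genes present in both.  Returns (r, two-sided p, n)."""
    a = _frame(stats_a).set_index("gene_id")["value"]
    b = _frame(stats_b).set_index("gene_id")["value"]
    shared = [g for g in focal_genes if g in a.index and g in b.index]
    if len(shared) < 3:
        raise ClassTestError(
            f"need >= 3 focal genes present in both populations, have {len(shared)}"
        )
    r, p = sps.pearsonr(a.loc[shared].to_numpy(), b.loc[shared].to_numpy())
    return float(r), float(p), len(shared)
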