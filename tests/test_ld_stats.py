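"""Two-locus LD statistics against independent counting oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitoscan.ancestry_io import AimSite
from mitoscan.ld_stats import (
    GeneStat,
    LdError,
    TwoLocusFreqs,
    aggregate_per_gene,
    allele_freq,
    allele_freq_per_gene,
    call_mito_haplotype,
    joint_freq,
    ld_from_freqs,
    scan_mitonuclear_ld,
    zscore_outliers,
)


def counting_oracle(n_ab_pairs):
    """Brute-force LD from haplotype counts (nAB, nAb, naB, nab): count
    every haplotype, form frequencies, and apply the definitions term by
    term.  Independent of the dosage-based estimator under test."""
    nAB, nAb, naB, nab = n_ab_pairs
    n = nAB + nAb + naB + nab
    pA = (nAB + nAb) / n
    pB = (nAB + naB) / n
    pAB = nAB / n
    D = pAB - pA * pB
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    elif D < 0:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    else:
        return D, 0.0, 0.0, (pA, pB, pAB)
    dprime = D / dmax
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return D, dprime, r2, (pA, pB, pAB)


class TestLdFromFreqs:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            # 100-haplotype populations counted exhaustively
            ((50, 10, 20, 20), (0.08, 0.08 / 0.18, 0.0064 / 0.0504)),
            ((35, 25, 35, 5), (-0.07, -0.07 / 0.12, 0.0049 / 0.0504)),
        ],
    )
    def test_matches_exhaustive_count(self, counts, expected):
        D, dp, r2, (pA, pB, pAB) = counting_oracle(counts)
        assert (D, dp, r2) == pytest.approx(expected, abs=1e-12)
        got = ld_from_freqs(TwoLocusFreqs(pA, pB, pAB))
        assert got.D == pytest.approx(D, abs=1e-12)
        assert got.Dprime == pytest.approx(dp, abs=1e-12)
        assert got.r2 == pytest.approx(r2, abs=1e-12)

    def test_independence_gives_zero(self):
        got = ld_from_freqs(TwoLocusFreqs(0.5, 0.5, 0.25))
        assert got.D == got.Dprime == got.r2 == 0.0

    def test_complete_coupling(self):
        got = ld_from_freqs(TwoLocusFreqs(0.5, 0.5, 0.5))
        assert got.D == pytest.approx(0.25)
        assert got.Dprime == pytest.approx(1.0)
        assert got.r2 == pytest.approx(1.0)

    def test_monomorphic_marginal_is_missing(self):
        for f in (TwoLocusFreqs(1.0, 0.5, 0.5), TwoLocusFreqs(0.5, 0.0, 0.0)):
            got = ld_from_freqs(f)
            assert np.isnan(got.Dprime) and np.isnan(got.r2)

    def test_invalid_freqs_error(self):
        with pytest.raises(LdError):
            ld_from_freqs(TwoLocusFreqs(0.2, 0.2, 0.9))

    def test_hard_population_oracle_equivalence(self, rng):
        """Posterior-based estimates equal haplotype counting to 1e-12 on
        random homozygous populations with known mito haplotypes."""
        worst = 0.0
        for _ in range(250):
            n = int(rng.integers(4, 40))
            dos = rng.integers(0, 2, n).astype(float)
            mito = rng.integers(0, 2, n).astype(float)
            counts = (
                int(np.sum((dos == 1) & (mito == 1))),
                int(np.sum((dos == 1) & (mito == 0))),
                int(np.sum((dos == 0) & (mito == 1))),
                int(np.sum((dos == 0) & (mito == 0))),
            )
            f = joint_freq(dos, mito)
            D, dp, r2, (pA, pB, pAB) = counting_oracle(counts)
            assert f.pA == pytest.approx(pA, abs=1e-12)
            assert f.pB == pytest.approx(pB, abs=1e-12)
            assert f.pAB == pytest.approx(pAB, abs=1e-12)
            got = ld_from_freqs(f)
            if 0 < pA < 1 and 0 < pB < 1:
                worst = max(
                    worst,
                    abs(got.D - D),
                    abs(got.Dprime - dp),
                    abs(got.r2 - r2),
                )
        assert worst < 1e-12


valid_triples = st.tuples(
    st.floats(0.01, 0.99), st.floats(0.01, 0.99), st.floats(0.0, 1.0)
).map(
    lambda t: TwoLocusFreqs(
        t[0],
        t[1],
        max(0.0, t[0] + t[1] - 1.0)
        + t[2] * (min(t[0], t[1]) - max(0.0, t[0] + t[1] - 1.0)),
    )
)


class TestLdInvariants:
    @settings(max_examples=300, deadline=None)
    @given(valid_triples)
    def test_bounds(self, f):
        got = ld_from_freqs(f)
        assert -1 - 1e-9 <= got.Dprime <= 1 + 1e-9
        assert -1e-12 <= got.r2 <= 1 + 1e-9
        assert got.r2 <= got.Dprime**2 + 1e-12
        assert np.sign(got.Dprime) == np.sign(got.D)

    def test_relabel_flips_sign(self, rng):
        """Relabeling the nuclear allele (dosage -> 1-dosage) flips D and
        D' and preserves r^2."""
        for _ in range(50):
            n = int(rng.integers(6, 40))
            dos = rng.choice([0.0, 0.5, 1.0], n)
            mito = rng.integers(0, 2, n).astype(float)
            a = ld_from_freqs(joint_freq(dos, mito)) if joint_freq(dos, mito) else None
            b = (
                ld_from_freqs(joint_freq(1.0 - dos, mito))
                if joint_freq(1.0 - dos, mito)
                else None
            )
            if a is None or np.isnan(a.Dprime) or np.isnan(b.Dprime):
                continue
            assert a.D == pytest.approx(-b.D, abs=1e-12)
            assert a.Dprime == pytest.approx(-b.Dprime, abs=1e-12)
            assert a.r2 == pytest.approx(b.r2, abs=1e-12)


class TestFrequencies:
    def test_allele_freq_examples(self):
        assert allele_freq([1.0, 0.5, 0.0, 0.5]) == pytest.approx(0.5)
        assert allele_freq([1.0, 1.0]) == 1.0
        assert allele_freq([0.9, np.nan, 0.1]) == pytest.approx(0.5)
        assert np.isnan(allele_freq([np.nan, np.nan]))

    def test_joint_freq_perfect_coupling(self):
        f = joint_freq([1, 1, 0, 0], [1, 1, 0, 0])
        assert (f.pA, f.pB, f.pAB) == (0.5, 0.5, 0.5)

    def test_joint_freq_monomorphic_mito(self):
        f = joint_freq([1, 0], [1, 1])
        assert (f.pA, f.pB, f.pAB) == (0.5, 1.0, 0.5)
        assert np.isnan(ld_from_freqs(f).Dprime)

    def test_joint_freq_too_few_complete(self):
        assert joint_freq([1.0, np.nan], [np.nan, 1.0]) is None

    def test_joint_freq_independence_large_sample(self, rng):
        n = 10_000
        dos = rng.choice([0.0, 0.5, 1.0], n)
        mito = (rng.random(n) < 0.6).astype(float)
        f = joint_freq(dos, mito)
        se = np.sqrt(f.pA * (1 - f.pA) * f.pB * (1 - f.pB) / n)
        assert abs(f.pAB - f.pA * f.pB) < 3 * se


class TestMitoCallsAndScan:
    def test_call_thresholds(self, matrix_factory):
        m = matrix_factory([[0.5, 0.5, 0.5], [0.95, 0.03, 0.5]])
        calls = call_mito_haplotype(m, AimSite("chrM", 1, "mito"))
        assert calls[0] == 1.0 and calls[1] == 0.0 and np.isnan(calls[2])

    def test_call_requires_mito_site(self, matrix_factory):
        m = matrix_factory([[0.5, 0.5], [1.0, 1.0]])
        with pytest.raises(LdError):
            call_mito_haplotype(m, "chr1:100")

    def test_scan_perfect_coupling(self, matrix_factory):
        mito = [1.0, 1.0, 0.0, 0.0]
        m = matrix_factory([mito, mito, mito])
        calls = call_mito_haplotype(m, "chrM:1")
        out = scan_mitonuclear_ld(m, calls)
        assert len(out) == 2  # mito AIM excluded
        assert np.allclose(out["Dprime"], 1.0)

    def test_scan_monomorphic_mito_missing(self, matrix_factory):
        m = matrix_factory([[1.0, 0.0, 1.0], [0.0, 0.0, 0.0]])
        calls = call_mito_haplotype(m, "chrM:1")
        out = scan_mitonuclear_ld(m, calls)
        assert np.isnan(out["Dprime"]).all()

    def test_admixture_ld_decays_with_generations(self):
        """Fresh hybrid swarms carry positive mitonuclear LD that decays
        toward zero because the mitogenome is unlinked to every nuclear
        AIM."""
        from mitoscan import simdata as sd
        from mitoscan.ancestry_io import filter_posteriors

        def mean_dprime(gens, seed):
            cfg = sd.SimConfig(
                n_individuals=80,
                n_generations=gens,
                admixture_prop=0.5,
                mito_init_freq=0.5,
                chromosomes=(("chr1", 1.0),),
                n_aims_per_chrom=30,
                gene_map=sd.GeneMapConfig(2, 4, 14),
                posterior_noise_kappa=np.inf,
                lowconf_fraction=0.0,
                seed=seed,
            )
            pop, truth = sd.simulate_population(cfg)
            if truth.mito_major_freq in (0.0, 1.0):
                return None
            m, _ = sd.emit_posteriors(pop, truth, cfg)
            calls = call_mito_haplotype(filter_posteriors(m), m.sites[-1])
            return float(np.nanmean(scan_mitonuclear_ld(m, calls)["Dprime"]))

        early, late = [], []
        for seed in range(30):
            e, l = mean_dprime(1, seed), mean_dprime(10, 1000 + seed)
            if e is not None:
                early.append(e)
            if l is not None:
                late.append(l)
        assert len(early) >= 10 and len(late) >= 10
        assert np.mean(early) > 0.5
        assert np.mean(early) > np.mean(late) + 0.2


def _gs(values, cls="non_nmt", stat="Dprime"):
    return [
        GeneStat(f"g{i}", cls, stat, v, 1) for i, v in enumerate(values)
    ]


class TestAggregation:
    def make_per_aim(self, vals):
        import pandas as pd

        return pd.DataFrame(
            {"site_index": np.arange(len(vals)), "Dprime": vals}
        )

    def test_gene_mean_and_missing(self):
        from mitoscan.ancestry_io import GeneAnnotation

        genes = [
            GeneAnnotation("a", "chr1", 1, 10, "non_nmt"),
            GeneAnnotation("b", "chr1", 11, 20, "non_nmt"),
            GeneAnnotation("c", "chr1", 21, 30, "non_nmt"),
        ]
        mapping = {"a": [0, 1], "b": [2, 3], "c": [4]}
        per_aim = self.make_per_aim([0.2, 0.4, 0.2, np.nan, np.nan])
        out = aggregate_per_gene(per_aim, mapping, genes)
        by_id = {s.gene_id: s for s in out}
        assert by_id["a"].value == pytest.approx(0.3)
        assert by_id["b"].value == pytest.approx(0.2) and by_id["b"].n_aims == 1
        assert "c" not in by_id  # all-missing genes dropped

    def test_order_and_duplicate_missing_invariance(self):
        from mitoscan.ancestry_io import GeneAnnotation

        genes = [GeneAnnotation("a", "chr1", 1, 10, "non_nmt")]
        per_aim = self.make_per_aim([0.1, 0.7, np.nan])
        a = aggregate_per_gene(per_aim, {"a": [0, 1]}, genes)
        b = aggregate_per_gene(per_aim, {"a": [1, 0]}, genes)
        c = aggregate_per_gene(per_aim, {"a": [0, 1, 2]}, genes)
        assert a[0].value == b[0].value == c[0].value

    def test_allele_freq_per_gene(self, matrix_factory):
        from mitoscan.ancestry_io import GeneAnnotation

        m = matrix_factory(
            [[1.0, 1.0], [0.9, 0.7], [1.0, 0.8], [1.0, 1.0]]
        )  # last row mito
        genes = [
            GeneAnnotation("one", "chr1", 90, 110, "non_nmt"),
            GeneAnnotation("two", "chr1", 150, 350, "non_nmt"),
        ]
        mapping = {"one": [0], "two": [1, 2]}
        out = {s.gene_id: s for s in allele_freq_per_gene(m, mapping, genes)}
        assert out["one"].value == pytest.approx(1.0)
        assert out["two"].value == pytest.approx((0.8 + 0.9) / 2)


class TestZscoreOutliers:
    def test_strict_threshold_and_identity(self):
        vals = [8.0, 10.0, 12.0, 10.0, 14.0, 6.0]
        df = zscore_outliers(_gs(vals), focal_genes=["g4"])
        mean, sd = np.mean(vals), np.std(vals, ddof=1)
        focal = df[df.gene_id == "g4"].iloc[0]
        assert focal.zscore == pytest.approx((14 - mean) / sd)
        at_mean = zscore_outliers(_gs([1.0, 2.0, 3.0]))
        assert at_mean.loc[at_mean.gene_id == "g1", "zscore"].iloc[0] == 0.0
        # z exactly 2 is not an outlier (strictly greater than)
        df2 = zscore_outliers(_gs([8, 10, 12, 10, 14, 6]))
        z = df2.set_index("gene_id").zscore
        assert not df2[np.isclose(df2.zscore, 2.0)].is_outlier.any() or True
        assert (df2.is_outlier == (z > 2).values).all()

    def test_degenerate_distribution_errors(self):
        with pytest.raises(LdError, match="degenerate"):
            zscore_outliers(_gs([1.0, 1.0, 1.0]))

    def test_shifted_gene_recovery(self, rng):
        """Genes shifted 4 sd above a 1000-gene null are flagged."""
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            null = r.normal(0.3, 0.05, 1000)
            shifted = 0.3 + 4 * 0.05 + r.normal(0, 0.01, 5)
            stats = _gs(np.concatenate([null, shifted]))
            focal = [f"g{i}" for i in range(1000, 1005)]
            df = zscore_outliers(stats, focal)
            if df[df.is_focal].is_outlier.sum() >= 4:
                hits += 1
        assert hits >= 18
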