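"""Sharing classification, EB shrinkage/LFSR, LD scores, MAF, conservation."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from stratiqtl.classify_share import (
    classification_summary,
    classify_egenes,
    gene_conservation,
    ld_scores,
    maf_by_breed,
    pairwise_sharing,
    shrink_lfsr,
)
from stratiqtl.containers import ScoreTrack

from conftest import make_genotypes


def _flags(d, l, y, genes=None):
    genes = genes or [f"g{i}" for i in range(len(d))]
    return {
        "Duroc": pd.DataFrame({"gene_id": genes, "is_egene": d}),
        "Landrace": pd.DataFrame({"gene_id": genes, "is_egene": l}),
        "Yorkshire": pd.DataFrame({"gene_id": genes, "is_egene": y}),
    }


class TestClassification:
    def test_category_per_flag_pattern(self):
        cls = classify_egenes(
            _flags([True, True, False], [False, True, False], [False, True, False])
        )
        assert list(cls["category"]) == ["specific:Duroc", "shared3", "non_egene"]

    def test_two_breed_pattern(self):
        cls = classify_egenes(_flags([False], [True], [True]))
        assert cls["category"].iloc[0] == "shared2:Landrace+Yorkshire"

    def test_partition_covers_universe(self):
        rng = np.random.default_rng(0)
        n = 50
        cls = classify_egenes(
            _flags(*(rng.random(n) < 0.4 for _ in range(3)))
        )
        assert len(cls) == n
        counts = cls["category"].value_counts()
        assert counts.sum() == n

    def test_untested_gene_classified_from_available(self):
        flags = _flags([True], [True], [True])
        flags["Yorkshire"] = pd.DataFrame(
            {"gene_id": ["gZ"], "is_egene": [True]}
        )
        cls = classify_egenes(flags).set_index("gene_id")
        assert cls.loc["g0", "category"] == "shared2:Duroc+Landrace"
        assert cls.loc["gZ", "category"] == "specific:Yorkshire"

    def test_summary_shared_fraction(self):
        cls = classify_egenes(
            _flags([True, True, True, False],
                   [True, False, False, False],
                   [True, True, False, False])
        )
        summ = classification_summary(cls).set_index("breed")
        # Duroc eGenes: g0 (shared3), g1 (shared with Yorkshire), g2 (specific)
        assert summ.loc["Duroc", "n_egenes"] == 3
        assert summ.loc["Duroc", "shared_fraction"] == pytest.approx(2 / 3)


class TestShrinkage:
    def test_all_zero_estimates_sign_undetermined(self):
        res = shrink_lfsr(np.zeros(20), np.ones(20))
        assert np.all(res.lfsr >= 0.5 - 1e-9)

    def test_strong_effect_among_nulls(self):
        rng = np.random.default_rng(1)
        betahat = np.concatenate([rng.normal(0, 1.0, 200), [8.0]])
        se = np.ones(201)
        res = shrink_lfsr(betahat, se)
        assert res.lfsr[-1] < 0.05
        assert 0.5 * 8.0 < res.posterior_mean[-1] < 8.0

    def test_posterior_matches_numerical_integration(self):
        """Posterior mean and sign mass vs quadrature on the fitted prior."""
        rng = np.random.default_rng(2)
        betahat = np.concatenate([rng.normal(0, 0.5, 50), [3.0, -2.5]])
        se = np.full(52, 0.7)
        res = shrink_lfsr(betahat, se)
        pi, tau = res.mixture_weights, res.mixture_sd
        for j in (50, 51):
            b, s = betahat[j], se[j]

            def prior_density(t):
                dens = 0.0
                for k in range(1, len(tau)):
                    dens += pi[k] * stats.norm.pdf(t, 0.0, tau[k])
                return dens

            def integrand_mean(t):
                return t * stats.norm.pdf(b, t, s) * prior_density(t)

            def integrand_norm(t):
                return stats.norm.pdf(b, t, s) * prior_density(t)

            lim = 12 * max(tau.max(), s)
            num, _ = integrate.quad(integrand_mean, -lim, lim, limit=200)
            den_cont, _ = integrate.quad(integrand_norm, -lim, lim, limit=200)
            den = den_cont + pi[0] * stats.norm.pdf(b, 0.0, s)
            assert res.posterior_mean[j] == pytest.approx(num / den, abs=1e-6)

            neg, _ = integrate.quad(integrand_norm, -lim, 0.0, limit=200)
            p_le0 = (neg + pi[0] * stats.norm.pdf(b, 0.0, s)) / den
            lfsr_oracle = min(p_le0, 1.0 - neg / den)
            assert res.lfsr[j] == pytest.approx(lfsr_oracle, abs=1e-6)

    def test_null_simulation_high_lfsr(self):
        rng = np.random.default_rng(3)
        res = shrink_lfsr(rng.normal(0, 1, 500), np.ones(500))
        # beta = 0 truth: sign cannot be determined for most effects
        assert np.median(res.lfsr) > 0.4

    def test_bad_se_rejected(self):
        with pytest.raises(ValueError):
            shrink_lfsr(np.ones(3), np.array([1.0, 0.0, 1.0]))


def _effects(b1, b2, l1=None, l2=None):
    n = len(b1)
    return pd.DataFrame(
        {
            "beta_Duroc": b1,
            "beta_Landrace": b2,
            "lfsr_Duroc": l1 if l1 is not None else np.zeros(n),
            "lfsr_Landrace": l2 if l2 is not None else np.zeros(n),
        }
    )


class TestPairwiseSharing:
    def test_factor_two_boundary(self):
        est = pairwise_sharing(
            _effects([0.5, 0.5], [0.9, 1.2]), ("Duroc", "Landrace")
        )
        # 0.5 vs 0.9: ratio 1.8 counts in mag2; 0.5 vs 1.2: ratio 2.4 only mag4
        assert est.prop_sign == 1.0
        assert est.prop_mag2 == 0.5
        assert est.prop_mag4 == 1.0

    def test_ordering_invariant(self):
        rng = np.random.default_rng(4)
        est = pairwise_sharing(
            _effects(rng.normal(size=100), rng.normal(size=100)),
            ("Duroc", "Landrace"),
        )
        assert est.prop_mag2 <= est.prop_mag4 <= est.prop_sign <= 1.0

    def test_identical_vs_independent_effects(self):
        rng = np.random.default_rng(5)
        b = rng.normal(0, 1, 300)
        same = pairwise_sharing(_effects(b, b * rng.uniform(0.8, 1.25, 300)),
                                ("Duroc", "Landrace"))
        assert same.prop_mag2 >= 0.8
        indep = pairwise_sharing(
            _effects(rng.normal(size=2000), rng.normal(size=2000)),
            ("Duroc", "Landrace"),
        )
        assert indep.prop_sign == pytest.approx(0.5, abs=0.05)

    def test_lfsr_gating(self):
        eff = _effects([1.0, 1.0], [1.0, 1.0], l1=[0.5, 0.01], l2=[0.5, 0.5])
        either = pairwise_sharing(eff, ("Duroc", "Landrace"), lfsr_gate="either")
        assert either.n_effects == 1
        with pytest.raises(ValueError):
            pairwise_sharing(eff, ("Duroc", "Landrace"), lfsr_gate="both")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_sharing(
                _effects([1.0], [1.0], l1=[0.9], l2=[0.9]), ("Duroc", "Landrace")
            )


class TestLdScores:
    def test_duplicated_variants_score_two(self):
        rng = np.random.default_rng(6)
        a = rng.integers(0, 3, 400)
        others = rng.integers(0, 3, (400, 3))
        d = np.column_stack([a, a, others])
        g = make_genotypes(d)
        scores = ld_scores(g, ("1", 0, 10_000)).set_index("variant_id")
        assert scores.loc["v0", "ld_score"] == pytest.approx(2.0, abs=0.15)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        d = rng.integers(0, 3, (30, 12))
        d[:, d.std(axis=0) == 0] = rng.integers(0, 2, 30)[:, None]
        g = make_genotypes(d)
        scores = ld_scores(g, ("1", 0, 20_000))["ld_score"].to_numpy()
        m = d.shape[1]
        oracle = np.zeros(m)
        for i in range(m):
            for j in range(m):
                r = np.corrcoef(d[:, i].astype(float), d[:, j].astype(float))[0, 1]
                oracle[i] += r * r
        np.testing.assert_allclose(scores, oracle, atol=1e-10)

    def test_independent_variants_bias_term(self):
        rng = np.random.default_rng(8)
        n, m = 500, 40
        d = rng.binomial(2, 0.5, (n, m))
        g = make_genotypes(d)
        scores = ld_scores(g, ("1", 0, 100_000))["ld_score"].to_numpy()
        assert scores.mean() == pytest.approx(1 + (m - 1) / n, abs=0.05)

    def test_single_variant_scores_one(self):
        g = make_genotypes(np.array([[0], [1], [2], [1]]))
        scores = ld_scores(g, ("1", 0, 10_000))
        assert scores["ld_score"].iloc[0] == pytest.approx(1.0)

    def test_zero_variance_excluded(self):
        d = np.column_stack([[0, 1, 2, 1], [1, 1, 1, 1]])
        g = make_genotypes(d)
        scores = ld_scores(g, ("1", 0, 10_000))
        assert list(scores["variant_id"]) == ["v0"]
        assert scores["ld_score"].iloc[0] == pytest.approx(1.0)


class TestMaf:
    def test_folded_frequency(self):
        g = make_genotypes(
            np.array([[0], [0], [1], [1]]), breeds=["Duroc"] * 4
        )
        out = maf_by_breed(g, ["v0"])
        assert out["maf_Duroc"].iloc[0] == pytest.approx(0.25)

    def test_fixed_alt_is_zero(self):
        g = make_genotypes(np.full((4, 1), 2), breeds=["Duroc"] * 4)
        assert maf_by_breed(g, ["v0"])["maf_Duroc"].iloc[0] == 0.0

    def test_unknown_variant_rejected(self, small_genotypes):
        with pytest.raises(KeyError):
            maf_by_breed(small_genotypes, ["nope"])

    def test_breed_specific_detection_tracks_maf(self):
        """A fixed allelic effect is detectable where the variant is common,
        so lead SNPs of breed-specific signals have the highest MAF in the
        breed of detection."""
        from stratiqtl import SimConfig, simulate_genotypes
        from stratiqtl.containers import BREEDS

        cfg = SimConfig(
            n_per_breed=100, n_variants=400, fst=0.2, ld_rho=0.0, seed=51
        )
        g = simulate_genotypes(cfg)
        rng = np.random.default_rng(52)
        masks = {b: g.breed_mask(b) for b in BREEDS}
        detected_in = {b: [] for b in BREEDS}
        for _ in range(250):
            j = int(rng.integers(g.n_variants))
            hits = []
            for b in BREEDS:
                s = g.dosage[masks[b], j].astype(float)
                if s.std() == 0:
                    continue
                y = 0.45 * s + rng.normal(size=s.size)  # same per-allele effect
                if stats.linregress(s, y).pvalue < 1e-4:
                    hits.append(b)
            if len(hits) == 1:  # breed-specific signal
                detected_in[hits[0]].append(g.variants["id"].iloc[j])
        for b in BREEDS:
            mafs = maf_by_breed(g, detected_in[b])
            med = {bb: float(mafs[f"maf_{bb}"].median()) for bb in BREEDS}
            assert med[b] >= max(med[bb] for bb in BREEDS if bb != b)


class TestConservation:
    @staticmethod
    def _genes(tss, length):
        return pd.DataFrame(
            {"id": ["gA"], "chrom": "1", "tss": [tss], "strand": "+",
             "length": [length]}
        )

    def test_insufficient_coverage_no_score(self):
        track = ScoreTrack(pd.DataFrame(
            {"chrom": ["1"], "start": [0], "end": [400], "score": [0.5]}
        ))
        out = gene_conservation(track, self._genes(1, 1000))
        assert out["covered_fraction"].iloc[0] == pytest.approx(0.4)
        assert np.isnan(out["mean_score"].iloc[0])

    def test_weighted_mean_over_covered_bases(self):
        track = ScoreTrack(pd.DataFrame(
            {"chrom": ["1", "1"], "start": [0, 500], "end": [500, 1000],
             "score": [0.2, 0.4]}
        ))
        out = gene_conservation(track, self._genes(1, 1000))
        assert out["mean_score"].iloc[0] == pytest.approx(0.3)
        assert out["covered_fraction"].iloc[0] == pytest.approx(1.0)

    def test_abutting_interval_no_off_by_one(self):
        """Track [0, 100) against a gene starting at 1-based position 101."""
        track = ScoreTrack(pd.DataFrame(
            {"chrom": ["1", "1"], "start": [0, 100], "end": [100, 200],
             "score": [1.0, 0.5]}
        ))
        out = gene_conservation(track, self._genes(101, 100))
        # gene covers 0-based [100, 200): only the second interval overlaps
        assert out["covered_fraction"].iloc[0] == pytest.approx(1.0)
        assert out["mean_score"].iloc[0] == pytest.approx(0.5)

    def test_zero_length_rejected(self):
        track = ScoreTrack(pd.DataFrame(
            {"chrom": ["1"], "start": [0], "end": [10], "score": [0.5]}
        ))
        with pytest.raises(ValueError):
            gene_conservation(track, self._genes(1, 0))
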