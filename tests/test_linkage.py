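"""Interval mapping: probabilities, scans, peaks, resolution, effects."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ailqtl as aq
from ailqtl.gmap import haldane_r
from ailqtl.linkage import LodCurve, _em_mixture, genotype_prob_matrix


# ---------------------------------------------------------------------------
# normalization and map conversion
# ---------------------------------------------------------------------------

class TestNormalize:
    def test_orthogonal_covariate_leaves_trait_unchanged(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0], "x": [1.0, -1.0, -1.0, 1.0]})
        adj = aq.normalize_phenotype(df, "y", ["x"])
        np.testing.assert_allclose(adj.to_numpy(), df["y"].to_numpy(), atol=1e-12)

    def test_planted_sex_effect_removed(self):
        rng = np.random.default_rng(0)
        sex = rng.integers(0, 2, 500)
        df = pd.DataFrame({"hw": rng.normal(0, 1, 500) + 2.0 * sex, "sex": sex})
        adj = aq.normalize_phenotype(df, "hw", ["sex"])
        gap = adj[df["sex"] == 1].mean() - adj[df["sex"] == 0].mean()
        assert abs(gap) < 3 * np.sqrt(4 / 250)

    def test_empty_covariates_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0]})
        with pytest.raises(ValueError):
            aq.normalize_phenotype(df, "y", [])

    def test_missing_values_dropped(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, np.nan],
                           "x": [0.0, 1.0, np.nan, 0.0]})
        adj = aq.normalize_phenotype(df, "y", ["x"])
        assert len(adj) == 2


class TestConvertMap:
    def test_identity_anchors(self):
        anchors = [(0, 0), (10, 10), (50, 50)]
        q = [0.0, 7.5, 49.0]
        np.testing.assert_allclose(aq.convert_map(q, anchors), q)

    def test_midpoint_between_anchors(self):
        assert aq.convert_map(20.0, [(10, 20), (30, 40)]) == pytest.approx(30.0)

    def test_three_anchor_unequal_slopes(self):
        # hand-computed: [0,10] doubles scale, [10,40] keeps it
        anchors = [(0, 0), (10, 20), (40, 50)]
        np.testing.assert_allclose(
            aq.convert_map([5.0, 10.0, 25.0], anchors), [10.0, 20.0, 35.0])

    def test_extrapolation_rejected(self):
        with pytest.raises(ValueError):
            aq.convert_map(41.0, [(0, 0), (40, 50)])

    @given(st.floats(min_value=0.0, max_value=40.0))
    @settings(derandomize=True, max_examples=30)
    def test_piecewise_linear_is_monotone(self, q):
        anchors = [(0, 5), (15, 12), (40, 80)]
        lo = aq.convert_map(max(q - 1, 0.0), anchors)
        hi = aq.convert_map(min(q + 1, 40.0), anchors)
        assert lo <= aq.convert_map(q, anchors) <= hi


# ---------------------------------------------------------------------------
# conditional genotype probabilities
# ---------------------------------------------------------------------------

def f2_conditional(gL, gR, dL, dR):
    """Independent oracle: classical F2 flanking-marker conditionals via full
    enumeration of the two gametes' alleles at the three loci."""
    rL, rR = haldane_r(dL), haldane_r(dR)

    def gamete_p(aL, aS, aR):
        p = 0.5
        p *= (1 - rL) if aL == aS else rL
        p *= (1 - rR) if aS == aR else rR
        return p

    out = np.zeros(3)
    tot = 0.0
    for combo in np.ndindex(2, 2, 2, 2, 2, 2):
        aLm, aSm, aRm, aLp, aSp, aRp = combo
        if aLm + aLp != gL or aRm + aRp != gR:
            continue
        w = gamete_p(aLm, aSm, aRm) * gamete_p(aLp, aSp, aRp)
        out[aSm + aSp] += w
        tot += w
    return out / tot


def ail_conditional(gL, gR, dL, dR, t):
    """Independent oracle for the AIL case: the same enumeration with the
    per-interval fractions expanded to R_t."""
    RL = aq.expected_recombinant_fraction(haldane_r(dL), t)
    RR = aq.expected_recombinant_fraction(haldane_r(dR), t)
    RLR = RL + RR - 2 * RL * RR

    def gamete_p(aL, aS, aR):
        # joint for one AIL gamete: P(aL) * P(aS|aL) * P(aR|aS)
        p = 0.5
        p *= (1 - RL) if aL == aS else RL
        p *= (1 - RR) if aS == aR else RR
        return p

    num = np.zeros(3)
    for combo in np.ndindex(2, 2, 2, 2, 2, 2):
        aLm, aSm, aRm, aLp, aSp, aRp = combo
        if aLm + aLp != gL or aRm + aRp != gR:
            continue
        num[aSm + aSp] += gamete_p(aLm, aSm, aRm) * gamete_p(aLp, aSp, aRp)
    return num / num.sum()


class TestGenotypeProbs:
    def test_typed_marker_collapses_to_call(self):
        assert aq.qtl_genotype_probs("QQ", "Qq", 0.0, 2.0, 14) == (1.0, 0.0, 0.0)
        assert aq.qtl_genotype_probs("qq", "QQ", 0.0, 2.0, 14) == (0.0, 0.0, 1.0)
        assert aq.qtl_genotype_probs("qq", "QQ", 3.0, 0.0, 14) == (1.0, 0.0, 0.0)

    def test_both_flanks_missing_gives_prior(self):
        assert aq.qtl_genotype_probs(None, None, 1.0, 1.0, 14) == (0.25, 0.5, 0.25)

    @pytest.mark.parametrize("gL,gR", [(2, 2), (2, 1), (1, 1), (0, 2), (1, 0)])
    def test_t2_matches_classical_f2_enumeration(self, gL, gR):
        dL, dR = 1.5, 0.5
        got = aq.qtl_genotype_probs(gL, gR, dL, dR, 2)       # (P_QQ,P_Qq,P_qq)
        exp = f2_conditional(gL, gR, dL, dR)                 # Q-count order
        np.testing.assert_allclose(got, exp[::-1], atol=1e-12)

    @pytest.mark.parametrize("gL,gR", [(2, 2), (1, 2), (0, 1)])
    def test_t14_matches_transmission_enumeration(self, gL, gR):
        got = aq.qtl_genotype_probs(gL, gR, 1.0, 1.0, 14)
        exp = ail_conditional(gL, gR, 1.0, 1.0, 14)
        np.testing.assert_allclose(got, exp[::-1], atol=1e-12)

    @given(st.integers(0, 2), st.integers(0, 2),
           st.floats(0.01, 10.0), st.floats(0.01, 10.0),
           st.integers(2, 20))
    @settings(derandomize=True, max_examples=60)
    def test_probabilities_sum_to_one(self, gL, gR, dL, dR, t):
        p = aq.qtl_genotype_probs(gL, gR, dL, dR, t)
        assert all(x >= 0 for x in p)
        assert sum(p) == pytest.approx(1.0)

    def test_matrix_path_matches_scalar_path(self, f14_cohort, gmap):
        geno, _ = f14_cohort
        _, mpos, calls = geno.chrom_calls(gmap, "1")
        pos = 31.0
        probs = genotype_prob_matrix(calls, mpos, pos, 14)
        jL, jR = 15, 16  # markers at 30 and 32 cM
        for i in (0, 5, 100):
            exp = aq.qtl_genotype_probs(int(calls[jL, i]), int(calls[jR, i]),
                                        pos - mpos[jL], mpos[jR] - pos, 14)
            np.testing.assert_allclose(probs[i], exp[::-1], atol=1e-12)

    def test_missing_calls_fall_through_to_next_informative_marker(self, gmap):
        calls = np.array([[2], [-1], [1]], dtype=np.int8)   # middle marker missing
        mpos = np.array([0.0, 2.0, 4.0])
        probs = genotype_prob_matrix(calls, mpos, 2.0, 14)
        exp = aq.qtl_genotype_probs(2, 1, 2.0, 2.0, 14)
        np.testing.assert_allclose(probs[0], exp[::-1], atol=1e-12)


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

class TestQuantitativeScan:
    def test_null_trait_has_low_lod(self, f14_cohort, gmap):
        geno, _ = f14_cohort
        y = np.random.default_rng(9).normal(0, 1, geno.n_individuals)
        curve = aq.scan_quantitative(geno, y, gmap, 14)[0]
        assert np.median(curve.lod) < 0.5
        assert (curve.lod >= 0).all()

    def test_planted_qtl_found_at_truth(self, f14_cohort, gmap, panel):
        geno, _ = f14_cohort
        models = {"y": aq.TraitModel(qtls=[aq.QTLEffect("1", 30.0, 1.0)])}
        phen = aq.simulate_phenotypes(geno, models, panel, seed=5)
        curve = aq.scan_quantitative(geno, phen["y"].to_numpy(), gmap, 14)[0]
        top = max(aq.find_peaks(curve, 2.0), key=lambda p: p.lod)
        assert abs(top.position - 30.0) <= 2.0
        assert top.ci_lo <= 30.0 <= top.ci_hi

    def test_lod_invariant_to_affine_trait_transform(self, f14_cohort, gmap, panel):
        geno, _ = f14_cohort
        models = {"y": aq.TraitModel(qtls=[aq.QTLEffect("1", 20.0, 0.5)])}
        y = aq.simulate_phenotypes(geno, models, panel, seed=6)["y"].to_numpy()
        c1 = aq.scan_quantitative(geno, y, gmap, 14, step=2.0)[0]
        c2 = aq.scan_quantitative(geno, 3.5 * y - 11.0, gmap, 14, step=2.0)[0]
        np.testing.assert_allclose(c1.lod, c2.lod, atol=1e-4)

    def test_em_reaches_grid_likelihood_on_toy(self):
        """EM LOD equals direct grid maximization of the mixture likelihood
        on a 20-individual instance."""
        from tests.oracles import grid_mixture_loglik
        rng = np.random.default_rng(4)
        panel = pd.DataFrame({"marker": ["m1", "m2"], "chrom": "1", "cm": [0.0, 2.0]})
        ped = aq.simulate_pedigree(aq.AILDesign(10, 2, seed=4), n_final=20)
        geno = aq.simulate_genotypes(ped, panel, seed=5)
        probs = genotype_prob_matrix(geno.calls, np.array([0.0, 2.0]), 1.0, 2)
        y = (geno.calls[0] - 1) * 0.8 + rng.normal(0, 1, 20)
        ll_em = _em_mixture(y, probs, n_starts=8)[0]
        ll_grid = grid_mixture_loglik(y, probs)
        assert abs(ll_em - ll_grid) / np.log(10) < 1e-4

    def test_monomorphic_trait_rejected(self, f14_cohort, gmap):
        geno, _ = f14_cohort
        with pytest.raises(ValueError, match="zero variance|monomorphic"):
            aq.scan_quantitative(geno, np.ones(geno.n_individuals), gmap, 14)


class TestBinaryScan:
    def test_null_positionwise_lod_near_chi2_mean(self, f14_cohort, gmap):
        geno, _ = f14_cohort
        y = (np.random.default_rng(1).random(geno.n_individuals) < 0.34).astype(float)
        curve = aq.scan_binary(geno, y, gmap, 14, step=4.0)[0]
        # LR ~ chi2_2 under the null: E[LOD] = 2 / (2 ln 10) ~ 0.434
        assert 0.1 < curve.lod.mean() < 0.9

    def test_planted_liability_qtl_detected(self, f14_cohort, gmap, panel):
        from scipy.stats import norm
        geno, _ = f14_cohort
        thr = float(norm.ppf(1 - 0.34))
        models = {"pfo": aq.TraitModel(qtls=[aq.QTLEffect("1", 30.0, -0.6)],
                                       liability_threshold=thr)}
        phen = aq.simulate_phenotypes(geno, models, panel, seed=7)
        curve = aq.scan_binary(geno, phen["pfo"].to_numpy(), gmap, 14)[0]
        top = max(aq.find_peaks(curve, 2.0), key=lambda p: p.lod)
        assert top.ci_lo <= 30.0 <= top.ci_hi

    def test_deterministic_trait_raises_separation_flag(self, f14_cohort, gmap):
        geno, _ = f14_cohort
        y = (geno.calls[15] == 0).astype(float)
        curve = aq.scan_binary(geno, y, gmap, 14, step=10.0)[0]
        assert curve.flags.get("separated")
        # capped at the saturated-model bound: null deviance / (2 ln 10)
        p = y.mean()
        dev0 = -2 * len(y) * (p * np.log(p) + (1 - p) * np.log(1 - p))
        assert curve.lod.max() <= dev0 / (2 * np.log(10)) + 1e-9

    def test_single_class_rejected(self, f14_cohort, gmap):
        geno, _ = f14_cohort
        with pytest.raises(ValueError):
            aq.scan_binary(geno, np.zeros(geno.n_individuals), gmap, 14)


# ---------------------------------------------------------------------------
# peaks, resolution, effects
# ---------------------------------------------------------------------------

class TestFindPeaks:
    def test_flat_curve_has_no_peaks(self):
        c = LodCurve("1", np.arange(0, 10, 0.25), np.zeros(40))
        assert aq.find_peaks(c) == []

    def test_single_peak_support_interval_is_one_lod_region(self):
        pos = np.arange(0, 20.25, 0.25)
        lod = 4.4 - 0.1 * np.abs(pos - 10.0) ** 2
        lod = np.clip(lod, 0, None)
        (pk,) = aq.find_peaks(LodCurve("1", pos, lod), 2.0)
        assert pk.lod == pytest.approx(4.4)
        inside = (pos >= pk.ci_lo) & (pos <= pk.ci_hi)
        assert (lod[inside] >= 3.4).all()
        # maximality: the neighbours just outside drop below peak - 1
        lo_i = np.searchsorted(pos, pk.ci_lo)
        hi_i = np.searchsorted(pos, pk.ci_hi)
        assert lo_i == 0 or lod[lo_i - 1] < 3.4
        assert hi_i == len(pos) - 1 or lod[hi_i + 1] < 3.4

    def test_adjacent_peaks_with_overlapping_intervals_flagged(self):
        pos = np.arange(0, 30.25, 0.25)
        lod = np.maximum(3.1 - 0.05 * (pos - 10) ** 2, 4.4 - 0.05 * (pos - 17) ** 2)
        lod = np.clip(lod, 0, None)
        peaks = aq.find_peaks(LodCurve("1", pos, lod), 2.0)
        assert len(peaks) == 2
        assert sorted(round(p.lod, 1) for p in peaks) == [3.1, 4.4]
        assert all(p.overlapping for p in peaks)


class TestResolveLinkedPeaks:
    def test_two_strong_qtl_declared_distinct(self, f14_cohort, gmap, panel):
        geno, _ = f14_cohort
        models = {"y": aq.TraitModel(qtls=[aq.QTLEffect("1", 24.0, 0.5),
                                           aq.QTLEffect("1", 36.0, 0.5)])}
        phen = aq.simulate_phenotypes(geno, models, panel, seed=8)
        y = phen["y"].to_numpy()
        curve = aq.scan_quantitative(geno, y, gmap, 14)[0]
        peaks = aq.find_peaks(curve, 2.0)
        near_a = min(peaks, key=lambda p: abs(p.position - 24.0))
        near_b = min(peaks, key=lambda p: abs(p.position - 36.0))
        verdict, cond = aq.resolve_linked_peaks(geno, y, gmap, 14, (near_a, near_b))
        assert verdict == "distinct"
        assert cond.model == "fixed-term"

    def test_fixing_unlinked_marker_barely_changes_curve(self, panel):
        # F2 cohort: unlinked chromosomes assort independently, so a
        # fixed marker on the other chromosome is an irrelevant covariate
        # (at F14 the small closed population develops cross-chromosome
        # associations by drift, which the fixed term genuinely absorbs)
        two_chrom = pd.concat([
            panel,
            pd.DataFrame({"marker": [f"2m{i:03d}" for i in range(5)],
                          "chrom": "2", "cm": np.arange(5) * 2.0}),
        ], ignore_index=True)
        ped = aq.simulate_pedigree(aq.AILDesign(48, 2, seed=13), n_final=400)
        geno = aq.simulate_genotypes(ped, two_chrom, seed=14)
        geno = geno.subset(ped[ped["generation"] == 2]["id"].tolist())
        gmap2 = aq.GeneticMap(two_chrom)
        models = {"y": aq.TraitModel(qtls=[aq.QTLEffect("1", 30.0, 0.7)])}
        y = aq.simulate_phenotypes(geno, models, two_chrom, seed=15)["y"].to_numpy()
        base = aq.scan_quantitative(geno, y, gmap2, 2, step=2.0, chromosomes=["1"])[0]
        cond = aq.scan_quantitative(geno, y, gmap2, 2, step=2.0,
                                    fixed_marker="2m002", chromosomes=["1"])[0]
        assert np.abs(base.lod - cond.lod).max() < 0.5


class TestEffects:
    def test_equal_homozygote_means_give_zero_additive(self):
        probs = np.eye(3)[[0, 0, 1, 1, 2, 2]]
        y = np.array([1.0, 1.0, 0.4, 0.6, 1.0, 1.0])
        eff = aq.estimate_effects(probs, y)
        assert eff.a_qtl == pytest.approx(0.0)
        assert eff.d_qtl == pytest.approx(-0.5)

    def test_midpoint_heterozygote_is_pure_additivity(self):
        probs = np.eye(3)[[0, 1, 2]]
        y = np.array([0.0, 0.5, 1.0])
        eff = aq.estimate_effects(probs, y)
        assert eff.d_qtl == pytest.approx(0.0)
        assert eff.a_qtl == pytest.approx(0.5)

    def test_parental_fvl_arithmetic(self):
        """mean_QQ = 1.13, mean_qq = 0.60 -> a = 0.265, 50% of the parental
        gap of 0.53."""
        probs = np.eye(3)[[0, 1, 2]]
        y = np.array([0.60, 0.865, 1.13])
        eff = aq.estimate_effects(probs, y, parental_means=(1.13, 0.60))
        assert eff.a_qtl == pytest.approx(0.265)
        assert eff.attributable_pct == pytest.approx(50.0)
        assert aq.classify_direction(eff, (1.13, 0.60)) == "normal"

    def test_empty_genotype_class_rejected(self):
        probs = np.eye(3)[[0, 1, 0, 1]]
        with pytest.raises(ValueError, match="zero expected count"):
            aq.estimate_effects(probs, np.zeros(4))

    def test_estimator_recovers_planted_effect(self, f14_cohort, gmap, panel):
        geno, _ = f14_cohort
        models = {"y": aq.TraitModel(qtls=[aq.QTLEffect("1", 30.0, 0.265)],
                                     residual_sd=0.11)}
        y = aq.simulate_phenotypes(geno, models, panel, seed=16)["y"].to_numpy()
        _, mpos, calls = geno.chrom_calls(gmap, "1")
        probs = genotype_prob_matrix(calls, mpos, 30.0, 14)
        eff = aq.estimate_effects(probs, y)
        assert eff.a_qtl == pytest.approx(0.265, abs=3 * 0.11 / np.sqrt(100))
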