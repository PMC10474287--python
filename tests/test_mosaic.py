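import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import episig as E
from episig.mosaic import (
    _loess_smooth,
    adjudicate,
    binomial_deviation,
    build_band,
    correct_variant_count,
    deviation_from_vaf,
    flag_potential_mosaic,
    leave_out_combinations,
    sample_depth_and_reads,
    synthesize_mosaic,
)
from episig.preprocess import beta_to_m
from helpers import cohort_groups


class TestDeviationArithmetic:
    def test_heterozygous_expectation_is_zero(self):
        for n in (10, 171, 500):
            assert binomial_deviation(n, n / 2) == 0.0

    @pytest.mark.parametrize("n,k,expected", [
        (171, 78.5, -1.07),   # corrected tandem-duplication count
        (166, 68, -2.33),     # re-called deletion reads
    ])
    def test_count_based_deviations(self, n, k, expected):
        assert round(binomial_deviation(n, k), 2) == expected

    @pytest.mark.parametrize("n,vaf,expected", [
        (129, 0.28, -5.00), (51, 0.35, -2.14), (370, 0.24, -10.00),
        (15, 0.13, -2.87), (211, 0.25, -7.26),
    ])
    def test_vaf_based_deviations(self, n, vaf, expected):
        assert round(deviation_from_vaf(n, vaf), 2) == pytest.approx(expected, abs=0.05)

    def test_corrected_count_worked_example(self):
        k = correct_variant_count(52, 2, 49)
        assert k == 78.5
        assert round(k / 171, 2) == 0.46
        assert correct_variant_count(7, 0, 0) == 7

    def test_preconditions(self):
        with pytest.raises(E.DomainError):
            binomial_deviation(100, 150)
        with pytest.raises(E.DomainError):
            deviation_from_vaf(100, 1.2)
        with pytest.raises(E.DomainError):
            correct_variant_count(-1, 0, 0)


class TestFlagging:
    def test_threshold_fraction(self):
        flagged, thr = flag_potential_mosaic(100, 50)
        assert thr == pytest.approx(0.4)  # 0.5 - 1/sqrt(100)
        assert not flagged
        assert flag_potential_mosaic(100, 39)[0]  # |39-50| = 11 > 10
        assert not flag_potential_mosaic(100, 40)[0]  # exactly at the bound

    def test_flag_iff_deviation_exceeds_two(self, rng):
        """The fraction threshold and the SD rule are the same rule."""
        for _ in range(200):
            n = int(rng.integers(10, 500))
            k = int(rng.integers(0, n + 1))
            flagged, _ = flag_potential_mosaic(n, k)
            assert flagged == (abs(binomial_deviation(n, k)) > 2.0)


class TestMixing:
    def test_endpoints_and_midpoint(self):
        a = pd.Series([0.8, 0.6], index=["x", "y"])
        u = pd.Series([0.2, 0.4], index=["x", "y"])
        assert synthesize_mosaic(a, u, 0.0).equals(u)
        assert synthesize_mosaic(a, u, 1.0).equals(a)
        assert synthesize_mosaic(a, u, 0.5)["x"] == pytest.approx(0.5)

    def test_mixing_is_on_beta_scale_not_m_scale(self):
        """M of the beta mixture is not the weighted average of M-values:
        the two operations differ because the logit transform is nonlinear."""
        aff, unaff = pd.Series([0.9]), pd.Series([0.2])
        m_of_mix = beta_to_m(synthesize_mosaic(aff, unaff, 0.5))[0]
        mix_of_m = 0.5 * beta_to_m(aff)[0] + 0.5 * beta_to_m(unaff)[0]
        assert m_of_mix == pytest.approx(np.log2(0.55 / 0.45), abs=1e-12)
        assert abs(m_of_mix - mix_of_m) > 0.1

    def test_misaligned_profiles_rejected(self):
        with pytest.raises(E.DomainError):
            synthesize_mosaic(pd.Series([0.5], index=["a"]),
                              pd.Series([0.5], index=["b"]), 0.5)

    def test_degree_domain(self):
        s = pd.Series([0.5])
        with pytest.raises(E.DomainError):
            synthesize_mosaic(s, s, 1.2)


class TestDepthSampling:
    def test_preset_truncation(self):
        n, _ = sample_depth_and_reads(0.5, *E.mosaic.DEPTH_PRESETS["KMT2B"], rng=0,
                                      size=2000)
        assert (n > 47).all()
        n2, _ = sample_depth_and_reads(0.5, *E.mosaic.DEPTH_PRESETS["KMT2D"], rng=0,
                                       size=2000)
        assert (n2 > 14).all()

    def test_constitutive_read_fraction(self):
        n, k = sample_depth_and_reads(1.0, rng=3, size=100000)
        assert (k / n).mean() == pytest.approx(0.5, abs=0.002)

    def test_zero_degree(self):
        _, k = sample_depth_and_reads(0.0, rng=1, size=100)
        assert (k == 0).all()


class TestInsilicoCohort:
    def test_leave_two_out_combinatorics(self):
        assert len(leave_out_combinations(range(7))) == 21
        assert len(leave_out_combinations(range(8))) == 28

    def test_cohort_shape_and_degrees(self, insilico):
        table, models, _ = insilico
        assert len(models) == 21  # C(7, 2)
        assert len(table) == 21 * 60
        assert table["d"].between(0, 1).all()
        assert (table["variant_reads"] <= table["depth"]).all()
        assert table["score"].between(0, 1).all()

    def test_score_rank_increases_with_degree(self, insilico):
        table, _, _ = insilico
        rho = stats.spearmanr(table["d"], table["score"]).statistic
        assert rho > 0.8

    def test_pool_too_small_rejected(self, strong_cohort):
        cfg, bm, sheet, truth = strong_cohort
        g = cohort_groups(truth)
        with pytest.raises(E.DomainError):
            E.generate_insilico_cohort(
                bm.values, truth.signature_site_ids, g["case_initial"], g["control"],
                g["case_initial"][:3], g["control"], leave_out=2,
            )


class TestBand:
    def test_constant_scores_flat_band(self, rng):
        mosaics = pd.DataFrame({"vaf": rng.uniform(0, 0.5, 600), "score": 0.7})
        band = build_band(mosaics, seed=0)
        assert np.allclose(band.table["q_low_smooth"], 0.7, atol=1e-9)
        assert np.allclose(band.table["q_high_smooth"], 0.7, atol=1e-9)

    def test_lower_never_exceeds_upper(self, insilico):
        _, _, band = insilico
        assert (band.table["q_low_smooth"] <= band.table["q_high_smooth"]).all()
        assert band.bin_width == 0.025

    def test_monotone_scores_give_monotone_upper_band(self, rng):
        d = rng.uniform(0, 1, 3000)
        n = rng.integers(100, 300, 3000)
        k = rng.binomial(n, d / 2)
        mosaics = pd.DataFrame({"vaf": k / n, "score": d})
        band = build_band(mosaics, seed=1)
        assert (np.diff(band.table["q_high_smooth"]) > -0.02).all()

    def test_loess_matches_reference_fit(self):
        """Frozen oracle: local-quadratic tricube fit on a 20-point series,
        reference values computed with a span-0.75 degree-2 direct-surface
        loess in an independent implementation."""
        x = np.arange(0.0125, 0.5, 0.025)
        y = np.array([
            0.1939296198, 0.2827358844, 0.5242905831, 0.6792486396, 0.6711160939,
            0.8287792505, 1.0123035307, 1.0872519457, 1.1831661942, 1.2051102268,
            1.3377128304, 1.3606469204, 1.3353201602, 1.3815006195, 1.3254892729,
            1.2213389976, 1.2318368476, 1.1034421088, 1.1244217764, 1.0006762181,
        ])
        expected = np.array([
            0.1778524902, 0.3350544681, 0.4828203983, 0.6212410314, 0.7501898765,
            0.8690914093, 0.9775328376, 1.0768731642, 1.1721340711, 1.2530056574,
            1.3101495360, 1.3443071105, 1.3573669988, 1.3429295779, 1.3185937761,
            1.2812426694, 1.2293922789, 1.1631580319, 1.0830668731, 0.9898171082,
        ])
        np.testing.assert_allclose(_loess_smooth(x, y), expected, atol=1e-8)

    def test_empty_bins_warn(self, rng):
        mosaics = pd.DataFrame({"vaf": rng.uniform(0.2, 0.3, 100),
                                "score": rng.uniform(0, 1, 100)})
        with pytest.warns(UserWarning, match="empty"):
            build_band(mosaics, seed=0)


class TestAdjudication:
    def test_true_mosaics_fall_within_band(self, strong_cohort, insilico):
        """Synthetic genuine mosaics (d ~ 0.5, consistent reads) land inside
        the 5th-95th band for the large majority of draws."""
        cfg, bm, sheet, truth = strong_cohort
        table, models, band = insilico
        g = cohort_groups(truth)
        rng = np.random.default_rng(21)
        beta = bm.values.copy()
        rows = []
        for i in range(20):
            aff = rng.choice(g["case_initial"])
            una = rng.choice(g["control"])
            mixed = synthesize_mosaic(beta[aff], beta[una], 0.5)
            sid = f"true_mosaic_{i}"
            beta[sid] = mixed
            n, k = sample_depth_and_reads(0.5, rng=rng)
            rows.append((sid, int(n[0]), int(k[0])))
        suspects = pd.DataFrame(rows, columns=["sample_id", "depth", "variant_reads"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            verdicts = adjudicate(suspects, beta, truth.signature_site_ids, band, models)
        assert (verdicts["verdict"] == "within").mean() >= 0.8

    def test_erroneous_call_lands_above_band(self, strong_cohort, insilico):
        """A constitutive case whose reported VAF is deflated to ~0.28 (the
        indel-undercall scenario) scores above the 95th percentile band."""
        cfg, bm, sheet, truth = strong_cohort
        _, models, band = insilico
        g = cohort_groups(truth)
        rows = [(c, 171, 48) for c in g["case_initial"][:5]]  # VAF 0.28, true d=1
        suspects = pd.DataFrame(rows, columns=["sample_id", "depth", "variant_reads"])
        verdicts = adjudicate(suspects, bm.values, truth.signature_site_ids, band, models)
        assert (verdicts["verdict"] == "above_95").mean() >= 0.9

    def test_unaffected_profile_never_above_band(self, strong_cohort, insilico):
        cfg, bm, sheet, truth = strong_cohort
        _, models, band = insilico
        g = cohort_groups(truth)
        rows = [(c, 200, 50) for c in g["independent_control"][:8]]  # VAF 0.25
        suspects = pd.DataFrame(rows, columns=["sample_id", "depth", "variant_reads"])
        verdicts = adjudicate(suspects, bm.values, truth.signature_site_ids, band, models)
        assert (verdicts["verdict"] != "above_95").all()

    def test_ci_contains_mean_and_out_of_support_warns(self, strong_cohort, insilico):
        cfg, bm, sheet, truth = strong_cohort
        _, models, band = insilico
        g = cohort_groups(truth)
        suspects = pd.DataFrame(
            [(g["case_initial"][0], 1000, 2)], columns=["sample_id", "depth", "variant_reads"]
        )
        with pytest.warns(UserWarning, match="support"):
            verdicts = adjudicate(suspects, bm.values, truth.signature_site_ids, band, models)
        row = verdicts.iloc[0]
        assert row["ci_low"] <= row["mean_score"] <= row["ci_high"]
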