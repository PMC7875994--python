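"""Tests of metabolite normalization, E/I ratios, and the gated link analysis."""

import math

import numpy as np
import pandas as pd
import pytest

from patchforage import agents, neurochem
from patchforage.neurochem import (
    LinkConfig,
    QCThresholds,
    compute_ei,
    ei_glm,
    normalize_metabolites,
    partial_correlation_region,
    partial_correlation_transmitter,
    qc_filter,
    region_coefficient_contrast,
    run_testing_hierarchy,
)

REGIONS = list(agents.REGIONS)


def _measure(participant=0, region="dACC", **overrides):
    row = {
        "participant": participant,
        "region": region,
        "gaba_abs": 2.0,
        "glu_abs": 4.0,
        "cr_abs": 8.0,
        "crlb_gaba": 10.0,
        "crlb_glu": 5.0,
        "fwhm": 12.0,
        "snr": 20.0,
        "gm_frac": 0.5,
        "wm_frac": 0.3,
    }
    row.update(overrides)
    return row


class TestQC:
    def test_high_crlb_excluded_with_reason(self):
        df = pd.DataFrame([_measure(crlb_gaba=25.0)])
        out, excluded = qc_filter(df)
        assert not out["included"].iloc[0]
        assert "CRLB" in out["reason"].iloc[0]
        assert excluded == [0]

    def test_broad_linewidth_excluded(self):
        out, _ = qc_filter(pd.DataFrame([_measure(fwhm=30.0)]))
        assert out["reason"].iloc[0] == "FWHM"

    def test_clean_measurement_included(self):
        df = pd.DataFrame([_measure(region=r) for r in REGIONS])
        out, excluded = qc_filter(df)
        assert out["included"].all()
        assert excluded == []

    def test_one_bad_region_drops_participant_listwise(self):
        rows = [_measure(participant=0, region=r) for r in REGIONS]
        rows[2]["snr"] = 5.0
        rows += [_measure(participant=1, region=r) for r in REGIONS]
        out, excluded = qc_filter(pd.DataFrame(rows))
        assert excluded == [0]

    def test_missing_quality_column_rejected(self):
        df = pd.DataFrame([_measure()]).drop(columns=["snr"])
        with pytest.raises(ValueError, match="snr"):
            qc_filter(df)


class TestNormalization:
    def test_arithmetic_chain(self):
        gaba, glu = normalize_metabolites(2.0, 4.0, 8.0, 0.5, 0.3)
        assert gaba == pytest.approx((2 / 0.5) / (8 / 0.8))
        assert glu == pytest.approx((4 / 0.5) / (8 / 0.8))

    def test_pure_grey_matter_is_creatine_ratio(self):
        gaba, _ = normalize_metabolites(2.0, 4.0, 8.0, 1.0, 0.0)
        assert gaba == pytest.approx(2.0 / 8.0)

    def test_doubling_creatine_halves_outputs(self):
        g1, u1 = normalize_metabolites(2.0, 4.0, 8.0, 0.5, 0.3)
        g2, u2 = normalize_metabolites(2.0, 4.0, 16.0, 0.5, 0.3)
        assert g2 == pytest.approx(g1 / 2) and u2 == pytest.approx(u1 / 2)

    def test_summed_probabilities_with_voxel_count(self):
        direct = normalize_metabolites(2.0, 4.0, 8.0, 0.5, 0.3)
        summed = normalize_metabolites(2.0, 4.0, 8.0, 50.0, 30.0, n_voxels=100)
        assert direct == pytest.approx(summed)

    def test_zero_gm_rejected(self):
        with pytest.raises(ValueError, match="grey"):
            normalize_metabolites(2.0, 4.0, 8.0, 0.0, 0.3)


class TestEI:
    def test_ratio(self):
        assert compute_ei(0.6, 1.2) == pytest.approx(2.0)
        assert compute_ei(0.7, 0.7) == pytest.approx(1.0)

    def test_invariant_to_common_creatine_scaling(self):
        g1, u1 = normalize_metabolites(2.0, 4.0, 8.0, 0.5, 0.3)
        g2, u2 = normalize_metabolites(2.0, 4.0, 11.0, 0.5, 0.3)
        assert compute_ei(g1, u1) == pytest.approx(compute_ei(g2, u2))

    def test_zero_gaba_rejected(self):
        with pytest.raises(ValueError):
            compute_ei(0.0, 1.0)


def _random_ei(rng, n=29):
    return pd.DataFrame(rng.normal(4.0, 0.5, size=(n, 5)), columns=REGIONS)


class TestEIGlm:
    def test_single_varying_region_equals_simple_regression(self):
        rng = np.random.default_rng(0)
        n = 29
        ei = pd.DataFrame({r: np.full(n, 4.0) for r in REGIONS})
        ei["dACC"] = rng.normal(4.0, 0.5, n)
        # constant columns are degenerate regressors and rejected outright
        with pytest.raises(ValueError, match="zero-variance"):
            ei_glm(pd.Series(rng.normal(size=n)), ei)
        # after dropping the constants the coefficient is the simple slope
        dv = pd.Series(0.5 * (ei["dACC"] - 4.0) / 0.5 + rng.normal(0, 1, n))
        glm = ei_glm(dv, ei[["dACC"]])
        x = (ei["dACC"] - ei["dACC"].mean()) / ei["dACC"].std(ddof=0)
        y = (dv - dv.mean()) / dv.std(ddof=0)
        simple = float(np.polyfit(x, y, 1)[0])
        assert glm.per_region["dACC"]["beta"] == pytest.approx(simple, abs=1e-10)

    def test_too_few_participants_rejected(self):
        rng = np.random.default_rng(1)
        ei = _random_ei(rng, n=6)
        with pytest.raises(ValueError, match="few"):
            ei_glm(pd.Series(rng.normal(size=6)), ei)

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(2)
        reps = 400
        rej = 0
        for _ in range(reps):
            ei = _random_ei(rng)
            dv = pd.Series(rng.normal(size=29))
            rej += ei_glm(dv, ei).per_region["dACC"]["p"] < 0.05
        rate = rej / reps
        se = math.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3.5 * se


class TestPartialCorrelations:
    def test_identical_dv_and_target_give_r_one(self):
        rng = np.random.default_rng(3)
        ei = _random_ei(rng)
        dv = ei["dACC"].copy()
        out = partial_correlation_region(dv, ei, "dACC")
        assert out["r"] == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_nuisance_recovers_zero_order_r(self):
        rng = np.random.default_rng(4)
        n = 10_000
        ei = pd.DataFrame(rng.normal(size=(n, 5)), columns=REGIONS)
        dv = pd.Series(0.5 * ei["dACC"] + rng.normal(size=n))
        from scipy.stats import pearsonr

        zero_order = pearsonr(dv, ei["dACC"]).statistic
        partial = partial_correlation_region(dv, ei, "dACC")["r"]
        assert partial == pytest.approx(zero_order, abs=0.02)

    def test_sign_agrees_with_glm_beta(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            ei = _random_ei(rng)
            dv = pd.Series(rng.normal(size=29))
            glm = ei_glm(dv, ei)
            for region in REGIONS:
                pc = partial_correlation_region(dv, ei, region)
                assert np.sign(pc["r"]) == np.sign(glm.per_region[region]["beta"])

    def test_transmitter_partial_detects_planted_pure_gaba_effect(self):
        rng = np.random.default_rng(6)
        n = 400
        gaba = pd.DataFrame(rng.normal(1.0, 0.1, size=(n, 5)), columns=REGIONS)
        glu = pd.DataFrame(rng.normal(4.0, 0.3, size=(n, 5)), columns=REGIONS)
        dv = pd.Series(-3.0 * gaba["dACC"] + rng.normal(0, 0.2, n))
        r_gaba = partial_correlation_transmitter(dv, gaba, glu, "dACC", "gaba")
        r_glu = partial_correlation_transmitter(dv, gaba, glu, "dACC", "glu")
        assert r_gaba["r"] < -0.5
        assert abs(r_glu["r"]) < 0.15

    def test_transmitter_partial_invariant_to_region_order(self):
        rng = np.random.default_rng(7)
        gaba = pd.DataFrame(rng.normal(1.0, 0.1, size=(29, 5)), columns=REGIONS)
        glu = pd.DataFrame(rng.normal(4.0, 0.3, size=(29, 5)), columns=REGIONS)
        dv = pd.Series(rng.normal(size=29))
        a = partial_correlation_transmitter(dv, gaba, glu, "dACC", "gaba")
        perm = ["rM1", "dACC", "vmPFC", "lM1", "dlPFC"]
        b = partial_correlation_transmitter(dv, gaba[perm], glu[perm], "dACC", "gaba")
        assert a["r"] == pytest.approx(b["r"], abs=1e-10)

    def test_too_few_participants_for_transmitter_partial(self):
        rng = np.random.default_rng(8)
        gaba = pd.DataFrame(rng.normal(1.0, 0.1, size=(10, 5)), columns=REGIONS)
        glu = pd.DataFrame(rng.normal(4.0, 0.3, size=(10, 5)), columns=REGIONS)
        with pytest.raises(ValueError, match="few"):
            partial_correlation_transmitter(
                pd.Series(rng.normal(size=10)), gaba, glu, "dACC", "gaba"
            )


class TestContrast:
    def test_self_contrast_is_zero(self):
        rng = np.random.default_rng(9)
        glm = ei_glm(pd.Series(rng.normal(size=29)), _random_ei(rng))
        t, _ = region_coefficient_contrast(glm, "dACC", "dACC")
        assert t == pytest.approx(0.0, abs=1e-12)

    def test_exchange_flips_sign(self):
        rng = np.random.default_rng(10)
        glm = ei_glm(pd.Series(rng.normal(size=29)), _random_ei(rng))
        t_ab, p_ab = region_coefficient_contrast(glm, "dACC", "vmPFC")
        t_ba, p_ba = region_coefficient_contrast(glm, "vmPFC", "dACC")
        assert t_ab == pytest.approx(-t_ba, abs=1e-10)
        assert p_ab == pytest.approx(p_ba, abs=1e-10)

    def test_matches_reparameterized_refit(self):
        # contrast t equals the t of the sum-coefficient when the design is
        # reparameterized as (a-b, a+b)
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        ei = _random_ei(rng)
        dv = pd.Series(rng.normal(size=29))
        glm = ei_glm(dv, ei)
        t, _ = region_coefficient_contrast(glm, "dACC", "vmPFC")

        def z(v):
            v = np.asarray(v, float)
            return (v - v.mean()) / v.std(ddof=0)

        za, zb = z(ei["dACC"]), z(ei["vmPFC"])
        X = pd.DataFrame({"diff": (za - zb) / 2, "sum": (za + zb) / 2})
        for r in ("dlPFC", "lM1", "rM1"):
            X[r] = z(ei[r])
        fit = sm.OLS(z(dv), sm.add_constant(X)).fit()
        assert t == pytest.approx(float(fit.tvalues["diff"]), abs=1e-8)


def _planted_cohort(rng, r=0.7, n=29):
    """E/I + metabolite tables with a strong dACC <-> dv correlation."""
    spec = agents.CohortSpec(
        n_participants=n, planted_effects=[agents.PlantedEffect("dACC", "dv", r)]
    )
    _, metab, latents = agents.generate_cohort(spec, rng)
    ei, gaba, glu = neurochem.ei_profiles(metab)
    dvs = pd.DataFrame(
        {"mean_pla": latents["dv"].to_numpy(), "nb_share": rng.normal(38.5, 1.0, n)},
        index=ei.index,
    )
    return dvs, ei, gaba, glu


class TestHierarchy:
    def test_no_followups_when_nothing_significant(self):
        rng = np.random.default_rng(12)
        # find a null draw with all regions non-significant
        for _ in range(20):
            ei = _random_ei(rng)
            dv = pd.Series(rng.normal(size=29))
            glm = ei_glm(dv, ei)
            if not glm.significant_regions():
                break
        else:
            pytest.fail("no fully null draw found")
        dvs = pd.DataFrame({"mean_pla": dv})
        report = run_testing_hierarchy(
            dvs, ei, config=LinkConfig(dv_list=("mean_pla",))
        )
        assert report["dvs"]["mean_pla"]["followups"] == {}

    def test_planted_effect_yields_dacc_followups(self):
        rng = np.random.default_rng(13)
        dvs, ei, gaba, glu = _planted_cohort(rng)
        report = run_testing_hierarchy(
            dvs, ei, gaba, glu, LinkConfig(dv_list=("mean_pla",))
        )
        entry = report["dvs"]["mean_pla"]
        assert "dACC" in entry["followups"]
        follow = entry["followups"]["dACC"]
        assert follow["partial_correlation"]["r"] > 0
        assert set(follow["transmitters"]) == {"gaba", "glu"}
        assert "robust" in follow and "contrasts" in follow

    def test_behavioural_gate_blocks_testing(self):
        rng = np.random.default_rng(14)
        dvs, ei, gaba, glu = _planted_cohort(rng)
        cfg = LinkConfig(dv_list=("mean_pla",), behavioural_p={"mean_pla": 0.5})
        report = run_testing_hierarchy(dvs, ei, gaba, glu, cfg)
        assert not report["dvs"]["mean_pla"]["tested"]

    def test_mediating_covariate_removes_effect(self):
        # a covariate that carries the whole planted effect should render
        # the region coefficient non-significant
        rng = np.random.default_rng(15)
        dvs, ei, gaba, glu = _planted_cohort(rng, r=0.6)
        dvs["mediator"] = dvs["mean_pla"] + 0.01 * rng.normal(size=len(dvs))
        cfg = LinkConfig(
            dv_list=("mean_pla",),
            mediation_covariates={"mean_pla": ["mediator"]},
        )
        report = run_testing_hierarchy(dvs, ei, gaba, glu, cfg)
        entry = report["dvs"]["mean_pla"]
        assert "dACC" not in entry["significant_regions"]

    def test_unavailable_dv_reported_with_reason(self):
        rng = np.random.default_rng(16)
        dvs, ei, _, _ = _planted_cohort(rng)
        report = run_testing_hierarchy(
            dvs, ei, config=LinkConfig(dv_list=("alpha",))
        )
        assert not report["dvs"]["alpha"]["tested"]
        assert "not available" in report["dvs"]["alpha"]["reason"]
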