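"""Prevalence-ratio meta-analysis against independent hand calculations."""
import math

import numpy as np
import pytest

from tbsdc.meta import (
    PooledRatio,
    RandomEffectsMeta,
    StudyRecord,
    pool_random_effects,
    study_log_pr,
)


def _dl_by_hand(effects):
    """Independent step-by-step DerSimonian-Laird pooling on the log scale."""
    y = np.array([e[0] for e in effects])
    v = np.array([e[1] for e in effects])
    w = 1 / v
    ybar_fe = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (y - ybar_fe) ** 2)
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (len(y) - 1)) / c)
    ws = 1 / (v + tau2)
    mu = np.sum(ws * y) / np.sum(ws)
    se = math.sqrt(1 / np.sum(ws))
    return mu, tau2, se


class TestStudyLogPr:
    def test_equal_prevalences_give_zero(self):
        lpr, _ = study_log_pr(StudyRecord("a", 20, 100, 0.2))
        assert lpr == pytest.approx(0.0)

    def test_continuity_correction_for_zero_cases(self):
        lpr, var = study_log_pr(StudyRecord("a", 0, 50, 0.1))
        p_hat = 0.5 / 50.5
        assert lpr == pytest.approx(math.log(p_hat / 0.1))
        assert var == pytest.approx((1 - p_hat) / 0.5)

    def test_delta_method_variance(self):
        lpr, var = study_log_pr(StudyRecord("a", 30, 120, 0.05))
        assert lpr == pytest.approx(math.log(5))
        assert var == pytest.approx((1 - 0.25) / 30)

    def test_comparator_binomial_term_when_ref_n_given(self):
        _, v_fixed = study_log_pr(StudyRecord("a", 30, 120, 0.05))
        _, v_full = study_log_pr(StudyRecord("a", 30, 120, 0.05, ref_n=1000))
        assert v_full == pytest.approx(v_fixed + (1 - 0.05) / (0.05 * 1000))

    def test_invalid_records_rejected(self):
        with pytest.raises(ValueError):
            StudyRecord("a", 5, 0, 0.1)
        with pytest.raises(ValueError):
            StudyRecord("a", 11, 10, 0.1)
        with pytest.raises(ValueError):
            StudyRecord("a", 5, 10, 1.5)


class TestPooling:
    def test_single_study_is_identity(self):
        s = StudyRecord("a", 30, 120, 0.05)
        pooled = pool_random_effects([s])
        lpr, var = study_log_pr(s)
        assert pooled.pr == pytest.approx(math.exp(lpr))
        assert pooled.tau2 == 0.0
        assert pooled.k == 1
        z = 1.959963984540054
        assert pooled.ci[0] == pytest.approx(math.exp(lpr - z * math.sqrt(var)))

    def test_two_identical_studies_have_no_heterogeneity(self):
        s = StudyRecord("a", 30, 120, 0.05)
        pooled = pool_random_effects([s, s])
        assert pooled.pr == pytest.approx(5.0, rel=1e-9)
        assert pooled.tau2 == pytest.approx(0.0, abs=1e-12)

    def test_two_study_case_matches_hand_derSimonian_laird(self):
        # log PRs 0 and ln 4 with equal variances 0.04:
        # (cases/n, ref) chosen so var = (1 - p_hat)/cases = 0.04 exactly
        a = StudyRecord("a", 20, 100, 0.20)  # p=0.2, PR=1
        b = StudyRecord("b", 20, 100, 0.05)  # p=0.2, PR=4
        mu, tau2, se = _dl_by_hand([study_log_pr(a), study_log_pr(b)])
        # hand values: Q = 2*25*(ln4/2)^2 = 24.0227, C = 25,
        # tau2 = (Q-1)/25 = 0.920906, equal weights -> mu = ln2
        assert mu == pytest.approx(math.log(2), rel=1e-12)
        assert tau2 == pytest.approx(0.9209060278, rel=1e-8)
        pooled = pool_random_effects([a, b], interval="wald")
        assert pooled.pr == pytest.approx(2.0, rel=1e-9)
        assert pooled.tau2 == pytest.approx(tau2, rel=1e-9)
        z = 1.959963984540054
        assert pooled.ci[0] == pytest.approx(math.exp(mu - z * se), rel=1e-6)
        assert pooled.ci[1] == pytest.approx(math.exp(mu + z * se), rel=1e-6)

    def test_hksj_interval_is_wider_here_and_contains_wald_point(self):
        a = StudyRecord("a", 20, 100, 0.20)
        b = StudyRecord("b", 20, 100, 0.05)
        hksj = pool_random_effects([a, b])
        wald = pool_random_effects([a, b], interval="wald")
        assert hksj.pr == pytest.approx(wald.pr)
        assert hksj.ci[0] <= wald.ci[0] and hksj.ci[1] >= wald.ci[1]

    def test_equal_variances_no_heterogeneity_reduces_to_mean_of_logs(self):
        # three studies with identical (cases, n) but graded refs whose log
        # PRs are nearly homogeneous: force tau2=0 by construction
        s = [StudyRecord(f"s{i}", 20, 100, 0.2) for i in range(3)]
        pooled = pool_random_effects(s)
        logs = [study_log_pr(x)[0] for x in s]
        assert math.log(pooled.pr) == pytest.approx(float(np.mean(logs)))

    def test_pooled_pr_within_study_range(self):
        studies = [
            StudyRecord("a", 25, 200, 0.05),
            StudyRecord("b", 60, 300, 0.08),
            StudyRecord("c", 10, 150, 0.04),
        ]
        pooled = pool_random_effects(studies)
        prs = [math.exp(study_log_pr(s)[0]) for s in studies]
        assert min(prs) <= pooled.pr <= max(prs)

    def test_forced_zero_tau2_equals_fixed_effect(self):
        # homogeneous studies (Q < df) -> DL truncates tau2 to 0 and the
        # pooled value equals the inverse-variance fixed-effect estimate
        studies = [
            StudyRecord("a", 40, 200, 0.1),
            StudyRecord("b", 41, 205, 0.1),
        ]
        pooled = pool_random_effects(studies)
        assert pooled.tau2 == 0.0
        eff = [study_log_pr(s) for s in studies]
        w = np.array([1 / v for _, v in eff])
        mu_fe = np.sum(w * [y for y, _ in eff]) / np.sum(w)
        assert math.log(pooled.pr) == pytest.approx(mu_fe, rel=1e-9)

    def test_agrees_with_statsmodels_on_heterogeneous_studies(self):
        from statsmodels.stats.meta_analysis import combine_effects

        studies = [  # strongly heterogeneous: tau2 > 0 in both routes
            StudyRecord("a", 20, 100, 0.20),
            StudyRecord("b", 20, 100, 0.05),
            StudyRecord("c", 60, 300, 0.04),
        ]
        eff = np.array([study_log_pr(s) for s in studies])
        res = combine_effects(eff[:, 0], eff[:, 1], method_re="dl", use_t=False)
        pooled = pool_random_effects(studies, interval="wald")
        assert pooled.tau2 == pytest.approx(float(res.tau2), rel=1e-9)
        assert math.log(pooled.pr) == pytest.approx(float(res.mean_effect_re), rel=1e-9)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            pool_random_effects([])

    def test_model_object_and_csv_round_trip(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {"study_id": ["a", "b"], "hhc_cases": [20, 20], "hhc_n": [100, 100],
             "ref_prevalence": [0.2, 0.05]}
        )
        df.to_csv(tmp_path / "studies.csv", index=False)
        pooled = RandomEffectsMeta.from_csv(tmp_path / "studies.csv").fit()
        assert isinstance(pooled, PooledRatio)
        assert pooled.pr == pytest.approx(2.0, rel=1e-9)
        assert "PR = 2.00" in pooled.summary()
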