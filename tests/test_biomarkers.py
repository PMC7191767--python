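import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import survgen as sg
from survgen.errors import ConfigurationError

from conftest import make_config


def _arm_true_counts(cohort, attr="nominal_biomarker"):
    counts = {"A": 0, "B": 0}
    for s in cohort.subjects:
        if getattr(s, attr):
            counts[s.arm] += 1
    return counts["A"], counts["B"]


class TestComputeP3:
    def test_flat_profile_returns_prevalence(self):
        assert sg.compute_p3(0.4, 0.4, 0.4, (0.3, 0.3, 0.4)) == pytest.approx(0.4)

    def test_hand_computed_value(self):
        p3 = sg.compute_p3(0.8, 0.6, 0.5, (0.25, 0.25, 0.5))
        assert p3 == pytest.approx(0.3)
        # and the balance identity re-evaluates to the prevalence
        assert 0.25 * 0.8 + 0.25 * 0.6 + 0.5 * p3 == pytest.approx(0.5)

    def test_infeasible_reports_prevalence_interval(self):
        with pytest.raises(ConfigurationError) as excinfo:
            sg.compute_p3(1.0, 1.0, 0.1, (0.4, 0.4, 0.2))
        message = str(excinfo.value)
        assert "0.8" in message and "1" in message  # feasible interval [0.8, 1.0]

    def test_empty_sts_leaf_with_residual_rejected(self):
        with pytest.raises(ConfigurationError):
            sg.compute_p3(0.5, 0.5, 0.9, (0.5, 0.5, 0.0))

    @given(
        p1=st.floats(0, 1),
        p2=st.floats(0, 1),
        f1=st.floats(0.05, 0.45),
        f2=st.floats(0.05, 0.45),
        p3_true=st.floats(0, 1),
    )
    def test_balance_identity_to_machine_precision(self, p1, p2, f1, f2, p3_true):
        """Construct a feasible prevalence, then recover p3 exactly."""
        f3 = 1.0 - f1 - f2
        prevalence = f1 * p1 + f2 * p2 + f3 * p3_true
        p3 = sg.compute_p3(p1, p2, prevalence, (f1, f2, f3))
        assert f1 * p1 + f2 * p2 + f3 * p3 == pytest.approx(prevalence, abs=1e-12)


def _random_feasible_config(rng, n_half=None):
    """A random cohort config whose biomarker settings are always feasible."""
    n_half = n_half or int(rng.integers(10, 120))
    lts = float(rng.uniform(0.2, 0.8))
    sf = float(rng.uniform(0.1, 0.9))
    p1, p2 = rng.uniform(0, 1, 2)
    counts = sg.allocate_subgroup_counts(n_half, lts, (sf, sf))
    f1, f2 = counts[0] / n_half, counts[1] / n_half
    f3 = (counts[2] + counts[3]) / n_half
    lo = f1 * p1 + f2 * p2
    prevalence = float(rng.uniform(lo, lo + f3))
    nominal = sg.NominalBiomarkerConfig(
        p1=float(p1), p2=float(p2), prevalence=prevalence,
        enriched_arm="A" if rng.random() < 0.5 else "B",
    )
    q1, q2 = rng.uniform(0, 1, 2)
    lo_q = f1 * q1 + f2 * q2
    numeric = sg.NumericBiomarkerConfig(
        marking=sg.NominalBiomarkerConfig(
            p1=float(q1), p2=float(q2),
            prevalence=float(rng.uniform(lo_q, lo_q + f3)),
        ),
        mu_biomarker=10.0, sigma_biomarker=1.0,
        mu_non_biomarker=0.0, sigma_non_biomarker=1.0,
    )
    return make_config(
        n_total=2 * n_half, lts_fraction=lts, survivor_fraction=sf,
        nominal=nominal, numeric=numeric, seed=int(rng.integers(0, 2**31)),
    )


class TestArmBalance:
    def test_exact_balance_over_random_configs(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            cohort = sg.build_cohort(_random_feasible_config(rng))
            assert _arm_true_counts(cohort, "nominal_biomarker")[0] == \
                _arm_true_counts(cohort, "nominal_biomarker")[1]
            assert _arm_true_counts(cohort, "numeric_biomarker_marked")[0] == \
                _arm_true_counts(cohort, "numeric_biomarker_marked")[1]

    def test_zero_prevalence_marks_nobody(self):
        nominal = sg.NominalBiomarkerConfig(p1=0.0, p2=0.0, prevalence=0.0)
        cohort = sg.build_cohort(make_config(n_total=100, nominal=nominal))
        assert _arm_true_counts(cohort) == (0, 0)

    def test_total_count_is_rounded_prevalence(self):
        nominal = sg.NominalBiomarkerConfig(p1=0.5, p2=0.5, prevalence=0.47)
        cohort = sg.build_cohort(
            make_config(n_total=200, survivor_fraction=0.5, nominal=nominal)
        )
        a, b = _arm_true_counts(cohort)
        assert a == b == round(100 * 0.47)


class TestEnrichment:
    def _leaf_rates(self, cohort, arm):
        leaves = {"lts_surv": [], "lts_non": [], "sts": []}
        for s in cohort.subjects:
            if s.arm != arm:
                continue
            key = ("lts_surv" if s.survivor else "lts_non") if s.group == "LTS" else "sts"
            leaves[key].append(s.nominal_biomarker)
        return {k: (np.mean(v) if v else np.nan, len(v)) for k, v in leaves.items()}

    def test_leaf_quotas_match_independent_apportionment(self):
        """Realized leaf counts equal an independently coded largest-remainder split."""
        nominal = sg.NominalBiomarkerConfig(p1=0.9, p2=0.7, prevalence=0.5)
        cfg = make_config(n_total=2000, lts_fraction=0.4,
                          survivor_fraction=0.5, nominal=nominal, seed=13)
        cohort = sg.build_cohort(cfg)
        rates = self._leaf_rates(cohort, "A")
        n1, n2 = rates["lts_surv"][1], rates["lts_non"][1]
        n3 = rates["sts"][1]
        n_arm = 1000
        p3 = sg.compute_p3(0.9, 0.7, 0.5, (n1 / n_arm, n2 / n_arm, n3 / n_arm))
        expected = [n1 * 0.9, n2 * 0.7, n3 * p3]
        # independent largest-remainder oracle
        total = round(n_arm * 0.5)
        base = [int(np.floor(e)) for e in expected]
        rem = sorted(range(3), key=lambda i: expected[i] - base[i], reverse=True)
        for i in rem[: total - sum(base)]:
            base[i] += 1
        realized = [
            int(round(rates[k][0] * rates[k][1]))
            for k in ("lts_surv", "lts_non", "sts")
        ]
        assert realized == base

    def test_enrichment_ordering_of_leaf_rates(self):
        """With p1 > p2 > p3 the realized leaf true-rates keep that order."""
        nominal = sg.NominalBiomarkerConfig(p1=0.9, p2=0.6, prevalence=0.4)
        cfg = make_config(n_total=4000, lts_fraction=0.4,
                          survivor_fraction=0.5, nominal=nominal, seed=5)
        rates = self._leaf_rates(sg.build_cohort(cfg), "A")
        assert rates["lts_surv"][0] >= rates["lts_non"][0] >= rates["sts"][0]

    def test_infeasible_prevalence_rejected_at_build(self):
        # saturated LTS leaves cannot be balanced down to a 0.1 prevalence
        nominal = sg.NominalBiomarkerConfig(p1=1.0, p2=1.0, prevalence=0.1)
        with pytest.raises(ConfigurationError):
            sg.build_cohort(
                make_config(n_total=40, lts_fraction=0.5,
                            survivor_fraction=0.5, nominal=nominal)
            )


class TestNumericBiomarker:
    def test_marked_values_follow_their_normal(self):
        numeric = sg.NumericBiomarkerConfig(
            marking=sg.NominalBiomarkerConfig(p1=0.5, p2=0.5, prevalence=0.5),
            mu_biomarker=10.0, sigma_biomarker=1.0,
            mu_non_biomarker=0.0, sigma_non_biomarker=1.0,
        )
        cfg = make_config(n_total=10_000, survivor_fraction=0.5,
                          numeric=numeric, seed=2)
        cohort = sg.build_cohort(cfg)
        marked = [s.numeric_biomarker for s in cohort.subjects
                  if s.numeric_biomarker_marked]
        unmarked = [s.numeric_biomarker for s in cohort.subjects
                    if not s.numeric_biomarker_marked]
        assert np.mean(marked) == pytest.approx(10.0, abs=0.05)
        assert np.mean(unmarked) == pytest.approx(0.0, abs=0.05)

    def test_degenerate_overlap_gives_identical_distributions(self):
        """Equal means and sds: zero planted intensity across subgroups."""
        numeric = sg.NumericBiomarkerConfig(
            marking=sg.NominalBiomarkerConfig(p1=0.9, p2=0.7, prevalence=0.5),
            mu_biomarker=5.0, sigma_biomarker=2.0,
            mu_non_biomarker=5.0, sigma_non_biomarker=2.0,
        )
        cfg = make_config(n_total=8000, lts_fraction=0.5,
                          survivor_fraction=0.5, numeric=numeric, seed=6)
        cohort = sg.build_cohort(cfg)
        lts = [s.numeric_biomarker for s in cohort.subjects if s.group == "LTS"]
        sts = [s.numeric_biomarker for s in cohort.subjects if s.group == "STS"]
        assert np.mean(lts) == pytest.approx(np.mean(sts), abs=0.15)

    def test_intensity_monotone_in_mean_separation(self):
        """KM separation of marked vs unmarked grows with |mu_bm - mu_non|."""
        areas = []
        for mu in (0.0, 3.0, 8.0):
            numeric = sg.NumericBiomarkerConfig(
                marking=sg.NominalBiomarkerConfig(p1=0.95, p2=0.85, prevalence=0.5),
                mu_biomarker=mu, sigma_biomarker=1.0,
                mu_non_biomarker=0.0, sigma_non_biomarker=1.0,
            )
            cfg = make_config(n_total=2000, lts_fraction=0.5,
                              survivor_fraction=0.5, numeric=numeric, seed=30)
            cohort = sg.build_cohort(cfg)
            values = np.array([s.numeric_biomarker for s in cohort.subjects])
            times = np.array([s.time for s in cohort.subjects])
            events = np.array([s.event for s in cohort.subjects])
            result = sg.find_best_cutoff(values, times, events, min_group_size=100)
            areas.append(result.area)
        assert areas[0] <= areas[1] <= areas[2]
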