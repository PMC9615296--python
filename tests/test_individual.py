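"""Patient-level probability profiles, the repeated-measures ANOVA, and
exact binomial prevalence/power computations."""

import math

import numpy as np
import pytest

from remicoh import (
    IncompleteDesignError,
    ValidationError,
    arcsine_transform,
    binomial_power,
    most_likely_networks,
    network_probabilities,
    prevalence_binomial,
    rm_anova,
)
from remicoh.types import ROI


def roi(original, altered=0, patient="p1", direction="increase"):
    return ROI(patient_id=patient, altered_network=altered,
               direction=direction, voxel_ids=(0,), peak_p=0.01,
               original_network=original)


class TestNetworkProbabilities:
    def test_counting_and_normalization(self):
        rois = [roi(3), roi(3), roi(4)]
        prof = network_probabilities(rois, "original", "increase", K=10,
                                     patient_id="p1")
        assert prof.probs[3] == pytest.approx(2 / 3)
        assert prof.probs[4] == pytest.approx(1 / 3)
        assert prof.probs.sum() == pytest.approx(1.0)
        assert not prof.missing

    def test_zero_roi_patient_flagged(self):
        prof = network_probabilities([], "original", "increase", K=5,
                                     patient_id="p1")
        assert prof.missing and prof.probs.sum() == 0

    def test_altered_basis_counts_altered_networks(self):
        rois = [roi(3, altered=1), roi(4, altered=1)]
        prof = network_probabilities(rois, "altered", "increase", K=5,
                                     patient_id="p1")
        assert prof.probs[1] == 1.0

    def test_direction_filtering(self):
        rois = [roi(2, direction="decrease")]
        prof = network_probabilities(rois, "original", "increase", K=5,
                                     patient_id="p1")
        assert prof.missing

    def test_most_likely_with_ties(self):
        rois = [roi(1), roi(2)]
        prof = network_probabilities(rois, "original", "increase", K=5,
                                     patient_id="p1")
        assert most_likely_networks(prof) == {1, 2}


class TestArcsineTransform:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.0, 0.0), (1.0, np.pi / 2), (0.5, np.pi / 4)],
    )
    def test_closed_forms(self, p, expected):
        assert arcsine_transform(p) == pytest.approx(expected)

    def test_domain_checked(self):
        with pytest.raises(ValidationError):
            arcsine_transform(1.2)


def anova_ss_oracle(y):
    """Brute-force cell-means two-factor within-subject decomposition,
    written with explicit loops (independent of the vectorized path)."""
    n, a, b = y.shape
    grand = y.mean()
    ss = {"A": 0.0, "B": 0.0, "AB": 0.0, "SA": 0.0, "SB": 0.0, "SAB": 0.0}
    for i in range(a):
        ss["A"] += n * b * (y[:, i, :].mean() - grand) ** 2
    for j in range(b):
        ss["B"] += n * a * (y[:, :, j].mean() - grand) ** 2
    for i in range(a):
        for j in range(b):
            ss["AB"] += n * (
                y[:, i, j].mean() - y[:, i, :].mean() - y[:, :, j].mean()
                + grand
            ) ** 2
    for s in range(n):
        for i in range(a):
            ss["SA"] += b * (
                y[s, i, :].mean() - y[s].mean() - y[:, i, :].mean() + grand
            ) ** 2
        for j in range(b):
            ss["SB"] += a * (
                y[s, :, j].mean() - y[s].mean() - y[:, :, j].mean() + grand
            ) ** 2
        for i in range(a):
            for j in range(b):
                ss["SAB"] += (
                    y[s, i, j]
                    - y[s, i, :].mean()
                    - y[s, :, j].mean()
                    - y[:, i, j].mean()
                    + y[s].mean()
                    + y[:, i, :].mean()
                    + y[:, :, j].mean()
                    - grand
                ) ** 2
    f_a = (ss["A"] / (a - 1)) / (ss["SA"] / ((n - 1) * (a - 1)))
    f_b = (ss["B"] / (b - 1)) / (ss["SB"] / ((n - 1) * (b - 1)))
    f_ab = (ss["AB"] / ((a - 1) * (b - 1))) / (
        ss["SAB"] / ((n - 1) * (a - 1) * (b - 1))
    )
    return f_a, f_b, f_ab


class TestRmAnova:
    def test_study_sized_degrees_of_freedom(self, rng):
        res = rm_anova(rng.standard_normal((18, 2, 10)))
        assert res.df_network == (9, 153)
        assert res.df_coherence == (1, 17)
        assert res.df_interaction == (9, 153)

    def test_matches_ss_oracle_on_random_designs(self, rng):
        for _ in range(10):
            y = rng.standard_normal((4, 2, 3)) + rng.standard_normal(
                (4, 1, 1)
            )
            res = rm_anova(y)
            f_a, f_b, f_ab = anova_ss_oracle(y)
            assert res.f_coherence == pytest.approx(f_a, rel=1e-8)
            assert res.f_network == pytest.approx(f_b, rel=1e-8)
            assert res.f_interaction == pytest.approx(f_ab, rel=1e-8)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        y = rng.standard_normal((6, 2, 4))
        res = rm_anova(y)
        rows = [
            {"subj": s, "coh": i, "net": j, "y": y[s, i, j]}
            for s in range(6) for i in range(2) for j in range(4)
        ]
        aov = pg.rm_anova(data=pd.DataFrame(rows), dv="y",
                          within=["coh", "net"], subject="subj",
                          detailed=True).set_index("Source")
        assert res.f_coherence == pytest.approx(aov.loc["coh", "F"],
                                                rel=1e-6)
        assert res.f_network == pytest.approx(aov.loc["net", "F"],
                                              rel=1e-6)
        assert res.f_interaction == pytest.approx(
            aov.loc["coh * net", "F"], rel=1e-6
        )

    def test_constant_data_flagged_undefined(self):
        res = rm_anova(np.full((4, 2, 3), 1.5))
        assert res.undefined and np.isnan(res.f_network)

    def test_incomplete_design_rejected(self, rng):
        y = rng.standard_normal((4, 2, 3))
        y[1, 0, 2] = np.nan
        with pytest.raises(IncompleteDesignError):
            rm_anova(y)


def binom_upper_tail_oracle(k, n, p):
    return sum(
        math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)
    )


class TestPrevalenceBinomial:
    def test_zero_successes_certain(self):
        assert prevalence_binomial(0, 18, 0.1056) == 1.0

    def test_all_successes_closed_form(self):
        assert prevalence_binomial(18, 18, 0.1) == pytest.approx(
            1e-18, rel=1e-9
        )

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(40):
            n = int(rng.integers(1, 26))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.01, 0.99))
            assert prevalence_binomial(k, n, p0) == pytest.approx(
                binom_upper_tail_oracle(k, n, p0), abs=1e-12
            )

    def test_monotone_decreasing_in_k(self):
        ps = [prevalence_binomial(k, 18, 0.1056) for k in range(19)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestBinomialPower:
    def test_size_bound_when_no_effect(self):
        power, k_star = binomial_power(18, 0.1, 0.05, 0.1)
        assert power <= 0.05 and k_star is not None

    def test_near_certain_alternative(self):
        power, _ = binomial_power(18, 0.1, 0.05, 0.999999)
        assert power > 1 - 1e-3

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 26))
            p0 = float(rng.uniform(0.05, 0.5))
            p1 = float(rng.uniform(0.5, 0.95))
            alpha = float(rng.uniform(0.01, 0.2))
            power, k_star = binomial_power(n, p0, alpha, p1)
            # oracle: scan k for the smallest valid critical value
            k_oracle = next(
                (k for k in range(n + 2)
                 if binom_upper_tail_oracle(k, n, p0) <= alpha),
            )
            if k_oracle > n:
                assert power == 0.0 and k_star is None
            else:
                assert k_star == k_oracle
                assert power == pytest.approx(
                    binom_upper_tail_oracle(k_oracle, n, p1), abs=1e-12
                )

    def test_domain_checks(self):
        with pytest.raises(ValidationError):
            binomial_power(10, 0.0, 0.05, 0.5)
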