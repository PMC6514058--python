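"""Variance-based and local sensitivity estimators on analytic toys."""

import numpy as np
import pytest

from nfkbdyn.exceptions import AnalysisError, ConfigurationError
from nfkbdyn.parameters import ParameterSet
from nfkbdyn.sensitivity import (LocalPerturbationResult, SensitivityDesign,
                                 local_sensitivity, total_effect_indices)


def run_design(evaluate, groups=("g1", "g2", "g3"), n=2048, seed=11,
               n_bootstrap=100):
    design = SensitivityDesign(groups=groups, n_samples=n, seed=seed)
    return total_effect_indices(design, evaluate, n_bootstrap=n_bootstrap)


class TestTotalEffect:
    def test_additive_equal_variance_model_splits_evenly(self):
        """Y = g1 + g2: the analytic variance decomposition gives
        ST1 = ST2 = 0.5; an unused third factor is inert."""
        res = run_design(lambda f: f[0] + f[1])
        assert res.st[0] == pytest.approx(0.5, abs=0.08)
        assert res.st[1] == pytest.approx(0.5, abs=0.08)
        assert res.st_lower[0] <= 0.5 <= res.st_upper[0]
        assert res.st_lower[1] <= 0.5 <= res.st_upper[1]
        assert abs(res.st[2]) < 0.05          # inert group
        assert res.top_group() in ("g1", "g2")

    def test_weighted_additive_model_ranks_factors(self):
        res = run_design(lambda f: 3.0 * f[0] + 1.0 * f[1])
        assert res.top_group() == "g1"
        # analytic: ST1 = 9/10, ST2 = 1/10
        assert res.st[0] == pytest.approx(0.9, abs=0.08)
        assert res.st[1] == pytest.approx(0.1, abs=0.05)

    def test_total_effect_dominates_first_order_with_interactions(self):
        res = run_design(lambda f: f[0] * f[1] + 0.5 * f[0])
        assert np.all(res.st[:2] + 0.05 >= res.s1[:2])

    def test_bootstrap_interval_contains_point_estimate(self):
        res = run_design(lambda f: f[0] + 2 * f[2])
        assert np.all(res.st_lower <= res.st)
        assert np.all(res.st <= res.st_upper)

    def test_reproducible_from_seed(self):
        a = run_design(lambda f: f[0] * f[1], n=64)
        b = run_design(lambda f: f[0] * f[1], n=64)
        assert np.array_equal(a.st, b.st)
        assert np.array_equal(a.st_lower, b.st_lower)

    def test_quadrupling_samples_shrinks_bootstrap_interval(self):
        small = run_design(lambda f: f[0] + f[1], n=128, n_bootstrap=200)
        large = run_design(lambda f: f[0] + f[1], n=512, n_bootstrap=200)
        width = lambda r: float(np.mean(r.st_upper - r.st_lower))  # noqa: E731
        assert width(large) < 0.75 * width(small)

    def test_failed_draws_discarded_and_capped(self):
        calls = {"n": 0}

        def flaky(f):
            calls["n"] += 1
            if calls["n"] % 200 == 0:
                raise RuntimeError("draw failed")
            return f[0]

        res = run_design(flaky, n=256)
        assert res.n_discarded > 0

        def broken(f):
            raise RuntimeError("always fails")

        with pytest.raises(AnalysisError, match="> 5%"):
            run_design(broken, n=64)

    def test_unknown_group_rejected_against_partition(self, ref_params):
        design = SensitivityDesign(groups=("not-a-group",), n_samples=8,
                                   seed=0)
        with pytest.raises(ConfigurationError, match="absent"):
            total_effect_indices(design, lambda f: 0.0,
                                 parameters=ref_params)

    def test_design_validation(self):
        with pytest.raises(ConfigurationError):
            SensitivityDesign(groups=("a",), range_fraction=1.5)
        with pytest.raises(ConfigurationError):
            SensitivityDesign(groups=("a",), n_samples=4)
        with pytest.raises(ConfigurationError):
            SensitivityDesign(groups=("a", "a"))


class TestLocalSensitivity:
    def test_linear_system_recovers_delta_exactly(self):
        """Readout proportional to a rate constant: a +10% perturbation
        scores exactly 0.10."""
        base = ParameterSet({"k": 2.0, "other": 1.0},
                            {"k": "Gr-I", "other": "Gr-II"})
        res = local_sensitivity(["k", "other"], base,
                                objective=lambda ps: 7.5 * ps["k"])
        assert res.scores["k"] == pytest.approx(0.10, abs=1e-9)
        assert res.scores["other"] == pytest.approx(0.0, abs=1e-12)

    def test_unknown_parameter_rejected(self):
        base = ParameterSet({"k": 1.0}, {"k": "Gr-I"})
        with pytest.raises(ConfigurationError, match="unknown"):
            local_sensitivity(["missing"], base, objective=lambda ps: 1.0)

    def test_zero_reference_cannot_normalise(self):
        base = ParameterSet({"k": 1.0}, {"k": "Gr-I"})
        with pytest.raises(AnalysisError):
            local_sensitivity(["k"], base, objective=lambda ps: 0.0)

    def test_result_frame_lists_all_parameters(self):
        base = ParameterSet({"a": 1.0, "b": 2.0},
                            {"a": "Gr-I", "b": "Gr-II"})
        res = local_sensitivity(["a", "b"], base,
                                objective=lambda ps: ps["a"] + ps["b"])
        assert isinstance(res, LocalPerturbationResult)
        assert list(res.to_frame()["parameter"]) == ["a", "b"]
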