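"""SSR objective, transcription, kdQ pre-fitting, multi-start estimation."""

import numpy as np
import pytest

from cfkinetics import (
    BDHParams,
    FitProblem,
    SolutionPool,
    fdh_model,
    fit_kdq,
    haldane_keq,
    haldane_residual,
    multistart_fit,
    ssr,
    summarize_pool,
    transcribe,
)
from cfkinetics.fit import FitSolution, problem_ssr
from cfkinetics.synthetic import gen_decomp_standards
from conftest import BDH_THERMO


class TestSSR:
    def test_perfect_prediction(self):
        assert ssr([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_arithmetic(self):
        assert ssr([0.0, 0.0], [1.0, 2.0]) == 5.0

    def test_quadratic_homogeneity(self):
        base = ssr([0.0, 0.0], [1.0, 2.0])
        assert ssr([0.0, 0.0], [2.0, 4.0]) == 4 * base

    def test_weights(self):
        assert ssr([0.0, 0.0], [1.0, 2.0], weights=[2.0, 0.5]) == 2 + 2

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            ssr([1.0], [1.0, 2.0])


class TestTranscription:
    def test_variable_and_constraint_counts(self, noiseless_fdh_series, fdh_truth):
        one = noiseless_fdh_series.datasets[0]
        from cfkinetics.preprocess import DatasetSeries

        problem = FitProblem(
            series=DatasetSeries([one], model_tag="fdh"),
            model=fdh_model(),
            n_starts=1,
        )
        nlp = transcribe(problem)
        n = len(one.trace)  # grid starts at t=0, matching the measurements
        m = len(fdh_model().species_ids)
        assert nlp.n_state_variables == n * m
        assert nlp.n_dynamics_constraints == (n - 1) * m
        assert nlp.n_parameters == len(problem.free_names())

    def test_objective_equivalence_with_dynamics_satisfied(
        self, noiseless_fdh_series, fdh_truth
    ):
        # the single-shooting states satisfy the implicit-Euler constraints,
        # and there the program objective equals the plain simulation SSR
        model = fdh_model()
        problem = FitProblem(series=noiseless_fdh_series, model=model, n_starts=1)
        nlp = transcribe(problem)
        params = {**model.params, **fdh_truth, "kcat": 0.25, "KMA": 0.05}
        states = nlp.eliminate_states(params)
        defects = nlp.constraint_residuals(params, states)
        assert np.abs(defects).max() < 1e-8
        assert nlp.objective(params, states) == pytest.approx(
            problem_ssr(problem, params), rel=1e-12, abs=1e-12
        )

    def test_truth_on_noiseless_data_has_zero_objective(
        self, noiseless_fdh_series, fdh_truth
    ):
        model = fdh_model()
        problem = FitProblem(series=noiseless_fdh_series, model=model, n_starts=1)
        nlp = transcribe(problem)
        params = {**model.params, **fdh_truth}
        states = nlp.eliminate_states(params)
        assert nlp.objective(params, states) < 1e-12

    def test_infeasible_fixed_range_rejected(self, noiseless_fdh_series):
        with pytest.raises(ValueError, match="empty"):
            FitProblem(
                series=noiseless_fdh_series,
                model=fdh_model(),
                fixed_ranges={"kdq": (0.5, 0.1)},
                n_starts=1,
            )


class TestFitKdq:
    def test_noiseless_recovery(self):
        kdq_true = 2e-4
        standards = gen_decomp_standards(kdq_true, [0.5, 1.0], noise_sd=0.0)
        lo, hi = fit_kdq(standards)
        assert lo == pytest.approx(kdq_true, rel=1e-6)
        assert hi == pytest.approx(kdq_true, rel=1e-6)

    def test_range_spans_distinct_standards(self):
        s1 = gen_decomp_standards(1.5e-4, [0.5], noise_sd=0.0)
        s2 = gen_decomp_standards(3.5e-4, [0.5], noise_sd=0.0)
        from cfkinetics.preprocess import DatasetSeries

        both = DatasetSeries(s1.datasets + s2.datasets, model_tag="decomp")
        lo, hi = fit_kdq(both)
        assert lo == pytest.approx(1.5e-4, rel=1e-6)
        assert hi == pytest.approx(3.5e-4, rel=1e-6)

    def test_nonpositive_values_use_nonlinear_fallback(self):
        standards = gen_decomp_standards(1e-3, [0.2], sampling=(600.0, 10.0),
                                         noise_sd=0.0)
        ds = standards.datasets[0]
        values = ds.trace.values.copy()
        values[-1] = 0.0  # a zero reading breaks the log-linear route
        from dataclasses import replace

        ds.trace = replace(ds.trace, values=values)
        lo, hi = fit_kdq(standards)
        # the zero reading is a gross outlier, so only rough agreement holds
        assert lo == pytest.approx(1e-3, rel=0.15)


class TestMultistart:
    def test_noiseless_fdh_recovery(self, fdh_recovery_pool, fdh_truth):
        best = fdh_recovery_pool.best
        assert best.ssr <= 1e-6
        assert best.params["kcat"] == pytest.approx(fdh_truth["kcat"], rel=0.05)
        assert best.params["KMA"] == pytest.approx(fdh_truth["KMA"], rel=0.05)

    def test_seeded_starts_are_reproducible_prefixes(self, noiseless_fdh_series):
        # start i always uses seed base+i, so a 1-start run reproduces the
        # first solution of a 2-start run and the best SSR is non-increasing
        from cfkinetics.preprocess import DatasetSeries

        one = DatasetSeries([noiseless_fdh_series.datasets[0]], model_tag="fdh")
        kw = dict(series=one, model=fdh_model(), seed=19)
        pool1 = multistart_fit(FitProblem(n_starts=1, **kw))
        pool2 = multistart_fit(FitProblem(n_starts=2, **kw))
        assert pool2.solutions[0].ssr == pool1.solutions[0].ssr
        assert pool2.best.ssr <= pool1.best.ssr

    def test_zero_starts_rejected(self, noiseless_fdh_series):
        with pytest.raises(ValueError, match="n_starts"):
            FitProblem(series=noiseless_fdh_series, model=fdh_model(), n_starts=0)

    def test_all_parameters_fixed_reproduces_simulation_ssr(
        self, noiseless_fdh_series, fdh_truth
    ):
        model = fdh_model()
        fixed = {**fdh_truth, "kcat": 0.2}  # deliberately off-truth
        problem = FitProblem(
            series=noiseless_fdh_series, model=model, fixed=fixed, n_starts=1,
        )
        assert problem.free_names() == []
        pool = multistart_fit(problem)
        direct = problem_ssr(problem, {**model.params, **fixed})
        assert pool.best.ssr == pytest.approx(direct, rel=1e-10)

    def test_haldane_constrained_solutions_satisfy_equality(self, bdh_haldane_pool):
        keq = haldane_keq(BDH_THERMO)
        for sol in bdh_haldane_pool.alternatives:
            p = BDHParams(
                kcatf=sol.params["kcatf"], kcatr=sol.params["kcatr"],
                KMS=sol.params["KMS"], KMQ=sol.params["KMQ"],
                KMP=sol.params["KMP"], KMA=sol.params["KMA"],
            )
            assert abs(haldane_residual(p, keq)) / keq <= 1e-6


class TestSolutionPool:
    def _pool(self, ssrs):
        return SolutionPool(solutions=[
            FitSolution(params={"k": float(i + 1)}, ssr=s, converged=True,
                        per_dataset_ssr=[s], start_index=i, seed=i)
            for i, s in enumerate(ssrs)
        ])

    def test_alternatives_within_ten_percent(self):
        pool = self._pool([1.0, 1.05, 1.2, 0.99])
        assert pool.best.ssr == 0.99
        alt = {s.ssr for s in pool.alternatives}
        assert alt == {0.99, 1.0, 1.05}

    def test_single_solution_summary(self):
        pool = self._pool([1.0])
        out = summarize_pool(pool)
        assert out["k"]["std"] == 0.0
        assert out["k"]["cov"] == 0.0

    def test_hand_made_summary(self):
        pool = self._pool([1.0, 1.0, 1.0])  # all within 10%, k = 1, 2, 3
        out = summarize_pool(pool)
        assert out["k"]["mean"] == pytest.approx(2.0)
        assert out["k"]["std"] == pytest.approx(1.0)
        assert out["k"]["cov"] == pytest.approx(0.5)

    def test_empty_pool_has_no_best(self):
        pool = SolutionPool(solutions=[
            FitSolution(params={}, ssr=float("inf"), converged=False,
                        per_dataset_ssr=[], start_index=0, seed=0)
        ])
        with pytest.raises(RuntimeError, match="no converged"):
            pool.best
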