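"""Flux estimation: free-flux basis, objective, recovery, uncertainty."""

import numpy as np
import pytest
from scipy import stats

from osmoflux.emu import emu_decompose, EMU
from osmoflux.fitting import (
    FitSettings,
    FluxEstimationProblem,
    InfeasibleConstraintsError,
    RateMeasurement,
    TracerExperiment,
    fit_fluxes,
    free_flux_basis,
    monte_carlo_ci,
    normalize_to_uptake,
    objective,
)
from osmoflux.labeling import (
    FluxVector,
    Fragment,
    MassIsotopomerDistribution,
    TracerMixture,
    simulate_mids,
)
from osmoflux.model import load_network
from osmoflux.synth import default_scenario
from conftest import write_model
from oracles import sympy_rank_and_nullity

TRACER = TracerMixture([("10", 1.0)])


def split_fragments(net):
    return [
        Fragment("B1", (EMU("B", frozenset({1})),)),
        Fragment("B2", (EMU("B", frozenset({2})),)),
        Fragment("B12", (EMU("B", frozenset({1, 2})),)),
    ]


def split_truth(net, r1=70.0):
    return FluxVector(
        net={"upt": 100.0, "r1": r1, "r2": 100.0 - r1, "out": 100.0}
    )


def make_split_problem(
    net, r1=70.0, mid_sd=0.01, rate_sd=2.0, rng=None, settings=None, tracer=TRACER
):
    """Skeleton-space estimation problem on the two-route toy; optionally
    perturbed by renormalized Gaussian noise."""
    fragments = split_fragments(net)
    emu_net = emu_decompose(net, sorted({e for f in fragments for e in f.emus}))
    mids = simulate_mids(net, emu_net, split_truth(net, r1), tracer, fragments)
    measurements = []
    for frag, mid in zip(fragments, mids):
        m = mid.m.copy()
        if rng is not None:
            m = np.clip(m + rng.normal(0, mid_sd, len(m)), 0, None)
            m /= m.sum()
        measurements.append(
            (frag, MassIsotopomerDistribution(frag.id, m, np.full(len(m), mid_sd)))
        )
    rate_value = 100.0 if rng is None else 100.0 + rng.normal(0, rate_sd)
    rates = [RateMeasurement("out", rate_value, rate_sd)]
    return FluxEstimationProblem(
        network=net,
        experiments=[TracerExperiment(tracer, measurements)],
        rates=rates,
        fixed={"upt": 100.0},
        settings=settings or FitSettings(restarts=3, seed=0, sigma_floor=1e-6),
    )


class TestFreeFluxBasis:
    def test_linear_chain_fully_determined(self, tmp_path):
        net = load_network(
            write_model(
                tmp_path,
                "upt,S (a) = A (a),0,measured-exchange,\n"
                "r,A (a) = B (a),0,free,\n"
                "out,B (a) = B_ex (a),0,measured-exchange,\n",
            ),
            substrate_id="S",
        )
        basis = free_flux_basis(net, {"upt": 100.0})
        assert basis.dimension == 0
        v = basis.flux_dict(np.zeros(0))
        assert v == {"upt": 100.0, "r": 100.0, "out": 100.0}

    def test_branch_point_one_free_flux(self, toy_split_network):
        basis = free_flux_basis(toy_split_network, {"upt": 100.0})
        assert basis.dimension == 1
        v = basis.flux_dict(np.array([30.0]))
        assert v["r1"] + v["r2"] == pytest.approx(100.0)
        assert v["out"] == pytest.approx(100.0)

    def test_shipped_model_dimension_matches_elimination_oracle(self, network):
        from osmoflux.model import stoichiometric_matrix

        scn = default_scenario(0.0, seed=0)
        fixed = scn.fixed
        S = stoichiometric_matrix(network)
        extra = np.zeros((len(fixed), S.shape[1]))
        cols = {r: j for j, r in enumerate(network.reaction_ids)}
        for i, rid in enumerate(sorted(fixed)):
            extra[i, cols[rid]] = 1.0
        M = np.vstack([S, extra])
        _, nullity = sympy_rank_and_nullity(M)
        basis = free_flux_basis(network, fixed)
        assert basis.dimension == nullity
        # every mapped vector satisfies the constraints
        rng = np.random.default_rng(0)
        u = rng.uniform(0, 50, basis.dimension)
        v = basis.map(u)
        assert np.max(np.abs(S @ v)) < 1e-8
        for rid, val in fixed.items():
            assert v[cols[rid]] == pytest.approx(val, abs=1e-8)

    def test_infeasible_fixed_rates_reported(self, tmp_path):
        net = load_network(
            write_model(
                tmp_path,
                "upt,S (a) = A (a),0,measured-exchange,\n"
                "r,A (a) = B (a),0,free,\n"
                "out,B (a) = B_ex (a),0,measured-exchange,\n",
            ),
            substrate_id="S",
        )
        with pytest.raises(InfeasibleConstraintsError):
            free_flux_basis(net, {"upt": 100.0, "out": 50.0})


class TestObjective:
    def test_zero_at_exact_measurements(self, toy_split_network):
        problem = make_split_problem(toy_split_network)
        params = np.array([self_free_value(problem, 70.0)])
        assert objective(problem, params) == pytest.approx(0.0, abs=1e-16)

    def test_single_two_sigma_residual_gives_four(self, toy_split_network):
        problem = make_split_problem(toy_split_network)
        problem.rates[0] = RateMeasurement("out", 104.0, 2.0)  # 2 sigma off
        params = np.array([self_free_value(problem, 70.0)])
        assert objective(problem, params) == pytest.approx(4.0, abs=1e-12)

    def test_random_perturbation_matches_hand_sum(self, toy_split_network):
        rng = np.random.default_rng(3)
        problem = make_split_problem(toy_split_network, rng=rng)
        params = np.array([self_free_value(problem, 70.0)])
        residuals = problem.measurement_residuals(params)
        assert objective(problem, params) == pytest.approx(float(residuals @ residuals))
        # hand summation over fragments and the rate
        fragments = split_fragments(toy_split_network)
        emu_net = emu_decompose(
            toy_split_network, sorted({e for f in fragments for e in f.emus})
        )
        sims = simulate_mids(
            toy_split_network, emu_net, split_truth(toy_split_network), TRACER, fragments
        )
        total = 0.0
        for (frag, meas), sim in zip(problem.experiments[0].measurements, sims):
            sd = np.maximum(meas.sd, problem.settings.sigma_floor)
            total += float(np.sum(((sim.m - meas.m) / sd) ** 2))
        rate = problem.rates[0]
        total += ((100.0 - rate.value) / rate.sd) ** 2
        assert objective(problem, params) == pytest.approx(total)


def self_free_value(problem, r1):
    """Free-parameter value that maps to r1 on the toy (r1 or r2 may pivot)."""
    (free_id,) = problem.basis.free_ids
    return r1 if free_id == "r1" else 100.0 - r1


class TestFitFluxes:
    def test_exact_recovery_noise_free(self, toy_split_network):
        problem = make_split_problem(toy_split_network)
        fit = fit_fluxes(problem)
        assert fit.ssr < 1e-6
        assert fit.fluxes.net["r1"] == pytest.approx(70.0, rel=1e-3)
        assert fit.fluxes.net["r2"] == pytest.approx(30.0, rel=1e-3)

    def test_noisy_recovery_within_three_sigma(self, toy_split_network):
        rng = np.random.default_rng(11)
        problem = make_split_problem(toy_split_network, rng=rng)
        fit = fit_fluxes(problem)
        sig = fit.net_flux_sigmas()
        for rid in ("r1", "r2"):
            err = abs(fit.fluxes.net[rid] - split_truth(toy_split_network).net[rid])
            assert err <= 3 * sig[rid] + 1e-6, rid

    def test_seed_determinism(self, toy_split_network):
        rng1 = np.random.default_rng(5)
        rng2 = np.random.default_rng(5)
        a = fit_fluxes(make_split_problem(toy_split_network, rng=rng1))
        b = fit_fluxes(make_split_problem(toy_split_network, rng=rng2))
        assert a.params.tobytes() == b.params.tobytes()
        assert a.ssr == b.ssr

    def test_constraint_satisfaction_at_fit(self, toy_split_network):
        from osmoflux.model import stoichiometric_matrix

        rng = np.random.default_rng(2)
        problem = make_split_problem(toy_split_network, rng=rng)
        fit = fit_fluxes(problem)
        S = stoichiometric_matrix(toy_split_network)
        v = np.array(
            [fit.fluxes.net[r] for r in toy_split_network.reaction_ids]
        )
        assert np.max(np.abs(S @ v)) < 1e-8

    def test_rates_only_problem_flags_nonidentifiable_split(self, toy_split_network):
        problem = FluxEstimationProblem(
            network=toy_split_network,
            experiments=[],
            rates=[RateMeasurement("out", 100.0, 2.0)],
            fixed={"upt": 100.0},
            settings=FitSettings(restarts=2, seed=0),
        )
        fit = fit_fluxes(problem)
        assert fit.nonidentifiable  # the split direction cannot be resolved
        assert any("r1" in d or "r2" in d for d in fit.nonidentifiable)

    def test_parameter_recovery_improves_as_noise_shrinks(self, toy_split_network):
        errors = []
        for sd in (0.02, 0.005, 0.00125):
            errs = []
            for rep in range(4):
                rng = np.random.default_rng(100 + rep)
                problem = make_split_problem(toy_split_network, mid_sd=sd, rng=rng)
                fit = fit_fluxes(problem)
                errs.append(abs(fit.fluxes.net["r1"] - 70.0))
            errors.append(np.mean(errs))
        assert errors[2] < errors[0]

    def test_ssr_distribution_matches_chi_square(self, toy_split_network):
        """Minimized SSR over noise-consistent replicates follows chi^2 with
        dof = n_measurements - n_free_parameters (KS test, fixed seed)."""
        master = np.random.default_rng(1234)
        # tracer mixture chosen so every MID entry is well away from zero:
        # the additive-noise model is then free of clipping censorship
        tracer = TracerMixture([("10", 0.5), ("11", 0.3), ("00", 0.2)])
        ssrs = []
        problem = None
        for _ in range(200):
            rng = np.random.default_rng(master.integers(2**31))
            problem = make_split_problem(
                toy_split_network,
                rng=rng,
                tracer=tracer,
                settings=FitSettings(restarts=1, seed=0, sigma_floor=1e-6),
            )
            ssrs.append(fit_fluxes(problem).ssr)
        dof = problem.degrees_of_freedom
        assert dof == problem.n_measurements - 1
        ks = stats.kstest(ssrs, stats.chi2(dof).cdf)
        assert ks.pvalue > 0.01


class TestNormalizeToUptake:
    def test_scaling(self, toy_split_network):
        v = FluxVector(net={"upt": 5.0, "r1": 2.5, "r2": 2.5, "out": 5.0})
        out = normalize_to_uptake(v, toy_split_network)
        assert out.net["upt"] == pytest.approx(100.0)
        assert out.net["r1"] == pytest.approx(50.0)

    def test_already_normalized_unchanged(self, toy_split_network):
        v = split_truth(toy_split_network)
        out = normalize_to_uptake(v, toy_split_network)
        assert out.net == pytest.approx(v.net)

    def test_zero_uptake_rejected(self, toy_split_network):
        v = FluxVector(net={"upt": 0.0})
        with pytest.raises(ValueError, match="uptake"):
            normalize_to_uptake(v, toy_split_network)

    def test_downstream_mids_scale_invariant(self, toy_split_network):
        net = toy_split_network
        fragments = split_fragments(net)
        emu_net = emu_decompose(net, sorted({e for f in fragments for e in f.emus}))
        raw = FluxVector(net={"upt": 7.0, "r1": 4.9, "r2": 2.1, "out": 7.0})
        a = simulate_mids(net, emu_net, raw, TRACER, fragments)
        b = simulate_mids(net, emu_net, normalize_to_uptake(raw, net), TRACER, fragments)
        for x, y in zip(a, b):
            assert np.allclose(x.m, y.m, atol=1e-12)


class TestMonteCarloCI:
    def test_vanishing_sigma_gives_vanishing_width(self, toy_split_network):
        problem = make_split_problem(toy_split_network, mid_sd=1e-6, rate_sd=1e-6)
        fit = fit_fluxes(problem)
        ci = monte_carlo_ci(problem, fit, n_samples=20, seed=0)
        lo, hi = ci.intervals["r1"]
        assert hi - lo < 1e-3
        assert lo <= fit.fluxes.net["r1"] <= hi

    def test_single_sample_degenerate(self, toy_split_network):
        rng = np.random.default_rng(8)
        problem = make_split_problem(toy_split_network, rng=rng)
        fit = fit_fluxes(problem)
        ci = monte_carlo_ci(problem, fit, n_samples=1, seed=3)
        lo, hi = ci.intervals["r1"]
        assert lo == pytest.approx(hi)

    def test_seed_determinism(self, toy_split_network):
        rng = np.random.default_rng(9)
        problem = make_split_problem(toy_split_network, rng=rng)
        fit = fit_fluxes(problem)
        a = monte_carlo_ci(problem, fit, n_samples=10, seed=4)
        b = monte_carlo_ci(problem, fit, n_samples=10, seed=4)
        assert a.samples.tobytes() == b.samples.tobytes()
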