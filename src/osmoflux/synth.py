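"""Synthetic tracer experiments and growth time courses with known truth.

The generator emulates the study conditions: cultures at a chosen NaCl
molarity with the printed growth physiology (mu, Y_X/S, q_s, organic-acid
yields), labeled with either 99 % 1-13C glucose or a 50 % U-12C / 50 % U-13C
mixture.  A ground-truth flux vector consistent with the measured exchange
rates and condition-specific biomass demands is pushed through the EMU
forward model, converted to raw GC-MS mass distributions via the fragment
correction matrices, and perturbed by additive Gaussian noise (clipped at
zero and renormalized) — matching how MID standard deviations are reported
and weighted in the fit.  Rates receive multiplicative Gaussian noise.

The default free-flux choices (oxidative PPP share rising with salt, fixed
minor pyruvate-carboxylase and pyruvate-oxidase contributions) are synthetic
conventions, not measured values; they qualitatively mimic the reported
rerouting toward PPP, proline and PHB at high osmolarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from osmoflux.correction import (
    FragmentSpec,
    correction_matrix,
    load_fragment_panel,
    natural_abundances,
    uncorrect_mid,
)
from osmoflux.fitting import (
    FitSettings,
    FluxEstimationProblem,
    RateMeasurement,
    TracerExperiment,
    free_flux_basis,
)
from osmoflux.labeling import (
    FluxVector,
    Fragment,
    MassIsotopomerDistribution,
    TracerMixture,
    simulate_mids,
)
from osmoflux.emu import emu_decompose
from osmoflux.model import (
    MetabolicNetwork,
    interpolate_biomass,
    load_biomass_compositions,
    load_network,
    shipped_biomass_path,
    shipped_model_path,
)
from osmoflux.physiology import GrowthTimecourse, load_physiology_table, table_value
from osmoflux.cofactors import drain_precursor

#: Default measurement noise: additive sd on MID mass fractions and relative
#: sd on extracellular rates (typical GC-MS / HPLC precision).
MID_SD = 0.005
RATE_REL_SD = 0.03

#: Synthetic truth for the oxidative PPP flux (% of uptake) per NaCl molarity,
#: rising with osmotic stress; and fixed minor anaplerotic/overflow splits
#: that amino-acid labeling alone cannot resolve (set by convention).
_ZWF_TRUTH = {0.0: 22.0, 0.6: 35.0, 1.2: 60.0}
_PYCA_FIXED = 2.0
_POX_FIXED = 5.0

#: Default exchange fluxes (same % scale) giving partial reversibility.
_EXCHANGE_TRUTH = {
    "pgi": 60.0,
    "fba": 20.0,
    "tpi": 150.0,
    "gapdh": 40.0,
    "eno": 60.0,
    "rpe": 30.0,
    "rpi": 25.0,
    "tkt1": 8.0,
    "tkt2": 8.0,
    "tal": 8.0,
    "sdh": 4.0,
    "fum": 80.0,
    "mdh": 50.0,
}


@dataclass
class SyntheticScenario:
    """A fully specified study condition with known ground truth."""

    network: MetabolicNetwork
    true_fluxes: FluxVector
    tracers: list[TracerMixture]
    fixed: dict[str, float]  # hard constraints handed to the fit
    rate_truth: dict[str, float]  # measured-exchange truth (% of uptake)
    growth: dict[str, float]  # mu, y_xs, q_s, yield_<product> (printed units)
    condition: float = 0.0
    mid_sd: float = MID_SD
    rate_rel_sd: float = RATE_REL_SD
    seed: int = 0
    panel: list[FragmentSpec] = field(default_factory=load_fragment_panel)


def sample_feasible_fluxes(
    network: MetabolicNetwork,
    fixed: dict[str, float],
    seed: int = 0,
    upper: float = 200.0,
    exchange: dict[str, float] | None = None,
    max_tries: int = 10000,
) -> FluxVector:
    """Uniformly sample free fluxes within bounds and keep the first draw
    whose mapped full flux vector keeps every irreversible net flux >= 0."""
    basis = free_flux_basis(network, fixed)
    irreversible = {r.id for r in network.reactions if not r.reversible}
    rng = np.random.default_rng(seed)
    lo = np.array([0.0 if rid in irreversible else -upper for rid in basis.free_ids])
    hi = np.full(basis.dimension, upper)
    for _ in range(max(max_tries, 1)):
        u = rng.uniform(lo, hi) if basis.dimension else np.zeros(0)
        net = basis.flux_dict(u)
        if all(net[rid] >= -1e-9 for rid in irreversible):
            net = {k: (0.0 if abs(v) < 1e-12 else v) for k, v in net.items()}
            return FluxVector(net=net, exchange=dict(exchange or {}))
    raise RuntimeError(
        f"rejection budget exceeded ({max_tries} tries) sampling feasible fluxes"
    )


def _condition_constraints(
    network: MetabolicNetwork, condition: float
) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """(hard fixed, secretion truth, growth parameters) for one condition."""
    table = load_physiology_table()
    mu, _ = table_value(table, "mu", condition)
    q_s, _ = table_value(table, "q_s", condition)
    growth = {"mu": mu, "q_s": q_s}
    growth["y_xs"], _ = table_value(table, "Y_XS", condition)
    secretion_map = {
        "ace_out": "Y_acetate",
        "pyr_out": "Y_pyruvate",
        "lac_out": "Y_lactate",
        "suc_out": "Y_succinate",
        "akg_out": "Y_oxoglutarate",
    }
    rate_truth = {}
    for rid, param in secretion_map.items():
        y_mmol_per_mol, _ = table_value(table, param, condition)
        rate_truth[rid] = y_mmol_per_mol / 10.0  # mmol/mol -> % of uptake
        growth[f"yield_{param[2:].lower()}"] = y_mmol_per_mol
    biomass = interpolate_biomass(
        load_biomass_compositions(shipped_biomass_path()), condition
    )
    scale = 100.0 * mu / q_s  # mmol gCDW^-1 -> % of uptake
    fixed = {network.uptake_reaction_id: 100.0}
    for rxn in network.reactions:
        if rxn.kind == "biomass-drain":
            fixed[rxn.id] = biomass.demands.get(drain_precursor(rxn), 0.0) * scale
        elif rxn.kind == "constrained":
            fixed[rxn.id] = {"pyca": _PYCA_FIXED, "pox": _POX_FIXED}[rxn.id]
    return fixed, rate_truth, growth


def default_scenario(
    condition: float = 0.0,
    seed: int = 0,
    network: MetabolicNetwork | None = None,
    mid_sd: float = MID_SD,
    rate_rel_sd: float = RATE_REL_SD,
) -> SyntheticScenario:
    """The shipped-model scenario at a given NaCl molarity (0, 0.6 or 1.2 M).

    Ground truth is the unique balanced flux vector consistent with the
    printed rates, the condition's biomass demands, and the synthetic free
    flux conventions above.
    """
    network = network or load_network(shipped_model_path())
    fixed, rate_truth, growth = _condition_constraints(network, condition)
    zwf = _ZWF_TRUTH.get(condition)
    if zwf is None:
        zwf = float(
            np.interp(condition, *zip(*sorted(_ZWF_TRUTH.items())))
        )
    determined = dict(fixed)
    determined.update(rate_truth)
    determined["zwf"] = zwf
    basis = free_flux_basis(network, determined)
    if basis.dimension != 0:
        raise RuntimeError(
            f"scenario under-determined: free fluxes remain {basis.free_ids}"
        )
    net = basis.flux_dict(np.zeros(0))
    truth = FluxVector(
        net={k: (0.0 if abs(v) < 1e-9 else v) for k, v in net.items()},
        exchange=dict(_EXCHANGE_TRUTH),
    )
    truth.validate(network)
    return SyntheticScenario(
        network=network,
        true_fluxes=truth,
        tracers=[TracerMixture.one_13c(0.99), TracerMixture.fifty_fifty()],
        fixed=fixed,
        rate_truth=rate_truth,
        growth=growth,
        condition=condition,
        mid_sd=mid_sd,
        rate_rel_sd=rate_rel_sd,
        seed=seed,
    )


def generate_tracer_experiment(
    scenario: SyntheticScenario,
    tracer: TracerMixture,
    seed: int | None = None,
) -> tuple[list[MassIsotopomerDistribution], list[RateMeasurement]]:
    """Noisy raw GC-MS MID table + rate table for one tracer experiment.

    Skeleton MIDs from the true fluxes are mapped to raw observed masses by
    the fragment correction matrices, perturbed by additive Gaussian noise
    of sd ``scenario.mid_sd`` (clipped at 0, renormalized), and emitted with
    their sd column.  Rates get multiplicative noise.  Deterministic per seed.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    network = scenario.network
    fragments = [spec.to_fragment(network) for spec in scenario.panel]
    emu_net = emu_decompose(
        network, sorted({e for f in fragments for e in f.emus})
    )
    skeleton = simulate_mids(
        network, emu_net, scenario.true_fluxes, tracer, fragments
    )
    abundances = natural_abundances()
    raws = []
    for spec, mid in zip(scenario.panel, skeleton):
        C = correction_matrix(spec, abundances)
        raw = uncorrect_mid(mid, C)
        noisy = np.clip(raw.m + rng.normal(0.0, scenario.mid_sd, len(raw.m)), 0.0, None)
        noisy /= noisy.sum()
        raws.append(
            MassIsotopomerDistribution(
                spec.id, noisy, np.full(len(noisy), scenario.mid_sd)
            )
        )
    rates = []
    for rid, truth in sorted(scenario.rate_truth.items()):
        sd = max(scenario.rate_rel_sd * abs(truth), 0.05)
        value = truth * (1.0 + rng.normal(0.0, scenario.rate_rel_sd))
        rates.append(RateMeasurement(rid, value, sd))
    return raws, rates


def assemble_problem(
    scenario: SyntheticScenario,
    experiments: list[
        tuple[TracerMixture, list[MassIsotopomerDistribution], list[RateMeasurement]]
    ],
    settings: FitSettings | None = None,
) -> FluxEstimationProblem:
    """Natural-isotope-correct raw experiments and bundle them into a fit.

    Rates from multiple experiments are pooled; MIDs are corrected to
    carbon-skeleton space with propagated standard deviations.
    """
    from osmoflux.correction import correct_mid

    abundances = natural_abundances()
    spec_by_id = {s.id: s for s in scenario.panel}
    tracer_experiments = []
    pooled_rates: dict[str, RateMeasurement] = {}
    for tracer, raws, rates in experiments:
        measurements = []
        for raw in raws:
            spec = spec_by_id[raw.fragment_id]
            C = correction_matrix(spec, abundances)
            skeleton = correct_mid(raw, C)
            measurements.append((spec.to_fragment(scenario.network), skeleton))
        tracer_experiments.append(TracerExperiment(tracer, measurements))
        for rate in rates:
            pooled_rates.setdefault(rate.reaction_id, rate)
    return FluxEstimationProblem(
        network=scenario.network,
        experiments=tracer_experiments,
        rates=list(pooled_rates.values()),
        fixed=scenario.fixed,
        settings=settings or FitSettings(seed=scenario.seed),
    )


def generate_growth_timecourse(
    scenario: SyntheticScenario,
    n_points: int = 10,
    noise: float = 0.0,
    seed: int | None = None,
    x0: float = 0.05,
    glucose0_mmol: float = 27.8,
) -> GrowthTimecourse:
    """Exponential-growth time course consistent with the scenario physiology.

    Biomass grows at mu from ``x0`` g/L; glucose and products follow from the
    yields; multiplicative Gaussian noise of the given relative sd is applied
    to every observation.  Deterministic per seed.
    """
    mu = scenario.growth["mu"]
    if mu <= 0:
        raise ValueError("mu must be > 0")
    y_xs = scenario.growth["y_xs"]
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    # grow until ~80 % of the glucose is consumed
    x_end = x0 + 0.8 * glucose0_mmol / 1000.0 * y_xs
    t_end = np.log(x_end / x0) / mu
    time = np.linspace(0.0, t_end, n_points)
    biomass = x0 * np.exp(mu * time)
    consumed = (biomass - x0) / y_xs * 1000.0  # mmol/L
    glucose = glucose0_mmol - consumed
    products = {}
    for key, y in scenario.growth.items():
        if key.startswith("yield_"):
            products[key[len("yield_"):]] = y / 1000.0 * consumed
    if noise > 0:
        biomass = np.clip(biomass * (1 + rng.normal(0, noise, n_points)), 1e-9, None)
        glucose = np.clip(glucose * (1 + rng.normal(0, noise, n_points)), 0.0, None)
        products = {
            k: np.clip(v * (1 + rng.normal(0, noise, n_points)), 0.0, None)
            for k, v in products.items()
        }
    return GrowthTimecourse(
        time=time,
        biomass=biomass,
        glucose=glucose,
        products=products,
        condition=scenario.condition,
    )
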