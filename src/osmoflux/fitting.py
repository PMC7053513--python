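"""Weighted least-squares flux estimation with Monte-Carlo confidence intervals.

The flux space is parametrized through a free-flux basis: Gaussian
elimination of the stoichiometric constraints (plus hard-fixed rates such as
biomass drains) identifies a set of free reactions whose values determine the
whole balanced flux vector affinely.  The fit minimizes

    SSR = sum_exp sum_frag sum_mass ((m_sim - m_meas)/sigma)^2
        + sum_rates ((v_sim - v_meas)/sigma)^2

over the free net fluxes and the exchange-flux parameters
xi = v_exch/(uptake + v_exch) in [0, 0.99] of every reversible reaction,
using bounded multi-start local minimization (scipy trust-region reflective).
Uncertainty comes from Monte-Carlo resampling: every measured MID entry and
rate is perturbed by Gaussian noise of its own sigma, the problem refit from
the point estimate, and per-flux 95 % intervals taken as the 2.5th/97.5th
percentiles of the refits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from osmoflux.labeling import (
    EmuSimulator,
    FluxVector,
    Fragment,
    MassIsotopomerDistribution,
    TracerMixture,
    convolve,
)
from osmoflux.emu import emu_decompose
from osmoflux.model import MetabolicNetwork, stoichiometric_matrix

#: Default floor on MID standard deviations (mol fraction) — typical GC-MS
#: precision; prevents unbounded weights on vanishing reported sigmas.
SIGMA_FLOOR = 0.003

XI_MAX = 0.99
_RANK_TOL = 1e-9


class InfeasibleConstraintsError(ValueError):
    pass


class NoConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class RateMeasurement:
    """A measured extracellular rate mapped to a model reaction.

    Values are on whatever scale the problem uses (conventionally % of
    glucose uptake after normalization); sd must be positive.
    """

    reaction_id: str
    value: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"{self.reaction_id}: rate sd must be > 0")


@dataclass
class FluxBasis:
    """Affine parametrization v = A u + c of the balanced flux space."""

    free_ids: list[str]
    A: np.ndarray  # (n_reactions, n_free)
    c: np.ndarray  # (n_reactions,)
    reaction_ids: list[str]

    @property
    def dimension(self) -> int:
        return len(self.free_ids)

    def map(self, u: np.ndarray) -> np.ndarray:
        return self.A @ np.asarray(u, dtype=float) + self.c

    def flux_dict(self, u: np.ndarray) -> dict[str, float]:
        v = self.map(u)
        return dict(zip(self.reaction_ids, v))


def _rref(M: np.ndarray, tol: float = _RANK_TOL):
    """Reduced row echelon form with partial pivoting; returns (R, pivots)."""
    R = M.astype(float).copy()
    n_rows, n_cols = R.shape
    pivots: list[int] = []
    row = 0
    for col in range(n_cols):
        if row >= n_rows:
            break
        pivot_row = row + int(np.argmax(np.abs(R[row:, col])))
        if abs(R[pivot_row, col]) <= tol:
            continue
        R[[row, pivot_row]] = R[[pivot_row, row]]
        R[row] /= R[row, col]
        mask = np.arange(n_rows) != row
        R[mask] -= np.outer(R[mask, col], R[row])
        pivots.append(col)
        row += 1
    return R, pivots


def free_flux_basis(
    network: MetabolicNetwork,
    fixed: dict[str, float] | None = None,
) -> FluxBasis:
    """Parametrize the stoichiometrically balanced flux space.

    ``fixed`` hard-constrains reaction net fluxes (typically the uptake
    normalization, biomass drains, and any conventionally fixed reactions).
    The remaining dimension is n_reactions - rank([S; fixed rows]).
    """
    fixed = fixed or {}
    rids = network.reaction_ids
    col = {r: j for j, r in enumerate(rids)}
    S = stoichiometric_matrix(network)
    extra = np.zeros((len(fixed), len(rids)))
    rhs_extra = np.zeros(len(fixed))
    for i, (rid, value) in enumerate(sorted(fixed.items())):
        if rid not in col:
            raise KeyError(f"fixed rate for unknown reaction {rid!r}")
        extra[i, col[rid]] = 1.0
        rhs_extra[i] = value
    M = np.vstack([S, extra])
    rhs = np.concatenate([np.zeros(S.shape[0]), rhs_extra])
    # scale rows so the rank tolerance is meaningful for large fixed values
    aug = np.hstack([M, rhs[:, None]])
    norms = np.maximum(np.linalg.norm(aug, axis=1), 1.0)
    R, pivots = _rref(aug / norms[:, None])
    n_cols = M.shape[1]
    for i in range(R.shape[0]):
        if np.all(np.abs(R[i, :n_cols]) <= 1e-8) and abs(R[i, n_cols]) > 1e-8:
            bad = ", ".join(sorted(fixed))
            raise InfeasibleConstraintsError(
                f"fixed rates are inconsistent with the stoichiometry "
                f"(constraints on: {bad})"
            )
    pivots = [p for p in pivots if p < n_cols]
    free_cols = [j for j in range(n_cols) if j not in pivots]
    A = np.zeros((n_cols, len(free_cols)))
    c = np.zeros(n_cols)
    for k, j in enumerate(free_cols):
        A[j, k] = 1.0
    for i, p in enumerate(pivots):
        c[p] = R[i, n_cols]
        for k, j in enumerate(free_cols):
            A[p, k] = -R[i, j]
    return FluxBasis(
        free_ids=[rids[j] for j in free_cols], A=A, c=c, reaction_ids=rids
    )


@dataclass
class TracerExperiment:
    """One labeling experiment: tracer mixture + measured skeleton MIDs."""

    tracer: TracerMixture
    measurements: list[tuple[Fragment, MassIsotopomerDistribution]]


@dataclass
class FitSettings:
    restarts: int = 20
    seed: int = 0
    sigma_floor: float = SIGMA_FLOOR
    xi_max: float = XI_MAX
    flux_upper: float = 500.0
    ftol: float = 1e-10
    xtol: float = 1e-10
    max_nfev: int | None = None
    penalty_weight: float = 1e4


@dataclass
class FluxEstimationProblem:
    """The full input of a flux fit.

    ``fixed`` are hard equality constraints (uptake normalization, biomass
    drains, conventionally fixed reactions); measured secretion rates enter
    the objective as weighted residuals instead.
    """

    network: MetabolicNetwork
    experiments: list[TracerExperiment]
    rates: list[RateMeasurement]
    fixed: dict[str, float]
    settings: FitSettings = field(default_factory=FitSettings)

    def __post_init__(self) -> None:
        rids = set(self.network.reaction_ids)
        for rate in self.rates:
            if rate.reaction_id not in rids:
                raise KeyError(f"rate measurement for unknown reaction {rate.reaction_id!r}")
        self._basis = free_flux_basis(self.network, self.fixed)
        self._reversible = [r.id for r in self.network.reactions if r.reversible]
        targets = {
            emu
            for exp in self.experiments
            for frag, _ in exp.measurements
            for emu in frag.emus
        }
        self._simulator = None
        if targets:
            self._simulator = EmuSimulator(
                self.network, emu_decompose(self.network, sorted(targets))
            )
        self._uptake = self.fixed.get(self.network.uptake_reaction_id, 100.0)

    @property
    def basis(self) -> FluxBasis:
        return self._basis

    @property
    def reversible_ids(self) -> list[str]:
        return self._reversible

    @property
    def n_parameters(self) -> int:
        return self._basis.dimension + len(self._reversible)

    @property
    def n_measurements(self) -> int:
        """Independent measurement count: each normalized MID of length k
        contributes k - 1 entries (the simplex constraint removes one), plus
        one per rate."""
        n = sum(
            len(mid.m) - 1
            for exp in self.experiments
            for _, mid in exp.measurements
        )
        return n + len(self.rates)

    @property
    def degrees_of_freedom(self) -> int:
        return self.n_measurements - self.n_parameters

    # -- parameter vector layout: [free net fluxes | xi per reversible] --

    def split_params(self, params: np.ndarray):
        k = self._basis.dimension
        return np.asarray(params[:k]), np.asarray(params[k:])

    def flux_vector(self, params: np.ndarray) -> FluxVector:
        u, xi = self.split_params(params)
        net = self._basis.flux_dict(u)
        xi = np.clip(xi, 0.0, self.settings.xi_max)
        exchange = {
            rid: self._uptake * x / (1.0 - x)
            for rid, x in zip(self._reversible, xi)
        }
        return FluxVector(net=net, exchange=exchange)

    def bounds(self):
        lo, hi = [], []
        irreversible_free = {
            r.id for r in self.network.reactions if not r.reversible
        }
        for rid in self._basis.free_ids:
            lo.append(0.0 if rid in irreversible_free else -self.settings.flux_upper)
            hi.append(self.settings.flux_upper)
        lo += [0.0] * len(self._reversible)
        hi += [self.settings.xi_max] * len(self._reversible)
        return np.array(lo), np.array(hi)

    def measurement_residuals(self, params: np.ndarray) -> np.ndarray:
        fluxes = self.flux_vector(params)
        residuals: list[np.ndarray] = []
        for exp in self.experiments:
            if self._simulator is None:
                break
            solved = self._simulator.solve(fluxes, exp.tracer)
            for frag, mid in exp.measurements:
                sim = solved[frag.emus[0]]
                for emu in frag.emus[1:]:
                    sim = convolve(sim, solved[emu])
                sd = (
                    mid.sd
                    if mid.sd is not None
                    else np.full_like(mid.m, self.settings.sigma_floor)
                )
                sd = np.maximum(sd, self.settings.sigma_floor)
                residuals.append((sim - mid.m) / sd)
        for rate in self.rates:
            v = fluxes.net.get(rate.reaction_id, 0.0)
            residuals.append(np.array([(v - rate.value) / rate.sd]))
        return np.concatenate(residuals) if residuals else np.zeros(0)

    def _penalty_residuals(self, params: np.ndarray) -> np.ndarray:
        """Soft non-negativity of dependent irreversible fluxes."""
        fluxes = self.flux_vector(params)
        pens = []
        for rxn in self.network.reactions:
            if not rxn.reversible:
                v = fluxes.net.get(rxn.id, 0.0)
                pens.append(self.settings.penalty_weight * min(v, 0.0))
        return np.array(pens)

    def full_residuals(self, params: np.ndarray) -> np.ndarray:
        """Measurement residuals plus feasibility penalties.

        At iterates where a dependent irreversible flux has gone negative the
        EMU cascade can become singular; the measurement block then degrades
        to a large constant and the penalty block steers the optimizer back
        into the feasible region.
        """
        from osmoflux.labeling import SingularEmuError

        penalties = self._penalty_residuals(params)
        try:
            measured = self.measurement_residuals(params)
        except SingularEmuError:
            measured = np.full(self._n_residual_entries(), 1e3)
        return np.concatenate([measured, penalties])

    def _n_residual_entries(self) -> int:
        return (
            sum(
                len(mid.m)
                for exp in self.experiments
                for _, mid in exp.measurements
            )
            + len(self.rates)
        )

    def feasible_start(self, rng: np.random.Generator, max_tries: int = 200) -> np.ndarray:
        """Random start within bounds whose mapped dependents are feasible."""
        lo, hi = self.bounds()
        irreversible = {
            r.id for r in self.network.reactions if not r.reversible
        }
        x0 = rng.uniform(lo, hi)
        for _ in range(max_tries):
            x0 = rng.uniform(lo, hi)
            net = self.basis.flux_dict(self.split_params(x0)[0])
            if all(
                net[rid] >= -1e-9 for rid in irreversible
            ):
                return x0
        return x0


def objective(problem: FluxEstimationProblem, params: np.ndarray) -> float:
    """Weighted sum of squared residuals at the given parameter vector."""
    r = problem.measurement_residuals(params)
    return float(r @ r)


@dataclass
class FitResult:
    fluxes: FluxVector
    params: np.ndarray
    ssr: float
    residuals: np.ndarray
    dof: int
    restart_table: list[dict]
    seed: int
    problem: FluxEstimationProblem = field(repr=False)
    nonidentifiable: list[str] = field(default_factory=list)

    def parameter_sigmas(self) -> np.ndarray:
        """Linearized parameter standard errors from the jacobian at the fit."""
        J = _jacobian(self.problem, self.params)
        cov = np.linalg.pinv(J.T @ J, rcond=1e-12)
        return np.sqrt(np.maximum(np.diag(cov), 0.0))

    def net_flux_sigmas(self) -> dict[str, float]:
        """Propagated standard errors of every net flux."""
        J = _jacobian(self.problem, self.params)
        cov = np.linalg.pinv(J.T @ J, rcond=1e-12)
        k = self.problem.basis.dimension
        A = self.problem.basis.A
        flux_cov = A @ cov[:k, :k] @ A.T
        sig = np.sqrt(np.maximum(np.diag(flux_cov), 0.0))
        return dict(zip(self.problem.basis.reaction_ids, sig))


def _jacobian(
    problem: FluxEstimationProblem, params: np.ndarray, eps: float = 1e-6
) -> np.ndarray:
    """Forward-difference jacobian with a backward-difference fallback for
    steps that leave the feasible labeling region (singular EMU systems)."""
    from osmoflux.labeling import SingularEmuError

    r0 = problem.measurement_residuals(params)
    J = np.zeros((len(r0), len(params)))
    for j in range(len(params)):
        p = params.copy()
        p[j] += eps
        try:
            J[:, j] = (problem.measurement_residuals(p) - r0) / eps
        except SingularEmuError:
            p[j] = params[j] - eps
            try:
                J[:, j] = (r0 - problem.measurement_residuals(p)) / eps
            except SingularEmuError:
                J[:, j] = 0.0
    return J


def _flag_nonidentifiable(
    problem: FluxEstimationProblem, params: np.ndarray, tol: float = 1e-6
) -> list[str]:
    J = _jacobian(problem, params)
    if J.size == 0:
        return ["no measurements: all directions unidentifiable"]
    _, s, Vt = np.linalg.svd(J, full_matrices=True)
    names = problem.basis.free_ids + [
        f"xi({r})" for r in problem.reversible_ids
    ]
    flags = []
    s = np.concatenate([s, np.zeros(len(names) - len(s))])
    for k in range(len(names)):
        if s[k] <= tol * max(s[0], 1.0):
            direction = Vt[k]
            main = [
                f"{direction[i]:+.2f}*{names[i]}"
                for i in np.argsort(-np.abs(direction))[:3]
                if abs(direction[i]) > 0.05
            ]
            flags.append(" ".join(main))
    return flags


def fit_fluxes(problem: FluxEstimationProblem) -> FitResult:
    """Best-of-restarts bounded local minimization of the weighted SSR.

    Starting points are drawn uniformly within the parameter bounds from the
    problem's seed; the result records every restart's outcome and is
    bit-for-bit reproducible for a fixed seed.
    """
    settings = problem.settings
    rng = np.random.default_rng(settings.seed)
    lo, hi = problem.bounds()
    table: list[dict] = []
    best = None
    for start in range(max(settings.restarts, 1)):
        x0 = problem.feasible_start(rng)
        try:
            res = least_squares(
                problem.full_residuals,
                x0,
                bounds=(lo, hi),
                method="trf",
                ftol=settings.ftol,
                xtol=settings.xtol,
                gtol=1e-12,
                max_nfev=settings.max_nfev,
            )
            ssr = objective(problem, res.x)
            table.append({"start": start, "ssr": ssr, "success": bool(res.success)})
            if np.isfinite(ssr) and (best is None or ssr < best[0]):
                best = (ssr, res.x)
        except Exception as exc:  # noqa: BLE001 — recorded per restart
            table.append({"start": start, "ssr": np.inf, "error": str(exc)})
    if best is None:
        raise NoConvergenceError(
            f"all {settings.restarts} restarts failed: {table}"
        )
    ssr, x = best
    fluxes = problem.flux_vector(x)
    return FitResult(
        fluxes=fluxes,
        params=x,
        ssr=ssr,
        residuals=problem.measurement_residuals(x),
        dof=problem.degrees_of_freedom,
        restart_table=table,
        seed=settings.seed,
        problem=problem,
        nonidentifiable=_flag_nonidentifiable(problem, x),
    )


def normalize_to_uptake(fit_or_fluxes, network: MetabolicNetwork | None = None) -> FluxVector:
    """Scale a flux vector so the glucose uptake reaction equals 100."""
    if isinstance(fit_or_fluxes, FitResult):
        fluxes = fit_or_fluxes.fluxes
        network = fit_or_fluxes.problem.network
    else:
        fluxes = fit_or_fluxes
        if network is None:
            raise ValueError("network required when passing a bare FluxVector")
    uptake = fluxes.net.get(network.uptake_reaction_id, 0.0)
    if uptake <= 0:
        raise ValueError("glucose uptake flux is zero; cannot normalize")
    return fluxes.scaled(100.0 / uptake)


@dataclass
class ConfidenceIntervals:
    intervals: dict[str, tuple[float, float]]
    n_samples: int
    seed: int
    samples: np.ndarray = field(repr=False, default=None)
    reaction_ids: list[str] = field(default_factory=list)


def monte_carlo_ci(
    problem: FluxEstimationProblem,
    fit: FitResult,
    n_samples: int = 200,
    seed: int = 0,
    max_failure_fraction: float = 0.2,
) -> ConfidenceIntervals:
    """95 % confidence intervals of the net fluxes by measurement resampling.

    Each replicate perturbs every measured MID entry and rate by Gaussian
    noise of its own sigma (MIDs clipped at 0 and renormalized), refits from
    the point estimate, and the 2.5th/97.5th percentiles over replicates give
    the interval per reaction.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    rids = problem.basis.reaction_ids
    collected = []
    failures = 0
    for _ in range(n_samples):
        experiments = []
        for exp in problem.experiments:
            measurements = []
            for frag, mid in exp.measurements:
                sd = (
                    mid.sd
                    if mid.sd is not None
                    else np.full_like(mid.m, problem.settings.sigma_floor)
                )
                noisy = np.clip(mid.m + rng.normal(0.0, sd), 0.0, None)
                total = noisy.sum()
                if total <= 0:
                    noisy = mid.m.copy()
                    total = noisy.sum()
                measurements.append(
                    (frag, MassIsotopomerDistribution(frag.id, noisy / total, sd))
                )
            experiments.append(TracerExperiment(exp.tracer, measurements))
        rates = [
            RateMeasurement(r.reaction_id, r.value + rng.normal(0.0, r.sd), r.sd)
            for r in problem.rates
        ]
        perturbed = FluxEstimationProblem(
            network=problem.network,
            experiments=experiments,
            rates=rates,
            fixed=problem.fixed,
            settings=problem.settings,
        )
        lo, hi = perturbed.bounds()
        x0 = np.clip(fit.params, lo, hi)
        try:
            res = least_squares(
                perturbed.full_residuals,
                x0,
                bounds=(lo, hi),
                method="trf",
                ftol=1e-9,
                xtol=1e-9,
                gtol=1e-12,
            )
            v = perturbed.basis.map(perturbed.split_params(res.x)[0])
            collected.append(v)
        except Exception:  # noqa: BLE001
            failures += 1
    if n_samples and failures / n_samples > max_failure_fraction:
        raise NoConvergenceError(
            f"{failures}/{n_samples} Monte-Carlo refits failed"
        )
    samples = np.array(collected)
    lo_q = np.percentile(samples, 2.5, axis=0)
    hi_q = np.percentile(samples, 97.5, axis=0)
    intervals = {
        rid: (float(lo_q[i]), float(hi_q[i])) for i, rid in enumerate(rids)
    }
    return ConfidenceIntervals(
        intervals=intervals,
        n_samples=n_samples,
        seed=seed,
        samples=samples,
        reaction_ids=list(rids),
    )
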