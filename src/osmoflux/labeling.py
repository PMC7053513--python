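"""Steady-state labeling simulation (the forward model of the flux analysis).

Given a balanced flux vector and a glucose tracer mixture, the EMU cascade is
solved size by size as linear systems, yielding the mass isotopomer
distribution (MID) of every EMU needed for the measured amino-acid fragments.
A fragment assembled from several independent precursor molecules (e.g.
valine from two pyruvates) has the convolution of its component EMU MIDs.

Exchange fluxes enter as bidirectional rates: for net flux v and exchange
flux ``exch``, the forward rate is ``max(v, 0) + exch`` and the backward rate
``max(-v, 0) + exch``.  Labeling depends only on flux ratios, so scaling all
fluxes by a constant leaves every MID unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from osmoflux.emu import EMU, EmuNetwork
from osmoflux.model import MetabolicNetwork


class SingularEmuError(RuntimeError):
    """EMU balance system is singular (typically a zero-flux dead end)."""


@dataclass
class TracerMixture:
    """Mixture of positional glucose isotopomers.

    Each species is a 6-character label pattern over the glucose carbons
    ('1' = 13C at that position) with its molar fraction.  The 99 %
    positionally pure 1-13C tracer is the two-component mixture
    0.99 x '100000' + 0.01 x '000000'.
    """

    species: list[tuple[str, float]]

    def __post_init__(self) -> None:
        fractions = [f for _, f in self.species]
        if any(f < 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError("tracer fractions must be >= 0 and sum to 1")
        lengths = {len(p) for p, _ in self.species}
        if len(lengths) != 1:
            raise ValueError("tracer label patterns differ in length")

    @classmethod
    def unlabeled(cls, n_carbons: int = 6) -> "TracerMixture":
        return cls([("0" * n_carbons, 1.0)])

    @classmethod
    def uniformly_labeled(cls, n_carbons: int = 6) -> "TracerMixture":
        return cls([("1" * n_carbons, 1.0)])

    @classmethod
    def one_13c(cls, purity: float = 0.99, n_carbons: int = 6) -> "TracerMixture":
        """Positionally labeled 1-13C glucose at the given purity."""
        pattern = "1" + "0" * (n_carbons - 1)
        return cls([(pattern, purity), ("0" * n_carbons, 1.0 - purity)])

    @classmethod
    def fifty_fifty(cls, n_carbons: int = 6) -> "TracerMixture":
        """50 % U-12C / 50 % U-13C glucose."""
        return cls([("0" * n_carbons, 0.5), ("1" * n_carbons, 0.5)])

    def input_mid(self, emu: EMU) -> np.ndarray:
        """MID of a substrate EMU under this mixture (no natural abundance)."""
        mid = np.zeros(emu.size + 1)
        for pattern, fraction in self.species:
            shift = sum(pattern[i - 1] == "1" for i in emu.atoms)
            mid[shift] += fraction
        return mid


@dataclass
class FluxVector:
    """Net and exchange fluxes, conventionally normalized to glucose uptake = 100.

    ``net`` maps every reaction id to its net rate; ``exchange`` maps
    reversible reactions to their bidirectional component (>= 0).
    """

    net: dict[str, float]
    exchange: dict[str, float] = field(default_factory=dict)

    def forward(self, rid: str) -> float:
        v = self.net.get(rid, 0.0)
        return max(v, 0.0) + self.exchange.get(rid, 0.0)

    def backward(self, rid: str) -> float:
        v = self.net.get(rid, 0.0)
        return max(-v, 0.0) + self.exchange.get(rid, 0.0)

    def scaled(self, factor: float) -> "FluxVector":
        return FluxVector(
            net={k: v * factor for k, v in self.net.items()},
            exchange={k: v * factor for k, v in self.exchange.items()},
        )

    def validate(self, network: MetabolicNetwork, atol: float = 1e-8) -> None:
        from osmoflux.model import stoichiometric_matrix

        for rxn in network.reactions:
            if not rxn.reversible:
                if self.net.get(rxn.id, 0.0) < -atol:
                    raise ValueError(f"irreversible reaction {rxn.id} has negative net flux")
                if self.exchange.get(rxn.id, 0.0) != 0.0:
                    raise ValueError(f"irreversible reaction {rxn.id} has exchange flux")
        for exch in self.exchange.values():
            if exch < 0:
                raise ValueError("exchange fluxes must be >= 0")
        S = stoichiometric_matrix(network)
        v = np.array([self.net.get(r, 0.0) for r in network.reaction_ids])
        residual = S @ v
        if np.max(np.abs(residual)) > atol:
            worst = network.balanced_metabolites[int(np.argmax(np.abs(residual)))]
            raise ValueError(
                f"flux vector violates steady state at {worst} "
                f"(residual {np.max(np.abs(residual)):.3g})"
            )


@dataclass
class MassIsotopomerDistribution:
    """Fractions of mass shifts M+0 ... M+n of one fragment.

    ``normalized=False`` skips the simplex check, for model-predicted raw
    MIDs over a truncated mass window whose tail mass is unrecorded.
    """

    fragment_id: str
    m: np.ndarray
    sd: np.ndarray | None = None
    normalized: bool = True

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        if np.any(self.m < -1e-12):
            raise ValueError(f"{self.fragment_id}: negative MID entry")
        if self.normalized and abs(self.m.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"{self.fragment_id}: MID sums to {self.m.sum():.6f}, not 1"
            )


@dataclass(frozen=True)
class Fragment:
    """A measured carbon-skeleton fragment: one or more precursor EMUs.

    Multiple EMUs mean the fragment's carbons derive from independent
    precursor molecules; its MID is their convolution.
    """

    id: str
    emus: tuple[EMU, ...]

    @property
    def n_carbons(self) -> int:
        return sum(e.size for e in self.emus)


def convolve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Discrete convolution of two MID vectors (the EMU condensation rule)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = np.zeros(len(a) + len(b) - 1)
    for i, ai in enumerate(a):
        if ai != 0.0:
            out[i : i + len(b)] += ai * b
    return out


class EmuSimulator:
    """Compiled EMU cascade: structure precomputed once, fluxes swapped freely.

    The per-size linear systems are assembled from (reaction, direction,
    weight) stamps recorded at construction, so repeated simulation inside
    the fitting loop costs only the numeric assembly and solves.
    """

    def __init__(self, network: MetabolicNetwork, emu_net: EmuNetwork):
        self.network = network
        self.emu_net = emu_net
        # consumption stamps: metabolite -> [(reaction_id, direction, n_instances)]
        self._consumption: dict[str, list[tuple[str, str, int]]] = {}
        for rxn in network.reactions:
            for direction in ["f"] + (["b"] if rxn.reversible else []):
                side = rxn.substrates if direction == "f" else rxn.products
                counts: dict[str, int] = {}
                for met, _ in side:
                    counts[met] = counts.get(met, 0) + 1
                for met, n in counts.items():
                    self._consumption.setdefault(met, []).append(
                        (rxn.id, direction, n)
                    )
        self._levels = []
        for size in emu_net.sizes:
            emus = emu_net.emus_of_size(size)
            index = {e: i for i, e in enumerate(emus)}
            same_size: list[tuple[int, int, str, str, float]] = []
            known: list[tuple[int, str, str, float, tuple[EMU, ...]]] = []
            for emu in emus:
                i = index[emu]
                for route in emu_net.routes[emu]:
                    if (
                        len(route.sources) == 1
                        and route.sources[0].size == size
                        and route.sources[0] not in emu_net.inputs
                    ):
                        same_size.append(
                            (i, index[route.sources[0]], route.reaction_id,
                             route.direction, route.weight)
                        )
                    else:
                        known.append(
                            (i, route.reaction_id, route.direction, route.weight,
                             route.sources)
                        )
            self._levels.append((size, emus, same_size, known))

    def _flux(self, fluxes: FluxVector, rid: str, direction: str) -> float:
        return fluxes.forward(rid) if direction == "f" else fluxes.backward(rid)

    def _consumption_total(self, fluxes: FluxVector, met: str) -> float:
        return sum(
            self._flux(fluxes, rid, d) * n
            for rid, d, n in self._consumption.get(met, [])
        )

    def solve(
        self, fluxes: FluxVector, tracer: TracerMixture
    ) -> dict[EMU, np.ndarray]:
        solved: dict[EMU, np.ndarray] = {
            e: tracer.input_mid(e) for e in self.emu_net.inputs
        }
        for size, emus, same_size, known in self._levels:
            n = len(emus)
            A = np.zeros((n, n))
            B = np.zeros((n, size + 1))
            for i, emu in enumerate(emus):
                cons = self._consumption_total(fluxes, emu.met)
                if cons <= 0.0:
                    raise SingularEmuError(
                        f"EMU {emu}: metabolite {emu.met} has zero total "
                        "consumption flux (dead end at the given fluxes)"
                    )
                A[i, i] = cons
            for i, j, rid, d, w in same_size:
                A[i, j] -= self._flux(fluxes, rid, d) * w
            for i, rid, d, w, sources in known:
                f = self._flux(fluxes, rid, d) * w
                if f == 0.0:
                    continue
                mid = solved[sources[0]]
                for src in sources[1:]:
                    mid = convolve(mid, solved[src])
                B[i] += f * mid
            try:
                X = np.linalg.solve(A, B)
            except np.linalg.LinAlgError as exc:
                raise SingularEmuError(
                    f"singular EMU system at size {size} "
                    f"(EMUs: {', '.join(map(str, emus))})"
                ) from exc
            for i, emu in enumerate(emus):
                solved[emu] = X[i]
        return solved


def solve_emu_mids(
    network: MetabolicNetwork,
    emu_net: EmuNetwork,
    fluxes: FluxVector,
    tracer: TracerMixture,
) -> dict[EMU, np.ndarray]:
    """Solve the EMU cascade and return the MID of every EMU in the network."""
    return EmuSimulator(network, emu_net).solve(fluxes, tracer)


def simulate_mids(
    network: MetabolicNetwork,
    emu_net: EmuNetwork,
    fluxes: FluxVector,
    tracer: TracerMixture,
    fragments: list[Fragment] | None = None,
) -> list[MassIsotopomerDistribution]:
    """Carbon-skeleton MIDs of the requested fragments for one flux vector.

    Without an explicit fragment list, the decomposition's target EMUs are
    reported one fragment each.
    """
    solved = solve_emu_mids(network, emu_net, fluxes, tracer)
    if fragments is None:
        fragments = [Fragment(str(e), (e,)) for e in emu_net.targets]
    out = []
    for frag in fragments:
        mid = solved[frag.emus[0]]
        for emu in frag.emus[1:]:
            mid = convolve(mid, solved[emu])
        out.append(MassIsotopomerDistribution(frag.id, mid))
    return out


@dataclass
class SteadyStateReport:
    max_deviation: float
    is_steady: bool
    worst_fragment: str | None = None


def check_isotopic_steady_state(
    mid_sets: list[dict[str, MassIsotopomerDistribution]],
    tol: float = 0.01,
) -> SteadyStateReport:
    """Compare fragment MIDs sampled at increasing cell density.

    Labeling is at isotopic steady state when the largest pairwise absolute
    deviation of any mass-shift fraction across the samplings stays below
    ``tol`` (the experimental check samples cultures at OD 2, 4 and 6).
    """
    if len(mid_sets) < 2:
        raise ValueError("need at least two MID collections")
    fragment_ids = set(mid_sets[0])
    for coll in mid_sets[1:]:
        if set(coll) != fragment_ids:
            raise ValueError(
                "fragment-set mismatch between collections: "
                f"{sorted(fragment_ids.symmetric_difference(set(coll)))}"
            )
    max_dev = 0.0
    worst = None
    for fid in sorted(fragment_ids):
        vectors = [coll[fid].m for coll in mid_sets]
        for i in range(len(vectors)):
            for j in range(i + 1, len(vectors)):
                dev = float(np.max(np.abs(vectors[i] - vectors[j])))
                if dev > max_dev:
                    max_dev, worst = dev, fid
    return SteadyStateReport(
        max_deviation=max_dev, is_steady=max_dev <= tol, worst_fragment=worst
    )
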