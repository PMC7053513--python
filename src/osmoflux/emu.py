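"""Elementary metabolite unit (EMU) decomposition.

An EMU is a specific subset of a metabolite's carbon atoms.  Decomposing the
atom-mapped network into the minimal set of EMUs reachable backwards from the
measured fragments turns steady-state isotopomer balancing into a cascade of
small linear systems ordered by EMU size: an EMU of size k is produced either
from a single same-size EMU (carbon-skeleton transfer) or by condensation of
strictly smaller EMUs (e.g. aldol additions, transketolase transfers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from osmoflux.model import MetabolicNetwork


class UnreachableEmuError(ValueError):
    """A measured fragment EMU cannot be traced back to the tracer substrate."""


@dataclass(frozen=True, order=True)
class EMU:
    met: str
    atoms: frozenset[int] = field(compare=False)
    _key: tuple[int, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_key", tuple(sorted(self.atoms)))

    @property
    def size(self) -> int:
        return len(self.atoms)

    def __str__(self) -> str:
        return f"{self.met}[{','.join(map(str, self._key))}]"

    def __hash__(self) -> int:
        return hash((self.met, self._key))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, EMU)
            and self.met == other.met
            and self._key == other._key
        )


@dataclass(frozen=True)
class EmuRoute:
    """One production route of an EMU: reaction + direction + atom sources.

    ``sources`` holds one EMU per contributing substrate molecule; more than
    one source means condensation (MID convolution).  ``weight`` is the
    probability of the atom-mapping variant this route derives from
    (0.5 per orientation for symmetric metabolites such as succinate).
    """

    reaction_id: str
    direction: str  # "f" or "b"
    weight: float
    sources: tuple[EMU, ...]


@dataclass
class EmuNetwork:
    routes: dict[EMU, list[EmuRoute]]
    inputs: set[EMU]
    targets: list[EMU]

    @property
    def sizes(self) -> list[int]:
        return sorted({e.size for e in self.routes})

    def emus_of_size(self, size: int) -> list[EMU]:
        return sorted(e for e in self.routes if e.size == size)


def _direction_sides(variant, direction: str):
    if direction == "f":
        return variant.substrates, variant.products
    return variant.products, variant.substrates


def _trace_routes(network: MetabolicNetwork, emu: EMU) -> list[EmuRoute]:
    """All production routes of ``emu`` across reactions, directions, variants."""
    routes: list[EmuRoute] = []
    for rxn in network.reactions:
        directions = ["f"] + (["b"] if rxn.reversible else [])
        for direction in directions:
            for variant in rxn.variants:
                consumed, produced = _direction_sides(variant, direction)
                for met, amap in produced:
                    if met != emu.met:
                        continue
                    # group traced atoms by the substrate instance they sit on
                    per_instance: dict[int, set[int]] = {}
                    for idx in emu.atoms:
                        letter = amap[idx - 1]
                        for inst, (smet, samap) in enumerate(consumed):
                            pos = samap.find(letter)
                            if pos >= 0:
                                per_instance.setdefault(inst, set()).add(pos + 1)
                                break
                        else:  # pragma: no cover - ruled out by load validation
                            raise ValueError(
                                f"reaction {rxn.id}: atom {letter!r} of {met} "
                                "has no substrate-side origin"
                            )
                    sources = tuple(
                        EMU(consumed[inst][0], frozenset(atoms))
                        for inst, atoms in sorted(per_instance.items())
                    )
                    routes.append(
                        EmuRoute(rxn.id, direction, variant.weight, sources)
                    )
    return routes


def emu_decompose(
    network: MetabolicNetwork,
    target_fragments: Iterable[tuple[str, Iterable[int]]] | Iterable[EMU],
) -> EmuNetwork:
    """Minimal EMU network closed under backward precursor tracing.

    ``target_fragments`` are (metabolite, carbon index subset) pairs (or EMU
    objects).  Only EMUs actually needed to simulate the targets are
    instantiated; cleavage by-products never enter the network.
    """
    targets: list[EMU] = []
    for frag in target_fragments:
        if isinstance(frag, EMU):
            emu = frag
        else:
            met, atoms = frag
            emu = EMU(met, frozenset(atoms))
        n_c = network.metabolites[emu.met].n_carbons
        if not emu.atoms or any(a < 1 or a > n_c for a in emu.atoms):
            raise ValueError(f"invalid carbon subset for {emu.met}: {set(emu.atoms)}")
        targets.append(emu)

    routes: dict[EMU, list[EmuRoute]] = {}
    inputs: set[EMU] = set()
    stack = list(targets)
    while stack:
        emu = stack.pop()
        if emu in routes or emu in inputs:
            continue
        role = network.metabolites[emu.met].role
        if role == "substrate":
            inputs.add(emu)
            continue
        emu_routes = _trace_routes(network, emu)
        if not emu_routes:
            raise UnreachableEmuError(
                f"EMU {emu} has no producing reaction; it cannot be traced "
                f"back to {network.substrate_id}"
            )
        routes[emu] = emu_routes
        for route in emu_routes:
            stack.extend(route.sources)

    for emu, emu_routes in routes.items():
        for route in emu_routes:
            assert sum(s.size for s in route.sources) == emu.size

    # grounding: every EMU must be reachable from the tracer substrate via at
    # least one route whose sources are all themselves grounded
    grounded: set[EMU] = set(inputs)
    changed = True
    while changed:
        changed = False
        for emu, emu_routes in routes.items():
            if emu in grounded:
                continue
            for route in emu_routes:
                if all(s in grounded for s in route.sources):
                    grounded.add(emu)
                    changed = True
                    break
    ungrounded = [e for e in routes if e not in grounded]
    if ungrounded:
        raise UnreachableEmuError(
            f"EMUs cannot be traced back to {network.substrate_id}: "
            f"{', '.join(str(e) for e in sorted(ungrounded)[:5])}"
        )
    return EmuNetwork(routes=routes, inputs=inputs, targets=targets)
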