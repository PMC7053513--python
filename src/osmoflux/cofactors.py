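"""Cofactor and gas balances derived from a flux vector.

NADPH supply (oxidative PPP, NADP-dependent isocitrate dehydrogenase) is
compared against demand from explicit pathway reactions (glutamate/proline
synthesis, PHB monomer reduction) plus the biosynthetic demand of biomass
formation, computed from the biomass-drain fluxes times per-precursor NADPH
costs.  NADPH and NADH pools are kept strictly separate (no transhydrogenase
in the model), so an NADPH excess is well defined.  CO2 participates in the
carbon skeleton, so its balance comes from the reaction equations themselves
(decarboxylations minus carboxylations), not from a bookkeeping column.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from osmoflux.labeling import FluxVector
from osmoflux.model import MetabolicNetwork, Reaction, _data_path

COFACTORS = ("NADPH", "NADH", "ATP", "FADH2", "CO2")


def load_nadph_costs(path: str | Path | None = None) -> dict[str, float]:
    """NADPH cost (mmol per mmol precursor) of converting each biomass
    precursor into monomers downstream of the modeled reactions."""
    path = Path(path) if path is not None else _data_path("nadph_costs.csv")
    with path.open(newline="") as fh:
        return {
            row["precursor"]: float(row["nadph_mmol_per_mmol"])
            for row in csv.DictReader(fh)
        }


def _is_transport(rxn: Reaction, network: MetabolicNetwork) -> bool:
    """True for pure export reactions (balanced species -> sink)."""
    return (
        len(rxn.substrates) == 1
        and len(rxn.products) == 1
        and network.metabolites[rxn.products[0][0]].role == "sink"
        and rxn.substrates[0][1] == rxn.products[0][1]
    )


def _cofactor_coefficient(
    rxn: Reaction, cofactor: str, network: MetabolicNetwork
) -> float:
    coeff = float(rxn.cofactors.get(cofactor, 0.0))
    if cofactor == "CO2" and not _is_transport(rxn, network):
        coeff += float(rxn.stoichiometry().get("CO2", 0.0))
    return coeff


def drain_precursor(rxn: Reaction) -> str:
    """Biomass precursor name served by a biomass-drain reaction."""
    product = rxn.products[0][0]
    return product[3:] if product.startswith("BM_") else product


@dataclass
class LedgerEntry:
    supply: float
    demand: float

    @property
    def net(self) -> float:
        return self.supply - self.demand

    @property
    def excess_percent(self) -> float | None:
        """100 * (supply - demand)/demand; None when demand is zero."""
        if self.demand == 0.0:
            return None
        return 100.0 * self.net / self.demand


@dataclass
class CofactorLedger:
    entries: dict[str, LedgerEntry]

    def __getitem__(self, cofactor: str) -> LedgerEntry:
        return self.entries[cofactor]


def cofactor_ledger(
    network: MetabolicNetwork,
    fluxes: FluxVector,
    nadph_costs: dict[str, float] | None = None,
    include_pathway_demand: bool = True,
) -> CofactorLedger:
    """Supply/demand ledger per cofactor for a balanced flux vector.

    Reaction terms use the signed cofactor coefficient times the net flux;
    the NADPH demand additionally includes the biomass-drain fluxes weighted
    by per-precursor NADPH costs.  With ``include_pathway_demand=False`` the
    explicit consuming reactions (proline and PHB synthesis, glutamate
    formation) are left out of the demand term, leaving only growth biomass.
    """
    costs = nadph_costs if nadph_costs is not None else load_nadph_costs()
    entries: dict[str, LedgerEntry] = {}
    for cofactor in COFACTORS:
        supply = demand = 0.0
        for rxn in network.reactions:
            c = _cofactor_coefficient(rxn, cofactor, network)
            if c == 0.0:
                continue
            term = c * fluxes.net.get(rxn.id, 0.0)
            if not include_pathway_demand and term < 0 and rxn.kind == "free":
                continue
            if term >= 0:
                supply += term
            else:
                demand += -term
        if cofactor == "NADPH":
            for rxn in network.reactions:
                if rxn.kind == "biomass-drain":
                    cost = costs.get(drain_precursor(rxn), 0.0)
                    demand += cost * fluxes.net.get(rxn.id, 0.0)
        entries[cofactor] = LedgerEntry(supply=supply, demand=demand)
    return CofactorLedger(entries=entries)


def _carbon_graph(network: MetabolicNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    for rxn in network.reactions:
        for smet, samap in rxn.substrates:
            for pmet, pamap in rxn.products:
                if set(samap) & set(pamap):  # carbon actually transferred
                    g.add_edge(smet, pmet, reaction=rxn.id)
    return g


def nadph_along_path(
    network: MetabolicNetwork, source: str, target: str
) -> float:
    """NADPH consumed per unit product along the unique source -> target path."""
    g = _carbon_graph(network)
    if source not in g or target not in g:
        raise ValueError(f"pathway absent: no route {source} -> {target}")
    paths = list(nx.all_simple_paths(g, source, target))
    if not paths:
        raise ValueError(f"pathway absent: no route {source} -> {target}")
    totals = set()
    for path in paths:
        total = 0.0
        for a, b in zip(path, path[1:]):
            rxn = network.reaction(g.edges[a, b]["reaction"])
            total += -float(rxn.cofactors.get("NADPH", 0.0))
        totals.add(round(total, 9))
    if len(totals) > 1:
        raise ValueError(
            f"multiple {source} -> {target} routes with differing NADPH "
            f"stoichiometry: {sorted(totals)}"
        )
    return totals.pop()


def nadph_per_proline(network: MetabolicNetwork) -> float:
    """Moles NADPH required per mole proline made from 2-oxoglutarate."""
    return nadph_along_path(network, "AKG", "PRO")


def nadph_per_phb_monomer(network: MetabolicNetwork) -> float:
    """Moles NADPH per 3-hydroxybutyrate monomer made from acetyl-CoA."""
    return nadph_along_path(network, "ACCOA", "PHB")


def co2_release(network: MetabolicNetwork, fluxes: FluxVector) -> float:
    """Net CO2 evolution: decarboxylations minus carboxylations (same scale
    as the fluxes, conventionally % of glucose uptake)."""
    total = 0.0
    for rxn in network.reactions:
        total += _cofactor_coefficient(rxn, "CO2", network) * fluxes.net.get(
            rxn.id, 0.0
        )
    return total


@dataclass
class AdenylatePools:
    """ATP/ADP/AMP pools (any common concentration unit)."""

    atp: float
    adp: float
    amp: float

    def __post_init__(self) -> None:
        if min(self.atp, self.adp, self.amp) < 0:
            raise ValueError("adenylate pools must be >= 0")
        if self.atp + self.adp + self.amp == 0:
            raise ValueError("adenylate pools are all zero")


def adenylate_energy_charge(pools: AdenylatePools) -> float:
    """Atkinson's adenylate energy charge (ATP + ADP/2)/(ATP + ADP + AMP)."""
    return (pools.atp + 0.5 * pools.adp) / (pools.atp + pools.adp + pools.amp)
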