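"""Carbon-mapped metabolic network model.

The model file dialect is a small CSV, one reaction per row::

    reaction_id,equation,reversible,kind,cofactors
    gnd,PG6 (abcdef) = RU5P (bcdef) + CO2 (a),0,free,NADPH:+1

* ``equation`` — substrates and products joined by ``=``, species joined by
  ``+``.  Every carbon-bearing species carries an atom-map string in
  parentheses; letters are arbitrary but unique within each side of the
  reaction and the substrate-side multiset must equal the product-side
  multiset (carbon conservation, asserted at load).  Symmetric metabolites
  (succinate, fumarate) may list equally weighted mapping alternatives
  separated by ``|``, e.g. ``FUM (abcd|dcba)``.
* ``reversible`` — 0/1.
* ``kind`` — one of ``free``, ``constrained``, ``measured-exchange``,
  ``biomass-drain``.
* ``cofactors`` — signed carbon-free bookkeeping, e.g. ``NADPH:-1;ATP:+1``.
  CO2 participates in carbon transfer and therefore appears in equations
  with an atom map rather than in this column.

Metabolite roles are inferred from topology: a species that is only
consumed is an external substrate, one that is only produced is a sink,
and everything else is balanced.  Substrates of biomass-drain reactions
are additionally tagged as biomass precursors.
"""

from __future__ import annotations

import csv
import itertools
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

CARBON_FREE_SPECIES = {"ATP", "ADP", "AMP", "NADH", "NADPH", "FADH2", "NH4", "Pi"}

REACTION_KINDS = ("free", "constrained", "measured-exchange", "biomass-drain")


class ModelError(ValueError):
    """Raised for malformed or carbon-imbalanced model files."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    n_carbons: int
    role: str = "balanced"  # balanced | substrate | sink | biomass-precursor

    def __post_init__(self) -> None:
        if self.n_carbons < 0:
            raise ModelError(f"metabolite {self.id}: negative carbon count")


@dataclass(frozen=True)
class MappingVariant:
    """One equally-weighted atom-mapping alternative of a reaction.

    ``substrates``/``products`` are tuples of (metabolite id, atom letters),
    one entry per molecule instance.
    """

    weight: float
    substrates: tuple[tuple[str, str], ...]
    products: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class Reaction:
    id: str
    variants: tuple[MappingVariant, ...]
    reversible: bool
    kind: str
    cofactors: dict[str, float] = field(default_factory=dict)

    @property
    def substrates(self) -> tuple[tuple[str, str], ...]:
        return self.variants[0].substrates

    @property
    def products(self) -> tuple[tuple[str, str], ...]:
        return self.variants[0].products

    def stoichiometry(self) -> dict[str, int]:
        """Net signed stoichiometric coefficient per metabolite."""
        coeffs: dict[str, int] = {}
        for met, _ in self.substrates:
            coeffs[met] = coeffs.get(met, 0) - 1
        for met, _ in self.products:
            coeffs[met] = coeffs.get(met, 0) + 1
        return coeffs


@dataclass
class MetabolicNetwork:
    metabolites: dict[str, Metabolite]
    reactions: list[Reaction]
    substrate_id: str
    uptake_reaction_id: str

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def balanced_metabolites(self) -> list[str]:
        order = []
        for r in self.reactions:
            for met, _ in r.substrates + r.products:
                role = self.metabolites[met].role
                if role in ("balanced", "biomass-precursor") and met not in order:
                    order.append(met)
        return order


_SPECIES_RE = re.compile(r"^\s*(?P<name>[A-Za-z0-9_]+)\s*(?:\(\s*(?P<map>[A-Za-z|]+)\s*\))?\s*$")


def _parse_side(side: str, rxn_id: str, line_no: int) -> list[tuple[str, list[str]]]:
    """Parse one equation side into (metabolite, mapping alternatives)."""
    out = []
    for token in side.split("+"):
        m = _SPECIES_RE.match(token)
        if not m:
            raise ModelError(
                f"line {line_no}: reaction {rxn_id}: cannot parse species {token!r}"
            )
        name = m.group("name")
        amap = m.group("map")
        if amap is None:
            if name not in CARBON_FREE_SPECIES:
                raise ModelError(
                    f"line {line_no}: reaction {rxn_id}: species {name!r} lacks an "
                    "atom map and is not a known carbon-free species"
                )
            continue
        alts = amap.split("|")
        if len({len(a) for a in alts}) != 1:
            raise ModelError(
                f"line {line_no}: reaction {rxn_id}: mapping alternatives for "
                f"{name} differ in length"
            )
        out.append((name, alts))
    return out


def _parse_cofactors(cell: str, rxn_id: str, line_no: int) -> dict[str, float]:
    cofactors: dict[str, float] = {}
    cell = cell.strip()
    if not cell:
        return cofactors
    for item in cell.split(";"):
        if not item.strip():
            continue
        try:
            name, value = item.split(":")
            cofactors[name.strip()] = float(value)
        except ValueError as exc:
            raise ModelError(
                f"line {line_no}: reaction {rxn_id}: bad cofactor entry {item!r}"
            ) from exc
    return cofactors


def _build_variants(
    subs: list[tuple[str, list[str]]],
    prods: list[tuple[str, list[str]]],
    rxn_id: str,
    line_no: int,
) -> tuple[MappingVariant, ...]:
    sub_alts = [[(name, a) for a in alts] for name, alts in subs]
    prod_alts = [[(name, a) for a in alts] for name, alts in prods]
    combos = list(itertools.product(*sub_alts, *prod_alts)) or [()]
    n_sub = len(subs)
    weight = 1.0 / len(combos)
    variants = []
    for combo in combos:
        variants.append(
            MappingVariant(
                weight=weight,
                substrates=tuple(combo[:n_sub]),
                products=tuple(combo[n_sub:]),
            )
        )
    return tuple(variants)


def _check_carbon_balance(rxn: Reaction, line_no: int | None = None) -> None:
    where = f"line {line_no}: " if line_no is not None else ""
    for variant in rxn.variants:
        sub_letters = "".join(a for _, a in variant.substrates)
        prod_letters = "".join(a for _, a in variant.products)
        if len(set(sub_letters)) != len(sub_letters):
            raise ModelError(
                f"{where}reaction {rxn.id}: repeated atom letter on substrate side"
            )
        if len(set(prod_letters)) != len(prod_letters):
            raise ModelError(
                f"{where}reaction {rxn.id}: repeated atom letter on product side"
            )
        if sorted(sub_letters) != sorted(prod_letters):
            raise ModelError(
                f"{where}reaction {rxn.id}: carbon imbalance — substrate atoms "
                f"{sorted(sub_letters)} != product atoms {sorted(prod_letters)}"
            )


def load_network(
    model_file: str | Path,
    substrate_id: str = "GLC",
) -> MetabolicNetwork:
    """Load and validate an atom-mapped network from a model CSV.

    Every reaction is checked for carbon conservation and consistent
    per-metabolite carbon counts; metabolite roles are inferred from the
    production/consumption topology.
    """
    path = Path(model_file)
    reactions: list[Reaction] = []
    carbon_counts: dict[str, int] = {}
    seen_ids: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"reaction_id", "equation", "reversible", "kind", "cofactors"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ModelError(
                f"{path}: header must contain columns {sorted(required)}"
            )
        for line_no, row in enumerate(reader, start=2):
            rid = row["reaction_id"].strip()
            if not rid or rid.startswith("#"):
                continue
            if rid in seen_ids:
                raise ModelError(f"line {line_no}: duplicate reaction id {rid!r}")
            seen_ids.add(rid)
            eq = row["equation"]
            if eq.count("=") != 1:
                raise ModelError(
                    f"line {line_no}: reaction {rid}: equation needs exactly one '='"
                )
            lhs, rhs = eq.split("=")
            subs = _parse_side(lhs, rid, line_no)
            prods = _parse_side(rhs, rid, line_no)
            kind = row["kind"].strip()
            if kind not in REACTION_KINDS:
                raise ModelError(
                    f"line {line_no}: reaction {rid}: unknown kind {kind!r}"
                )
            rxn = Reaction(
                id=rid,
                variants=_build_variants(subs, prods, rid, line_no),
                reversible=bool(int(row["reversible"])),
                kind=kind,
                cofactors=_parse_cofactors(row["cofactors"], rid, line_no),
            )
            _check_carbon_balance(rxn, line_no)
            for met, amap in rxn.substrates + rxn.products:
                prev = carbon_counts.setdefault(met, len(amap))
                if prev != len(amap):
                    raise ModelError(
                        f"line {line_no}: reaction {rid}: metabolite {met} has "
                        f"{len(amap)} carbons here but {prev} elsewhere"
                    )
            reactions.append(rxn)
    if not reactions:
        raise ModelError(f"{path}: no reactions found")

    produced = {m for r in reactions for m, _ in r.products}
    consumed = {m for r in reactions for m, _ in r.substrates}
    for r in reactions:
        if r.reversible:
            produced.update(m for m, _ in r.substrates)
            consumed.update(m for m, _ in r.products)
    drained = {
        m for r in reactions if r.kind == "biomass-drain" for m, _ in r.substrates
    }
    metabolites: dict[str, Metabolite] = {}
    for met, n_c in carbon_counts.items():
        if met in produced and met in consumed:
            role = "biomass-precursor" if met in drained else "balanced"
        elif met in consumed:
            role = "substrate"
        else:
            role = "sink"
        metabolites[met] = Metabolite(id=met, n_carbons=n_c, role=role)
    if substrate_id not in metabolites:
        raise ModelError(f"unknown substrate metabolite {substrate_id!r}")

    uptake = [
        r.id
        for r in reactions
        if any(m == substrate_id for m, _ in r.substrates)
        and r.kind == "measured-exchange"
    ]
    if not uptake:
        # fall back to the unique consumer of the substrate
        uptake = [
            r.id
            for r in reactions
            if any(m == substrate_id for m, _ in r.substrates)
        ]
    if len(uptake) != 1:
        raise ModelError(
            f"expected exactly one uptake reaction consuming {substrate_id}, "
            f"found {uptake}"
        )
    return MetabolicNetwork(
        metabolites=metabolites,
        reactions=reactions,
        substrate_id=substrate_id,
        uptake_reaction_id=uptake[0],
    )


def stoichiometric_matrix(network: MetabolicNetwork) -> np.ndarray:
    """Signed stoichiometric matrix S over (balanced metabolites x reactions).

    Row order follows first appearance in the model file, column order the
    file's reaction order, so two loads of the same file give bitwise
    identical matrices.
    """
    rows = network.balanced_metabolites
    index = {m: i for i, m in enumerate(rows)}
    S = np.zeros((len(rows), len(network.reactions)))
    for j, rxn in enumerate(network.reactions):
        for met, coeff in rxn.stoichiometry().items():
            i = index.get(met)
            if i is not None:
                S[i, j] = coeff
    return S


@dataclass
class BiomassComposition:
    """Condition-specific biomass precursor demands (mmol per g cell dry weight).

    ``nacl`` is the NaCl molarity of the condition; ``fractions`` optionally
    records macromolecule mass fractions (protein, RNA, lipid, PHB, other).
    """

    nacl: float
    demands: dict[str, float]
    fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for prec, d in self.demands.items():
            if d < 0:
                raise ModelError(f"negative demand for {prec}")
        if self.fractions and sum(self.fractions.values()) > 1 + 1e-9:
            raise ModelError("macromolecule fractions sum to more than 1")


def interpolate_biomass(
    compositions: list[BiomassComposition], nacl: float
) -> BiomassComposition:
    """Piecewise-linear interpolation of precursor demands over NaCl molarity.

    Demands are interpolated per precursor between the anchor conditions;
    queries beyond the last anchor are held constant (with a warning), which
    mirrors how condition-specific compositions measured at a few salt
    concentrations are extended to intermediate ones.
    """
    if not compositions:
        raise ValueError("empty anchor list")
    anchors = sorted(compositions, key=lambda c: c.nacl)
    xs = np.array([c.nacl for c in anchors])
    if nacl < xs[0] or nacl > xs[-1]:
        logger.warning(
            "NaCl %.3g M outside anchor range [%.3g, %.3g]; holding the nearest "
            "anchor constant",
            nacl,
            xs[0],
            xs[-1],
        )
    precursors: list[str] = []
    for c in anchors:
        for p in c.demands:
            if p not in precursors:
                precursors.append(p)
    demands = {
        p: float(np.interp(nacl, xs, [c.demands.get(p, 0.0) for c in anchors]))
        for p in precursors
    }
    fractions = {}
    keys = {k for c in anchors for k in c.fractions}
    for k in sorted(keys):
        fractions[k] = float(
            np.interp(nacl, xs, [c.fractions.get(k, 0.0) for c in anchors])
        )
    return BiomassComposition(nacl=nacl, demands=demands, fractions=fractions)


def load_biomass_compositions(path: str | Path) -> list[BiomassComposition]:
    """Read a biomass CSV (condition, precursor, demand_mmol_per_gCDW)."""
    rows: dict[float, dict[str, float]] = {}
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            cond = float(row["condition"])
            rows.setdefault(cond, {})[row["precursor"]] = float(
                row["demand_mmol_per_gCDW"]
            )
    return [BiomassComposition(nacl=c, demands=d) for c, d in sorted(rows.items())]


def _data_path(name: str) -> Path:
    return Path(resources.files("osmoflux") / "data" / name)


def shipped_model_path() -> Path:
    """Path of the packaged *B. megaterium* central-metabolism model CSV."""
    return _data_path("bmegaterium_model.csv")


def shipped_biomass_path() -> Path:
    return _data_path("biomass_composition.csv")
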