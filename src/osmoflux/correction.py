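"""Natural-isotope correction for TBDMS-derivatized GC-MS fragments.

A derivatized amino-acid fragment ion carries, besides the metabolically
labeled backbone carbons, a large shell of derivatization atoms (C, H, Si, O,
N, S) whose natural heavy isotopes shift the observed mass distribution.
The correction matrix C maps the carbon-skeleton MID x to the observed raw
MID: column j of C is the distribution of observed mass shifts given j
backbone 13C atoms — the convolution of the natural-isotope distributions of
every non-backbone atom and (by default) of the remaining unlabeled backbone
carbons at natural 13C abundance.  Measured raw MIDs are corrected by a
bounded non-negative least-squares solve of C x ~= raw followed by
renormalization, which is robust to truncated mass windows.

Isotope abundances are pinned in a versioned table shipped with the package
(data/isotopes.csv) so corrections are reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import nnls

from osmoflux.emu import EMU
from osmoflux.labeling import Fragment, MassIsotopomerDistribution, convolve
from osmoflux.model import MetabolicNetwork, _data_path

#: Default number of observed masses recorded beyond M+n_backbone.
DEFAULT_EXTRA_MASSES = 4


def natural_abundances(path: str | Path | None = None) -> dict[str, np.ndarray]:
    """Natural isotope mass-shift distributions per element."""
    path = Path(path) if path is not None else _data_path("isotopes.csv")
    table: dict[str, dict[int, float]] = {}
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            table.setdefault(row["element"], {})[int(row["mass_shift"])] = float(
                row["abundance"]
            )
    out = {}
    for element, shifts in table.items():
        vec = np.zeros(max(shifts) + 1)
        for shift, ab in shifts.items():
            vec[shift] = ab
        if abs(vec.sum() - 1.0) > 1e-6:
            raise ValueError(f"abundances for {element} sum to {vec.sum():.6f}")
        out[element] = vec
    return out


@dataclass(frozen=True)
class FragmentSpec:
    """Elemental composition of one derivatized fragment ion.

    ``elements`` counts every atom of the ion *except* the backbone carbons,
    which are listed separately via ``n_backbone`` (the metabolically traced
    carbons).  ``emus`` records which precursor EMUs the backbone derives
    from, e.g. ``"OAA:1234+PYR:23"`` for isoleucine.
    """

    amino_acid: str
    label: str
    n_backbone: int
    elements: dict[str, int]
    emus: str = ""

    def __post_init__(self) -> None:
        if self.n_backbone < 1:
            raise ValueError(f"{self.id}: fragment needs >= 1 backbone carbon")
        for el, count in self.elements.items():
            if count < 0:
                raise ValueError(f"{self.id}: negative {el} count")

    @property
    def id(self) -> str:
        return f"{self.amino_acid}_{self.label}"

    def to_fragment(self, network: MetabolicNetwork) -> Fragment:
        """Resolve the EMU composition against a network."""
        emus = []
        for part in self.emus.split("+"):
            met, idx = part.split(":")
            if met not in network.metabolites:
                raise KeyError(f"{self.id}: unknown metabolite {met}")
            emus.append(EMU(met, frozenset(int(c) for c in idx)))
        if sum(e.size for e in emus) != self.n_backbone:
            raise ValueError(f"{self.id}: EMU sizes do not add up to n_backbone")
        return Fragment(self.id, tuple(emus))


@dataclass
class CorrectionMatrix:
    """Natural-abundance correction matrix of one fragment.

    ``C[i, j]`` = probability of observing mass shift i given j backbone 13C.
    Rows are truncated to the observed mass window; ``column_mass`` keeps the
    untruncated column sums (1 for an untruncated matrix).
    """

    fragment_id: str
    C: np.ndarray
    column_mass: np.ndarray
    abundances: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def n_backbone(self) -> int:
        return self.C.shape[1] - 1

    @property
    def n_observed(self) -> int:
        return self.C.shape[0]

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.C))


def _self_convolve(dist: np.ndarray, n: int) -> np.ndarray:
    out = np.array([1.0])
    for _ in range(n):
        out = convolve(out, dist)
    return out


def correction_matrix(
    frag: FragmentSpec,
    abundances: dict[str, np.ndarray] | None = None,
    n_observed: int | None = None,
    include_backbone_na: bool = True,
) -> CorrectionMatrix:
    """Build the natural-isotope correction matrix for one fragment.

    ``include_backbone_na`` selects whether the (n_backbone - j) backbone
    carbons not carrying tracer label contribute natural 13C to column j
    (the default) or are treated as pure 12C.
    """
    ab = abundances if abundances is not None else natural_abundances()
    shell = np.array([1.0])
    for element, count in sorted(frag.elements.items()):
        if count == 0:
            continue
        if element not in ab:
            raise KeyError(f"{frag.id}: no abundance table for element {element}")
        shell = convolve(shell, _self_convolve(ab[element], count))
    n_back = frag.n_backbone
    n_obs = (
        n_observed
        if n_observed is not None
        else n_back + 1 + DEFAULT_EXTRA_MASSES
    )
    carbon_13 = ab["C"][1] if include_backbone_na else 0.0
    backbone_dist = np.array([1.0 - carbon_13, carbon_13])
    columns = []
    for j in range(n_back + 1):
        col = np.zeros(j)  # j labeled backbone carbons shift everything by j
        unlabeled = _self_convolve(backbone_dist, n_back - j)
        columns.append(np.concatenate([col, convolve(unlabeled, shell)]))
    width = max(len(c) for c in columns)
    full = np.zeros((width, n_back + 1))
    for j, col in enumerate(columns):
        full[: len(col), j] = col
    column_mass = full.sum(axis=0)
    return CorrectionMatrix(
        fragment_id=frag.id,
        C=full[: min(n_obs, width)],
        column_mass=column_mass,
        abundances=ab,
    )


class IllConditionedError(RuntimeError):
    pass


def correct_mid(
    raw: MassIsotopomerDistribution,
    C: CorrectionMatrix,
    cond_limit: float = 1e8,
) -> MassIsotopomerDistribution:
    """Carbon-skeleton MID from a raw observed MID.

    Solves ``C x ~= raw`` by non-negative least squares and renormalizes to
    the simplex.  Standard deviations, when present, are propagated through
    the linearized (pseudo-inverse) solution.
    """
    if len(raw.m) < C.C.shape[0]:
        raise ValueError(
            f"{raw.fragment_id}: raw MID has {len(raw.m)} masses, "
            f"correction matrix expects {C.C.shape[0]}"
        )
    cond = C.condition_number()
    if cond > cond_limit:
        raise IllConditionedError(
            f"{C.fragment_id}: correction matrix condition number {cond:.3g} "
            f"exceeds {cond_limit:.3g}"
        )
    y = raw.m[: C.C.shape[0]]
    x, _ = nnls(C.C, y)
    total = x.sum()
    if total <= 0:
        raise ValueError(f"{raw.fragment_id}: corrected MID collapsed to zero")
    x = x / total
    sd = None
    if raw.sd is not None:
        P = np.linalg.pinv(C.C)
        sd = np.sqrt((P**2) @ (raw.sd[: C.C.shape[0]] ** 2))
    return MassIsotopomerDistribution(raw.fragment_id, x, sd)


def uncorrect_mid(
    skeleton: MassIsotopomerDistribution, C: CorrectionMatrix
) -> MassIsotopomerDistribution:
    """Forward application C.x: raw observed MID over the recorded mass window.

    The simplex is preserved exactly for an untruncated matrix; a truncated
    window loses the tail mass beyond the last recorded isotopologue.
    """
    if len(skeleton.m) != C.C.shape[1]:
        raise ValueError(
            f"{skeleton.fragment_id}: skeleton MID length {len(skeleton.m)} != "
            f"n_backbone+1 = {C.C.shape[1]}"
        )
    raw = C.C @ skeleton.m
    sd = None
    if skeleton.sd is not None:
        sd = np.sqrt((C.C**2) @ (skeleton.sd**2))
    return MassIsotopomerDistribution(
        skeleton.fragment_id, raw, sd, normalized=False
    )


def load_fragment_panel(path: str | Path | None = None) -> list[FragmentSpec]:
    """The TBDMS fragment panel (default: the shipped [M-57]/[M-159] table).

    The default panel covers Ala, Gly, Val, Leu, Ile, Ser, Thr, Asp, Glu,
    Phe, Tyr and Pro; Gln and Asn pool into Glu and Asp under acid
    hydrolysis, Cys and Trp are hydrolysis-labile and excluded.
    """
    path = Path(path) if path is not None else _data_path("fragments.csv")
    specs = []
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            n_backbone = int(row["n_backbone"])
            elements = {
                el: int(row[el]) - (n_backbone if el == "C" else 0)
                for el in ("C", "H", "N", "O", "Si", "S")
            }
            specs.append(
                FragmentSpec(
                    amino_acid=row["amino_acid"],
                    label=row["fragment"],
                    n_backbone=n_backbone,
                    elements=elements,
                    emus=row["emus"],
                )
            )
    return specs
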