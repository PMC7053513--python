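"""Independent reference implementations used only by the tests.

These deliberately avoid the package's EMU machinery: the labeling oracle
enumerates full positional isotopomer distributions (2^n states per
metabolite) and solves the steady-state balance by fixed-point iteration,
tracing atoms directly from the reaction mapping variants.  Tractable for
toy networks up to ~6 carbons.
"""

from __future__ import annotations

import itertools

import numpy as np


def _direction_sides(variant, direction):
    if direction == "f":
        return variant.substrates, variant.products
    return variant.products, variant.substrates


def enumerate_isotopomers(network, fluxes, tracer, tol=1e-14, max_iter=20000):
    """Full isotopomer fractions per balanced metabolite by fixed point.

    Returns {metabolite: vector of length 2^n}, bit i (LSB) = carbon i+1
    is 13C.  Substrate isotopomer fractions come straight from the tracer
    patterns.
    """
    state: dict[str, np.ndarray] = {}
    # substrate distributions
    for met, info in network.metabolites.items():
        if info.role == "substrate":
            vec = np.zeros(2 ** info.n_carbons)
            for pattern, fraction in tracer.species:
                idx = sum(
                    1 << i for i, ch in enumerate(pattern) if ch == "1"
                )
                vec[idx] += fraction
            state[met] = vec
    balanced = [
        m
        for m, info in network.metabolites.items()
        if info.role in ("balanced", "biomass-precursor")
    ]
    for met in balanced:
        n = network.metabolites[met].n_carbons
        state[met] = np.full(2**n, 1.0 / 2**n)

    def flux_of(rxn, direction):
        return fluxes.forward(rxn.id) if direction == "f" else fluxes.backward(rxn.id)

    # consumption totals
    def consumption(met):
        total = 0.0
        for rxn in network.reactions:
            for direction in ["f"] + (["b"] if rxn.reversible else []):
                consumed, _ = _direction_sides(rxn.variants[0], direction)
                count = sum(1 for m, _ in consumed if m == met)
                total += flux_of(rxn, direction) * count
        return total

    cons = {met: consumption(met) for met in balanced}

    for _ in range(max_iter):
        new = {}
        for met in balanced:
            n = network.metabolites[met].n_carbons
            acc = np.zeros(2**n)
            for rxn in network.reactions:
                for direction in ["f"] + (["b"] if rxn.reversible else []):
                    f_dir = flux_of(rxn, direction)
                    if f_dir == 0.0:
                        continue
                    for variant in rxn.variants:
                        consumed, produced = _direction_sides(variant, direction)
                        for pmet, pamap in produced:
                            if pmet != met:
                                continue
                            # atom origin: product atom k -> (instance, pos)
                            origins = []
                            for k in range(n):
                                letter = pamap[k]
                                for inst, (smet, samap) in enumerate(consumed):
                                    pos = samap.find(letter)
                                    if pos >= 0:
                                        origins.append((inst, pos))
                                        break
                            dists = [state[m] for m, _ in consumed]
                            sizes = [len(a) for _, a in consumed]
                            contribution = np.zeros(2**n)
                            for combo in itertools.product(
                                *[range(2**s) for s in sizes]
                            ):
                                p = 1.0
                                for d, idx in zip(dists, combo):
                                    p *= d[idx]
                                if p == 0.0:
                                    continue
                                target = 0
                                for k, (inst, pos) in enumerate(origins):
                                    if (combo[inst] >> pos) & 1:
                                        target |= 1 << k
                                contribution[target] += p
                            acc += f_dir * variant.weight * contribution
            new[met] = acc / cons[met]
        delta = max(
            float(np.max(np.abs(new[m] - state[m]))) for m in balanced
        )
        state.update(new)
        if delta < tol:
            break
    else:  # pragma: no cover
        raise RuntimeError("isotopomer fixed point did not converge")
    return state


def isotopomer_mid(state_vec: np.ndarray, atoms: set[int]) -> np.ndarray:
    """Marginalize a 2^n isotopomer vector to the MID of a carbon subset."""
    n = int(np.log2(len(state_vec)))
    mid = np.zeros(len(atoms) + 1)
    for iso, p in enumerate(state_vec):
        shift = sum(1 for a in atoms if (iso >> (a - 1)) & 1)
        mid[shift] += p
    return mid


def sympy_rank_and_nullity(matrix: np.ndarray) -> tuple[int, int]:
    """Rank/nullity by exact-ish elimination through sympy."""
    from sympy import Matrix, Rational, nsimplify

    M = Matrix(
        [[nsimplify(Rational(str(round(x, 9)))) for x in row] for row in matrix]
    )
    rank = M.rank()
    return rank, matrix.shape[1] - rank
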