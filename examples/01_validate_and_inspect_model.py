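"""Load the shipped B. megaterium central-metabolism model and inspect it.

Prints the model size, the rank of the stoichiometric matrix (which fixes
how many free fluxes a fit must determine), and the NADPH stoichiometry of
the proline and PHB branches.
"""

import numpy as np

from osmoflux import (
    load_network,
    nadph_per_phb_monomer,
    nadph_per_proline,
    shipped_model_path,
    stoichiometric_matrix,
)

network = load_network(shipped_model_path())
S = stoichiometric_matrix(network)
rank = np.linalg.matrix_rank(S)

print(f"reactions:            {len(network.reactions)}")
print(f"balanced metabolites: {len(network.balanced_metabolites)}")
print(f"rank(S):              {rank}")
print(f"free fluxes (no constraints): {len(network.reactions) - rank}")
print(f"NADPH per proline (from 2-oxoglutarate): {nadph_per_proline(network):.0f}")
print(f"NADPH per PHB monomer (from acetyl-CoA): {nadph_per_phb_monomer(network):.0f}")
# The two pathway numbers are the cofactor costs that make proline and PHB
# synthesis sinks for the NADPH formed in the oxidative PPP under salt stress.
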