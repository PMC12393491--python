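"""Network-control transition energies and the energy landscape.

Models activity as linear dynamics on a stabilized structural
connectome and computes the optimal-control energy of steering the
system between brain states (rho = 1, S = I, B = I, horizon T = 1).
Exit/enter energy asymmetries classify each state as a local minimum
(sink-like) or maximum (source-like) of the landscape.
"""

import numpy as np

from capdyn.control import (
    exit_enter_energies,
    normalize_adjacency,
    transition_energy_matrix,
)
from capdyn.synthetic import generate_connectome, generate_state_patterns

connectome = generate_connectome(85, seed=0, subject_id="sub-demo")
system = normalize_adjacency(connectome, c=1.0)
print(f"stabilized system: spectrum in "
      f"[{np.linalg.eigvalsh(system.a_norm).min():.3f}, "
      f"{np.linalg.eigvalsh(system.a_norm).max():.3f}] (all negative: stable)")

centroids = generate_state_patterns(4, 85, seed=1)
totals, nodal = transition_energy_matrix(system, centroids)
print("\ntotal transition energy (row: from-state, col: to-state, a.u.):")
print(np.round(totals, 1))
print("\n(the matrix is asymmetric: moving i->j generally costs a")
print(" different amount than j->i; diagonal entries are the cost of")
print(" holding a state against the passive decay of the dynamics)")

landscape = exit_enter_energies(totals)
print("\nenergy landscape:")
print(landscape.table.round(1).to_string(index=False))
print("\nsink-like: exit > enter (a local minimum, costly to leave);")
print("source-like: enter > exit (a local maximum, costly to reach).")
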