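"""Independent brute-force oracles used to cross-check the closed forms.

These deliberately avoid the package's statistical-weight shortcut: the
binding-site oracle sums Boltzmann factors over all 2^4 site-occupancy
microstates from the coupling *energies*, and the heteromer oracle counts
subunit-type assignments and ligand placements one by one.
"""

from itertools import combinations, product
from math import comb, exp

import numpy as np

KB = 0.0019872041  # kcal/(mol K)


def microstate_probabilities(delta_e, j, k, m, concentration, temperature=298.0):
    """Boltzmann sum over every occupancy pattern of four equivalent sites.

    A pattern with ``n`` occupied sites has energy
    n*delta_e + C(n,2)*j + C(n,3)*k + C(n,4)*m (kcal/mol) and carries one
    factor of the dimensionless activity x = exp(-beta*0)*[L]/1M per bound
    ligand.  Returns the aggregated probabilities p0..p4.
    """
    beta = 1.0 / (KB * temperature)
    x = concentration / 1.0  # activity of the free ligand, reference 1 M
    weights = np.zeros(5)
    for pattern in product((0, 1), repeat=4):
        n = sum(pattern)
        energy = n * delta_e + comb(n, 2) * j + comb(n, 3) * k + comb(n, 4) * m
        weights[n] += x ** n * exp(-beta * energy)
    return weights / weights.sum()


def heteromer_multiplicities(n_subunits=4):
    """Count (bound-ligand) microstates of a WT/mutant tetramer mixture.

    Enumerates every assignment of subunit types to the four positions and
    every subset of wild-type positions holding a ligand.  Returns the
    aggregate counts g0..g4 (16, 32, 24, 8, 1 for the tetramer).
    """
    counts = np.zeros(n_subunits + 1, dtype=int)
    for types in product(("wt", "mut"), repeat=n_subunits):
        wt_positions = [i for i, t in enumerate(types) if t == "wt"]
        for n_bound in range(len(wt_positions) + 1):
            counts[n_bound] += sum(1 for _ in combinations(wt_positions, n_bound))
    return counts


def bisect_half_response(curve, target, lo, hi, iters=200):
    """Plain bisection root finder for response(conc) == target."""
    flo = curve(lo) - target
    for _ in range(iters):
        mid = (lo * hi) ** 0.5  # geometric midpoint: concentrations span decades
        fmid = curve(mid) - target
        if flo * fmid <= 0:
            hi = mid
        else:
            lo, flo = mid, fmid
    return (lo * hi) ** 0.5
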