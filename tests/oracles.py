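"""Independent brute-force oracles used to freeze expected values.

Each oracle deliberately avoids the implementation path it checks: masses
are summed atom-by-atom from formula strings, binding equilibria are solved
by bisection/nested bisection on the raw mass-balance equations, and rigid
superposition is found by numerical search over rotation vectors.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

# --- elemental mass oracle -------------------------------------------------

# Residue formulas written as plain strings and parsed per atom; atomic
# masses entered here independently of the package's constant table.
RESIDUE_FORMULAS = {
    "G": "C2H3NO", "A": "C3H5NO", "S": "C3H5NO2", "P": "C5H7NO",
    "V": "C5H9NO", "T": "C4H7NO2", "C": "C3H5NOS", "L": "C6H11NO",
    "I": "C6H11NO", "N": "C4H6N2O2", "D": "C4H5NO3", "Q": "C5H8N2O2",
    "K": "C6H12N2O", "E": "C5H7NO3", "M": "C5H9NOS", "H": "C6H7N3O",
    "F": "C9H9NO", "R": "C6H12N4O", "Y": "C9H9NO2", "W": "C11H10N2O",
}
ATOM_MONO = {"C": 12.0, "H": 1.0078250319, "N": 14.0030740052,
             "O": 15.9949146221, "S": 31.97207069}
ATOM_AVG = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06}


def _parse_formula(formula: str) -> dict[str, int]:
    import re

    counts: dict[str, int] = {}
    for el, num in re.findall(r"([A-Z])(\d*)", formula):
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    return counts


def oracle_mass(seq: str, table=ATOM_MONO, n_disulfides: int = 0,
                amide: bool = False, n15: bool = False, c13: bool = False) -> float:
    total = 0.0
    n_atoms = {"C": 0, "H": 0, "N": 0, "O": 0, "S": 0}
    for aa in seq:
        for el, k in _parse_formula(RESIDUE_FORMULAS[aa]).items():
            n_atoms[el] += k
    n_atoms["H"] += 2
    n_atoms["O"] += 1
    n_atoms["H"] -= 2 * n_disulfides
    if amide:
        n_atoms["O"] -= 1
        n_atoms["H"] += 1
        n_atoms["N"] += 1
    for el, k in n_atoms.items():
        total += k * table[el]
    if n15:
        total += n_atoms["N"] * (15.0001088984 - 14.0030740052)
    if c13:
        total += n_atoms["C"] * (13.0033548378 - 12.0)
    return total


# --- binding equilibrium oracles ------------------------------------------

def bisect(f, lo, hi, maxit=200):
    # fixed-iteration bisection: 200 halvings exhaust double precision on
    # any bracket, including sub-nanomolar ones
    flo = f(lo)
    for _ in range(maxit):
        mid = (lo + hi) / 2.0
        if mid == lo or mid == hi:
            break
        fm = f(mid)
        if fm == 0:
            return mid
        if (flo < 0) == (fm < 0):
            lo, flo = mid, fm
        else:
            hi = mid
    return (lo + hi) / 2.0


def oracle_bound_fraction(p_tot, l_tot, kd):
    """Bisection on [PL]*Kd = ([P]-[PL])([L]-[PL])."""
    if l_tot == 0:
        return 0.0

    def f(pl):
        return pl * kd - (p_tot - pl) * (l_tot - pl)

    pl = bisect(f, 0.0, min(p_tot, l_tot))
    return pl / l_tot


def oracle_competitive(p_tot, a_tot, b_tot, kd_a, kd_b):
    """Nested bisection on the two complex concentrations."""

    def pa_given(pb):
        def f(pa):
            return pa * kd_a - (p_tot - pa - pb) * (a_tot - pa)

        hi = min(a_tot, max(p_tot - pb, 0.0))
        if hi <= 0:
            return 0.0
        return bisect(f, 0.0, hi)

    def g(pb):
        pa = pa_given(pb)
        return pb * kd_b - (p_tot - pa - pb) * (b_tot - pb)

    if b_tot == 0:
        pa = pa_given(0.0)
        return p_tot - pa, pa, 0.0
    pb = bisect(g, 0.0, min(b_tot, p_tot))
    pa = pa_given(pb)
    return p_tot - pa - pb, pa, pb


# --- superposition oracle --------------------------------------------------

def oracle_superpose_rmsd(mobile: np.ndarray, reference: np.ndarray,
                          n_starts: int = 12, seed: int = 0) -> float:
    """Minimum RMSD over rigid motions via rotation-vector search.

    For a fixed rotation the optimal translation matches centroids, so the
    search is 3-dimensional; multiple random starts guard against local
    minima.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)

    def cost(rotvec):
        rot = Rotation.from_rotvec(rotvec).as_matrix()
        d = mc @ rot.T - rc
        return float((d * d).sum(axis=1).mean())

    rng = np.random.default_rng(seed)
    best = np.inf
    starts = [np.zeros(3)] + [rng.uniform(-np.pi, np.pi, 3) for _ in range(n_starts)]
    for x0 in starts:
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 5000})
        best = min(best, res.fun)
    return float(np.sqrt(best))
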