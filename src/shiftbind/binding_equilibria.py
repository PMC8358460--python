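"""Single-site binding equilibria and thermodynamic identities.

Two solvers shared by the NMR titration and ITC modules:

* ``bound_fraction_1to1`` — the exact 1:1 isotherm.  With receptor total
  ``P``, ligand total ``L`` and dissociation constant ``Kd``, the complex
  concentration is the physical root of ``[PL]^2 - (P+L+Kd)[PL] + PL = 0``,
  evaluated in a cancellation-safe form.

* ``competitive_equilibrium`` — one site, two ligands (A and B) competing for
  the same receptor.  Free receptor ``p`` satisfies the monotone mass balance

      p + p*A/(Kd_A + p) + p*B/(Kd_B + p) = N*P_tot

  which is solved by safeguarded bracketing (robust across all magnitudes,
  unlike the raw cubic formula).

Energies use ``dG = R T ln Kd`` (1 M standard state) with
``R = 1.987204e-3 kcal/mol/K`` and the exact identity ``-T dS = dG - dH``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "BindingParameters",
    "SpeciesState",
    "bound_fraction_1to1",
    "competitive_equilibrium",
    "delta_g_from_kd",
    "entropy_term",
    "R_KCAL",
]

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.987204e-3


@dataclass(frozen=True)
class BindingParameters:
    """Kd/dH/N for one or two ligands of a single receptor site.

    Concentrations molar, enthalpies kcal/mol.  ``kd_b``/``dh_b`` describe an
    optional competitor sharing the site.
    """

    kd_a: float
    dh_a: float = 0.0
    kd_b: float | None = None
    dh_b: float = 0.0
    n: float = 1.0

    def __post_init__(self) -> None:
        if self.kd_a <= 0:
            raise ValueError("kd_a must be positive")
        if self.kd_b is not None and self.kd_b <= 0:
            raise ValueError("kd_b must be positive")
        if self.n <= 0:
            raise ValueError("stoichiometry n must be positive")


@dataclass(frozen=True)
class SpeciesState:
    """Solved species concentrations (molar) of the one-site two-ligand system."""

    p_tot: float
    a_tot: float
    b_tot: float
    p_free: float
    pa: float
    pb: float

    @property
    def fraction_a_bound(self) -> float:
        return self.pa / self.a_tot if self.a_tot > 0 else 0.0

    @property
    def fraction_b_bound(self) -> float:
        return self.pb / self.b_tot if self.b_tot > 0 else 0.0


def bound_fraction_1to1(
    p_tot: float, l_tot: float, kd: float, n_sites: float = 1.0
) -> float:
    """Fraction of ligand bound for the exact 1:1 single-site isotherm.

    ``n_sites`` scales the receptor into an effective site concentration
    ``n_sites * p_tot``.  Returns 0 when ``l_tot`` is 0 by convention.
    """
    if p_tot < 0 or l_tot < 0:
        raise ValueError("concentrations must be non-negative")
    if kd <= 0:
        raise ValueError("Kd must be positive")
    if l_tot == 0:
        return 0.0
    p = n_sites * p_tot
    b = p + l_tot + kd
    disc = b * b - 4.0 * p * l_tot
    # [PL] = (b - sqrt(disc))/2, rewritten to avoid cancellation when the
    # root is small relative to b.
    pl = 2.0 * p * l_tot / (b + math.sqrt(max(disc, 0.0)))
    return min(pl / l_tot, 1.0)


def competitive_equilibrium(
    p_tot: float,
    a_tot: float,
    b_tot: float,
    kd_a: float,
    kd_b: float,
    n_sites: float = 1.0,
    rtol: float = 1e-12,
) -> SpeciesState:
    """Exact one-site/two-ligand equilibrium by monotone bracketing.

    Solves for free receptor on ``[0, n_sites*p_tot]``; the mass-balance
    residual of the returned state is below 1e-9 relative (asserted).
    """
    if min(p_tot, a_tot, b_tot) < 0:
        raise ValueError("totals must be non-negative")
    if kd_a <= 0 or kd_b <= 0:
        raise ValueError("Kd values must be positive")
    p_sites = n_sites * p_tot
    if p_sites == 0:
        return SpeciesState(p_tot, a_tot, b_tot, 0.0, 0.0, 0.0)

    def balance(p: float) -> float:
        return p + p * a_tot / (kd_a + p) + p * b_tot / (kd_b + p) - p_sites

    p_free = brentq(balance, 0.0, p_sites, xtol=1e-300, rtol=max(rtol, 1e-15))
    pa = p_free * a_tot / (kd_a + p_free)
    pb = p_free * b_tot / (kd_b + p_free)
    resid = abs(p_free + pa + pb - p_sites) / p_sites
    if resid > 1e-9:
        raise RuntimeError(
            f"equilibrium solver failed to converge: relative residual {resid:.3e}"
        )
    return SpeciesState(p_tot, a_tot, b_tot, p_free, pa, pb)


def delta_g_from_kd(kd: float, temperature: float) -> float:
    """Binding free energy dG = R T ln(Kd) in kcal/mol (1 M standard state)."""
    if kd <= 0 or temperature <= 0:
        raise ValueError("Kd and temperature must be positive")
    return R_KCAL * temperature * math.log(kd)


def entropy_term(dg: float, dh: float) -> float:
    """Entropic contribution -T dS = dG - dH, exactly."""
    if not (math.isfinite(dg) and math.isfinite(dh)):
        raise ValueError("dG and dH must be finite")
    return dg - dh
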