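"""Equilibrium statistical-thermodynamic model of activator binding to a
tetrameric ion channel.

A channel with four equivalent activator sites populates five binding
configurations CF0..CF4 (0–4 ligands bound).  Each configuration ``k`` has a
statistical weight

    g_k * w_k * x**k,       x = K_A * [L]  (dimensionless activity,
                                            reference concentration 1 M)

where ``g_k`` is the configuration multiplicity (1,4,6,4,1 for a homomeric
tetramer), and the cooperativity factor

    w_k = gamma**C(k,2) * mu**C(k,3) * nu**C(k,4)

collects the Boltzmann factors of the pairwise (J), triple (K) and quadruple
(M) coupling energies: ``gamma = exp(-beta*J)`` etc.  Occupancy probabilities
are the normalized weights; the measurable normalized current potentiation is
the conductance-weighted sum ``a*p1 + b*p2 + c*p3 + d*p4``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from math import comb
from typing import NamedTuple

import numpy as np

__all__ = [
    "KB_KCAL_PER_MOL_K",
    "DEFAULT_TEMPERATURE_K",
    "ThermoParams",
    "EnergyParams",
    "BindingCoefficients",
    "DegeneracyVector",
    "OccupancyProfile",
    "WT_DEGENERACIES",
    "ZTZ240_KCNQ2_BEST_FIT",
    "coop_weight",
    "statistical_weights",
    "occupancy_probabilities",
    "occupancy_curve",
    "response",
    "average_occupancy",
    "energies_to_coefficients",
    "coefficients_to_energies",
    "kd",
    "ec50",
]

#: Boltzmann constant times Avogadro's number, kcal / (mol K).
KB_KCAL_PER_MOL_K = 0.0019872041

#: Room temperature used for energy <-> coefficient conversions.
DEFAULT_TEMPERATURE_K = 298.0


@dataclass(frozen=True)
class ThermoParams:
    """The eight-parameter set of the binding model.

    Parameters
    ----------
    k_a
        Association constant of one ligand for one subunit site, per molar.
    gamma, mu, nu
        Dimensionless cooperativity coefficients for two, three and four
        simultaneously bound ligands (Boltzmann factors of the coupling
        energies; values > 1 mean favourable coupling).
    a, b, c, d
        Conductance coefficients of configurations CF1..CF4: the fraction of
        maximal current each configuration carries, in ``(0, bound]``.
    conductance_bound
        Upper bound enforced on a–d (default 1, i.e. fractions of the
        maximal conductance).
    """

    k_a: float
    gamma: float
    mu: float
    nu: float
    a: float
    b: float
    c: float
    d: float
    conductance_bound: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_a", "gamma", "mu", "nu", "a", "b", "c", "d"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v <= 0.0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
            object.__setattr__(self, name, v)
        for name in ("a", "b", "c", "d"):
            if getattr(self, name) > self.conductance_bound:
                raise ValueError(
                    f"conductance coefficient {name}={getattr(self, name)} "
                    f"exceeds bound {self.conductance_bound}"
                )

    @property
    def conductances(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    def to_dict(self) -> dict[str, float]:
        return {
            "k_a": self.k_a, "gamma": self.gamma, "mu": self.mu, "nu": self.nu,
            "a": self.a, "b": self.b, "c": self.c, "d": self.d,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThermoParams":
        return cls(**{k: float(d[k]) for k in
                      ("k_a", "gamma", "mu", "nu", "a", "b", "c", "d")})


class BindingCoefficients(NamedTuple):
    """Binding part of the parameter set (no conductances)."""

    k_a: float
    gamma: float
    mu: float
    nu: float


@dataclass(frozen=True)
class EnergyParams:
    """Energy representation of the binding parameters, in kcal/mol.

    ``delta_e`` is the binding free energy of one ligand to one site;
    ``j``, ``k``, ``m`` are the pair, triple and quadruple coupling energies.
    Negative energies are favourable.  Related to the coefficient
    representation by ``K_A = exp(-delta_e / (k_B T))`` and likewise for
    gamma/mu/nu.
    """

    delta_e: float
    j: float
    k: float
    m: float
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def beta(self) -> float:
        """1 / (k_B T), mol/kcal."""
        return 1.0 / (KB_KCAL_PER_MOL_K * self.temperature)


def energies_to_coefficients(energies: EnergyParams) -> BindingCoefficients:
    """Convert coupling energies (kcal/mol) to binding coefficients.

    ``K_A = exp(-beta * delta_e)`` and analogously gamma, mu, nu from
    j, k, m.  With all energies zero every coefficient is 1.
    """
    b = energies.beta
    return BindingCoefficients(
        k_a=math.exp(-b * energies.delta_e),
        gamma=math.exp(-b * energies.j),
        mu=math.exp(-b * energies.k),
        nu=math.exp(-b * energies.m),
    )


def coefficients_to_energies(
    params: ThermoParams | BindingCoefficients,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> EnergyParams:
    """Inverse of :func:`energies_to_coefficients`: energies in kcal/mol."""
    if not (temperature > 0):
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    kt = KB_KCAL_PER_MOL_K * temperature
    return EnergyParams(
        delta_e=-kt * math.log(params.k_a),
        j=-kt * math.log(params.gamma),
        k=-kt * math.log(params.mu),
        m=-kt * math.log(params.nu),
        temperature=temperature,
    )


@dataclass(frozen=True)
class DegeneracyVector:
    """Multiplicities g0..g4 of the five binding configurations.

    For a homomeric tetramer these are the binomial counts (1, 4, 6, 4, 1).
    Heteromeric ensembles aggregate several subunit compositions and carry
    different (possibly non-integer, after rescaling) multiplicities; only
    the ratios matter for the probabilities.
    """

    g: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        g = tuple(float(v) for v in self.g)
        if len(g) != 5:
            raise ValueError("exactly five multiplicities g0..g4 required")
        if any(not math.isfinite(v) or v < 0 for v in g):
            raise ValueError(f"multiplicities must be finite and >= 0: {g}")
        if g[4] < 1.0:
            raise ValueError("g4 must be >= 1 (fully liganded state present)")
        if sum(v > 0 for v in g) < 2:
            raise ValueError("at least two configurations must be populated")
        object.__setattr__(self, "g", g)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.g, dtype=float)

    def __iter__(self):
        return iter(self.g)

    def __getitem__(self, k: int) -> float:
        return self.g[k]


#: Homomeric (wild-type) tetramer: binomial multiplicities.
WT_DEGENERACIES = DegeneracyVector((1, 4, 6, 4, 1))

#: Published best-fit parameter set for ztz240 potentiating wild-type KCNQ2.
ZTZ240_KCNQ2_BEST_FIT = ThermoParams(
    k_a=1.805e5, gamma=0.928, mu=0.4529, nu=65.24,
    a=0.3083, b=0.2375, c=0.4011, d=0.9863,
)


@dataclass(frozen=True)
class OccupancyProfile:
    """Configuration probabilities p0..p4 at one ligand concentration."""

    concentration: float
    p: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0 M")
        p = tuple(float(v) for v in self.p)
        if len(p) != 5 or any(v < -1e-12 or v > 1 + 1e-12 for v in p):
            raise ValueError(f"probabilities must lie in [0, 1]: {p}")
        if abs(sum(p) - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {sum(p)}")
        object.__setattr__(self, "p", p)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.p, dtype=float)

    def __getitem__(self, k: int) -> float:
        return self.p[k]


def coop_weight(k: int, params: ThermoParams) -> float:
    """Cooperativity factor w_k = gamma^C(k,2) * mu^C(k,3) * nu^C(k,4).

    w0 = w1 = 1 (no coupling below two bound ligands); w2 = gamma;
    w3 = gamma^3 * mu; w4 = gamma^6 * mu^4 * nu.
    """
    if not isinstance(k, (int, np.integer)) or isinstance(k, bool):
        raise TypeError(f"configuration index must be an integer, got {k!r}")
    if not 0 <= k <= 4:
        raise ValueError(f"configuration index must be in 0..4, got {k}")
    return params.gamma ** comb(k, 2) * params.mu ** comb(k, 3) * params.nu ** comb(k, 4)


def _weight_matrix(
    params: ThermoParams, degeneracies: DegeneracyVector, concentration
) -> np.ndarray:
    """Statistical weights g_k w_k x^k, shape (5,) or (5, n)."""
    conc = np.asarray(concentration, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be >= 0 M")
    x = params.k_a * conc  # activity relative to the 1 M reference
    w = np.array([coop_weight(k, params) for k in range(5)])
    g = degeneracies.as_array()
    k = np.arange(5)
    if conc.ndim == 0:
        return g * w * x ** k
    return g[:, None] * w[:, None] * x[None, :] ** k[:, None]


def statistical_weights(
    params: ThermoParams, degeneracies: DegeneracyVector, concentration: float
) -> np.ndarray:
    """Unnormalized weights of CF0..CF4 at one concentration (Z-terms)."""
    return _weight_matrix(params, degeneracies, float(concentration))


def occupancy_probabilities(
    params: ThermoParams, degeneracies: DegeneracyVector, concentration: float
) -> OccupancyProfile:
    """Probabilities of the five binding configurations at one concentration.

    p_k = g_k w_k x^k / sum_j g_j w_j x^j with x = K_A * [L].  At zero
    concentration only the unliganded configuration is populated.
    """
    terms = _weight_matrix(params, degeneracies, float(concentration))
    # scale by the dominant term so extreme parameters cannot overflow the sum
    terms = terms / terms.max()
    p = terms / terms.sum()
    return OccupancyProfile(concentration=float(concentration), p=tuple(p))


def occupancy_curve(
    params: ThermoParams, degeneracies: DegeneracyVector, concentrations
) -> np.ndarray:
    """Probabilities at many concentrations; returns an (n, 5) array."""
    conc = np.atleast_1d(np.asarray(concentrations, dtype=float))
    terms = _weight_matrix(params, degeneracies, conc)
    terms = terms / terms.max(axis=0, keepdims=True)
    return (terms / terms.sum(axis=0, keepdims=True)).T


def response(
    params: ThermoParams, degeneracies: DegeneracyVector, concentration
):
    """Normalized current potentiation a*p1 + b*p2 + c*p3 + d*p4.

    Accepts a scalar concentration (returns a float) or an array (returns an
    array).  Tends to ``d`` as the concentration grows without bound.
    """
    conduct = np.array([0.0, params.a, params.b, params.c, params.d])
    conc = np.asarray(concentration, dtype=float)
    if conc.ndim == 0:
        return float(occupancy_probabilities(params, degeneracies, float(conc)).as_array() @ conduct)
    return occupancy_curve(params, degeneracies, conc) @ conduct


def average_occupancy(
    params: ThermoParams, degeneracies: DegeneracyVector, concentration
):
    """Mean number of bound ligands, <N> = sum_k k * p_k.

    Equals the thermodynamic identity x * d(ln Z)/dx for the binding
    polynomial Z = sum_k g_k w_k x^k; ranges from 0 to 4 and is
    nondecreasing in concentration.
    """
    k = np.arange(5, dtype=float)
    conc = np.asarray(concentration, dtype=float)
    if conc.ndim == 0:
        return float(occupancy_probabilities(params, degeneracies, float(conc)).as_array() @ k)
    return occupancy_curve(params, degeneracies, conc) @ k


def kd(params: ThermoParams) -> float:
    """Dissociation constant K_D = 1 / K_A, molar."""
    return 1.0 / params.k_a


def ec50(
    params: ThermoParams,
    degeneracies: DegeneracyVector = WT_DEGENERACIES,
    *,
    definition: str = "asymptotic",
    bracket: tuple[float, float] = (1e-12, 1.0),
    grid_points: int = 600,
) -> float:
    """Concentration at which the response reaches half its maximum.

    ``definition="asymptotic"`` (default) targets half of the infinite-
    concentration plateau ``d``; ``definition="observed"`` targets half of
    the largest response found on the search bracket.  The crossing is
    located by a bracketing root search to relative tolerance 1e-10.

    Raises
    ------
    ValueError
        If no crossing lies inside the bracket, or if the response is
        non-monotone enough to cross the half-maximum more than once (the
        message then lists every crossing concentration).
    """
    from scipy.optimize import brentq

    lo, hi = bracket
    if not (0 < lo < hi):
        raise ValueError(f"invalid bracket {bracket}")
    grid = np.logspace(math.log10(lo), math.log10(hi), grid_points)
    y = response(params, degeneracies, grid)
    if definition == "asymptotic":
        target = 0.5 * params.d
    elif definition == "observed":
        target = 0.5 * float(np.max(y))
    else:
        raise ValueError(f"unknown EC50 definition {definition!r}")

    f = y - target
    idx = np.nonzero(np.sign(f[:-1]) * np.sign(f[1:]) < 0)[0]
    exact = np.nonzero(f == 0)[0]
    crossings = [float(grid[i]) for i in exact]
    for i in idx:
        crossings.append(
            float(brentq(
                lambda c: response(params, degeneracies, float(c)) - target,
                # xtol scaled below the bracket so the relative rtol governs
                grid[i], grid[i + 1], rtol=1e-12, xtol=float(grid[i]) * 1e-13,
            ))
        )
    if not crossings:
        raise ValueError(
            f"response never reaches {target:.4g} inside bracket {bracket}"
        )
    if len(crossings) > 1:
        raise ValueError(
            "response crosses the half-maximum more than once; crossings at "
            + ", ".join(f"{c:.6g} M" for c in sorted(crossings))
        )
    return crossings[0]
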