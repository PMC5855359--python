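"""Wild-type/mutant heteromeric tetramer ensembles.

Cotransfecting wild-type subunits with a binding-deficient point mutant
(e.g. KCNQ2 F137A) produces a mixture of tetramers with 0–4 wild-type
subunits.  Only wild-type subunits bind the activator, so a tetramer with
``m`` wild-type subunits contributes C(m, k) microstates to the k-liganded
configuration CF_k, weighted by the number of ways the composition itself
can assemble.  Aggregating over compositions yields an effective
DegeneracyVector that drops into the homomeric response formula unchanged —
the ensemble response is bi-sigmoidal in log concentration, unlike any
single Hill curve.

Two multiplicity conventions are provided: ``published`` uses the counts
(2, 32, 24, 8, 1) reported for the 1:1 WT–F137A mixture; ``combinatorial``
derives the counts from first principles by enumerating all subunit-type
assignments, giving (16, 32, 24, 8, 1) for the same mixture.  The two differ
only in the unliganded multiplicity; ``published`` is the default because it
reproduces the reported heteromeric predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .thermo import (
    DegeneracyVector,
    ThermoParams,
    WT_DEGENERACIES,
    response,
)

__all__ = [
    "EnsembleSpec",
    "PUBLISHED_HETEROMER_DEGENERACIES",
    "heteromer_degeneracies",
    "enumerate_microstates",
    "heteromer_response",
    "inflection_count",
    "count_inflections",
]

#: Reported multiplicities for the 1:1 WT–F137A heteromeric ensemble.
PUBLISHED_HETEROMER_DEGENERACIES = DegeneracyVector((2, 32, 24, 8, 1))


@dataclass(frozen=True)
class EnsembleSpec:
    """Composition of a WT/mutant channel ensemble.

    Parameters
    ----------
    mutant_fraction
        Fraction of mutant subunits in the subunit pool (0.5 for a 1:1
        cotransfection). Subunits are assumed to assemble independently, so
        compositions are binomially distributed.
    mutant_bindable
        Whether mutant subunits can still bind the activator (False for a
        binding-site knockout such as F137A).
    multiplicity_mode
        ``"published"`` or ``"combinatorial"`` (see module docstring).
    """

    n_subunits: int = 4
    mutant_fraction: float = 0.5
    mutant_bindable: bool = False
    multiplicity_mode: str = "published"

    def __post_init__(self) -> None:
        if self.n_subunits != 4:
            raise ValueError(
                f"only tetramers (n_subunits=4) are supported, got {self.n_subunits}"
            )
        if not 0.0 <= self.mutant_fraction <= 1.0:
            raise ValueError(
                f"mutant_fraction must be in [0, 1], got {self.mutant_fraction}"
            )
        if self.multiplicity_mode not in ("published", "combinatorial"):
            raise ValueError(
                f"multiplicity_mode must be 'published' or 'combinatorial', "
                f"got {self.multiplicity_mode!r}"
            )


def heteromer_degeneracies(spec: EnsembleSpec) -> DegeneracyVector:
    """Effective configuration multiplicities for a WT/mutant ensemble.

    In ``combinatorial`` mode the multiplicities are

        g_k ∝ sum_m C(4, m) f_wt^m f_mut^(4-m) C(m, k)

    over compositions with ``m`` bindable subunits, rescaled so that g4 = 1
    (only ratios matter).  At a 1:1 mixture this gives (16, 32, 24, 8, 1);
    with no mutant subunits it reduces to the homomeric (1, 4, 6, 4, 1).
    ``published`` mode returns the reported (2, 32, 24, 8, 1) for the 1:1
    case and is only defined there.
    """
    f_mut = spec.mutant_fraction
    if spec.mutant_bindable or f_mut == 0.0:
        return WT_DEGENERACIES
    if f_mut == 1.0:
        raise ValueError(
            "a pure mutant ensemble has no bindable subunits; the binding "
            "model does not apply"
        )
    if spec.multiplicity_mode == "published":
        if f_mut != 0.5:
            raise ValueError(
                "published multiplicities are only available for the 1:1 "
                f"mixture (mutant_fraction=0.5), got {f_mut}"
            )
        return PUBLISHED_HETEROMER_DEGENERACIES
    n = spec.n_subunits
    f_wt = 1.0 - f_mut
    raw = [
        sum(
            comb(n, m) * f_wt ** m * f_mut ** (n - m) * comb(m, k)
            for m in range(k, n + 1)
        )
        for k in range(n + 1)
    ]
    g = tuple(v / raw[n] for v in raw)  # rescale so the fully liganded g = 1
    # at the symmetric mixture the rescaled values are exact small integers
    g = tuple(round(v) if abs(v - round(v)) < 1e-9 else v for v in g)
    return DegeneracyVector(g)


def enumerate_microstates(spec: EnsembleSpec) -> pd.DataFrame:
    """Brute-force count of (composition, bound-count) microstates.

    Enumerates every subunit-type assignment of the tetramer (2^4 when both
    types are present) and every placement of ``k`` ligands on bindable
    subunits.  Returns a tidy table with columns ``n_wt``, ``n_mutant``,
    ``n_bound`` and ``multiplicity`` = C(4, n_wt) * C(n_bindable, n_bound).
    Aggregating multiplicity over ``n_bound`` reproduces
    :func:`heteromer_degeneracies` in combinatorial mode for the 1:1 mixture.
    """
    n = spec.n_subunits
    if n > 8:
        raise ValueError("enumeration is limited to n_subunits <= 8")
    rows = []
    for n_wt in range(n + 1):
        n_bindable = n if spec.mutant_bindable else n_wt
        for k in range(n_bindable + 1):
            rows.append(
                {
                    "n_wt": n_wt,
                    "n_mutant": n - n_wt,
                    "n_bound": k,
                    "multiplicity": comb(n, n_wt) * comb(n_bindable, k),
                }
            )
    return pd.DataFrame(rows)


def heteromer_response(
    params: ThermoParams, spec: EnsembleSpec, concentration
):
    """Normalized current potentiation of the heteromeric ensemble.

    Identical to the homomeric response evaluated with the ensemble's
    effective multiplicities; conductance coefficients are shared with the
    wild-type channel (the mutation is assumed not to alter conductance).
    """
    return response(params, heteromer_degeneracies(spec), concentration)


def count_inflections(
    curve,
    log10_range: tuple[float, float] = (-9.0, -3.0),
    grid_points: int = 601,
    threshold: float = 1e-6,
) -> int:
    """Number of inflections of ``curve`` with respect to log10 concentration.

    ``curve`` maps an array of molar concentrations to responses.  The second
    derivative is estimated by central differences on a uniform log10 grid;
    values below ``threshold`` in magnitude are treated as zero so numerical
    noise on flat stretches does not register as curvature.  A plain sigmoid
    counts 1; a mixture of channel populations with well-separated apparent
    affinities counts 2 or more.
    """
    if grid_points < 200:
        raise ValueError("grid_points must be >= 200 for a stable estimate")
    lo, hi = log10_range
    if not hi > lo:
        raise ValueError(f"invalid log10_range {log10_range}")
    lg = np.linspace(lo, hi, grid_points)
    y = np.asarray(curve(10.0 ** lg), dtype=float)
    h = lg[1] - lg[0]
    d2 = (y[2:] - 2.0 * y[1:-1] + y[:-2]) / h ** 2
    signs = np.sign(d2)
    signs[np.abs(d2) < threshold] = 0
    s = signs[signs != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(s[1:] != s[:-1]))


def inflection_count(
    params: ThermoParams,
    degeneracies: DegeneracyVector,
    log10_range: tuple[float, float] = (-9.0, -3.0),
    grid_points: int = 601,
    threshold: float = 1e-6,
) -> int:
    """Inflection count of the model response for a given ensemble."""
    return count_inflections(
        lambda c: response(params, degeneracies, c),
        log10_range=log10_range,
        grid_points=grid_points,
        threshold=threshold,
    )
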