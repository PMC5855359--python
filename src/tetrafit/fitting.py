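"""Concentration-response curve fitting.

Fits the eight-parameter thermodynamic response model, and a Hill-equation
baseline, to normalized concentration-response data by multi-start
trust-region nonlinear least squares.  Affinity and cooperativity parameters
are optimized on a log10 scale (they are positive and span decades);
conductance coefficients are box-constrained to (0, 1].  Each start draws
its initial point from a seeded generator — log-uniform for the scale
parameters, uniform for the conductances — and the lowest-SSE converged
start wins, followed by one high-accuracy polishing run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import __version__ as _version
from .thermo import (
    DegeneracyVector,
    ThermoParams,
    average_occupancy,
    occupancy_curve,
    response,
)

__all__ = [
    "ResponseDataset",
    "HillParams",
    "FitResult",
    "FitConvergenceError",
    "DEFAULT_THERMO_BOUNDS",
    "sse",
    "r_square",
    "hill_response",
    "fit_thermo",
    "fit_hill",
    "predict_curve",
]

#: Default parameter box for the thermodynamic fit: association constants
#: spanning plausible pharmacology, cooperativities allowed to be strongly
#: negative or positive, conductances as fractions of the maximum.
DEFAULT_THERMO_BOUNDS: dict[str, tuple[float, float]] = {
    "k_a": (1e2, 1e9),
    "gamma": (1e-4, 1e4),
    "mu": (1e-4, 1e4),
    "nu": (1e-4, 1e4),
    "a": (1e-12, 1.0),
    "b": (1e-12, 1.0),
    "c": (1e-12, 1.0),
    "d": (1e-12, 1.0),
}

DEFAULT_HILL_BOUNDS: dict[str, tuple[float, float]] = {
    "ec50": (1e-12, 1.0),
    "hill_n": (0.05, 20.0),
    "amplitude": (1e-6, 10.0),
}


class FitConvergenceError(RuntimeError):
    """No optimization start converged; carries per-start diagnostics."""

    def __init__(self, message: str, per_start_sse, per_start_status):
        super().__init__(message)
        self.per_start_sse = list(per_start_sse)
        self.per_start_status = list(per_start_status)


@dataclass(frozen=True)
class ResponseDataset:
    """An ordered concentration-response table.

    ``concentrations`` are molar and strictly increasing; ``responses`` are
    normalized potentiation values (dI/dImax).  Optional per-point SEMs and
    raw current ratios (I/I0) travel with the data.
    """

    concentrations: np.ndarray
    responses: np.ndarray
    sem: Optional[np.ndarray] = None
    raw_ratio: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self) -> None:
        conc = np.array(self.concentrations, dtype=float)
        resp = np.array(self.responses, dtype=float)
        if conc.ndim != 1 or resp.shape != conc.shape:
            raise ValueError("concentrations and responses must be 1-D and equal length")
        if conc.size == 0:
            raise ValueError("dataset has no points")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be > 0 M")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if not np.all(np.isfinite(resp)):
            raise ValueError("responses must be finite")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)
        for name in ("sem", "raw_ratio"):
            v = getattr(self, name)
            if v is not None:
                v = np.array(v, dtype=float)
                if v.shape != conc.shape:
                    raise ValueError(f"{name} must match the number of points")
                if name == "sem" and np.any(v < 0):
                    raise ValueError("sem values must be >= 0")
                object.__setattr__(self, name, v)
        for arr in (self.concentrations, self.responses, self.sem, self.raw_ratio):
            if arr is not None:
                arr.flags.writeable = False

    def __len__(self) -> int:
        return int(self.concentrations.size)

    @property
    def log10_concentrations(self) -> np.ndarray:
        return np.log10(self.concentrations)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "concentration_M": self.concentrations,
                "log10_conc": self.log10_concentrations,
                "response": self.responses,
            }
        )
        if self.sem is not None:
            df["sem"] = self.sem
        if self.raw_ratio is not None:
            df["i_over_i0"] = self.raw_ratio
        return df


@dataclass(frozen=True)
class HillParams:
    """Hill-equation parameters: amplitude * [L]^n / (EC50^n + [L]^n)."""

    ec50: float
    hill_n: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ec50", "hill_n", "amplitude"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    def to_dict(self) -> dict[str, float]:
        return {"ec50": self.ec50, "hill_n": self.hill_n, "amplitude": self.amplitude}


def hill_response(params: HillParams, concentration):
    """Hill curve; a single sigmoid in log concentration."""
    conc = np.asarray(concentration, dtype=float)
    cn = conc ** params.hill_n
    out = params.amplitude * cn / (params.ec50 ** params.hill_n + cn)
    return float(out) if conc.ndim == 0 else out


def sse(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Sum of squared errors between two equal-length vectors."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-D and equal length")
    if obs.size < 1:
        raise ValueError("need at least one point")
    return float(np.sum((obs - pred) ** 2))


def r_square(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination 1 - SSE/SST (SST about the observed mean).

    Can be negative for a fit worse than the constant mean; undefined (and
    an error) when the observed values are all equal.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least two points for R-square")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("observed values are constant; R-square is undefined")
    return 1.0 - sse(observed, predicted) / sst


@dataclass(frozen=True)
class FitResult:
    """Outcome of a multi-start least-squares fit."""

    model: str
    params: object  # ThermoParams or HillParams
    sse: float
    r_square: float
    n_starts: int
    seed: int
    best_start_index: int
    converged: bool
    per_start_sse: tuple = field(default_factory=tuple)
    per_start_status: tuple = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "tool": "tetrafit",
            "version": _version,
            "model": self.model,
            "params": self.params.to_dict(),
            "sse": self.sse,
            "r_square": self.r_square,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "best_start_index": self.best_start_index,
            "converged": self.converged,
            "per_start_sse": list(self.per_start_sse),
            "per_start_status": list(self.per_start_status),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def _require_fittable(data: ResponseDataset, n_params: int) -> None:
    if len(data) < 3:
        raise ValueError(
            f"at least 3 points are required to fit; dataset has {len(data)}"
        )
    if len(data) < n_params:
        import warnings

        warnings.warn(
            f"fitting {n_params} parameters to {len(data)} points: the "
            "parameter vector is underdetermined (only the curve is reliable)",
            stacklevel=3,
        )


def _residual_weights(data: ResponseDataset, weighted: bool) -> np.ndarray:
    if not weighted:
        return np.ones(len(data))
    if data.sem is None or np.any(data.sem <= 0):
        raise ValueError("SEM weighting requested but SEMs are missing or zero")
    return 1.0 / data.sem


def _multi_start(
    residual, draw_start, lower, upper, n_starts, seed,
    max_nfev, ftol, xtol, gtol,
):
    """Shared multi-start driver; returns (best_theta, diagnostics)."""
    rng = np.random.default_rng(seed)
    per_sse, per_status, solutions = [], [], []
    for _ in range(n_starts):
        theta0 = draw_start(rng)
        try:
            res = least_squares(
                residual, theta0, bounds=(lower, upper), method="trf",
                ftol=ftol, xtol=xtol, gtol=gtol, max_nfev=max_nfev,
            )
            per_sse.append(2.0 * float(res.cost))
            per_status.append(int(res.status))
            solutions.append(res.x if res.status > 0 else None)
        except Exception:  # singular start etc. — record, keep going
            per_sse.append(float("inf"))
            per_status.append(-1)
            solutions.append(None)
    ok = [i for i, s in enumerate(solutions) if s is not None]
    if not ok:
        raise FitConvergenceError(
            f"none of {n_starts} optimization starts converged",
            per_sse, per_status,
        )
    best = min(ok, key=lambda i: per_sse[i])
    # polish the winning start at tight tolerance so the reported optimum
    # does not depend on the coarse per-start stopping rule
    res = least_squares(
        residual, solutions[best], bounds=(lower, upper), method="trf",
        ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=10 * max_nfev,
    )
    theta = res.x if res.status > 0 and 2 * res.cost <= per_sse[best] else solutions[best]
    return theta, best, per_sse, per_status


def fit_thermo(
    data: ResponseDataset,
    degeneracies: DegeneracyVector,
    n_starts: int = 50,
    seed: int = 0,
    bounds: Optional[dict[str, tuple[float, float]]] = None,
    *,
    weighted: bool = False,
    max_nfev: int = 600,
    ftol: float = 1e-6,
    xtol: float = 1e-6,
    gtol: float = 1e-6,
) -> FitResult:
    """Multi-start trust-region fit of the eight-parameter binding model.

    Starts are drawn log-uniformly inside the bounds for K_A, gamma, mu, nu
    and uniformly in (0, 1] for the conductance coefficients; the fit itself
    runs on log10-transformed scale parameters.  Deterministic for a given
    seed.  With six-point datasets the parameter vector is not identifiable
    — only the fitted curve (and its SSE) is meaningful.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    _require_fittable(data, 8)
    box = dict(DEFAULT_THERMO_BOUNDS)
    if bounds:
        box.update(bounds)
    names = ("k_a", "gamma", "mu", "nu", "a", "b", "c", "d")
    lo = np.array([box[n][0] for n in names], dtype=float)
    hi = np.array([box[n][1] for n in names], dtype=float)
    if np.any(lo <= 0) or np.any(hi <= lo):
        raise ValueError("bounds must be positive with lower < upper")
    # scale parameters on log10; conductances linear
    lower = np.concatenate([np.log10(lo[:4]), lo[4:]])
    upper = np.concatenate([np.log10(hi[:4]), hi[4:]])

    w = _residual_weights(data, weighted)
    conc = data.concentrations
    obs = data.responses

    def unpack(theta) -> ThermoParams:
        k_a, gamma, mu, nu = 10.0 ** theta[:4]
        a, b, c, d = theta[4:]
        return ThermoParams(k_a=k_a, gamma=gamma, mu=mu, nu=nu, a=a, b=b, c=c, d=d)

    def residual(theta):
        return w * (response(unpack(theta), degeneracies, conc) - obs)

    def draw_start(rng):
        logs = rng.uniform(lower[:4], upper[:4])
        conducts = rng.uniform(1e-3, 1.0, size=4)
        return np.concatenate([logs, conducts])

    theta, best, per_sse, per_status = _multi_start(
        residual, draw_start, lower, upper, n_starts, seed,
        max_nfev, ftol, xtol, gtol,
    )
    params = unpack(theta)
    fit_sse = sse(obs, response(params, degeneracies, conc))
    r2 = r_square(obs, response(params, degeneracies, conc))
    return FitResult(
        model="thermo", params=params, sse=fit_sse, r_square=r2,
        n_starts=n_starts, seed=seed, best_start_index=best,
        converged=bool(per_status[best] > 0 and r2 > 0),
        per_start_sse=tuple(per_sse), per_start_status=tuple(per_status),
    )


def fit_hill(
    data: ResponseDataset,
    fix_amplitude: bool = False,
    n_starts: int = 50,
    seed: int = 0,
    bounds: Optional[dict[str, tuple[float, float]]] = None,
    *,
    weighted: bool = False,
    max_nfev: int = 600,
    ftol: float = 1e-6,
    xtol: float = 1e-6,
    gtol: float = 1e-6,
) -> FitResult:
    """Multi-start least-squares Hill fit (amplitude free unless fixed at 1).

    Same multi-start and seeding contract as :func:`fit_thermo`.  A result
    whose curve explains none of the variance (R-square <= 0) is flagged as
    not converged rather than silently returned as a fit.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    _require_fittable(data, 2 if fix_amplitude else 3)
    box = dict(DEFAULT_HILL_BOUNDS)
    if bounds:
        box.update(bounds)
    names = ("ec50", "hill_n") if fix_amplitude else ("ec50", "hill_n", "amplitude")
    lo = np.array([box[n][0] for n in names], dtype=float)
    hi = np.array([box[n][1] for n in names], dtype=float)
    if np.any(lo <= 0) or np.any(hi <= lo):
        raise ValueError("bounds must be positive with lower < upper")
    # EC50 on log10 scale; hill_n and amplitude linear
    lower = np.concatenate([[np.log10(lo[0])], lo[1:]])
    upper = np.concatenate([[np.log10(hi[0])], hi[1:]])

    w = _residual_weights(data, weighted)
    conc = data.concentrations
    obs = data.responses
    # seed EC50 guesses from the observed concentration window
    lg_lo = max(np.log10(conc.min()) - 2.0, lower[0])
    lg_hi = min(np.log10(conc.max()) + 2.0, upper[0])

    def unpack(theta) -> HillParams:
        if fix_amplitude:
            return HillParams(ec50=10.0 ** theta[0], hill_n=theta[1], amplitude=1.0)
        return HillParams(ec50=10.0 ** theta[0], hill_n=theta[1], amplitude=theta[2])

    def residual(theta):
        return w * (hill_response(unpack(theta), conc) - obs)

    def draw_start(rng):
        vals = [rng.uniform(lg_lo, lg_hi), rng.uniform(0.3, 4.0)]
        if not fix_amplitude:
            vals.append(rng.uniform(0.2, 2.0))
        return np.clip(np.array(vals), lower, upper)

    theta, best, per_sse, per_status = _multi_start(
        residual, draw_start, lower, upper, n_starts, seed,
        max_nfev, ftol, xtol, gtol,
    )
    params = unpack(theta)
    fit_sse = sse(obs, hill_response(params, conc))
    r2 = r_square(obs, hill_response(params, conc))
    return FitResult(
        model="hill", params=params, sse=fit_sse, r_square=r2,
        n_starts=n_starts, seed=seed, best_start_index=best,
        converged=bool(per_status[best] > 0 and r2 > 0),
        per_start_sse=tuple(per_sse), per_start_status=tuple(per_status),
    )


def predict_curve(
    params: ThermoParams,
    degeneracies: DegeneracyVector,
    concentrations: Sequence[float],
) -> pd.DataFrame:
    """Tabulate response, configuration probabilities and mean occupancy.

    Returns a DataFrame with one row per concentration and columns
    concentration_M, log10_conc, response, p0..p4, avg_occupancy.
    """
    conc = np.asarray(list(concentrations), dtype=float)
    cols = ["concentration_M", "log10_conc", "response",
            "p0", "p1", "p2", "p3", "p4", "avg_occupancy"]
    if conc.size == 0:
        return pd.DataFrame(columns=cols)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0 M")
    if np.any(np.diff(conc) < 0):
        raise ValueError("concentrations must be sorted ascending")
    probs = occupancy_curve(params, degeneracies, conc)
    df = pd.DataFrame(
        {
            "concentration_M": conc,
            "log10_conc": np.log10(conc),
            "response": response(params, degeneracies, conc),
            **{f"p{k}": probs[:, k] for k in range(5)},
            "avg_occupancy": average_occupancy(params, degeneracies, conc),
        }
    )
    return df[cols]
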