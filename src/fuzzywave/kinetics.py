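"""Monod-type hydrolysis kinetics of DMP degradation in an AAO train.

The rate law instantiates the ASM2 hydrolysis template.  With the
substrate-to-biomass ratio ``u = S / X_H`` the specific hydrolysis rate is

    r = eta * K * u / (Ks + u) * X_H * [zone switching functions]

where ``K`` is the maximum specific hydrolysis rate, ``Ks`` the
half-saturation coefficient (in ``u`` units) and ``eta`` the hydrolysis
reduction factor (1 in the aerobic zone, < 1 anaerobically/anoxically).
The zone switching multipliers are the usual oxygen/nitrate saturation and
inhibition terms:

    aerobic    S_O2 / (K_O2 + S_O2)
    anoxic     K_O2 / (K_O2 + S_O2) * S_NO3 / (K_NO3 + S_NO3)
    anaerobic  K_O2 / (K_O2 + S_O2) * K_NO3 / (K_NO3 + S_NO3)

``pure_monod=True`` disables the switching multipliers; all parameter
estimation here uses that simplified Monod form.  Parameters are estimated
by the double-reciprocal (Lineweaver-Burk) linearization: with
``x = 1/u`` and ``y = 1/v`` the Monod law becomes the straight line
``y = (Ks/K) x + 1/K``, so ``K = 1/intercept`` and ``Ks = slope/intercept``.
The reduction factor of a zone is ``eta = K_zone / K_aerobic`` (capped at 1).

Zone effluents come from the steady-state completely-mixed (CSTR) mass
balance ``S_in - S_out = r(S_out) * HRT`` solved by bisection, chained
anaerobic -> anoxic -> aerobic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import (
    DegenerateDesignError,
    InvalidParameterError,
    NonPhysicalFitError,
    SolverError,
)

log = logging.getLogger(__name__)

__all__ = [
    "ZONES",
    "KineticParameters",
    "KineticState",
    "LinearFit",
    "hydrolysis_rate",
    "linearize",
    "fit_linear",
    "coefficients_to_params",
    "reduction_factor",
    "predict_effluent",
]

ZONES = ("anaerobic", "anoxic", "aerobic")


@dataclass
class KineticParameters:
    """Per-zone hydrolysis constants: K (max specific rate), Ks
    (half-saturation, in substrate-to-biomass units), eta (reduction factor)."""

    K: float
    Ks: float
    eta: float = 1.0
    zone: str = "aerobic"

    def __post_init__(self) -> None:
        if self.zone not in ZONES:
            raise InvalidParameterError(f"unknown zone {self.zone!r}")
        if self.K < 0.0:
            raise InvalidParameterError("K must be >= 0")
        if self.Ks <= 0.0:
            raise InvalidParameterError("Ks must be > 0")
        if not 0.0 < self.eta <= 1.0:
            raise InvalidParameterError("eta must be in (0, 1]")

    def as_table_row(self) -> dict:
        """Two-decimal reporting convention; full precision stays in the fields."""
        return {
            "zone": self.zone,
            "K": round(self.K, 2),
            "Ks": round(self.Ks, 2),
            "eta": round(self.eta, 2),
        }

    def to_dict(self) -> dict:
        return {"zone": self.zone, "K": self.K, "Ks": self.Ks, "eta": self.eta}

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        return cls(K=d["K"], Ks=d["Ks"], eta=d.get("eta", 1.0), zone=d.get("zone", "aerobic"))


@dataclass
class KineticState:
    """Instantaneous reactor state entering the rate law.

    ``S`` is the DMP concentration (ug/L), ``X_H`` the heterotrophic biomass
    proxied by MLSS (mg/L); ``S_O2``/``S_NO3`` the oxygen and nitrate
    concentrations with switching coefficients ``K_O2``/``K_NO3`` (mg/L).
    """

    S: float
    X_H: float
    S_O2: float = 0.0
    S_NO3: float = 0.0
    S_s: float = 0.0
    K_O2: float = 0.2
    K_NO3: float = 0.2

    def __post_init__(self) -> None:
        for name in ("S", "X_H", "S_O2", "S_NO3", "S_s"):
            if getattr(self, name) < 0.0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.K_O2 <= 0.0 or self.K_NO3 <= 0.0:
            raise InvalidParameterError("switching coefficients must be > 0")


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float


def _switching_multiplier(state: KineticState, zone: str) -> float:
    ox_on = state.S_O2 / (state.K_O2 + state.S_O2)
    ox_off = state.K_O2 / (state.K_O2 + state.S_O2)
    if zone == "aerobic":
        return ox_on
    if zone == "anoxic":
        return ox_off * state.S_NO3 / (state.K_NO3 + state.S_NO3)
    return ox_off * state.K_NO3 / (state.K_NO3 + state.S_NO3)


def hydrolysis_rate(
    state: KineticState, params: KineticParameters, pure_monod: bool = False
) -> float:
    """Volumetric DMP removal rate (substrate units per unit time).

    ``pure_monod=True`` drops the zone switching multipliers, leaving the
    simplified Monod law used for parameter fitting.
    """
    if state.X_H == 0.0:
        raise InvalidParameterError("X_H = 0: specific rate undefined")
    u = state.S / state.X_H
    r = params.eta * params.K * u / (params.Ks + u) * state.X_H
    if not pure_monod:
        r *= _switching_multiplier(state, params.zone)
    return float(r)


# ----------------------------------------------------------------------
# linearized parameter estimation
# ----------------------------------------------------------------------

def linearize(rate_observations) -> tuple[np.ndarray, np.ndarray]:
    """Double-reciprocal transform of ``(u, v)`` observations to ``(1/u, 1/v)``.

    Non-positive ``u`` or ``v`` observations cannot be transformed; they are
    dropped with a logged count.
    """
    obs = np.asarray(rate_observations, dtype=float)
    if obs.ndim == 1:
        obs = obs[None, :]
    if obs.shape[1] != 2:
        raise DegenerateDesignError("rate observations must be (u, v) pairs")
    keep = (obs[:, 0] > 0.0) & (obs[:, 1] > 0.0)
    dropped = int((~keep).sum())
    if dropped:
        log.warning("linearize: dropped %d non-positive (u, v) observations", dropped)
    obs = obs[keep]
    return 1.0 / obs[:, 0], 1.0 / obs[:, 1]


def fit_linear(x, y=None) -> LinearFit:
    """Ordinary least squares line through transformed points."""
    if y is None:
        pts = np.asarray(x, dtype=float)
        x, y = pts[:, 0], pts[:, 1]
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise DegenerateDesignError("fit_linear requires >= 2 distinct x values")
    res = stats.linregress(x, y)
    pred = res.intercept + res.slope * x
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept), r_squared=r2)


def coefficients_to_params(
    fit: LinearFit,
    zone: str = "aerobic",
    K_aerobic_reference: float | None = None,
) -> KineticParameters:
    """Map a double-reciprocal fit to kinetic constants.

    ``K = 1/intercept``; ``Ks = slope/intercept``; ``eta = K/K_aerobic`` when
    the aerobic reference is given (capped at 1), else 1.
    """
    if fit.intercept <= 0.0:
        raise NonPhysicalFitError(
            f"intercept {fit.intercept:.4g} <= 0 implies non-physical K"
        )
    K = 1.0 / fit.intercept
    Ks = fit.slope / fit.intercept
    if Ks <= 0.0:
        raise NonPhysicalFitError(f"slope {fit.slope:.4g} implies non-physical Ks")
    eta = 1.0 if K_aerobic_reference is None else reduction_factor(K, K_aerobic_reference, ndigits=None)
    return KineticParameters(K=K, Ks=Ks, eta=eta, zone=zone)


def reduction_factor(K_zone: float, K_aerobic: float, ndigits: int | None = 2) -> float:
    """Hydrolysis reduction factor ``eta = K_zone / K_aerobic``, capped at 1.

    Rounded to two decimals by default (the reporting convention);
    ``ndigits=None`` returns full precision.
    """
    if K_aerobic <= 0.0:
        raise InvalidParameterError("K_aerobic must be > 0")
    if K_zone <= 0.0:
        raise InvalidParameterError("K_zone must be > 0")
    eta = min(1.0, K_zone / K_aerobic)
    return eta if ndigits is None else round(eta, ndigits)


# ----------------------------------------------------------------------
# steady-state zone chain
# ----------------------------------------------------------------------

def _solve_zone(
    S_in: float,
    params: KineticParameters,
    template: KineticState,
    hrt: float,
    X_H: float,
    pure_monod: bool,
) -> float:
    if hrt <= 0.0:
        raise InvalidParameterError("HRT must be > 0")
    if S_in == 0.0:
        return 0.0

    def balance(S: float) -> float:
        st = KineticState(
            S=S,
            X_H=X_H,
            S_O2=template.S_O2,
            S_NO3=template.S_NO3,
            S_s=template.S_s,
            K_O2=template.K_O2,
            K_NO3=template.K_NO3,
        )
        return S_in - S - hydrolysis_rate(st, params, pure_monod=pure_monod) * hrt

    f_hi = balance(S_in)
    if f_hi >= 0.0:  # no net removal (e.g. K == 0 or switching fully off)
        return S_in
    try:
        return float(optimize.bisect(balance, 0.0, S_in, xtol=1e-9, maxiter=200))
    except (ValueError, RuntimeError) as exc:  # pragma: no cover - monotone r brackets
        raise SolverError(
            f"zone {params.zone}: failed to solve mass balance for S_in={S_in}"
        ) from exc


def predict_effluent(
    influent_S: float,
    zone_sequence,
    X_H: float | None = None,
    pure_monod: bool = True,
) -> float:
    """Chain steady-state CSTR zones and return the final effluent DMP.

    ``zone_sequence`` is an iterable of ``(KineticParameters, KineticState
    template, HRT)`` in flow order; ``X_H`` overrides the template biomass
    when given.  The result always lies in ``[0, influent_S]``.
    """
    if influent_S < 0.0:
        raise InvalidParameterError("influent_S must be >= 0")
    S = float(influent_S)
    for params, template, hrt in zone_sequence:
        biomass = X_H if X_H is not None else template.X_H
        S = _solve_zone(S, params, template, hrt, biomass, pure_monod)
    return S
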