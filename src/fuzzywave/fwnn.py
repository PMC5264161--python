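"""Five-layer fuzzy wavelet neural network (FWNN).

The network is a Takagi--Sugeno--Kang (TSK) style fuzzy system whose rule
consequents are wavelet neurons.  For an input vector ``x`` of length ``n``
and ``R`` rules:

* layer 1 passes the (scaled) inputs through;
* layer 2 fuzzifies each input against each rule with a Gaussian membership
  ``F[j,i] = exp(-(x_i - c[j,i])^2 / (2 sigma[j,i]^2))``;
* layer 3 forms the rule firing strength ``mu_j = prod_i F[j,i]`` (product
  as the fuzzy AND);
* layer 4 evaluates one wavelet neuron per rule,
  ``psihat_j = w_j * prod_i psi((x_i - b[j,i]) / a[j,i])`` with a Mexican-hat
  mother wavelet by default;
* layer 5 aggregates.  The default is the TSK normalized weighted mean
  ``sum_j mu_j psihat_j / sum_j mu_j``; a plain weighted sum is available.

Spreads ``sigma`` and dilations ``a`` enter only through even functions, so
their sign never affects the output; negative entries are legal (and occur in
the packaged reference parameter set), only exact zeros are rejected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable

import numpy as np

from .errors import DegenerateActivationError, InvalidParameterError, SchemaError

__all__ = [
    "FWNNParameters",
    "ForwardTrace",
    "gaussian_membership",
    "rule_strength",
    "mother_wavelet",
    "wavelet_neuron",
    "forward",
    "batch_predict",
    "load_reference_parameters",
    "WAVELETS",
    "AGGREGATIONS",
]

# exp() underflows to 0 below ~exp(-745); clip arguments so single memberships
# stay strictly positive (products of several may still underflow to 0).
_EXP_CLIP = 700.0

#: minimal summed firing strength for normalized aggregation
_MIN_ACTIVATION = 1e-300

AGGREGATIONS = ("normalized", "sum")


def _psi_mexican_hat(z: np.ndarray) -> np.ndarray:
    zz = np.square(z)
    return (1.0 - zz) * np.exp(-np.clip(zz / 2.0, 0.0, _EXP_CLIP))


def _dpsi_mexican_hat(z: np.ndarray) -> np.ndarray:
    zz = np.square(z)
    return (zz - 3.0) * z * np.exp(-np.clip(zz / 2.0, 0.0, _EXP_CLIP))


def _psi_morlet(z: np.ndarray) -> np.ndarray:
    zz = np.square(z)
    return np.cos(5.0 * z) * np.exp(-np.clip(zz / 2.0, 0.0, _EXP_CLIP))


def _dpsi_morlet(z: np.ndarray) -> np.ndarray:
    zz = np.square(z)
    e = np.exp(-np.clip(zz / 2.0, 0.0, _EXP_CLIP))
    return (-5.0 * np.sin(5.0 * z) - z * np.cos(5.0 * z)) * e


#: mother wavelet registry: name -> (psi, dpsi/dz)
WAVELETS: dict[str, tuple[Callable, Callable]] = {
    "mexican_hat": (_psi_mexican_hat, _dpsi_mexican_hat),
    "morlet": (_psi_morlet, _dpsi_morlet),
}


@dataclass
class FWNNParameters:
    """All trainable quantities of an FWNN with ``n_rules`` x ``n_inputs`` layout.

    ``centers``/``spreads`` parameterize the Gaussian memberships, ``dilations``/
    ``translations`` the wavelet neurons, ``weights`` the per-rule consequent
    weights.  All matrices are ``(n_rules, n_inputs)``; ``weights`` has length
    ``n_rules``.
    """

    centers: np.ndarray
    spreads: np.ndarray
    dilations: np.ndarray
    translations: np.ndarray
    weights: np.ndarray
    input_names: tuple[str, ...] | None = None
    wavelet: str = "mexican_hat"
    aggregation: str = "normalized"

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.spreads = np.asarray(self.spreads, dtype=float)
        self.dilations = np.asarray(self.dilations, dtype=float)
        self.translations = np.asarray(self.translations, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_rules(self) -> int:
        return self.centers.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.centers.shape[1]

    def validate(self) -> None:
        if self.centers.ndim != 2:
            raise InvalidParameterError("centers must be a 2-D (rules x inputs) matrix")
        shape = self.centers.shape
        for name in ("spreads", "dilations", "translations"):
            if getattr(self, name).shape != shape:
                raise InvalidParameterError(
                    f"{name} has shape {getattr(self, name).shape}, expected {shape}"
                )
        if self.weights.shape != (shape[0],):
            raise InvalidParameterError(
                f"weights has shape {self.weights.shape}, expected ({shape[0]},)"
            )
        if self.input_names is not None and len(self.input_names) != shape[1]:
            raise InvalidParameterError("input_names length does not match n_inputs")
        if self.wavelet not in WAVELETS:
            raise InvalidParameterError(f"unknown wavelet family {self.wavelet!r}")
        if self.aggregation not in AGGREGATIONS:
            raise InvalidParameterError(f"unknown aggregation mode {self.aggregation!r}")
        for name in ("spreads", "dilations"):
            arr = getattr(self, name)
            bad = np.argwhere(arr == 0.0)
            if bad.size:
                j, i = bad[0]
                raise InvalidParameterError(
                    f"{name}[{j},{i}] is zero (divisor); rule {j}, input {i}"
                )

    def copy(self) -> "FWNNParameters":
        return FWNNParameters(
            centers=self.centers.copy(),
            spreads=self.spreads.copy(),
            dilations=self.dilations.copy(),
            translations=self.translations.copy(),
            weights=self.weights.copy(),
            input_names=self.input_names,
            wavelet=self.wavelet,
            aggregation=self.aggregation,
        )

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_inputs": self.n_inputs,
            "n_rules": self.n_rules,
            "input_names": list(self.input_names) if self.input_names else None,
            "centers": self.centers.tolist(),
            "spreads": self.spreads.tolist(),
            "dilations": self.dilations.tolist(),
            "translations": self.translations.tolist(),
            "weights": self.weights.tolist(),
            "aggregation": self.aggregation,
            "wavelet": self.wavelet,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FWNNParameters":
        p = cls(
            centers=np.asarray(d["centers"], dtype=float),
            spreads=np.asarray(d["spreads"], dtype=float),
            dilations=np.asarray(d["dilations"], dtype=float),
            translations=np.asarray(d["translations"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            input_names=tuple(d["input_names"]) if d.get("input_names") else None,
            wavelet=d.get("wavelet", "mexican_hat"),
            aggregation=d.get("aggregation", "normalized"),
        )
        if "n_inputs" in d and d["n_inputs"] != p.n_inputs:
            raise SchemaError("declared n_inputs does not match centers shape")
        if "n_rules" in d and d["n_rules"] != p.n_rules:
            raise SchemaError("declared n_rules does not match centers shape")
        return p

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FWNNParameters":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ForwardTrace:
    """Intermediate quantities of one forward pass, for inspection and tests."""

    memberships: np.ndarray  # (R, n), each in (0, 1]
    firing_strengths: np.ndarray  # (R,), product over inputs
    wavelet_outputs: np.ndarray  # (R,), signed consequents w_j * prod psi
    output: float = field(default=float("nan"))


def load_reference_parameters() -> FWNNParameters:
    """Load the packaged eight-rule, five-input reference parameter set.

    This is a published parameter set for an effluent-DMP model over the
    inputs (pH, DMP_in, DO, ORP, MLSS); it ships with the package as a fixed
    regression/oracle target.
    """
    with resources.files("fuzzywave.data").joinpath("reference_model.json").open(
        "r", encoding="utf-8"
    ) as fh:
        return FWNNParameters.from_dict(json.load(fh))


# ----------------------------------------------------------------------
# layer-wise scalar operations
# ----------------------------------------------------------------------

def gaussian_membership(x: float, c: float, sigma: float) -> float:
    """Layer-2 Gaussian membership ``exp(-(x-c)^2 / (2 sigma^2))``.

    ``sigma`` enters squared, so its sign is irrelevant; ``sigma == 0`` is
    rejected.  Returns a value in ``(0, 1]``, equal to 1 iff ``x == c``.
    """
    if sigma == 0.0:
        raise InvalidParameterError("gaussian membership requires sigma != 0")
    arg = (x - c) ** 2 / (2.0 * sigma * sigma)
    return math.exp(-min(arg, _EXP_CLIP))


def rule_strength(memberships) -> float:
    """Layer-3 firing strength: product of the per-input memberships."""
    m = np.asarray(memberships, dtype=float)
    if m.size == 0:
        raise InvalidParameterError("rule_strength requires at least one membership")
    return float(np.prod(m))


def mother_wavelet(z, family: str = "mexican_hat"):
    """Evaluate the mother wavelet; Mexican hat ``(1-z^2) exp(-z^2/2)`` by default."""
    try:
        psi, _ = WAVELETS[family]
    except KeyError:
        raise InvalidParameterError(f"unknown wavelet family {family!r}") from None
    out = psi(np.asarray(z, dtype=float))
    return float(out) if np.isscalar(z) or np.ndim(z) == 0 else out


def wavelet_neuron(x, a_row, b_row, w: float, family: str = "mexican_hat") -> float:
    """Layer-4 consequent ``w * prod_i psi((x_i - b_i)/a_i)`` for one rule."""
    x = np.asarray(x, dtype=float)
    a = np.asarray(a_row, dtype=float)
    b = np.asarray(b_row, dtype=float)
    bad = np.argwhere(a == 0.0)
    if bad.size:
        raise InvalidParameterError(f"dilation a[{bad[0][0]}] is zero (divisor)")
    psi, _ = WAVELETS[family]
    return float(w * np.prod(psi((x - b) / a)))


# ----------------------------------------------------------------------
# full forward pass
# ----------------------------------------------------------------------

def _layers(params: FWNNParameters, X: np.ndarray):
    """Vectorized layers 2-4 for a batch ``X`` of shape (N, n).

    Returns memberships F (N,R,n), firing strengths mu (N,R), wavelet argument
    z (N,R,n), per-input wavelet values psi (N,R,n), and consequents
    psihat (N,R).
    """
    psi_fn, _ = WAVELETS[params.wavelet]
    diff = X[:, None, :] - params.centers[None, :, :]
    arg = np.square(diff) / (2.0 * np.square(params.spreads))[None, :, :]
    F = np.exp(-np.clip(arg, 0.0, _EXP_CLIP))
    mu = F.prod(axis=2)
    z = (X[:, None, :] - params.translations[None, :, :]) / params.dilations[None, :, :]
    psi = psi_fn(z)
    psihat = params.weights[None, :] * psi.prod(axis=2)
    return F, mu, z, psi, psihat


def _aggregate(mu: np.ndarray, psihat: np.ndarray, aggregation: str) -> np.ndarray:
    weighted = (mu * psihat).sum(axis=1)
    if aggregation == "sum":
        return weighted
    S = mu.sum(axis=1)
    if np.any(S < _MIN_ACTIVATION):
        k = int(np.argmax(S < _MIN_ACTIVATION))
        raise DegenerateActivationError(
            f"no rule fires for sample {k}: summed firing strength {S[k]:.3g} "
            "< 1e-300; the probe lies outside the fuzzified input region"
        )
    return weighted / S


def forward(params: FWNNParameters, x, aggregation: str | None = None):
    """One forward pass; returns ``(prediction, ForwardTrace)``.

    ``aggregation`` overrides ``params.aggregation`` when given
    ("normalized" or "sum").
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (params.n_inputs,):
        raise SchemaError(
            f"input vector has shape {x.shape}, expected ({params.n_inputs},)"
        )
    mode = aggregation or params.aggregation
    if mode not in AGGREGATIONS:
        raise InvalidParameterError(f"unknown aggregation mode {mode!r}")
    F, mu, _, _, psihat = _layers(params, x[None, :])
    y = _aggregate(mu, psihat, mode)
    trace = ForwardTrace(
        memberships=F[0],
        firing_strengths=mu[0],
        wavelet_outputs=psihat[0],
        output=float(y[0]),
    )
    return float(y[0]), trace


def batch_predict(params: FWNNParameters, X, aggregation: str | None = None) -> np.ndarray:
    """Forward pass over a 2-D batch of scaled inputs; one prediction per row."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise SchemaError("batch_predict expects a 2-D array of samples")
    if X.shape[0] == 0:
        return np.empty(0)
    if X.shape[1] != params.n_inputs:
        raise SchemaError(
            f"dataset has {X.shape[1]} columns, model expects {params.n_inputs}"
        )
    mode = aggregation or params.aggregation
    if mode not in AGGREGATIONS:
        raise InvalidParameterError(f"unknown aggregation mode {mode!r}")
    _, mu, _, _, psihat = _layers(params, X)
    return _aggregate(mu, psihat, mode)
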