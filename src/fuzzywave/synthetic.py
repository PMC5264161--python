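"""Synthetic AAO process-data generator.

Stands in for unavailable plant measurements: input variables are drawn
within the reactor's stated operating envelope (feed DMP levels 30-80 ug/L,
aerobic DO 2.54-5.72 mg/L, MLSS around 3000 mg/L), and the effluent DMP is
produced by a *teacher* mechanism:

* ``kinetic`` (default): the three-zone steady-state hydrolysis chain of
  :mod:`fuzzywave.kinetics` with MLSS as the biomass, times multiplicative
  lognormal noise.  pH and ORP do not enter this mechanism - they act as
  deliberately uninformative nuisance inputs.
* ``fwnn``: a known FWNN evaluated on min-max-scaled inputs plus additive
  Gaussian noise, mapped affinely to concentration units; the basis of
  teacher-student recovery experiments.

pH and ORP distributions are generator conventions (the operating ranges are
not reported); both are configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dataio import COLUMNS
from .errors import ConfigError
from .fwnn import FWNNParameters, batch_predict
from .kinetics import KineticParameters, KineticState, predict_effluent

__all__ = [
    "GeneratorConfig",
    "DEFAULT_KINETICS",
    "DEFAULT_HRT",
    "generate_dataset",
    "make_teacher_fwnn",
    "default_zone_sequence",
]

#: per-zone hydrolysis constants of the reference kinetic table
DEFAULT_KINETICS: dict[str, KineticParameters] = {
    "anaerobic": KineticParameters(K=9.68, Ks=148.31, eta=0.68, zone="anaerobic"),
    "anoxic": KineticParameters(K=11.36, Ks=180.81, eta=0.80, zone="anoxic"),
    "aerobic": KineticParameters(K=14.27, Ks=95.89, eta=1.0, zone="aerobic"),
}

#: zone residence times (internal time units; 1:1:4 like the 40/40/160 L zones)
DEFAULT_HRT: dict[str, float] = {"anaerobic": 2.5, "anoxic": 2.5, "aerobic": 10.0}


@dataclass
class GeneratorConfig:
    n_samples: int = 50
    seed: int = 0
    dmp_in_levels: tuple[float, ...] = (30.0, 40.0, 50.0, 60.0, 80.0)
    dmp_in_jitter: float = 2.0
    do_range: tuple[float, float] = (2.54, 5.72)
    mlss_mean: float = 3000.0
    mlss_sd: float = 150.0
    ph_range: tuple[float, float] = (6.8, 7.8)
    orp_range: tuple[float, float] = (-250.0, 150.0)
    noise_sd: float = 0.05
    hrt: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HRT))
    kinetics: dict[str, KineticParameters] = field(
        default_factory=lambda: dict(DEFAULT_KINETICS)
    )
    teacher_mode: str = "kinetic"
    teacher_params: FWNNParameters | None = None
    #: affine map from the fwnn teacher's scaled output to concentration units
    teacher_output_center: float = 30.0
    teacher_output_scale: float = 10.0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if self.noise_sd < 0.0:
            raise ConfigError("noise_sd must be >= 0")
        if self.dmp_in_jitter < 0.0:
            raise ConfigError("dmp_in_jitter must be >= 0")
        for name in ("do_range", "ph_range", "orp_range"):
            lo, hi = getattr(self, name)
            if hi <= lo:
                raise ConfigError(f"{name} must satisfy high > low")
        if not self.dmp_in_levels:
            raise ConfigError("dmp_in_levels must be nonempty")
        if self.teacher_mode not in ("kinetic", "fwnn"):
            raise ConfigError(f"unknown teacher_mode {self.teacher_mode!r}")
        if self.teacher_mode == "kinetic":
            missing = [z for z in ("anaerobic", "anoxic", "aerobic") if z not in self.kinetics]
            if missing:
                raise ConfigError(f"kinetics missing zone(s) {missing}")
            if any(self.hrt.get(z, 0.0) <= 0.0 for z in ("anaerobic", "anoxic", "aerobic")):
                raise ConfigError("each zone HRT must be > 0")

    def provenance(self) -> dict:
        d = asdict(self)
        d["kinetics"] = {z: p.to_dict() if hasattr(p, "to_dict") else p for z, p in self.kinetics.items()}
        if self.teacher_params is not None:
            d["teacher_params"] = self.teacher_params.to_dict()
        return d


def default_zone_sequence(config: GeneratorConfig | None = None):
    """The (params, state template, HRT) triples of the three-zone chain."""
    config = config or GeneratorConfig()
    seq = []
    for zone in ("anaerobic", "anoxic", "aerobic"):
        template = KineticState(S=0.0, X_H=config.mlss_mean)
        seq.append((config.kinetics[zone], template, config.hrt[zone]))
    return seq


def make_teacher_fwnn(n_rules: int, n_inputs: int, seed: int = 0) -> FWNNParameters:
    """A well-conditioned random FWNN: spreads/dilations in [0.5, 2],
    centers/translations in [-1, 1], weights in [-2, 2]; deterministic per seed."""
    if n_rules < 1:
        raise ConfigError("n_rules must be >= 1")
    rng = np.random.default_rng(seed)
    shape = (n_rules, n_inputs)
    return FWNNParameters(
        centers=rng.uniform(-1.0, 1.0, shape),
        spreads=rng.uniform(0.5, 2.0, shape),
        dilations=rng.uniform(0.5, 2.0, shape),
        translations=rng.uniform(-1.0, 1.0, shape),
        weights=rng.uniform(-2.0, 2.0, n_rules),
    )


def _scale_inputs(X: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Min-max map of the five raw inputs onto [-1, 1] using the configured ranges."""
    lo_dmp = min(config.dmp_in_levels) - config.dmp_in_jitter
    hi_dmp = max(config.dmp_in_levels) + config.dmp_in_jitter
    # MLSS range: +/- 3 sd around the mean covers essentially all draws
    ranges = np.array(
        [
            config.ph_range,
            (lo_dmp, hi_dmp),
            config.do_range,
            config.orp_range,
            (config.mlss_mean - 3 * config.mlss_sd, config.mlss_mean + 3 * config.mlss_sd),
        ]
    )
    return 2.0 * (X - ranges[:, 0]) / (ranges[:, 1] - ranges[:, 0]) - 1.0


def generate_dataset(config: GeneratorConfig | None = None) -> tuple[pd.DataFrame, dict]:
    """Draw a synthetic process dataset; returns ``(dataframe, provenance)``.

    The provenance dict records the full configuration and seed and is meant
    to be written as a JSON sidecar next to the CSV.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    ph = rng.uniform(*config.ph_range, n)
    dmp_in = rng.choice(config.dmp_in_levels, n) + rng.uniform(
        -config.dmp_in_jitter, config.dmp_in_jitter, n
    )
    do = rng.uniform(*config.do_range, n)
    orp = rng.uniform(*config.orp_range, n)
    mlss = np.clip(rng.normal(config.mlss_mean, config.mlss_sd, n), 1.0, None)

    X = np.column_stack([ph, dmp_in, do, orp, mlss])

    if config.teacher_mode == "kinetic":
        seq = default_zone_sequence(config)
        eff = np.array(
            [predict_effluent(dmp_in[k], seq, X_H=mlss[k], pure_monod=True) for k in range(n)]
        )
        if config.noise_sd > 0.0:
            eff = eff * np.exp(rng.normal(0.0, config.noise_sd, n))
        # multiplicative noise cannot create mass
        eff = np.minimum(eff, dmp_in)
    else:
        teacher = config.teacher_params or make_teacher_fwnn(3, 5, seed=config.seed)
        y_scaled = batch_predict(teacher, _scale_inputs(X, config))
        if config.noise_sd > 0.0:
            y_scaled = y_scaled + rng.normal(0.0, config.noise_sd, n)
        eff = np.clip(
            config.teacher_output_center + config.teacher_output_scale * y_scaled, 0.0, None
        )

    df = pd.DataFrame(X, columns=list(COLUMNS[:5]))
    df[COLUMNS[5]] = eff
    return df, {"generator": config.provenance(), "provenance": "synthetic"}
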