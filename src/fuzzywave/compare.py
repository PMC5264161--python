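"""Three-model comparison harness: FWNN vs GA-NN baseline vs kinetic model.

All three models are evaluated on the identical test split:

* the FWNN is trained by the hybrid GA -> gradient-descent schedule on the
  scaled training split;
* the GA-NN baseline (tanh perceptron) gets the identical schedule;
* the kinetic model is *estimated the mechanistic way*: per-sample overall
  specific removal rates from the training split are put through the
  double-reciprocal linearization, fitted by least squares, and the resulting
  single effective Monod CSTR (over the total residence time) predicts the
  test effluent.  It never sees the generating parameters.

Metrics are computed on the original concentration scale by default
(``space="scaled"`` switches to the scaled target space).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from . import dataio, kinetics, metrics as _metrics, training
from .errors import ConfigError, SolverError
from .fwnn import batch_predict
from .synthetic import DEFAULT_HRT

__all__ = ["ComparisonResult", "EffectiveMonodModel", "fit_effective_kinetics", "run_comparison"]


@dataclass
class EffectiveMonodModel:
    """A Monod rate curve estimated by the double-reciprocal fit.

    The fitted line ``1/v = slope * (1/u) + intercept`` is equivalent to the
    rate curve ``v(u) = u / (slope + intercept * u)``, which stays
    well-defined over the observed operating range even when the intercept
    (and hence ``K = 1/intercept``) is too poorly identified to report: in
    the first-order regime ``u << Ks`` only the ratio ``slope = Ks/K`` is
    strongly determined by the data.
    """

    fit: "kinetics.LinearFit"
    total_hrt: float

    def specific_rate(self, u: float) -> float:
        denom = self.fit.slope + self.fit.intercept * u
        if denom <= 0.0:
            return 0.0
        return u / denom

    def predict_effluent(self, s_in: float, x_h: float) -> float:
        """Steady-state single-CSTR mass balance with the fitted rate curve."""
        if s_in <= 0.0:
            return max(s_in, 0.0)

        def balance(s: float) -> float:
            return s_in - s - self.total_hrt * x_h * self.specific_rate(s / x_h)

        if balance(s_in) >= 0.0:
            return s_in
        try:
            return float(optimize.bisect(balance, 0.0, s_in, xtol=1e-9, maxiter=200))
        except (ValueError, RuntimeError) as exc:  # pragma: no cover
            raise SolverError(f"effective kinetic model failed to solve for S_in={s_in}") from exc

    def physical_params(self) -> "kinetics.KineticParameters | None":
        """Extracted (K, Ks) when the fit is physically interpretable."""
        try:
            return kinetics.coefficients_to_params(self.fit, zone="aerobic")
        except Exception:
            return None


@dataclass
class ComparisonResult:
    table: pd.DataFrame  # rows R2/MAPE/RMSE/MSE, columns FWNN/GA-NN/Kinetic
    metrics: dict[str, "_metrics.Metrics"]
    fwnn_report: "training.TrainingReport"
    nn_report: "training.TrainingReport"
    kinetic_model: EffectiveMonodModel
    seed: int


def fit_effective_kinetics(train_df: pd.DataFrame, total_hrt: float) -> EffectiveMonodModel:
    """Fit one effective Monod CSTR to observed removals in a training split.

    Treats the whole train as a single completely-mixed reactor with residence
    time ``total_hrt``: the mass balance gives the specific removal rate
    ``v = (S_in - S_out) / (total_hrt * X_H)`` at ratio ``u = S_out / X_H``;
    (u, v) pairs go through the double-reciprocal fit.
    """
    s_in = train_df["DMP_in"].to_numpy(dtype=float)
    s_out = train_df["DMP_eff"].to_numpy(dtype=float)
    x_h = train_df["MLSS"].to_numpy(dtype=float)
    u = s_out / x_h
    v = (s_in - s_out) / (total_hrt * x_h)
    x, y = kinetics.linearize(np.column_stack([u, v]))
    fit = kinetics.fit_linear(x, y)
    return EffectiveMonodModel(fit=fit, total_hrt=total_hrt)


def run_comparison(
    df: pd.DataFrame,
    n_train: int = 35,
    seed: int = 0,
    n_rules: int = 3,
    hidden_units: int = 6,
    ga_config: "training.GAConfig | None" = None,
    gd_config: "training.GDConfig | None" = None,
    total_hrt: float | None = None,
    space: str = "original",
) -> ComparisonResult:
    """Run the full benchmark on one dataset and return the comparison table."""
    if space not in ("original", "scaled"):
        raise ConfigError(f"unknown metric space {space!r}")
    ga_config = ga_config or training.GAConfig(
        population_size=60, max_generations=120, seed=seed
    )
    gd_config = gd_config or training.GDConfig(max_epochs=500)
    total_hrt = total_hrt if total_hrt is not None else sum(DEFAULT_HRT.values())

    train_df, test_df = dataio.split_dataset(df, n_train=n_train, seed=seed)
    spec = dataio.fit_scaling(train_df, method="minmax_sym")
    tr_s = dataio.apply_scaling(train_df, spec)
    te_s = dataio.apply_scaling(test_df, spec)
    train_xy = dataio.to_arrays(tr_s)
    test_xy = dataio.to_arrays(te_s)

    fwnn_report = training.hybrid_train(
        train_xy, test_xy, n_rules=n_rules, ga_config=ga_config, gd_config=gd_config
    )
    nn_report = training.baseline_nn_train(
        train_xy, test_xy, hidden_units=hidden_units, ga_config=ga_config, gd_config=gd_config
    )
    kin_model = fit_effective_kinetics(train_df, total_hrt)

    # test-split predictions of all three models, original units
    lo, hi = spec.stats["DMP_eff"]
    unscale = lambda v: lo + (np.asarray(v) + 1.0) * (hi - lo) / 2.0
    scale = lambda v: 2.0 * (np.asarray(v) - lo) / (hi - lo) - 1.0

    pred_fwnn = unscale(batch_predict(fwnn_report.final_params, test_xy[0]))
    pred_nn = unscale(nn_report.final_params.predict(test_xy[0]))
    pred_kin = np.array(
        [kin_model.predict_effluent(row.DMP_in, row.MLSS) for row in test_df.itertuples()]
    )

    observed = test_df["DMP_eff"].to_numpy(dtype=float)
    if space == "scaled":
        observed_m, preds = scale(observed), {
            "FWNN": scale(pred_fwnn),
            "GA-NN": scale(pred_nn),
            "Kinetic": scale(pred_kin),
        }
    else:
        observed_m, preds = observed, {
            "FWNN": pred_fwnn,
            "GA-NN": pred_nn,
            "Kinetic": pred_kin,
        }

    mets = {name: _metrics.compute_metrics(observed_m, p) for name, p in preds.items()}
    return ComparisonResult(
        table=_metrics.comparison_table(mets),
        metrics=mets,
        fwnn_report=fwnn_report,
        nn_report=nn_report,
        kinetic_model=kin_model,
        seed=seed,
    )
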