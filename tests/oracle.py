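"""Deliberately naive scalar reference implementations used as oracles.

Everything here is written with plain ``math`` loops, independently of the
vectorized package code, so agreement is meaningful.
"""

import math


def psi_mexican_hat(z: float) -> float:
    return (1.0 - z * z) * math.exp(-z * z / 2.0)


def psi_morlet(z: float) -> float:
    return math.cos(5.0 * z) * math.exp(-z * z / 2.0)


_PSI = {"mexican_hat": psi_mexican_hat, "morlet": psi_morlet}


def forward_scalar(centers, spreads, dilations, translations, weights, x,
                   aggregation="normalized", wavelet="mexican_hat"):
    """Loop-based FWNN forward pass over nested Python lists."""
    psi = _PSI[wavelet]
    R = len(weights)
    n = len(x)
    mus, psihats = [], []
    for j in range(R):
        mu = 1.0
        for i in range(n):
            arg = (x[i] - centers[j][i]) ** 2 / (2.0 * spreads[j][i] ** 2)
            mu *= math.exp(-min(arg, 700.0))
        prod = 1.0
        for i in range(n):
            prod *= psi((x[i] - translations[j][i]) / dilations[j][i])
        mus.append(mu)
        psihats.append(weights[j] * prod)
    num = sum(m * p for m, p in zip(mus, psihats))
    if aggregation == "sum":
        return num
    return num / sum(mus)


def wavelet_neuron_scalar(x, a_row, b_row, w, wavelet="mexican_hat"):
    psi = _PSI[wavelet]
    prod = 1.0
    for xi, ai, bi in zip(x, a_row, b_row):
        prod *= psi((xi - bi) / ai)
    return w * prod


def metrics_scalar(observed, predicted):
    """(mse, rmse, mape_percent, r_squared) by plain loops."""
    n = len(observed)
    mse = sum((o - p) ** 2 for o, p in zip(observed, predicted)) / n
    mape = 100.0 * sum(abs(o - p) / abs(o) for o, p in zip(observed, predicted)) / n
    mean = sum(observed) / n
    ss_tot = sum((o - mean) ** 2 for o in observed)
    r2 = 1.0 - sum((o - p) ** 2 for o, p in zip(observed, predicted)) / ss_tot
    return mse, math.sqrt(mse), mape, r2


def random_params(rng, n_rules, n_inputs):
    """Well-conditioned random parameter lists for oracle-equivalence draws."""
    def mat(lo, hi, sign=False):
        out = []
        for _ in range(n_rules):
            row = []
            for _ in range(n_inputs):
                v = rng.uniform(lo, hi)
                if sign and rng.random() < 0.5:
                    v = -v
                row.append(v)
            out.append(row)
        return out

    centers = mat(-1.5, 1.5)
    spreads = mat(0.3, 2.5, sign=True)
    dilations = mat(0.3, 2.5, sign=True)
    translations = mat(-1.5, 1.5)
    weights = [rng.uniform(-2.5, 2.5) for _ in range(n_rules)]
    return centers, spreads, dilations, translations, weights
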