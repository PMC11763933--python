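"""Independent brute-force reference implementations used as oracles.

Deliberately naive: explicit loops and textbook formulas, sharing no
code with the package's optimized paths.
"""

from __future__ import annotations

import numpy as np


def naive_lgs_codes(X: np.ndarray, pattern) -> np.ndarray:
    """Per-window, per-edge LGS evaluation straight from the pattern table."""
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    R, C = pattern.block_rows, pattern.block_cols
    out = np.zeros((m - R + 1, n - C + 1), dtype=int)
    for r in range(m - R + 1):
        for c in range(n - C + 1):
            block = X[r : r + R, c : c + C]
            code = 0
            for edges, positions in pattern.groups:
                sub = 0
                for ((rf, cf), (rt, ct)), pos in zip(edges, positions):
                    bit = 1 if block[rf, cf] - block[rt, ct] >= 0 else 0
                    sub |= bit << pos
                code = code | sub  # OR-combination; identical for one group
            out[r, c] = code
    return out


def naive_granger_variances(
    source: np.ndarray, target: np.ndarray, p: int
) -> tuple[float, float]:
    """Textbook OLS residual variances (restricted, full) for lag order p.

    Both models fit on t = p .. n-1 with an intercept; variance uses
    divisor n_obs.
    """
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    n = len(target)
    rows_r, rows_f, y = [], [], []
    for t in range(p, n):
        own = [target[t - k] for k in range(1, p + 1)]
        cross = [source[t - k] for k in range(1, p + 1)]
        rows_r.append([1.0] + own)
        rows_f.append([1.0] + own + cross)
        y.append(target[t])
    y = np.array(y)
    var = []
    for rows in (rows_r, rows_f):
        Z = np.array(rows)
        coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ coef
        var.append(float(resid @ resid) / len(y))
    return var[0], var[1]


def metric_formulas(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Direct evaluation of the four confusion-matrix metrics."""
    total = tp + tn + fp + fn
    accuracy = (tp + tn) / total
    precision = tp / (tp + fp) if tp + fp else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity
        else 0.0
    )
    return {
        "accuracy": accuracy,
        "precision": precision,
        "sensitivity": sensitivity,
        "f1": f1,
    }


def simulate_bivariate_var2(
    n: int, coupling: float, seed: int, reverse: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Two-channel VAR(2): ch0 drives ch1 at lag 1 with the given strength.

    Independent of the package generator (different recursion layout).
    """
    rng = np.random.default_rng(seed)
    a1, a2 = 0.5, -0.2
    x = np.zeros(n + 200)
    y = np.zeros(n + 200)
    ex = rng.standard_normal(n + 200)
    ey = rng.standard_normal(n + 200)
    for t in range(2, n + 200):
        x[t] = a1 * x[t - 1] + a2 * x[t - 2] + ex[t]
        y[t] = a1 * y[t - 1] + a2 * y[t - 2] + coupling * x[t - 1] + ey[t]
    if reverse:
        x, y = y, x
    return x[200:], y[200:]
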