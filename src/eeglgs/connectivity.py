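"""Pairwise (bivariate) Granger causality between EEG channels.

For an ordered channel pair (source x, target y) two nested
autoregressions are fit by ordinary least squares on the same sample
range:

    restricted:  y(t) = c + sum_i a(i) y(t-i) + e(t)
    full:        y(t) = c + sum_i a(i) y(t-i) + sum_j b(j) x(t-j) + e~(t)

x Granger-causes y when adding the source lags reduces the residual
variance: the binary decision is 1 iff var(e~) < var(e). Because the
models are nested and fit on identical samples, the raw variance rule is
satisfied almost surely; a relative ``min_improvement`` guard and an
F-test mode (``binarize_mode="ftest"``) are provided for calibrated edge
detection. The raw variance rule remains the default.

Matrix convention: entry (i, j) is the decision for channel i as source
and channel j as target — rows cause columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError, ContractError, DegenerateSignalError
from .io_preprocess import BandDefinition, BandSegment


@dataclass(frozen=True)
class GrangerConfig:
    """Settings for the bivariate Granger fits and binarization."""

    lag_order: int | str = "auto"  # "auto" = BIC on the restricted model
    max_lag: int = 20
    order_criterion: str = "bic"
    binarize: bool = True
    binarize_mode: str = "variance"  # "variance" | "ftest"
    alpha: float = 0.05
    min_improvement: float = 0.0  # relative var reduction required in variance mode

    def __post_init__(self) -> None:
        if isinstance(self.lag_order, int):
            if not 1 <= self.lag_order <= self.max_lag:
                raise ConfigurationError(
                    f"need 1 <= lag_order <= max_lag, got {self.lag_order}, {self.max_lag}"
                )
        elif self.lag_order != "auto":
            raise ConfigurationError(f"lag_order must be int or 'auto', got {self.lag_order!r}")
        if self.order_criterion not in ("bic", "aic"):
            raise ConfigurationError(f"unknown order criterion {self.order_criterion!r}")
        if self.binarize_mode not in ("variance", "ftest"):
            raise ConfigurationError(f"unknown binarize_mode {self.binarize_mode!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class GrangerFit:
    """OLS results for one ordered pair, both nested models."""

    var_restricted: float
    var_full: float
    coef_a: np.ndarray  # target's own lag coefficients
    coef_b: np.ndarray  # source lag coefficients (full model)
    lag_order: int
    n_obs: int
    f_stat: float = np.nan
    p_value: float = np.nan


@dataclass
class ConnectivityMatrix:
    """Square channel x channel connectivity; rows cause columns."""

    values: np.ndarray
    binary: bool
    band: BandDefinition | None = None
    segment_index: int = 0
    subject_id: str = ""
    class_label: str | None = None
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n, m = self.values.shape
        if n != m:
            raise ContractError(f"connectivity matrix must be square, got {n}x{m}")
        if not np.all(np.isfinite(self.values)):
            raise ContractError("connectivity matrix contains NaN/Inf")
        if np.any(np.diag(self.values) != 0.0):
            raise ContractError("connectivity diagonal must be zero")
        if self.binary and not np.isin(self.values, (0.0, 1.0)).all():
            raise ContractError("binary connectivity matrix must contain only 0/1")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# OLS machinery (Gram-matrix formulation)
# ---------------------------------------------------------------------------

def _lag_design(data: np.ndarray, trim: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Precompute Gram blocks for all channels' lagged regressors.

    Returns (G, H, yty, Y) where Z = [1, lags(ch0, 1..trim), lags(ch1, ...)],
    G = Z'Z, H = Z'Y, and rows of ``data`` are channels. Column ``1 + c*trim + (k-1)``
    of Z holds channel c at lag k. All models are fit on t = trim..n-1 so
    nested comparisons share an identical sample range.
    """
    n_ch, n = data.shape
    n_obs = n - trim
    if n_obs < 10:
        raise ContractError(f"series too short: {n} samples for trim {trim}")
    Y = data[:, trim:].T  # n_obs x n_ch
    cols = [np.ones((n_obs, 1))]
    for c in range(n_ch):
        for k in range(1, trim + 1):
            cols.append(data[c, trim - k : n - k][:, None])
    Z = np.hstack(cols)
    G = Z.T @ Z
    H = Z.T @ Y
    yty = np.einsum("ij,ij->j", Y, Y)
    return G, H, yty, Y


def _rss(G: np.ndarray, H: np.ndarray, yty: np.ndarray, idx: list[int], j: int) -> tuple[float, np.ndarray]:
    """Residual sum of squares for regressing target j on columns ``idx``."""
    A = G[np.ix_(idx, idx)]
    b = H[idx, j]
    try:
        coef = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise DegenerateSignalError(
            f"singular design matrix for target channel {j} (constant or collinear series?)"
        ) from exc
    rss = float(yty[j] - coef @ b)
    return max(rss, 0.0), coef


def _select_order(
    G: np.ndarray, H: np.ndarray, yty: np.ndarray, j: int, trim: int, n_obs: int,
    criterion: str, col0: int,
) -> int:
    """Lag order for target j by information criterion on the restricted model."""
    best_p, best_ic = 1, np.inf
    for p in range(1, trim + 1):
        idx = [0] + list(range(col0, col0 + p))
        rss, _ = _rss(G, H, yty, idx, j)
        var = max(rss / n_obs, 1e-300)
        k = p + 1
        penalty = k * np.log(n_obs) if criterion == "bic" else 2.0 * k
        ic = n_obs * np.log(var) + penalty
        if ic < best_ic - 1e-12:
            best_ic, best_p = ic, p
    return best_p


def _pair_fit(
    G: np.ndarray, H: np.ndarray, yty: np.ndarray,
    i: int, j: int, p: int, trim: int, n_obs: int,
) -> GrangerFit:
    ci = 1 + i * trim
    cj = 1 + j * trim
    idx_r = [0] + list(range(cj, cj + p))
    idx_f = idx_r + list(range(ci, ci + p))
    rss_r, coef_r = _rss(G, H, yty, idx_r, j)
    rss_f, coef_f = _rss(G, H, yty, idx_f, j)
    df_den = n_obs - 2 * p - 1
    if rss_f > 0 and df_den > 0:
        f_stat = ((rss_r - rss_f) / p) / (rss_f / df_den)
        f_stat = max(f_stat, 0.0)
        p_value = float(stats.f.sf(f_stat, p, df_den))
    else:
        f_stat, p_value = np.nan, np.nan
    return GrangerFit(
        var_restricted=rss_r / n_obs,
        var_full=rss_f / n_obs,
        coef_a=coef_f[1 : 1 + p],
        coef_b=coef_f[1 + p :],
        lag_order=p,
        n_obs=n_obs,
        f_stat=f_stat,
        p_value=p_value,
    )


def fit_pair(source: np.ndarray, target: np.ndarray, cfg: GrangerConfig = GrangerConfig()) -> GrangerFit:
    """Fit restricted and full models for one ordered (source, target) pair."""
    source = np.asarray(source, dtype=np.float64).ravel()
    target = np.asarray(target, dtype=np.float64).ravel()
    if source.shape != target.shape:
        raise ContractError("source and target must have equal length")
    if not (np.all(np.isfinite(source)) and np.all(np.isfinite(target))):
        raise ContractError("series contain NaN/Inf")
    if source.std() == 0.0 or target.std() == 0.0:
        raise DegenerateSignalError("constant series cannot be fit")
    trim = cfg.max_lag if cfg.lag_order == "auto" else int(cfg.lag_order)
    data = np.vstack([source, target])
    G, H, yty, _ = _lag_design(data, trim)
    n_obs = data.shape[1] - trim
    if cfg.lag_order == "auto":
        p = _select_order(G, H, yty, 1, trim, n_obs, cfg.order_criterion, col0=1 + trim)
    else:
        p = int(cfg.lag_order)
    return _pair_fit(G, H, yty, i=0, j=1, p=p, trim=trim, n_obs=n_obs)


def granger_causes(fit: GrangerFit, cfg: GrangerConfig = GrangerConfig()) -> int:
    """Binary causality decision for a fitted pair.

    Variance mode: 1 iff var(full) < var(restricted) * (1 - min_improvement);
    ties yield 0. F-test mode: 1 iff the nested-model F-test p-value is
    below ``cfg.alpha``.
    """
    if cfg.binarize_mode == "ftest":
        return int(np.isfinite(fit.p_value) and fit.p_value < cfg.alpha)
    threshold = fit.var_restricted * (1.0 - cfg.min_improvement)
    return int(fit.var_full < threshold)


def granger_matrix(bs: BandSegment, cfg: GrangerConfig = GrangerConfig()) -> ConnectivityMatrix:
    """All-pairs Granger decisions for one normalized band segment.

    Entry (i, j) is 1 when channel i Granger-causes channel j under the
    configured rule; the diagonal is fixed at 0. With ``binarize=False``
    the entries are the relative variance reductions
    ``1 - var(full)/var(restricted)`` (clipped at 0).
    """
    if not bs.normalized:
        raise ContractError("granger_matrix requires a z-scored BandSegment")
    data = bs.data
    n_ch = data.shape[0]
    if n_ch < 2:
        raise ContractError("need at least 2 channels")
    trim = cfg.max_lag if cfg.lag_order == "auto" else int(cfg.lag_order)
    G, H, yty, _ = _lag_design(data, trim)
    n_obs = data.shape[1] - trim

    orders = np.empty(n_ch, dtype=int)
    for j in range(n_ch):
        if cfg.lag_order == "auto":
            orders[j] = _select_order(
                G, H, yty, j, trim, n_obs, cfg.order_criterion, col0=1 + j * trim
            )
        else:
            orders[j] = int(cfg.lag_order)

    values = np.zeros((n_ch, n_ch))
    for j in range(n_ch):
        p = int(orders[j])
        for i in range(n_ch):
            if i == j:
                continue
            try:
                fit = _pair_fit(G, H, yty, i, j, p, trim, n_obs)
            except DegenerateSignalError as exc:
                raise DegenerateSignalError(
                    f"pair (source={i}, target={j}): {exc}"
                ) from exc
            if cfg.binarize:
                values[i, j] = granger_causes(fit, cfg)
            else:
                vr = fit.var_restricted
                values[i, j] = max(1.0 - fit.var_full / vr, 0.0) if vr > 0 else 0.0
    return ConnectivityMatrix(
        values=values,
        binary=cfg.binarize,
        band=bs.band,
        segment_index=bs.segment_index,
        subject_id=bs.subject_id,
        class_label=bs.class_label,
    )
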