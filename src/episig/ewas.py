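"""Per-CpG differential-methylation testing (EWAS) and dual-threshold site
selection.

Each CpG site's M-values are regressed on an intercept, the binary
case/control status and any numeric covariates (sex, age, estimated blood
cell fractions). The status coefficient's t statistic and two-sided p-value
are reported together with the raw between-group mean M difference, and the
primary episignature sites are those passing both a genome-wide significance
threshold and an absolute mean-difference threshold.

The regression is ordinary least squares, vectorized across sites. An
optional moderated mode squeezes the per-site residual variances toward a
common prior (an empirical-Bayes shrinkage in the style of moderated
t-statistics), which stabilizes inference at small sample sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .exceptions import DomainError, EmptySignatureError


def fit_ewas(
    m_values: pd.DataFrame,
    status,
    covariates: pd.DataFrame | None = None,
    moderated: bool = False,
) -> pd.DataFrame:
    """Site-wise regression of M-values on case status with covariate adjustment.

    Parameters
    ----------
    m_values
        Sites × samples M-value matrix (complete cases; no NaN).
    status
        Binary (0/1) vector over samples; 1 = case. Both classes required.
    covariates
        Optional samples × covariates numeric DataFrame, aligned to the
        sample columns of ``m_values``. An intercept is always included.
    moderated
        If True, residual variances are shrunk toward an empirical-Bayes
        prior before forming t statistics (moderated t with augmented
        degrees of freedom).

    Returns
    -------
    DataFrame indexed by site with columns ``effect`` (adjusted status
    coefficient, M units), ``mean_diff`` (raw case−control mean M
    difference), ``t``, ``p``, and boolean ``constant`` flagging zero-variance
    sites (reported with effect 0, p 1).
    """
    y = np.asarray(status, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise DomainError("status must contain both classes, coded 0/1")
    Y = m_values.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise DomainError("EWAS requires complete cases; run QC filters first")
    n = Y.shape[1]
    cols = [np.ones(n), y]
    names = ["intercept", "status"]
    if covariates is not None:
        cov = covariates.loc[list(m_values.columns)]
        for c in cov.columns:
            cols.append(cov[c].to_numpy(dtype=float))
            names.append(str(c))
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise DomainError("design matrix is rank deficient (collinear covariates)")

    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T                      # p × n
    B = Y @ H.T                            # sites × p
    resid = Y - B @ X.T
    df = n - X.shape[1]
    if df <= 0:
        raise DomainError("no residual degrees of freedom")
    s2 = (resid**2).sum(axis=1) / df

    const = Y.var(axis=1) == 0.0
    t_df = float(df)
    if moderated:
        d0, s0_2 = _squeeze_var_prior(s2[~const], df)
        s2 = np.where(const, s2, (d0 * s0_2 + df * s2) / (d0 + df))
        t_df = df + d0

    se = np.sqrt(s2 * XtX_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = B[:, 1] / se
    p = 2.0 * stats.t.sf(np.abs(t), t_df)

    mean_diff = Y[:, y == 1].mean(axis=1) - Y[:, y == 0].mean(axis=1)
    effect = B[:, 1].copy()
    effect[const] = 0.0
    t[const] = 0.0
    p[const] = 1.0
    mean_diff[const] = 0.0
    return pd.DataFrame(
        {"effect": effect, "mean_diff": mean_diff, "t": t, "p": p, "constant": const},
        index=m_values.index,
    )


def _squeeze_var_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (d0, s0²) to observed
    residual variances, using the log-variance mean/variance identities of
    the chi-square distribution. Returns (d0, s0²); d0 = inf collapses to the
    common-variance limit and is capped at a large finite value."""
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return 0.0, float(s2.mean()) if s2.size else 1.0
    z = np.log(s2)
    e = z.mean() - special.digamma(df / 2.0) + np.log(df / 2.0)
    v = z.var(ddof=1) - special.polygamma(1, df / 2.0)
    if v <= 0:
        return 1e6, float(np.exp(e))
    # invert trigamma by Newton iteration (monotone decreasing)
    x = 0.5 + 1.0 / v
    for _ in range(50):
        tri = special.polygamma(1, x)
        delta = tri * (1.0 - tri / v) / special.polygamma(2, x)
        x += delta
        if abs(delta) < 1e-10 * x:
            break
    d0 = 2.0 * x
    s0_2 = np.exp(e - special.digamma(x) + np.log(x))
    return float(d0), float(s0_2)


def select_sites(
    result: pd.DataFrame,
    p_thresh: float = 5e-8,
    diff_thresh: float = 0.4,
) -> list:
    """Primary episignature selection: p < ``p_thresh`` AND |mean_diff| >
    ``diff_thresh`` (both strict), ordered by ascending p.

    The mean-difference threshold applies to the raw between-group M-value
    difference. Raises :class:`EmptySignatureError` when nothing passes.
    """
    if p_thresh <= 0 or diff_thresh < 0:
        raise DomainError("thresholds must be positive")
    mask = (result["p"] < p_thresh) & (result["mean_diff"].abs() > diff_thresh)
    selected = result[mask].sort_values("p")
    if selected.empty:
        raise EmptySignatureError(
            f"no site passed p < {p_thresh:g} and |mean_diff| > {diff_thresh:g}"
        )
    return list(selected.index)
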