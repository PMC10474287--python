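"""Mean normalized methylation deviation and its association with age at
disease onset.

The deviation statistic summarizes how far an individual's methylation at
the episignature CpG sites departs from the control distribution: per site
z = (M − μ_control)/σ_control, and the statistic is the mean |z| over the
episignature sites. In an allelic series, stronger variants produce larger
deviations; association with age at onset is assessed by Cox
proportional-hazards regression with right-censoring (onset not yet
observed at examination) and a likelihood-ratio test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .exceptions import DomainError


def control_reference(
    m_values: pd.DataFrame, control_ids, signature_sites
) -> tuple[pd.Series, pd.Series]:
    """Per-site control mean and SD (n−1 denominator) at the episignature
    sites; the reference against which z-values are formed."""
    sub = m_values.loc[list(signature_sites), list(control_ids)]
    return sub.mean(axis=1), sub.std(axis=1, ddof=1)


def mean_norm_meth_deviation(
    sample_m,
    control_mean: pd.Series,
    control_sd: pd.Series,
    signature_sites=None,
):
    """Mean absolute z over the episignature sites.

    ``sample_m`` may be a Series (one sample) or a sites × samples
    DataFrame; returns a float or a per-sample Series accordingly. Sites
    with zero control SD are dropped with a warning.
    """
    sites = list(signature_sites) if signature_sites is not None else list(control_mean.index)
    mu = control_mean.loc[sites]
    sd = control_sd.loc[sites]
    ok = sd > 0
    if not ok.all():
        warnings.warn(
            f"dropping {(~ok).sum()} site(s) with zero control SD", stacklevel=2
        )
        sites = list(mu.index[ok])
        mu, sd = mu[ok], sd[ok]
    if not sites:
        raise DomainError("no usable signature sites (all zero control SD)")
    if isinstance(sample_m, pd.DataFrame):
        z = sample_m.loc[sites].sub(mu, axis=0).div(sd, axis=0)
        return z.abs().mean(axis=0)
    z = (sample_m.loc[sites] - mu) / sd
    return float(z.abs().mean())


def onset_association(scores, age_at_onset, observed) -> dict:
    """Cox proportional-hazards fit of onset age on the deviation score.

    Right-censored samples (``observed`` 0) enter risk sets only. Returns
    the hazard ratio with 95% CI, the likelihood-ratio statistic and its
    p-value. Requires at least 3 observed events.
    """
    df = pd.DataFrame(
        {"score": np.asarray(scores, dtype=float),
         "time": np.asarray(age_at_onset, dtype=float),
         "event": np.asarray(observed, dtype=int)}
    )
    if not np.isfinite(df["score"]).all():
        raise DomainError("scores must be finite")
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise DomainError("no observed onset events")
    if n_events < 3:
        raise DomainError(f"need >= 3 observed events, got {n_events}")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    lr = cph.log_likelihood_ratio_test()
    ci = cph.confidence_intervals_
    return {
        "hazard_ratio": float(np.exp(cph.params_["score"])),
        "hr_ci_low": float(np.exp(ci.iloc[0, 0])),
        "hr_ci_high": float(np.exp(ci.iloc[0, 1])),
        "lr_statistic": float(lr.test_statistic),
        "p": float(lr.p_value),
        "n_events": n_events,
    }


def correlation_with_proxy(
    scores, age_at_onset, observed, age_at_exam
) -> tuple[float, float, float]:
    """Pearson correlation between deviation score and age at onset, using
    age at examination as proxy for the censored samples. Returns
    (r, r², p)."""
    s = np.asarray(scores, dtype=float)
    onset = np.asarray(age_at_onset, dtype=float)
    obs = np.asarray(observed, dtype=int)
    proxy = np.where(obs == 1, onset, np.asarray(age_at_exam, dtype=float))
    if np.isnan(s).any() or np.isnan(proxy).any():
        raise DomainError("inputs must be complete")
    if s.size < 3:
        raise DomainError("need at least 3 points")
    r, p = stats.pearsonr(s, proxy)
    return float(r), float(r * r), float(p)
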