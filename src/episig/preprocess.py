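"""Methylation-matrix containers, beta/M conversion, probe & sample QC, and
PCA-ellipse outlier detection.

The central container is :class:`BetaMatrix`, a thin wrapper around a
sites × samples :class:`pandas.DataFrame` of methylation fractions
(beta values, strictly inside (0, 1)), optionally carrying per-cell
detection p-values and per-site boolean annotation flags (sex-chromosome,
SNP-overlapping, cross-reactive probes).

All statistics downstream run on M-values, M = log2(beta / (1 - beta)),
the variance-stabilized logit scale customary for array methylation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError, EmptyCohortError

PROBE_FLAG_COLUMNS = ("sex_chromosome", "snp_overlap", "cross_reactive")


@dataclass
class BetaMatrix:
    """Sites × samples methylation fractions with optional QC metadata.

    Parameters
    ----------
    values
        DataFrame indexed by CpG site ID, columns are sample IDs; entries
        are beta values in the open interval (0, 1). NaN marks a failed
        (uncalled) measurement.
    detection_p
        Optional DataFrame of per-cell detection p-values, same shape.
    flags
        Optional boolean DataFrame indexed by site ID whose columns are a
        subset of ``PROBE_FLAG_COLUMNS``.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    flags: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise DomainError(f"duplicate site ID {dup!r}")
        vals = self.values.to_numpy(dtype=float)
        bad = (vals <= 0.0) | (vals >= 1.0)
        if np.any(bad & ~np.isnan(vals)):
            i, j = np.argwhere(bad & ~np.isnan(vals))[0]
            raise DomainError(
                f"beta value {vals[i, j]!r} outside (0,1) at site "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )
        if self.detection_p is not None and self.detection_p.shape != self.values.shape:
            raise DomainError("detection_p shape differs from values")

    @property
    def site_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset(self, sites=None, samples=None) -> "BetaMatrix":
        """Restrict to the given sites and/or samples (order preserved)."""
        v = self.values
        d = self.detection_p
        f = self.flags
        if sites is not None:
            v = v.loc[sites]
            d = d.loc[sites] if d is not None else None
            f = f.loc[f.index.intersection(v.index)] if f is not None else None
        if samples is not None:
            v = v[list(samples)]
            d = d[list(samples)] if d is not None else None
        return BetaMatrix(v, d, f, dict(self.meta))

    # ----- TSV round trip ---------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "site_id"
        out.to_csv(path, sep="\t", na_rep=".")

    @classmethod
    def from_tsv(cls, path, detection_p=None, flags=None) -> "BetaMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0, na_values=".")
        dp = (
            pd.read_csv(detection_p, sep="\t", index_col=0, na_values=".")
            if detection_p is not None
            else None
        )
        fl = pd.read_csv(flags, sep="\t", index_col=0).astype(bool) if flags is not None else None
        return cls(values, dp, fl)


def beta_to_m(beta) -> pd.DataFrame:
    """M-value transform, M = log2(beta / (1 - beta)).

    Accepts a :class:`BetaMatrix`, DataFrame, Series or array; beta must be
    strictly inside (0, 1) (NaN passes through). Raises :class:`DomainError`
    naming the offending site/sample otherwise.
    """
    if isinstance(beta, BetaMatrix):
        beta = beta.values
    arr = np.asarray(beta, dtype=float)
    bad = ((arr <= 0.0) | (arr >= 1.0)) & ~np.isnan(arr)
    if np.any(bad):
        idx = np.argwhere(bad)[0]
        loc = ""
        if isinstance(beta, pd.DataFrame):
            loc = f" at site {beta.index[idx[0]]!r}, sample {beta.columns[idx[1]]!r}"
        elif isinstance(beta, pd.Series):
            loc = f" at {beta.index[idx[0]]!r}"
        raise DomainError(f"beta outside (0,1){loc}; cannot form M-value")
    m = np.log2(arr / (1.0 - arr))
    if isinstance(beta, (pd.DataFrame, pd.Series)):
        return beta.__class__(m, index=beta.index, **(
            {"columns": beta.columns} if isinstance(beta, pd.DataFrame) else {}
        ))
    return m


def m_to_beta(m):
    """Inverse M-value transform, beta = 2^M / (1 + 2^M)."""
    if isinstance(m, (pd.DataFrame, pd.Series)):
        arr = m.to_numpy(dtype=float)
        out = 1.0 / (1.0 + np.exp2(-arr))
        return m.__class__(out, index=m.index, **(
            {"columns": m.columns} if isinstance(m, pd.DataFrame) else {}
        ))
    arr = np.asarray(m, dtype=float)
    return 1.0 / (1.0 + np.exp2(-arr))


def filter_probes(
    matrix: BetaMatrix,
    masks: dict[str, list] | None = None,
    det_p_thresh: float = 0.01,
    call_rate_thresh: float = 0.95,
    det_p_fail_fraction: float = 0.0,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Drop probes failing detection, annotation-mask, or call-rate criteria.

    A probe is excluded when the fraction of samples with detection
    p > ``det_p_thresh`` exceeds ``det_p_fail_fraction`` (default 0: a single
    failing sample excludes the probe — the strict rule), when it carries any
    mask flag (sex-chromosome, SNP-overlapping, cross-reactive; from
    ``matrix.flags`` and/or the ``masks`` dict of ID lists), or when its call
    rate across samples falls below ``call_rate_thresh``.

    Returns the filtered matrix and an exclusion report with columns
    ``site_id`` and ``reason`` (first matching reason per probe, in the order
    detection_p, mask flags, call_rate). Mask IDs absent from the matrix
    produce a warning, not an error.
    """
    if not (0.0 < det_p_thresh <= 1.0 and 0.0 < call_rate_thresh <= 1.0):
        raise DomainError("thresholds must lie in (0, 1]")
    reasons: dict = {}

    if matrix.detection_p is not None:
        fail_frac = (matrix.detection_p > det_p_thresh).mean(axis=1)
        for site in matrix.site_ids[fail_frac > det_p_fail_fraction]:
            reasons.setdefault(site, "detection_p")

    flag_sets: dict[str, set] = {name: set() for name in PROBE_FLAG_COLUMNS}
    if matrix.flags is not None:
        for name in matrix.flags.columns:
            flag_sets.setdefault(name, set()).update(
                matrix.flags.index[matrix.flags[name].astype(bool)]
            )
    for name, ids in (masks or {}).items():
        unknown = set(ids) - set(matrix.site_ids)
        if unknown:
            warnings.warn(
                f"mask {name!r} references {len(unknown)} unknown probe IDs", stacklevel=2
            )
        flag_sets.setdefault(name, set()).update(ids)
    for name in PROBE_FLAG_COLUMNS:
        for site in matrix.site_ids:
            if site in flag_sets.get(name, ()):
                reasons.setdefault(site, name)

    call_rate = matrix.values.notna().mean(axis=1)
    for site in matrix.site_ids[call_rate < call_rate_thresh]:
        reasons.setdefault(site, "call_rate")

    keep = [s for s in matrix.site_ids if s not in reasons]
    report = pd.DataFrame(
        {"site_id": list(reasons), "reason": list(reasons.values())}
    )
    return matrix.subset(sites=keep), report


def filter_samples(
    matrix: BetaMatrix,
    mean_det_p_thresh: float = 0.05,
    call_rate_thresh: float = 0.95,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Drop samples with mean detection p above threshold or low call rate."""
    if not (0.0 < mean_det_p_thresh <= 1.0 and 0.0 < call_rate_thresh <= 1.0):
        raise DomainError("thresholds must lie in (0, 1]")
    reasons: dict = {}
    if matrix.detection_p is not None:
        mean_p = matrix.detection_p.mean(axis=0)
        for sid in matrix.sample_ids[mean_p > mean_det_p_thresh]:
            reasons.setdefault(sid, "mean_detection_p")
    call_rate = matrix.values.notna().mean(axis=0)
    for sid in matrix.sample_ids[call_rate < call_rate_thresh]:
        reasons.setdefault(sid, "call_rate")
    keep = [s for s in matrix.sample_ids if s not in reasons]
    if not keep:
        raise EmptyCohortError("all samples failed QC")
    report = pd.DataFrame({"sample_id": list(reasons), "reason": list(reasons.values())})
    return matrix.subset(samples=keep), report


def pca_outlier_ellipse(
    m_values: pd.DataFrame,
    coverage: float = 0.99,
    border_tol: float = 0.01,
) -> pd.DataFrame:
    """Classify samples against the confidence ellipse of the first two PCs.

    Samples are observations, sites features; the matrix is centered per site
    (no scaling — M-values share a scale). The ellipse is the set of points
    whose squared Mahalanobis distance in (PC1, PC2), under the empirical PC
    covariance (diagonal by construction), is at most the chi-square(2)
    quantile at ``coverage``. A sample within ``border_tol`` (relative) of
    that quantile is reported ``border``, mirroring cohort descriptions of
    samples "within or at the border" of the ellipse.

    Returns a DataFrame indexed by sample with columns pc1, pc2, mahal_sq and
    classification in {inside, border, outside}.
    """
    if m_values.shape[1] < 3:
        raise DomainError("PCA ellipse needs at least 3 samples")
    X = m_values.to_numpy(dtype=float).T  # samples × sites
    X = X - X.mean(axis=0, keepdims=True)
    # economy SVD; PCs = left singular vectors scaled by singular values
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    if S.size < 2 or S[1] <= S[0] * 1e-12:
        raise DomainError("input is rank-deficient: fewer than 2 non-degenerate PCs")
    scores = U[:, :2] * S[:2]
    var = scores.var(axis=0, ddof=1)
    d2 = (scores**2 / var).sum(axis=1)
    q = stats.chi2.ppf(coverage, df=2)
    cls = np.where(
        np.abs(d2 - q) <= border_tol * q, "border", np.where(d2 <= q, "inside", "outside")
    )
    return pd.DataFrame(
        {"pc1": scores[:, 0], "pc2": scores[:, 1], "mahal_sq": d2, "classification": cls},
        index=m_values.columns,
    )
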