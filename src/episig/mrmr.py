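"""Minimum-redundancy-maximum-relevance (mRMR) feature selection over
EWAS-selected CpG sites: the classical greedy algorithm and its bootstrap
ensemble variant.

Relevance and redundancy are measured by the Gaussian mutual-information
surrogate MI(x, y) = −ln(1 − ρ(x, y)²)/2 nats, with ρ the Pearson
correlation (point-biserial for the 0/1 phenotype). The greedy step picks
the candidate maximizing MI with the phenotype minus the mean MI with the
already-selected sites. The ensemble variant runs the classical algorithm on
b class-stratified bootstrap resamples of the samples and unites the
selected sites, which compresses a correlated EWAS hit list far below the
b·s ceiling while retaining independent information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError

#: MI assigned when |rho| = 1 within floating point (perfectly collinear).
MI_CAP = -0.5 * np.log(1e-15)


@dataclass
class MrmrConfig:
    """Ensemble settings: ``n_bootstraps`` b ≥ 1 resamples, each running
    classical mRMR with solution length ``solution_length`` s ≥ 1."""

    n_bootstraps: int = 20
    solution_length: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bootstraps < 1 or self.solution_length < 1:
            raise ConfigurationError("n_bootstraps and solution_length must be >= 1")


@dataclass
class MrmrSelection:
    """Result of the bootstrap ensemble: per-bootstrap ordered selections,
    their deduplicated union (ordered by first appearance), and provenance
    (which bootstraps chose each site)."""

    per_bootstrap: list[list]
    union: list
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for site in self.union:
            chosen_by = self.provenance.get(site, [])
            first_rank = min(
                self.per_bootstrap[b].index(site) for b in chosen_by
            )
            rows.append((site, len(chosen_by), first_rank))
        return pd.DataFrame(rows, columns=["site_id", "n_bootstraps_chosen", "first_rank"])


def mutual_info(x, y) -> float:
    """Gaussian-form mutual information −ln(1−ρ²)/2 in nats.

    Constant input yields MI 0 with a warning; |ρ| = 1 is capped at
    ``MI_CAP`` with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise DomainError("vectors must share length >= 3")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        warnings.warn("constant vector: MI defined as 0", stacklevel=2)
        return 0.0
    rho = np.corrcoef(x, y)[0, 1]
    return _mi_from_rho(rho)


def _mi_from_rho(rho: float) -> float:
    r2 = rho * rho
    if r2 >= 1.0 - 1e-15:
        warnings.warn("|rho| = 1: MI capped", stacklevel=3)
        return float(MI_CAP)
    return float(-0.5 * np.log1p(-r2))


def _mi_matrix_with_target(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Relevance MI of each row of X (features × samples) with y."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (Xc @ yc) / (sx * sy)
    rho = np.nan_to_num(rho, nan=0.0)
    r2 = np.minimum(rho * rho, 1.0 - 1e-15)
    return -0.5 * np.log1p(-r2)


def _pairwise_mi_column(X: np.ndarray, j: int) -> np.ndarray:
    """MI of feature j with every feature (features × samples input)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    s = np.sqrt((Xc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (Xc @ Xc[j]) / (s * s[j])
    rho = np.nan_to_num(rho, nan=0.0)
    r2 = np.minimum(rho * rho, 1.0 - 1e-15)
    return -0.5 * np.log1p(-r2)


def mrmr_classic(
    m_sites: pd.DataFrame,
    y,
    max_size: int,
    tie_break_p: pd.Series | None = None,
) -> list:
    """Greedy mRMR: start from the site with maximal MI with the phenotype,
    then repeatedly add the candidate maximizing
    MI(x, y) − mean_{j∈S} MI(x, x_j); stop at ``max_size`` or exhaustion.

    ``m_sites`` is sites × samples. Score ties are broken by ascending
    ``tie_break_p`` (e.g. EWAS p-values), then lexicographic site ID, for
    determinism.
    """
    if max_size < 1:
        raise DomainError("max_size must be >= 1")
    if m_sites.shape[0] < 1:
        raise DomainError("need at least one candidate site")
    sites = list(m_sites.index)
    X = m_sites.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    relevance = _mi_matrix_with_target(X, yv)
    pvals = (
        tie_break_p.reindex(sites).to_numpy(dtype=float)
        if tie_break_p is not None
        else np.full(len(sites), np.nan)
    )

    def keyed(order_scores: np.ndarray, candidates: list[int]) -> int:
        # max score; ties -> min p, then min site id
        best = None
        for i in candidates:
            k = (-order_scores[i], pvals[i] if np.isfinite(pvals[i]) else np.inf, str(sites[i]))
            if best is None or k < best[0]:
                best = (k, i)
        return best[1]

    remaining = list(range(len(sites)))
    selected: list[int] = []
    redundancy_sum = np.zeros(len(sites))
    while remaining and len(selected) < max_size:
        if selected:
            score = relevance - redundancy_sum / len(selected)
        else:
            score = relevance
        pick = keyed(score, remaining)
        selected.append(pick)
        remaining.remove(pick)
        if remaining and len(selected) < max_size:
            redundancy_sum += _pairwise_mi_column(X, pick)
    return [sites[i] for i in selected]


def mrmr_ensemble_bootstrap(
    m_sites: pd.DataFrame,
    y,
    config: MrmrConfig,
    tie_break_p: pd.Series | None = None,
    resample: bool = True,
) -> MrmrSelection:
    """Bootstrap-ensemble mRMR: b stratified resamples of the samples, each
    running classical mRMR with solution length s; the union of the b
    selections is the episignature candidate set.

    Resampling is stratified by class (cases and controls drawn separately
    with replacement, preserving counts) so no bootstrap loses a class.
    ``resample=False`` makes every bootstrap the identity sample (with b=1
    this reduces to :func:`mrmr_classic`). Deterministic given
    ``config.seed``.
    """
    yv = np.asarray(y, dtype=float)
    if (yv == 1).sum() < 2 or (yv == 0).sum() < 2:
        raise DomainError("need at least 2 samples per class")
    rng = np.random.default_rng(config.seed)
    idx_case = np.flatnonzero(yv == 1)
    idx_ctrl = np.flatnonzero(yv == 0)
    per_bootstrap: list[list] = []
    for _ in range(config.n_bootstraps):
        if resample:
            take = np.concatenate(
                [rng.choice(idx_case, size=idx_case.size, replace=True),
                 rng.choice(idx_ctrl, size=idx_ctrl.size, replace=True)]
            )
        else:
            take = np.arange(yv.size)
        sel = mrmr_classic(
            m_sites.iloc[:, take], yv[take], config.solution_length, tie_break_p
        )
        per_bootstrap.append(sel)
    union: list = []
    provenance: dict = {}
    for b, sel in enumerate(per_bootstrap):
        for site in sel:
            if site not in provenance:
                union.append(site)
                provenance[site] = []
            provenance[site].append(b)
    return MrmrSelection(per_bootstrap, union, provenance)
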