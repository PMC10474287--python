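"""Linear SVM episignature classifier with Platt probability scores,
stepwise re-training, specificity evaluation, and the classifier-length
performance sweep.

The classifier is a linear-kernel maximum-margin machine on the M-values of
the selected CpG sites, with Platt sigmoid calibration fit by internal
cross-validation so that each sample receives a probability-of-case score in
[0, 1]; the decision cut-off is 0.5 throughout.

Stepwise re-training addresses the sensitivity limit of episignatures
trained only on unambiguous strong-effect cases: the classifier scores all
candidate carriers, every candidate reaching 0.5 joins the case set, and the
whole chain (EWAS site selection → bootstrap-ensemble mRMR → SVM) is re-run
until the case set stops changing. This recovers moderate-effect and mosaic
carriers while the controls anchor specificity.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from . import ewas as _ewas
from . import mrmr as _mrmr
from .exceptions import DomainError, EmptySignatureError, PipelineError

#: Single probability cut-off used for classification everywhere.
SCORE_THRESHOLD = 0.5


@dataclass
class EpisignatureModel:
    """A trained episignature: ordered CpG site list, fitted linear SVM with
    cross-validated Platt sigmoid calibration, and training provenance."""

    site_ids: list
    clf: CalibratedClassifierCV
    case_ids: list
    control_ids: list
    stage: int = 0
    cost: float = 1.0
    seed: int = 0
    cv_accuracy: float | None = None
    cv_folds: int | None = None

    @property
    def training_ids(self) -> set:
        return set(self.case_ids) | set(self.control_ids)

    @property
    def linear_svc(self) -> SVC:
        """The underlying maximum-margin classifier (weight vector etc.)."""
        return self.clf.calibrated_classifiers_[0].estimator

    def to_dict(self) -> dict:
        cal = self.clf.calibrated_classifiers_[0].calibrators[0]
        return {
            "site_ids": list(self.site_ids),
            "case_ids": list(self.case_ids),
            "control_ids": list(self.control_ids),
            "stage": self.stage,
            "cost": self.cost,
            "seed": self.seed,
            "cv_accuracy": self.cv_accuracy,
            "cv_folds": self.cv_folds,
            "coef": self.linear_svc.coef_.ravel().tolist(),
            "intercept": float(self.linear_svc.intercept_[0]),
            "platt_a": float(cal.a_),
            "platt_b": float(cal.b_),
        }


def train(
    m_values: pd.DataFrame,
    case_ids,
    control_ids,
    sites=None,
    cost: float = 1.0,
    seed: int = 0,
    class_weight: str | dict | None = "balanced",
    cv_folds: int = 10,
    stage: int = 0,
) -> EpisignatureModel:
    """Fit the linear SVM episignature classifier on M-values.

    ``m_values`` is sites × samples; ``sites`` restricts to the selected
    episignature (default: all rows). Platt sigmoid calibration is fit
    internally (cross-validated), and a stratified ``cv_folds``-fold
    cross-validated accuracy is recorded; the fold count is reduced with a
    warning when a class has fewer members than folds. Class imbalance is
    handled by inverse-frequency class weights by default.
    """
    case_ids, control_ids = list(case_ids), list(control_ids)
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise DomainError("need at least 2 cases and 2 controls")
    if sites is None:
        sites = list(m_values.index)
    sites = list(sites)
    missing = [s for s in sites if s not in m_values.index]
    if missing:
        raise DomainError(f"sites absent from matrix: {missing[:5]}")
    samples = case_ids + control_ids
    X = m_values.loc[sites, samples].to_numpy(dtype=float).T
    y = np.array([1] * len(case_ids) + [0] * len(control_ids))

    folds = min(cv_folds, len(case_ids), len(control_ids))
    if folds < cv_folds:
        warnings.warn(
            f"reducing CV folds from {cv_folds} to {folds} (smallest class)", stacklevel=2
        )
    svc = SVC(kernel="linear", C=cost, class_weight=class_weight)
    calib_folds = min(5, len(case_ids), len(control_ids))
    clf = CalibratedClassifierCV(
        svc, method="sigmoid", ensemble=False,
        cv=StratifiedKFold(n_splits=calib_folds, shuffle=True, random_state=seed),
    )
    cv_acc = None
    if folds >= 2:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        cv_acc = float(cross_val_score(SVC(kernel="linear", C=cost, class_weight=class_weight), X, y, cv=cv).mean())
    clf.fit(X, y)
    return EpisignatureModel(
        site_ids=sites, clf=clf, case_ids=case_ids, control_ids=control_ids,
        stage=stage, cost=cost, seed=seed, cv_accuracy=cv_acc, cv_folds=folds,
    )


@dataclass
class LinearScorer:
    """Binary-free form of a trained episignature model: the linear decision
    function f(x) = w·x + b over the site M-values and the Platt sigmoid
    P(case) = 1/(1 + exp(a·f + b_platt)). Round-trips through JSON/TSV."""

    site_ids: list
    coef: np.ndarray
    intercept: float
    platt_a: float
    platt_b: float

    @classmethod
    def from_dict(cls, d: dict) -> "LinearScorer":
        return cls(list(d["site_ids"]), np.asarray(d["coef"], dtype=float),
                   float(d["intercept"]), float(d["platt_a"]), float(d["platt_b"]))

    @classmethod
    def from_model(cls, model: "EpisignatureModel") -> "LinearScorer":
        d = model.to_dict()
        return cls.from_dict(d)

    @property
    def training_ids(self) -> set:
        return set()


def score(model, m_values: pd.DataFrame) -> pd.Series:
    """Platt probability score in [0, 1] for every sample column.

    ``model`` may be an :class:`EpisignatureModel` or a
    :class:`LinearScorer`. Classification is score ≥ 0.5. Raises if any
    model site is missing from the matrix.
    """
    missing = [s for s in model.site_ids if s not in m_values.index]
    if missing:
        raise DomainError(f"model sites missing from matrix: {missing[:5]}")
    X = m_values.loc[model.site_ids].to_numpy(dtype=float).T
    if isinstance(model, LinearScorer):
        f = X @ model.coef + model.intercept
        probs = 1.0 / (1.0 + np.exp(model.platt_a * f + model.platt_b))
    else:
        case_col = int(np.flatnonzero(model.clf.classes_ == 1)[0])
        probs = model.clf.predict_proba(X)[:, case_col]
    return pd.Series(probs, index=m_values.columns, name="score")


@dataclass
class RetrainStep:
    """One re-training step: the case set it was trained on, the fitted
    model, and the scores of all candidates under that model."""

    case_ids: list
    model: EpisignatureModel
    candidate_scores: pd.Series


@dataclass
class RetrainTrajectory:
    steps: list[RetrainStep]
    stop_reason: str  # fixed_point | cycle | max_iter

    @property
    def final_model(self) -> EpisignatureModel:
        return self.steps[-1].model

    @property
    def final_case_ids(self) -> list:
        return self.steps[-1].case_ids

    def verified_candidates(self, threshold: float = SCORE_THRESHOLD) -> list:
        s = self.steps[-1].candidate_scores
        return list(s.index[s >= threshold])


def retrain_stepwise(
    m_values: pd.DataFrame,
    initial_cases,
    controls,
    candidates,
    covariates: pd.DataFrame | None = None,
    threshold: float = SCORE_THRESHOLD,
    max_iter: int = 10,
    p_thresh: float = 5e-8,
    diff_thresh: float = 0.4,
    mrmr_config: _mrmr.MrmrConfig | None = None,
    cost: float = 1.0,
    seed: int = 0,
    refit_sites: bool = True,
) -> RetrainTrajectory:
    """Iteratively enlarge the training case set with candidates scoring
    ≥ ``threshold`` and re-fit the full chain.

    Step 0 trains on the initial unambiguous cases. Each step runs EWAS on
    the current cases vs controls, dual-threshold site selection,
    bootstrap-ensemble mRMR, SVM training, then scores all candidates; the
    next case set is the initial cases plus every candidate at or above the
    threshold. Iteration stops at a fixed point, on a detected cycle, or at
    ``max_iter``. Initial cases are never removed. With
    ``refit_sites=False`` the step-0 site selection is frozen and only the
    SVM is re-fit each step.
    """
    initial_cases = list(initial_cases)
    controls = list(controls)
    candidates = list(candidates)
    if set(candidates) & set(controls):
        raise DomainError("candidates must be disjoint from controls")
    cfg = mrmr_config or _mrmr.MrmrConfig(seed=seed)

    steps: list[RetrainStep] = []
    seen: list[frozenset] = []
    current = list(initial_cases)
    frozen_sites: list | None = None
    stop_reason = "max_iter"
    for it in range(max_iter):
        training = current + controls
        status = pd.Series([1] * len(current) + [0] * len(controls), index=training)
        if refit_sites or frozen_sites is None:
            try:
                res = _ewas.fit_ewas(
                    m_values[training], status.to_numpy(),
                    covariates.loc[training] if covariates is not None else None,
                )
                selected = _ewas.select_sites(res, p_thresh, diff_thresh)
            except EmptySignatureError as err:
                raise PipelineError(
                    f"re-training step {it}: empty EWAS selection ({err})"
                ) from err
            msel = _mrmr.mrmr_ensemble_bootstrap(
                m_values.loc[selected, training], status.to_numpy(), cfg,
                tie_break_p=res["p"],
            )
            sites = msel.union
            if frozen_sites is None:
                frozen_sites = sites
        else:
            sites = frozen_sites
        model = train(
            m_values, current, controls, sites=sites, cost=cost, seed=seed, stage=it
        )
        cand_scores = (
            score(model, m_values[candidates]) if candidates else pd.Series(dtype=float)
        )
        steps.append(RetrainStep(list(current), model, cand_scores))

        nxt = sorted(
            set(initial_cases) | {c for c in candidates if cand_scores.get(c, 0.0) >= threshold}
        )
        key = frozenset(nxt)
        if key == frozenset(current):
            stop_reason = "fixed_point"
            break
        if key in seen:
            stop_reason = "cycle"
            break
        seen.append(frozenset(current))
        current = nxt
    return RetrainTrajectory(steps, stop_reason)


def evaluate_specificity(
    model: EpisignatureModel, independent_control_m: pd.DataFrame
) -> tuple[float, float, float]:
    """Specificity (fraction scoring < 0.5) and the 50th/95th score
    quantiles (empirical, linear interpolation) on controls that took no
    part in any training."""
    overlap = set(independent_control_m.columns) & model.training_ids
    if overlap:
        raise DomainError(f"independent controls overlap training: {sorted(overlap)[:5]}")
    s = score(model, independent_control_m)
    specificity = float((s < SCORE_THRESHOLD).mean())
    q50, q95 = (float(q) for q in np.quantile(s.to_numpy(), [0.5, 0.95]))
    return specificity, q50, q95


@dataclass
class SweepResult:
    """Outcome of the (b, s) configuration sweep: per-configuration rows,
    per-episignature-length averages, and plateau onsets."""

    configs: pd.DataFrame   # b, s, k, specificity, n_positive, pseudo_sensitivity
    per_k: pd.DataFrame     # k, specificity, pseudo_sensitivity (averaged)
    plateau: dict           # metric -> smallest stable k (or None)


def length_sweep(
    m_values: pd.DataFrame,
    cases,
    controls,
    candidates,
    independent_controls,
    covariates: pd.DataFrame | None = None,
    b_range=range(1, 21),
    s_range=range(2, 16),
    p_thresh: float = 5e-8,
    diff_thresh: float = 0.4,
    stability_tol: float = 0.015,
    window: int = 5,
    cost: float = 1.0,
    seed: int = 0,
) -> SweepResult:
    """Sweep classifier performance against episignature length k.

    One classifier per (b, s) pair — b bootstraps × mRMR solution length s
    over the fixed EWAS-selected site pool (the default 1..20 × 2..15 grid
    gives 280 configurations). For each configuration the resulting
    episignature length k = |union|, the specificity on independent
    controls, and the number of candidates verified positive are recorded;
    pseudo-sensitivity is that count divided by its maximum over all
    configurations. Metrics are then averaged per realized k and the plateau
    onset is the smallest k from which every ``window``-wide run of realized
    k deviates at most ``stability_tol`` from its window mean.
    """
    cases, controls = list(cases), list(controls)
    candidates, independent_controls = list(candidates), list(independent_controls)
    training = cases + controls
    status = pd.Series([1] * len(cases) + [0] * len(controls), index=training)
    res = _ewas.fit_ewas(
        m_values[training], status.to_numpy(),
        covariates.loc[training] if covariates is not None else None,
    )
    pool = _ewas.select_sites(res, p_thresh, diff_thresh)
    pool_m = m_values.loc[pool, training]

    ss = np.random.SeedSequence(seed)
    rows = []
    for i, (b, s) in enumerate(itertools.product(b_range, s_range)):
        child_seed = int(ss.spawn(i + 1)[-1].generate_state(1)[0] % (2**31))
        cfg = _mrmr.MrmrConfig(n_bootstraps=b, solution_length=s, seed=child_seed)
        msel = _mrmr.mrmr_ensemble_bootstrap(
            pool_m, status.to_numpy(), cfg, tie_break_p=res["p"]
        )
        model = train(m_values, cases, controls, sites=msel.union, cost=cost, seed=seed)
        spec, _, _ = evaluate_specificity(model, m_values[independent_controls])
        n_pos = (
            int((score(model, m_values[candidates]) >= SCORE_THRESHOLD).sum())
            if candidates
            else 0
        )
        rows.append((b, s, len(msel.union), spec, n_pos))
    configs = pd.DataFrame(rows, columns=["b", "s", "k", "specificity", "n_positive"])
    max_pos = configs["n_positive"].max()
    if max_pos == 0:
        warnings.warn("no configuration verified any candidate positive", stacklevel=2)
        configs["pseudo_sensitivity"] = 0.0
    else:
        configs["pseudo_sensitivity"] = configs["n_positive"] / max_pos

    per_k = (
        configs.groupby("k")[["specificity", "pseudo_sensitivity"]].mean().reset_index()
    )
    plateau = {
        m: _plateau_onset(per_k["k"].to_numpy(), per_k[m].to_numpy(), stability_tol, window)
        for m in ("specificity", "pseudo_sensitivity")
    }
    return SweepResult(configs, per_k, plateau)


def _plateau_onset(k: np.ndarray, v: np.ndarray, tol: float, window: int):
    """Smallest realized k from which every window of ``window`` consecutive
    realized k-values deviates at most ``tol`` from that window's mean."""
    n = len(k)
    if n < window:
        return None
    ok = np.array(
        [np.abs(v[i : i + window] - v[i : i + window].mean()).max() <= tol
         for i in range(n - window + 1)]
    )
    suffix_ok = np.logical_and.accumulate(ok[::-1])[::-1]
    hits = np.flatnonzero(suffix_ok)
    return int(k[hits[0]]) if hits.size else None


def compare_subthreshold_scores(
    vus_scores: pd.Series,
    control_scores: pd.Series,
    q95: float,
    families: pd.Series | None = None,
) -> float:
    """One-sided Wilcoxon rank-sum p for VUS-carrier scores exceeding
    independent-control scores, both restricted below the controls' 95th
    percentile; same-family carriers contribute their mean (one value per
    family). Continuity-corrected normal approximation, as in R's
    ``wilcox.test``."""
    vus = vus_scores[vus_scores < q95]
    ctrl = control_scores[control_scores < q95]
    if families is not None:
        fam = families.reindex(vus.index)
        fam = fam.fillna(pd.Series(vus.index, index=vus.index))
        vus = vus.groupby(fam).mean()
    if vus.empty or ctrl.empty:
        raise DomainError("a group is empty after the q95 filter")
    return float(
        stats.mannwhitneyu(
            vus.to_numpy(), ctrl.to_numpy(), alternative="greater",
            use_continuity=True, method="asymptotic",
        ).pvalue
    )


def plot_sweep(sweep: SweepResult, path) -> None:
    """Specificity and pseudo-sensitivity versus episignature length."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(sweep.per_k["k"], sweep.per_k["specificity"], "-", label="specificity")
    ax.plot(
        sweep.per_k["k"], sweep.per_k["pseudo_sensitivity"], "--",
        label="pseudo-sensitivity",
    )
    for metric, k0 in sweep.plateau.items():
        if k0 is not None:
            ax.axvline(k0, color="grey", lw=0.5)
    ax.set_xlabel("episignature length k (CpG sites)")
    ax.set_ylabel("metric")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
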