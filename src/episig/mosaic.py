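"""Mosaicism evaluation: binomial-deviation flagging, in-silico mosaic
synthesis, leave-2-out classifier ensembles, smoothed quantile bands, and
adjudication of suspected mosaics.

A heterozygous constitutive variant at read depth n is expected to show
n/2 variant-supporting reads; the signed deviation in binomial sampling-SD
units is (k − n/2)/(√n/2). A case is flagged as a potential mosaic when the
absolute deviation exceeds 2 SD, i.e. |k − n/2| > √n, which as a variant
read fraction is the threshold 0.5 − 1/√n.

Whether a flagged case is a genuine mosaic is adjudicated against in-silico
mosaics: methylation profiles mixed on the beta scale,
β_mix = d·β_affected + (1−d)·β_unaffected with mosaic degree d ~ U(0,1),
assigned a read depth from a truncated-normal depth model and a variant
read count k ~ Binomial(n, d/2), and scored by leave-2-out classifier
ensembles so that training variability propagates into the score
distribution. The 5th/95th score percentiles in 0.025-wide bins of variant
read fraction, loess-smoothed, form the reference band; a suspect whose
mean ensemble score exceeds the upper band at its variant read fraction is
likely an erroneous mosaic call (e.g. indel under-counting deflating the
reported VAF of a constitutive carrier).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import classifier as _classifier
from .exceptions import DomainError
from .preprocess import beta_to_m

#: Gene-specific read-depth presets (mean, SD, strict lower truncation).
DEPTH_PRESETS = {"KMT2B": (184.0, 93.0, 47), "KMT2D": (213.0, 121.0, 14)}


# ----- binomial-deviation arithmetic ---------------------------------------

def binomial_deviation(n: float, k: float) -> float:
    """Signed deviation of k variant reads from the heterozygous expectation
    n/2, in binomial SD units: (k − n/2)/(√n/2). k may be fractional after
    count correction."""
    if n < 1:
        raise DomainError("read depth must be >= 1")
    if not 0 <= k <= n:
        raise DomainError(f"variant reads k={k} outside [0, n={n}]")
    return (k - n / 2.0) / (math.sqrt(n) / 2.0)


def deviation_from_vaf(n: float, vaf: float) -> float:
    """Deviation in binomial SD units from a reported variant allele
    fraction: (vaf − 0.5)·2·√n. For table-reported (rounded) fractions."""
    if n < 1:
        raise DomainError("read depth must be >= 1")
    if not 0.0 <= vaf <= 1.0:
        raise DomainError(f"vaf={vaf} outside [0, 1]")
    return (vaf - 0.5) * 2.0 * math.sqrt(n)


def flag_potential_mosaic(n: float, k: float) -> tuple[bool, float]:
    """Flag when |k − n/2| > √n (2 binomial SD). Also returns the flagging
    threshold expressed as a variant read fraction, 0.5 − 1/√n."""
    if n < 1:
        raise DomainError("read depth must be >= 1")
    threshold_fraction = 0.5 - 1.0 / math.sqrt(n)
    return abs(k - n / 2.0) > math.sqrt(n), threshold_fraction


def correct_variant_count(called: float, extra_variant: float, noninformative: float) -> float:
    """Corrected variant read count after read re-examination: the called
    reads, plus reads misinterpreted as mismatches, plus half of the
    non-informative reads (assuming an unbiased distribution of allelic
    reads): k = called + extra_variant + noninformative/2."""
    if called < 0 or extra_variant < 0 or noninformative < 0:
        raise DomainError("counts must be non-negative")
    return called + extra_variant + noninformative / 2.0


# ----- in-silico mosaic construction ---------------------------------------

def synthesize_mosaic(beta_affected: pd.Series, beta_unaffected: pd.Series, d: float) -> pd.Series:
    """Mix two beta profiles on the beta scale:
    β_mix = d·β_affected + (1−d)·β_unaffected, elementwise. M-values of the
    mixture must be recomputed from β_mix (mixing is affine on the beta
    scale, not on the M scale)."""
    if not 0.0 <= d <= 1.0:
        raise DomainError(f"mosaic degree d={d} outside [0, 1]")
    if not beta_affected.index.equals(beta_unaffected.index):
        raise DomainError("profiles are not site-aligned")
    return d * beta_affected + (1.0 - d) * beta_unaffected


def sample_depth_and_reads(
    d: float,
    depth_mean: float = 184.0,
    depth_sd: float = 93.0,
    depth_min: int = 47,
    rng=None,
    size: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample read depths n from a lower-truncated normal (rejection
    sampling, rounded to integers strictly above ``depth_min``) and variant
    read counts k ~ Binomial(n, d/2). See ``DEPTH_PRESETS`` for the shipped
    gene presets."""
    if not 0.0 <= d <= 1.0:
        raise DomainError(f"mosaic degree d={d} outside [0, 1]")
    rng = np.random.default_rng(rng)
    n = np.empty(size, dtype=int)
    filled = 0
    while filled < size:
        draw = np.round(rng.normal(depth_mean, depth_sd, size=2 * (size - filled)))
        draw = draw[draw > depth_min].astype(int)
        take = min(draw.size, size - filled)
        n[filled : filled + take] = draw[:take]
        filled += take
    k = rng.binomial(n, d / 2.0)
    return n, k


def leave_out_combinations(training_cases, leave_out: int = 2) -> list[tuple]:
    """All ways of leaving ``leave_out`` cases out of the training set
    (e.g. C(7,2) = 21, C(8,2) = 28)."""
    return list(itertools.combinations(sorted(training_cases), leave_out))


def generate_insilico_cohort(
    beta: pd.DataFrame,
    signature_sites,
    affected_pool,
    unaffected_pool,
    training_cases,
    training_controls,
    leave_out: int = 2,
    per_combo: int = 150,
    depth_preset: str | tuple = "KMT2B",
    cost: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Build the in-silico mosaic cohort with its leave-2-out classifier
    ensemble.

    For every way of leaving ``leave_out`` cases out of ``training_cases``
    a classifier is trained on the reduced case set against the controls at
    the fixed ``signature_sites`` (no re-training); the left-out cases join
    the affected donor pool for that combination. ``per_combo`` mosaics are
    then synthesized per combination — random affected/unaffected donor
    pair, degree d ~ U(0,1), beta-scale mixing, a depth n from the
    truncated-normal model and reads k ~ Bin(n, d/2) — and scored by that
    combination's classifier.

    Returns the mosaic table (combo, left_out, d, affected, unaffected,
    depth, variant_reads, vaf, score) and the dict of per-combination
    models.
    """
    training_cases = sorted(training_cases)
    affected_pool = list(affected_pool)
    unaffected_pool = list(unaffected_pool)
    if len(training_cases) < leave_out + 2:
        raise DomainError("training set too small for the requested leave-out")
    if not unaffected_pool:
        raise DomainError("unaffected donor pool is empty")
    mean, sd, dmin = (
        DEPTH_PRESETS[depth_preset] if isinstance(depth_preset, str) else depth_preset
    )
    sig_beta = beta.loc[list(signature_sites)]
    m_all = beta_to_m(sig_beta)
    rng = np.random.default_rng(seed)

    combos = leave_out_combinations(training_cases, leave_out)
    models: dict = {}
    rows = []
    for ci, left_out in enumerate(combos):
        reduced = [c for c in training_cases if c not in left_out]
        model = _classifier.train(
            m_all, reduced, training_controls, cost=cost, seed=seed, cv_folds=5
        )
        models[ci] = model
        pool = sorted(set(affected_pool) | set(left_out))
        aff = rng.choice(pool, size=per_combo, replace=True)
        unaff = rng.choice(unaffected_pool, size=per_combo, replace=True)
        dvals = rng.uniform(0.0, 1.0, size=per_combo)
        mixed = {}
        for j in range(per_combo):
            mixed[f"mosaic_{ci}_{j}"] = synthesize_mosaic(
                sig_beta[aff[j]], sig_beta[unaff[j]], dvals[j]
            )
        mixed_m = beta_to_m(pd.DataFrame(mixed))
        scores = _classifier.score(model, mixed_m)
        for j in range(per_combo):
            n, k = sample_depth_and_reads(dvals[j], mean, sd, dmin, rng=rng)
            rows.append(
                (ci, "|".join(map(str, left_out)), dvals[j], aff[j], unaff[j],
                 int(n[0]), int(k[0]), k[0] / n[0], float(scores.iloc[j]))
            )
    table = pd.DataFrame(
        rows,
        columns=["combo", "left_out", "d", "affected", "unaffected",
                 "depth", "variant_reads", "vaf", "score"],
    )
    return table, models


# ----- quantile band --------------------------------------------------------

@dataclass
class QuantileBand:
    """Loess-smoothed 5th/95th score percentiles over variant-read-fraction
    bins. ``table`` columns: bin_center, q_low_raw, q_high_raw, q_low_smooth,
    q_high_smooth."""

    table: pd.DataFrame
    bin_width: float
    quantiles: tuple

    def _interp(self, frac: float, col: str) -> float:
        x = self.table["bin_center"].to_numpy()
        if frac < x[0] or frac > x[-1]:
            warnings.warn(
                f"fraction {frac:.3f} outside band support [{x[0]:.3f}, {x[-1]:.3f}]; "
                "using nearest endpoint", stacklevel=3,
            )
        return float(np.interp(frac, x, self.table[col].to_numpy()))

    def lower(self, frac: float) -> float:
        return self._interp(frac, "q_low_smooth")

    def upper(self, frac: float) -> float:
        return self._interp(frac, "q_high_smooth")


def _loess_smooth(
    x: np.ndarray, y: np.ndarray, span: float = 0.75, degree: int = 2
) -> np.ndarray:
    """Local polynomial (loess) smoother with tricube weights, evaluated at
    the input points; direct fit, matching R's loess(family="gaussian",
    surface="direct") defaults of span 0.75 and degree 2."""
    n = len(x)
    q = max(degree + 1, int(math.ceil(span * n)))
    q = min(q, n)
    out = np.empty(n)
    for i in range(n):
        dist = np.abs(x - x[i])
        h = np.sort(dist)[q - 1]
        if span > 1.0:
            h *= span
        w = np.clip(dist / h if h > 0 else dist * 0.0, 0.0, 1.0)
        w = (1.0 - w**3) ** 3
        active = w > 0
        deg = min(degree, active.sum() - 1)
        coeffs = np.polyfit(x[active] - x[i], y[active], deg, w=np.sqrt(w[active]))
        out[i] = coeffs[-1]
    return out


def build_band(
    mosaics: pd.DataFrame,
    bin_width: float = 0.025,
    quantiles: tuple = (0.05, 0.95),
    n_subsample: int = 3000,
    seed: int = 0,
    loess_span: float = 0.75,
) -> QuantileBand:
    """Quantile band of in-silico mosaic scores over variant read fraction.

    ``n_subsample`` mosaics are drawn at random (without replacement when
    possible), sorted into ``bin_width``-sized bins of k/n between 0 and
    0.5, the requested score quantiles computed per occupied bin, and the
    binned quantiles loess-smoothed against the bin centers. Empty bins are
    skipped with a warning; the smoothed lower curve is clipped to the upper
    one where smoothing would cross them.
    """
    rng = np.random.default_rng(seed)
    if len(mosaics) > n_subsample:
        take = rng.choice(len(mosaics), size=n_subsample, replace=False)
        mosaics = mosaics.iloc[take]
    edges = np.arange(0.0, 0.5 + bin_width, bin_width)
    centers, qlo, qhi = [], [], []
    idx = np.digitize(mosaics["vaf"].to_numpy(), edges) - 1
    for b in range(len(edges) - 1):
        sel = mosaics["score"].to_numpy()[idx == b]
        if sel.size == 0:
            warnings.warn(f"empty variant-read-fraction bin at {edges[b]:.3f}", stacklevel=2)
            continue
        centers.append((edges[b] + edges[b + 1]) / 2.0)
        qlo.append(float(np.quantile(sel, quantiles[0])))
        qhi.append(float(np.quantile(sel, quantiles[1])))
    if not centers:
        raise DomainError("no occupied bins; cannot build band")
    x = np.asarray(centers)
    lo_s = _loess_smooth(x, np.asarray(qlo), span=loess_span) if len(x) > 2 else np.asarray(qlo)
    hi_s = _loess_smooth(x, np.asarray(qhi), span=loess_span) if len(x) > 2 else np.asarray(qhi)
    lo_s = np.minimum(lo_s, hi_s)  # enforce lower <= upper after smoothing
    table = pd.DataFrame(
        {"bin_center": x, "q_low_raw": qlo, "q_high_raw": qhi,
         "q_low_smooth": lo_s, "q_high_smooth": hi_s}
    )
    return QuantileBand(table, bin_width, tuple(quantiles))


# ----- adjudication ---------------------------------------------------------

def adjudicate(
    suspects: pd.DataFrame,
    beta: pd.DataFrame,
    signature_sites,
    band: QuantileBand,
    models: dict,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Score each suspected mosaic with every leave-2-out classifier and
    place its mean score against the quantile band at its variant read
    fraction.

    ``suspects`` needs columns ``sample_id``, ``depth`` and
    ``variant_reads`` (or a precomputed ``vaf``). The verdict is
    ``above_95`` when the ensemble mean exceeds the smoothed upper band
    (suspicious: methylation looks constitutive despite the deflated VAF),
    ``below_5`` under the lower band, else ``within``. The CI is the
    t-interval across the ensemble scores.
    """
    m = beta_to_m(beta.loc[list(signature_sites)])
    rows = []
    for _, rec in suspects.iterrows():
        sid = rec["sample_id"]
        vaf = rec["vaf"] if "vaf" in rec and pd.notna(rec.get("vaf")) else (
            rec["variant_reads"] / rec["depth"]
        )
        scores = np.array(
            [float(_classifier.score(mod, m[[sid]]).iloc[0]) for mod in models.values()]
        )
        mean = float(scores.mean())
        if scores.size > 1:
            half = stats.t.ppf((1 + ci_level) / 2, scores.size - 1) * scores.std(ddof=1) / math.sqrt(scores.size)
        else:
            half = 0.0
        lo, hi = band.lower(vaf), band.upper(vaf)
        verdict = "above_95" if mean > hi else ("below_5" if mean < lo else "within")
        rows.append((sid, mean, mean - half, mean + half, float(vaf), verdict))
    return pd.DataFrame(
        rows, columns=["sample_id", "mean_score", "ci_low", "ci_high", "vaf", "verdict"]
    )


def plot_band(
    band: QuantileBand,
    mosaics: pd.DataFrame | None = None,
    verdicts: pd.DataFrame | None = None,
    path=None,
):
    """Score versus variant read fraction with the smoothed quantile band,
    the in-silico cloud, and suspect means with CIs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    if mosaics is not None:
        ax.plot(mosaics["vaf"], mosaics["score"], ".", color="0.7", ms=2, label="in-silico mosaics")
    t = band.table
    ax.plot(t["bin_center"], t["q_low_smooth"], "--", color="C0", label="5th/95th percentile")
    ax.plot(t["bin_center"], t["q_high_smooth"], "--", color="C0")
    if verdicts is not None:
        ax.errorbar(
            verdicts["vaf"], verdicts["mean_score"],
            yerr=[verdicts["mean_score"] - verdicts["ci_low"],
                  verdicts["ci_high"] - verdicts["mean_score"]],
            fmt="o", color="red", label="suspects (95% CI)",
        )
    ax.set_xlabel("variant read fraction k/n")
    ax.set_ylabel("SVM probability score")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
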