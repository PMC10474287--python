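"""Synthetic EPIC-like methylation cohorts with planted episignatures,
allelic-series effect scaling, covariate confounding, mosaic mixtures, and
variant read counts.

The generator makes every downstream stage testable without any array
download. Control (unaffected) methylation is drawn from a three-component
baseline mixture (hypo- ~0.1, hemi- ~0.5, hyper-methylated ~0.9 beta) and
perturbed on the M scale by per-site covariate slopes and Gaussian noise.
Cases carry an additive M-scale shift of u_i · effect_delta at the planted
signature sites, where the per-case severity multiplier u_i in (0, 1]
realizes an allelic series; mosaic cases (degree d < 1) are produced by
beta-scale mixing of the case's affected and unaffected profiles, the same
rule the mosaic-evaluation module uses. Variant read counts follow
k ~ Binomial(n, d/2) at truncated-normal read depths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError
from .mosaic import sample_depth_and_reads, synthesize_mosaic
from .preprocess import BetaMatrix, beta_to_m, m_to_beta

#: Beta-mixture centers of the unaffected baseline (hypo, hemi, hyper).
BASELINE_CENTERS_BETA = (0.1, 0.5, 0.9)
BASELINE_WEIGHTS = (0.35, 0.30, 0.35)
BASELINE_SITE_SD = 0.5      # M-scale spread of per-site means around a center
BETA_EPS = 1e-9             # keep generated betas strictly inside (0, 1)


@dataclass
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror a single-gene episignature study arm: 19 training
    controls, 7 initial unambiguous cases, 28 further variant carriers of
    graded severity, a planted 100-site differential set among 5000 CpGs,
    and the KMT2B-like read-depth model (184 ± 93, > 47).
    """

    n_sites: int = 5000
    n_signature_sites: int = 100
    n_controls: int = 19
    n_cases: int = 7
    n_candidates: int = 28
    n_independent_controls: int = 0
    effect_delta: float = 2.0
    severity_range: tuple = (0.3, 1.0)
    noise_sd: float = 0.5
    covariate_effects: dict = field(
        default_factory=lambda: {"sex": 0.2, "age": 0.01, "cd4t": 1.0, "gran": 1.0}
    )
    depth_mean: float = 184.0
    depth_sd: float = 93.0
    depth_min: int = 47
    seed: int = 0
    # explicit per-candidate overrides (None -> drawn from severity_range / all 1)
    candidate_severities: tuple | None = None
    candidate_mosaic_degrees: tuple | None = None

    def __post_init__(self) -> None:
        counts = (self.n_sites, self.n_signature_sites, self.n_controls, self.n_cases)
        if any(c <= 0 for c in counts) or self.n_candidates < 0 or self.n_independent_controls < 0:
            raise ConfigurationError("all counts must be positive")
        if self.n_signature_sites >= self.n_sites:
            raise ConfigurationError("n_signature_sites must be < n_sites")
        if self.depth_min < 1:
            raise ConfigurationError("depth_min must be >= 1")
        if not np.isfinite(self.effect_delta):
            raise ConfigurationError("effect_delta must be finite")
        lo, hi = self.severity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigurationError("severity_range must lie in (0, 1]")
        for name, seq in (
            ("candidate_severities", self.candidate_severities),
            ("candidate_mosaic_degrees", self.candidate_mosaic_degrees),
        ):
            if seq is not None and len(seq) != self.n_candidates:
                raise ConfigurationError(f"{name} must have length n_candidates")


@dataclass
class GroundTruth:
    """What was planted: the signature sites and each sample's severity
    multiplier u, mosaic degree d, and true status."""

    signature_site_ids: list
    severity: dict       # sample_id -> u in [0, 1]; 0 for controls
    mosaic_degree: dict  # sample_id -> d in [0, 1]; 1 = constitutive
    status: dict         # sample_id -> control | case_initial | candidate
    metadata: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"signature_site_ids": self.signature_site_ids,
                 "severity": self.severity, "mosaic_degree": self.mosaic_degree,
                 "status": self.status, "metadata": self.metadata},
                fh, indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["signature_site_ids"], d["severity"], d["mosaic_degree"],
                   d["status"], d.get("metadata", {}))


def generate_cohort(config: CohortConfig) -> tuple[BetaMatrix, pd.DataFrame, GroundTruth]:
    """Draw a full synthetic cohort: beta matrix, sample sheet, ground truth.

    Deterministic given ``config.seed`` (one global seed fans out to
    per-component child streams, recorded in the ground-truth metadata).
    """
    ss = np.random.SeedSequence(config.seed)
    seed_baseline, seed_cov, seed_case, seed_onset = ss.spawn(4)
    rng_base = np.random.default_rng(seed_baseline)
    rng_cov = np.random.default_rng(seed_cov)
    rng_case = np.random.default_rng(seed_case)
    rng_onset = np.random.default_rng(seed_onset)

    site_ids = [f"cg{i:06d}" for i in range(config.n_sites)]
    controls = [f"ctrl_{i:02d}" for i in range(config.n_controls)]
    cases = [f"case_{i:02d}" for i in range(config.n_cases)]
    candidates = [f"cand_{i:02d}" for i in range(config.n_candidates)]
    indep = [f"ictrl_{i:03d}" for i in range(config.n_independent_controls)]
    samples = controls + cases + candidates + indep
    n_samples = len(samples)

    # per-site baseline means on the M scale, three-component beta mixture
    centers_m = np.log2(np.array(BASELINE_CENTERS_BETA) / (1 - np.array(BASELINE_CENTERS_BETA)))
    comp = rng_base.choice(3, size=config.n_sites, p=BASELINE_WEIGHTS)
    site_mean = centers_m[comp] + rng_base.normal(0.0, BASELINE_SITE_SD, config.n_sites)

    # covariates and per-site covariate slopes (confounding structure)
    sex = rng_cov.integers(0, 2, n_samples).astype(float)
    age = rng_cov.uniform(2.0, 50.0, n_samples)
    cd4t = np.clip(rng_cov.normal(0.15, 0.03, n_samples), 0.01, 0.5)
    gran = np.clip(rng_cov.normal(0.60, 0.05, n_samples), 0.2, 0.9)
    cov_values = {"sex": sex, "age": age, "cd4t": cd4t, "gran": gran}
    unknown = set(config.covariate_effects) - set(cov_values)
    if unknown:
        raise ConfigurationError(f"unknown covariate_effects keys: {sorted(unknown)}")

    M = np.tile(site_mean[:, None], (1, n_samples))
    for name, scale in config.covariate_effects.items():
        slopes = rng_cov.normal(0.0, scale, config.n_sites)
        x = cov_values[name]
        M += slopes[:, None] * (x - x.mean())[None, :]
    M += rng_base.normal(0.0, config.noise_sd, (config.n_sites, n_samples))

    # plant the signature
    sig_idx = np.sort(rng_case.choice(config.n_sites, config.n_signature_sites, replace=False))
    sig_sign = rng_case.choice([-1.0, 1.0], config.n_signature_sites)
    delta_site = sig_sign * config.effect_delta

    severity = {s: 0.0 for s in controls + indep}
    degree = {s: 0.0 for s in controls + indep}
    status = {s: "control" for s in controls} | {s: "independent_control" for s in indep}
    u_cand = (
        np.asarray(config.candidate_severities, dtype=float)
        if config.candidate_severities is not None
        else rng_case.uniform(*config.severity_range, config.n_candidates)
    )
    d_cand = (
        np.asarray(config.candidate_mosaic_degrees, dtype=float)
        if config.candidate_mosaic_degrees is not None
        else np.ones(config.n_candidates)
    )
    if np.any((d_cand < 0) | (d_cand > 1)):
        raise DomainError("mosaic degrees must lie in [0, 1]")

    affected = list(zip(cases, [1.0] * len(cases), [1.0] * len(cases))) + list(
        zip(candidates, u_cand, d_cand)
    )
    for sid, u, d in affected:
        j = samples.index(sid)
        col_unaffected = M[:, j].copy()
        col_affected = col_unaffected.copy()
        col_affected[sig_idx] += u * delta_site
        if d >= 1.0:
            M[:, j] = col_affected
        else:
            beta_a = pd.Series(m_to_beta(col_affected), index=site_ids)
            beta_u = pd.Series(m_to_beta(col_unaffected), index=site_ids)
            mix = synthesize_mosaic(beta_a, beta_u, d)
            M[:, j] = beta_to_m(mix).to_numpy()
        severity[sid] = float(u)
        degree[sid] = float(d)
        status[sid] = "case_initial" if sid in cases else "candidate"

    beta = np.clip(m_to_beta(M), BETA_EPS, 1.0 - BETA_EPS)
    matrix = BetaMatrix(
        pd.DataFrame(beta, index=site_ids, columns=samples),
        meta={"seed": config.seed},
    )

    # age at onset: earlier onset for stronger effective dose u*d
    age_at_onset = np.full(n_samples, np.nan)
    observed = np.zeros(n_samples, dtype=int)
    for sid, u, d in affected:
        j = samples.index(sid)
        latent = max(0.1, rng_onset.normal(2.0 + 28.0 * (1.0 - u * d), 4.0))
        if latent <= age[j]:
            age_at_onset[j] = latent
            observed[j] = 1
        else:
            age_at_onset[j] = age[j]  # censored at examination
            observed[j] = 0

    sheet = pd.DataFrame(
        {"sample_id": samples,
         "status": [status[s] for s in samples],
         "sex": sex.astype(int), "age": age, "cd4t": cd4t, "gran": gran,
         "age_at_onset": age_at_onset, "onset_observed": observed}
    ).set_index("sample_id")

    truth = GroundTruth(
        signature_site_ids=[site_ids[i] for i in sig_idx],
        severity=severity, mosaic_degree=degree, status=status,
        metadata={
            "seed": config.seed,
            "child_streams": ["baseline", "covariates", "case_effects", "onset"],
        },
    )
    return matrix, sheet, truth


def generate_variant_observations(
    truth: GroundTruth,
    config: CohortConfig,
    gene: str = "KMT2B",
    undercall: dict | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Variant read counts for every variant carrier: depth n from the
    lower-truncated normal depth model, k ~ Binomial(n, d/2).

    ``undercall`` maps sample IDs to a deflation factor applied to the
    sampled variant read count (reported k = round(k · factor)), emulating
    erroneous exome calls — e.g. indel under-counting making a constitutive
    carrier (d = 1) look like a mosaic.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    undercall = undercall or {}
    rows = []
    for sid, st in truth.status.items():
        if st == "control":
            continue
        d = truth.mosaic_degree[sid]
        if not 0.0 <= d <= 1.0:
            raise DomainError(f"mosaic degree {d} outside [0, 1] for {sid}")
        n, k = sample_depth_and_reads(
            d, config.depth_mean, config.depth_sd, config.depth_min, rng=rng
        )
        k_rep = int(round(k[0] * undercall[sid])) if sid in undercall else int(k[0])
        rows.append((sid, gene, int(n[0]), k_rep))
    return pd.DataFrame(rows, columns=["sample_id", "gene", "depth", "variant_reads"])


# ----- TSV plumbing ---------------------------------------------------------

def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", na_rep=".")


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=".")


def write_variant_observations(obs: pd.DataFrame, path) -> None:
    obs.to_csv(path, sep="\t", index=False, na_rep=".")


def read_variant_observations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=".")
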