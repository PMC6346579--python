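"""Synthetic participant registry: Gaussian-copula risk-factor generator.

A single latent multivariate-normal draw couples age, sex, education,
systolic blood pressure, BMI, cholesterol status, physical activity,
a hypertension-diagnosis propensity and the total WMH load on the rank
scale; marginals are then obtained by inverse-CDF transforms, so every
pairwise Spearman correlation between continuous columns matches its
copula target (up to sampling error).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import COPULA_VARS, GeneratorParams

#: APOE allele -> (rs429358 base, rs7412 base) haplotype
ALLELE_TO_BASES = {"e1": ("C", "T"), "e2": ("T", "T"),
                   "e3": ("T", "C"), "e4": ("C", "C")}

REGISTRY_COLUMNS = [
    "id", "age", "sex", "education_years", "sbp_mmhg", "bmi",
    "hchol_selfreport", "hchol_medication", "htn_selfreport", "htn_medication",
    "moderate_activity_min", "vigorous_activity_min",
    "rs429358", "rs7412",
    "maternal_ad_onset", "paternal_ad_onset", "family_history_available",
    "wmh_total_cm3", "tiv_cm3",
]


def _genotype_to_snps(label: str) -> tuple[str, str]:
    """'e3/e4' -> phased two-character strings for rs429358 and rs7412."""
    a1, a2 = label.split("/")
    b1 = ALLELE_TO_BASES[a1]
    b2 = ALLELE_TO_BASES[a2]
    return b1[0] + b2[0], b1[1] + b2[1]


def generate_registry(params: GeneratorParams,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a registry of ``params.n`` participants.

    Deterministic given ``params`` (the seed lives in the params); pass an
    explicit ``rng`` to decouple the stream from ``params.seed``.
    """
    if params.n < 2:
        raise ValueError("registry size must be at least 2")
    R = params.copula_matrix()          # raises on non-PSD input
    rng = np.random.default_rng(params.seed) if rng is None else rng

    n = params.n
    L = np.linalg.cholesky(R + 1e-12 * np.eye(len(COPULA_VARS)))
    z = rng.standard_normal((n, len(COPULA_VARS))) @ L.T
    col = {v: z[:, i] for i, v in enumerate(COPULA_VARS)}
    u = {v: stats.norm.cdf(col[v]) for v in COPULA_VARS}

    lo, hi = params.age_range
    a, b = (lo - params.age_mean) / params.age_sd, (hi - params.age_mean) / params.age_sd
    age = stats.truncnorm.ppf(u["age"], a, b, loc=params.age_mean, scale=params.age_sd)

    sex = np.where(u["sex"] > 1.0 - params.frac_male, "male", "female")
    education = np.clip(
        stats.norm.ppf(u["education"], params.education_mean, params.education_sd),
        0.0, 30.0)
    sbp = np.clip(stats.norm.ppf(u["sbp"], params.sbp_mean, params.sbp_sd), 70.0, 230.0)
    bmi = np.clip(np.exp(stats.norm.ppf(u["bmi"], params.bmi_log_median,
                                        params.bmi_log_sd)), 15.0, 60.0)

    hchol_self = u["chol"] > 1.0 - params.prev_hchol
    hchol_med = hchol_self & (rng.random(n) < params.frac_hchol_medicated)
    htn_dx = u["htn_dx"] > 1.0 - params.prev_htn_dx
    htn_med = htn_dx & (rng.random(n) < params.frac_htn_medicated)

    z_act = col["activity"]
    moderate = np.exp(params.moderate_log_median + params.moderate_log_sd * z_act)
    z_vig = 0.7 * z_act + np.sqrt(1 - 0.7 ** 2) * rng.standard_normal(n)
    vigorous = np.exp(params.vigorous_log_median + params.vigorous_log_sd * z_vig)
    act_missing = rng.random(n) < params.frac_activity_missing
    moderate[act_missing] = np.nan
    vigorous[act_missing] = np.nan

    wmh = np.exp(params.wmh_log_median + params.wmh_log_sd * col["wmh"])
    tiv = np.clip(rng.normal(params.tiv_mean, params.tiv_sd, n), 1000.0, None)

    geno_labels = list(params.apoe_freqs)
    geno_p = np.array([params.apoe_freqs[g] for g in geno_labels], dtype=float)
    genotype = rng.choice(geno_labels, size=n, p=geno_p / geno_p.sum())
    snps = [_genotype_to_snps(g) for g in genotype]
    rs429358 = np.array([s[0] for s in snps])
    rs7412 = np.array([s[1] for s in snps])

    fh_labels = list(params.famhist_freqs)
    fh_p = np.array([params.famhist_freqs[c] for c in fh_labels], dtype=float)
    famhist = rng.choice(fh_labels, size=n, p=fh_p / fh_p.sum())
    maternal = np.full(n, np.nan)
    paternal = np.full(n, np.nan)
    affected = famhist != "missing"
    for side, arr in (("maternal", maternal), ("paternal", paternal)):
        hit = np.isin(famhist, [side, "both"])
        arr[hit] = rng.uniform(50.0, 74.9, hit.sum())
        # occasional late-onset parent on the non-counting side exercises the
        # < 75 years rule downstream
        other = affected & ~hit & (rng.random(n) < 0.10)
        arr[other] = rng.uniform(75.0, 90.0, other.sum())

    df = pd.DataFrame({
        "id": [f"sub-{i:04d}" for i in range(n)],
        "age": age, "sex": sex, "education_years": education,
        "sbp_mmhg": sbp, "bmi": bmi,
        "hchol_selfreport": hchol_self, "hchol_medication": hchol_med,
        "htn_selfreport": htn_dx, "htn_medication": htn_med,
        "moderate_activity_min": moderate, "vigorous_activity_min": vigorous,
        "rs429358": rs429358, "rs7412": rs7412,
        "maternal_ad_onset": maternal, "paternal_ad_onset": paternal,
        "family_history_available": affected,
        "wmh_total_cm3": wmh, "tiv_cm3": tiv,
    }, columns=REGISTRY_COLUMNS)
    df.attrs["provenance"] = {"seed": int(params.seed), "n": int(n),
                              "generator": "wmh_bullseye.cohort.generate_registry"}
    return df


def apply_exclusion_cascade(registry: pd.DataFrame, params: GeneratorParams,
                            rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Remove non-consenters, then invalid scans, then quality failures.

    Exclusions are drawn at random (independently of covariates).  The
    returned table keeps only analyzable participants; the per-participant
    exclusion reasons are recorded in ``df.attrs['exclusions']``.
    """
    counts = [("non_consent", params.n_nonconsent),
              ("invalid_scan", params.n_invalid_scan),
              ("quality", params.n_quality_exclusion)]
    total = sum(c for _, c in counts)
    if any(c < 0 for _, c in counts):
        raise ValueError("exclusion counts must be non-negative")
    if total > len(registry):
        raise ValueError("exclusion counts exceed registry size")
    rng = np.random.default_rng(params.seed + 1) if rng is None else rng

    remaining = registry.index.to_numpy().copy()
    dropped: list[tuple[str, str]] = []
    for reason, count in counts:
        pick = rng.choice(len(remaining), size=count, replace=False)
        for i in np.sort(pick):
            dropped.append((registry.loc[remaining[i], "id"], reason))
        remaining = np.delete(remaining, pick)

    out = registry.loc[remaining].reset_index(drop=True)
    out.attrs["provenance"] = dict(registry.attrs.get("provenance", {}))
    out.attrs["exclusions"] = pd.DataFrame(dropped, columns=["id", "reason"])
    return out


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
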