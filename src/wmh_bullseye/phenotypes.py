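"""Non-imaging phenotype derivation.

Risk-factor classifiers, APOE allele calling from the rs429358/rs7412
haplotypes, family-history grouping, and the CAIDE-I midlife dementia risk
score (points 0-15) with its logistic 20-year risk mapping.

Boundary conventions are strict (``>``, not ``>=``) wherever the defining
criterion reads "above" or "more than": SBP above 140 mmHg, more than
150 min/week moderate or 75 min/week vigorous exercise, parental dementia
onset younger than 75 years.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd


class MissingDataError(ValueError):
    """A required phenotype input is absent."""


# ---------------------------------------------------------------------------
# risk-factor classifiers
# ---------------------------------------------------------------------------

def classify_hypertension_composite(selfreport: bool, medication: bool,
                                    sbp: float) -> bool:
    """Hypertensive iff self-reported diagnosis, on medication, or SBP > 140."""
    if sbp <= 0:
        raise ValueError("systolic blood pressure must be positive")
    return bool(selfreport) or bool(medication) or sbp > 140.0


def classify_hypertension_caide(sbp: float) -> bool:
    """The CAIDE scale uses only the measured-pressure criterion."""
    if sbp <= 0:
        raise ValueError("systolic blood pressure must be positive")
    return sbp > 140.0


def classify_hypercholesterolemia(selfreport: bool, medication: bool) -> bool:
    return bool(selfreport) or bool(medication)


def classify_activity(moderate: float, vigorous: float) -> bool:
    """Active iff > 150 min/week moderate or > 75 min/week vigorous exercise."""
    if moderate < 0 or vigorous < 0:
        raise ValueError("activity minutes must be non-negative")
    return moderate > 150.0 or vigorous > 75.0


def classify_family_history(maternal_onset: float | None,
                            paternal_onset: float | None) -> str:
    """'maternal' / 'paternal' / 'both' / 'none'; a side counts iff onset < 75 y."""
    def counts(onset):
        return onset is not None and not (isinstance(onset, float) and math.isnan(onset)) \
            and onset < 75.0
    m, p = counts(maternal_onset), counts(paternal_onset)
    if m and p:
        return "both"
    if m:
        return "maternal"
    if p:
        return "paternal"
    return "none"


# ---------------------------------------------------------------------------
# APOE
# ---------------------------------------------------------------------------

_BASES_TO_ALLELE = {("C", "T"): "e1", ("T", "T"): "e2",
                    ("T", "C"): "e3", ("C", "C"): "e4"}


def apoe_allele(rs429358: str, rs7412: str) -> str:
    """One haplotype's APOE allele from its two SNP bases."""
    key = (str(rs429358).upper(), str(rs7412).upper())
    if key not in _BASES_TO_ALLELE:
        raise ValueError(f"bases must be C or T, got {key}")
    return _BASES_TO_ALLELE[key]


def apoe_genotype(rs429358_pair: str, rs7412_pair: str) -> str:
    """Genotype label from phased two-base strings, e.g. ('CT','CC') -> 'e3/e4'.

    The label is the unordered allele pair, sorted (so 'e3/e4', never 'e4/e3').
    """
    if len(rs429358_pair) != 2 or len(rs7412_pair) != 2:
        raise ValueError("each SNP field must carry exactly two bases")
    alleles = sorted(apoe_allele(a, b)
                     for a, b in zip(rs429358_pair, rs7412_pair))
    return "/".join(alleles)


# ---------------------------------------------------------------------------
# CAIDE-I
# ---------------------------------------------------------------------------

#: Logistic coefficients of the 20-year dementia risk expression on the
#: logit scale, fixed by a least-squares fit of the logit line through the
#: published (score, risk%) quantile pairs (4, 0.67), (6, 1.47), (8, 3.22);
#: the fit reproduces all three pairs to two decimals.
CAIDE_LOGIT_INTERCEPT = -6.596160266915627
CAIDE_LOGIT_SLOPE = 0.3989665512538833


def caide_points(age: float, education_years: float, sex: str, sbp: float,
                 bmi: float, hypercholesterolemia: bool, active: bool) -> dict:
    """CAIDE-I factor points and total (0-15).

    Scoring table (model without APOE): age < 47 -> 0, 47-53 -> 3, > 53 -> 4;
    education >= 10 y -> 0, 7-9 y -> 2, < 7 y -> 3; male -> 1; SBP > 140 -> 2;
    BMI > 30 -> 2; hypercholesterolemia -> 2; physically inactive -> 1.

    Raises :class:`MissingDataError` if any input is NaN/None, mirroring the
    per-analysis exclusion of records with unavailable fields.
    """
    vals = dict(age=age, education_years=education_years, sex=sex, sbp=sbp,
                bmi=bmi, hypercholesterolemia=hypercholesterolemia, active=active)
    for name, v in vals.items():
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise MissingDataError(f"CAIDE input '{name}' is missing")
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    pts = {
        "age": 0 if age < 47 else (3 if age <= 53 else 4),
        "education": 0 if education_years >= 10 else (2 if education_years >= 7 else 3),
        "sex": 1 if sex == "male" else 0,
        "sbp": 2 if classify_hypertension_caide(sbp) else 0,
        "bmi": 2 if bmi > 30 else 0,
        "cholesterol": 2 if hypercholesterolemia else 0,
        "activity": 0 if active else 1,
    }
    pts["total"] = sum(pts.values())
    return pts


def caide_risk(total: float) -> float:
    """20-year dementia probability (percent) for a CAIDE-I total score."""
    if not 0 <= total <= 15:
        raise ValueError("CAIDE total score must lie in [0, 15]")
    logit = CAIDE_LOGIT_INTERCEPT + CAIDE_LOGIT_SLOPE * float(total)
    return 100.0 / (1.0 + math.exp(-logit))


# ---------------------------------------------------------------------------
# cohort-level derivation
# ---------------------------------------------------------------------------

def derive_phenotypes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append every derived phenotype column to a registry table.

    Adds: hypertension (composite), hypertension_caide, hypercholesterolemia,
    active, sex_male, apoe_genotype, family_history, the CAIDE factor points,
    caide_total and caide_risk_pct.  Missing activity or family-history data
    propagate as NaN (row count is preserved; exclusion is per-analysis).
    """
    df = cohort.copy()
    df["hypertension"] = [
        classify_hypertension_composite(s, m, p)
        for s, m, p in zip(df["htn_selfreport"], df["htn_medication"],
                           df["sbp_mmhg"])]
    df["hypertension_caide"] = [classify_hypertension_caide(p)
                                for p in df["sbp_mmhg"]]
    df["hypercholesterolemia"] = [
        classify_hypercholesterolemia(s, m)
        for s, m in zip(df["hchol_selfreport"], df["hchol_medication"])]
    df["sex_male"] = df["sex"] == "male"

    active = []
    for mod, vig in zip(df["moderate_activity_min"], df["vigorous_activity_min"]):
        if math.isnan(mod) or math.isnan(vig):
            active.append(np.nan)
        else:
            active.append(float(classify_activity(mod, vig)))
    df["active"] = active

    df["apoe_genotype"] = [apoe_genotype(a, b)
                           for a, b in zip(df["rs429358"], df["rs7412"])]

    fam = []
    avail = df.get("family_history_available",
                   pd.Series(True, index=df.index))
    for ok, m, p in zip(avail, df["maternal_ad_onset"], df["paternal_ad_onset"]):
        fam.append(classify_family_history(m, p) if ok else np.nan)
    df["family_history"] = fam

    factor_cols = ["age", "education", "sex", "sbp", "bmi", "cholesterol",
                   "activity"]
    pts_rows = []
    for _, row in df.iterrows():
        try:
            pts = caide_points(row["age"], row["education_years"], row["sex"],
                               row["sbp_mmhg"], row["bmi"],
                               row["hypercholesterolemia"],
                               bool(row["active"]) if not _isnan(row["active"])
                               else float("nan"))
        except MissingDataError:
            pts = {k: np.nan for k in factor_cols + ["total"]}
        pts_rows.append(pts)
    for k in factor_cols:
        df[f"caide_pts_{k}"] = [r[k] for r in pts_rows]
    df["caide_total"] = [r["total"] for r in pts_rows]
    df["caide_risk_pct"] = [np.nan if _isnan(t) else caide_risk(t)
                            for t in df["caide_total"]]
    return df


def _isnan(x) -> bool:
    return isinstance(x, float) and math.isnan(x)
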