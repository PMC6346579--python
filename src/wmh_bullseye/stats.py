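"""Nonparametric association engine.

Effect sizes (Spearman's rho, Cohen's d, the phi coefficient), permutation
p-values obtained by re-assigning the outcome vector to the predictors
(shuffles, never resamples), Benjamini-Hochberg FDR, and the three
covariate models:

* Model 1 - direct association, no covariate;
* Model 2 - corrected for age;
* Model 3 - corrected for hypertension status (not age).

Covariate correction is rank-based: the outcome (and any continuous
predictor) is rank-transformed and residualized on the rank-transformed
covariate by least squares, and the permutation re-assigns the residualized
outcome (a Freedman-Lane-style scheme).  The resulting correlation of
residual ranks is the classical partial Spearman coefficient.

The model surface follows the statsmodels convention: a
:class:`RegionalAssociation` model built from data whose ``fit`` returns a
:class:`RegionalAssociationResults` carrying estimates, bootstrap CIs,
permutation p-values, FDR q-values, and a ``summary()``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .parcellation import region_spec

DEFAULT_N_PERM = 10_000
DEFAULT_N_BOOT = 1_000

MODEL_COVARIATES = {1: None, 2: "age", 3: "hypertension"}

#: predictor name -> how it enters the analysis
CONTINUOUS_PREDICTORS = ("caide_risk_pct", "age", "bmi", "education_years",
                         "sbp_mmhg")
DICHOTOMOUS_PREDICTORS = ("hypertension", "hypertension_caide",
                          "hypercholesterolemia", "sex_male", "active",
                          "htn_selfreport", "htn_medication")
GROUP_PREDICTORS = {
    # reference group, levels excluded from testing (too few participants)
    "apoe_genotype": {"reference": "e3/e3", "exclude": ("e2/e2",)},
    "family_history": {"reference": "none", "exclude": ()},
}


class UndefinedStatisticError(ValueError):
    """The statistic is undefined on this input (e.g. a constant column)."""


@dataclass
class EffectEstimate:
    kind: str                       # spearman_rho | cohens_d | phi
    value: float
    ci95: tuple[float, float] | None = None
    z: float | None = None          # permuted test statistic, where distinct


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _ranks(v: np.ndarray) -> np.ndarray:
    return sps.rankdata(np.asarray(v, dtype=float))


def residualize(values: np.ndarray,
                covariate: np.ndarray | None = None) -> np.ndarray:
    """Rank-transform ``values`` and remove the least-squares fit on the
    rank-transformed covariate.  With no (or a constant) covariate this is
    plain rank-centering, so downstream correlations reduce to ordinary
    Spearman coefficients."""
    r = _ranks(values)
    r = r - r.mean()
    if covariate is None:
        return r
    c = _ranks(covariate)
    c = c - c.mean()
    denom = float(c @ c)
    if denom == 0.0:
        return r
    return r - (float(c @ r) / denom) * c


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise UndefinedStatisticError("constant input: correlation undefined")
    return float(a @ b / (na * nb))


def _mw_rank_stats(group: np.ndarray, ranks: np.ndarray
                   ) -> tuple[float, float, float]:
    """(observed rank sum of group 1, its null mean, its null SD with ties)."""
    n = len(ranks)
    n1 = int(group.sum())
    n2 = n - n1
    if n1 == 0 or n2 == 0:
        raise UndefinedStatisticError("both groups must be non-empty")
    r1 = float(ranks[group].sum())
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum()) / (n * (n - 1)))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        raise UndefinedStatisticError("degenerate ranks: zero variance")
    return r1, mu, float(np.sqrt(var))


def mann_whitney_z(group: np.ndarray, values: np.ndarray) -> float:
    """Tie-corrected normal-approximation z of the Mann-Whitney statistic."""
    group = np.asarray(group, dtype=bool)
    r1, mu, sd = _mw_rank_stats(group, _ranks(values))
    return (r1 - mu) / sd


def cohens_d(group: np.ndarray, values: np.ndarray) -> float:
    """Pooled-SD standardized mean difference (group 1 minus group 0)."""
    group = np.asarray(group, dtype=bool)
    a, b = np.asarray(values, float)[group], np.asarray(values, float)[~group]
    if len(a) < 2 or len(b) < 2:
        raise UndefinedStatisticError("need >= 2 observations per group for d")
    sp = np.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                 / (len(a) + len(b) - 2))
    if sp == 0:
        raise UndefinedStatisticError("zero pooled SD")
    return float((a.mean() - b.mean()) / sp)


def _percentile_ci(samples: np.ndarray) -> tuple[float, float]:
    lo, hi = np.nanpercentile(samples, [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# public effect-size operations
# ---------------------------------------------------------------------------

def spearman_effect(x, y, n_boot: int = DEFAULT_N_BOOT,
                    rng: np.random.Generator | None = None) -> EffectEstimate:
    """Spearman's rho (average ranks for ties) with a percentile bootstrap CI."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("constant input: Spearman rho undefined")
    rho = _pearson(residualize(x), residualize(y))
    ci = None
    if n_boot:
        rng = np.random.default_rng() if rng is None else rng
        idx = rng.integers(0, len(x), size=(n_boot, len(x)))
        boots = np.empty(n_boot)
        for i, ii in enumerate(idx):
            xb, yb = x[ii], y[ii]
            if np.ptp(xb) == 0 or np.ptp(yb) == 0:
                boots[i] = np.nan
                continue
            boots[i] = _pearson(residualize(xb), residualize(yb))
        ci = _percentile_ci(boots)
    return EffectEstimate("spearman_rho", rho, ci)


def mannwhitney_effect(group, y, n_boot: int = DEFAULT_N_BOOT,
                       rng: np.random.Generator | None = None) -> EffectEstimate:
    """Cohen's d (on the raw outcome) with the tie-corrected Mann-Whitney z
    attached as the permuted test statistic; stratified bootstrap CI for d."""
    group = np.asarray(group, dtype=bool)
    y = np.asarray(y, float)
    z = mann_whitney_z(group, y)
    d = cohens_d(group, y)
    ci = None
    if n_boot:
        rng = np.random.default_rng() if rng is None else rng
        i1, i0 = np.flatnonzero(group), np.flatnonzero(~group)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            ii = np.concatenate([rng.choice(i1, len(i1)), rng.choice(i0, len(i0))])
            try:
                boots[b] = cohens_d(group[ii], y[ii])
            except UndefinedStatisticError:
                boots[b] = np.nan
        ci = _percentile_ci(boots)
    return EffectEstimate("cohens_d", d, ci, z=z)


def chi2_phi(a, b) -> EffectEstimate:
    """Chi-square test of a 2x2 table with the signed phi coefficient."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    table = np.array([[np.sum(~a & ~b), np.sum(~a & b)],
                      [np.sum(a & ~b), np.sum(a & b)]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise UndefinedStatisticError("2x2 table has a zero margin")
    chi2 = sps.chi2_contingency(table, correction=False)[0]
    n = table.sum()
    sign = np.sign(table[1, 1] * table[0, 0] - table[1, 0] * table[0, 1])
    phi = float(sign * np.sqrt(chi2 / n))
    return EffectEstimate("phi", phi, None, z=float(chi2))


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------

def permutation_p(statistic, x, y, n_perm: int = DEFAULT_N_PERM,
                  rng: np.random.Generator | None = None,
                  seed: int | None = None) -> float:
    """Two-sided permutation p-value by re-assigning ``y`` to ``x``.

    ``p = #{|T_perm| >= |T_obs|} / n_perm``; permutations are shuffles of
    the outcome (never resamples).  A literal zero count is floored at
    ``1 / n_perm`` since an exact zero is unreportable.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed) if rng is None else rng
    y = np.asarray(y)
    obs = abs(float(statistic(x, y)))
    count = 0
    for _ in range(n_perm):
        if abs(float(statistic(x, rng.permutation(y)))) >= obs - 1e-12:
            count += 1
    return max(count, 1) / n_perm


def _linear_perm_pvalue(coef: np.ndarray, yvec: np.ndarray, obs: float,
                        n_perm: int, rng: np.random.Generator,
                        mu: float = 0.0, sd: float = 1.0,
                        block: int = 256) -> float:
    """Permutation p for statistics affine in the permuted outcome vector,
    ``T = (coef . y_perm - mu) / sd`` (Spearman-type correlations and the
    Mann-Whitney rank sum both are).  Equivalent to :func:`permutation_p`
    but vectorized over permutations."""
    n = len(yvec)
    obs_abs = abs(obs)
    count = 0
    base = np.arange(n)
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        idx = rng.permuted(np.tile(base, (b, 1)), axis=1)
        t = (yvec[idx] @ coef - mu) / sd
        count += int((np.abs(t) >= obs_abs - 1e-12).sum())
        done += b
    return max(count, 1) / n_perm


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw p)."""
    p = np.asarray(pvals, dtype=float)
    valid = ~np.isnan(p)
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if valid.sum():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# the model object
# ---------------------------------------------------------------------------

class RegionalAssociation:
    """Association between one predictor and the global + 36 regional
    WMH outcomes under one covariate model.

    Parameters
    ----------
    cohort : DataFrame with the derived phenotype columns.
    outcomes : DataFrame with columns ``'global'`` and region codes 1..36
        (the %TIV outcome matrix; see :func:`wmh_bullseye.quantify.outcome_matrix`),
        row-aligned with ``cohort``.
    predictor : a continuous, dichotomous, or group-valued phenotype name.
    model : 1 (direct), 2 (age-corrected) or 3 (hypertension-corrected).
    """

    def __init__(self, cohort: pd.DataFrame, outcomes: pd.DataFrame,
                 predictor: str, model: int = 1):
        if model not in MODEL_COVARIATES:
            raise ValueError(f"unknown model id {model!r}; expected 1, 2 or 3")
        known = (set(CONTINUOUS_PREDICTORS) | set(DICHOTOMOUS_PREDICTORS)
                 | set(GROUP_PREDICTORS))
        if predictor not in known:
            raise ValueError(f"unknown predictor {predictor!r}")
        if predictor not in cohort.columns:
            raise ValueError(f"predictor column {predictor!r} not in cohort")
        if len(cohort) != len(outcomes):
            raise ValueError("cohort and outcomes are not row-aligned")
        self.cohort = cohort.reset_index(drop=True)
        self.outcomes = outcomes.reset_index(drop=True)
        self.predictor = predictor
        self.model = model
        self.covariate = MODEL_COVARIATES[model]

    # -- contrasts ---------------------------------------------------------
    def _contrasts(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """(contrast label, x or group bool, row mask) triples."""
        col = self.cohort[self.predictor]
        if self.predictor in GROUP_PREDICTORS:
            spec = GROUP_PREDICTORS[self.predictor]
            ref = spec["reference"]
            levels = [lv for lv in pd.unique(col.dropna())
                      if lv != ref and lv not in spec["exclude"]]
            out = []
            for lv in sorted(levels):
                mask = col.isin([lv, ref]).to_numpy()
                out.append((f"{lv} vs {ref}", (col == lv).to_numpy(), mask))
            return out
        x = col.to_numpy(dtype=float)
        return [(self.predictor, x, ~np.isnan(x))]

    # -- fitting -----------------------------------------------------------
    def fit(self, n_perm: int = DEFAULT_N_PERM, n_boot: int = DEFAULT_N_BOOT,
            seed: int | None = None,
            regions: list | None = None) -> "RegionalAssociationResults":
        rng = np.random.default_rng(seed)
        continuous = self.predictor in CONTINUOUS_PREDICTORS
        cov_all = (None if self.covariate is None
                   else self.cohort[self.covariate].to_numpy(dtype=float))
        if regions is None:
            regions = ["global", *range(1, 37)]
        rows = []
        for label, xfull, base_mask in self._contrasts():
            for region in regions:
                y = self.outcomes[region].to_numpy(dtype=float)
                mask = base_mask & ~np.isnan(y)
                if cov_all is not None:
                    mask = mask & ~np.isnan(cov_all)
                rows.append(self._fit_one(
                    label, region, xfull[mask],
                    y[mask], None if cov_all is None else cov_all[mask],
                    continuous, n_perm, n_boot, rng))
        frame = pd.DataFrame(rows)
        # FDR family: the 36 regional tests of each contrast; the global row
        # belongs to the cross-predictor family assembled in
        # global_association_table and carries no q here.
        frame["q_fdr"] = np.nan
        for label in frame["contrast"].unique():
            sel = (frame["contrast"] == label) & (frame["region"] != "global")
            if sel.any():
                frame.loc[sel, "q_fdr"] = fdr_adjust(frame.loc[sel, "p_perm"])
        frame["significant"] = frame["q_fdr"] < 0.05
        return RegionalAssociationResults(self, frame, n_perm=n_perm,
                                          n_boot=n_boot, seed=seed)

    def _fit_one(self, label, region, x, y, cov, continuous,
                 n_perm, n_boot, rng) -> dict:
        row = {"predictor": self.predictor, "contrast": label,
               "model": self.model, "region": region,
               "n": len(y), "effect_kind": None, "effect": np.nan,
               "ci_low": np.nan, "ci_high": np.nan, "z": np.nan,
               "p_perm": np.nan}
        if region != "global":
            seg, layer = region_spec(region)
            row["segment"], row["layer"] = seg, layer
        else:
            row["segment"], row["layer"] = "global", 0
        try:
            if continuous:
                est, p = self._continuous_test(x, y, cov, n_perm, n_boot, rng)
            else:
                est, p = self._dichotomous_test(x.astype(bool), y, cov,
                                                n_perm, n_boot, rng)
        except UndefinedStatisticError:
            return row
        row.update(effect_kind=est.kind, effect=est.value, p_perm=p)
        if est.ci95 is not None:
            row["ci_low"], row["ci_high"] = est.ci95
        if est.z is not None:
            row["z"] = est.z
        return row

    def _continuous_test(self, x, y, cov, n_perm, n_boot, rng):
        if len(y) < 3:
            raise UndefinedStatisticError("too few complete observations")
        xr = residualize(x, cov)
        yr = residualize(y, cov)
        obs = _pearson(xr, yr)
        coef = xr / (np.linalg.norm(xr) * np.linalg.norm(yr))
        p = _linear_perm_pvalue(coef, yr, obs, n_perm, rng)
        ci = None
        if n_boot:
            boots = np.empty(n_boot)
            n = len(y)
            for b in range(n_boot):
                ii = rng.integers(0, n, n)
                try:
                    boots[b] = _pearson(
                        residualize(x[ii], None if cov is None else cov[ii]),
                        residualize(y[ii], None if cov is None else cov[ii]))
                except UndefinedStatisticError:
                    boots[b] = np.nan
            ci = _percentile_ci(boots)
        return EffectEstimate("spearman_rho", obs, ci), p

    def _dichotomous_test(self, g, y, cov, n_perm, n_boot, rng):
        yr = residualize(y, cov)
        ry = _ranks(yr)
        r1, mu, sd = _mw_rank_stats(g, ry)
        z = (r1 - mu) / sd
        p = _linear_perm_pvalue(g.astype(float), ry, z, n_perm, rng,
                                mu=mu, sd=sd)
        # Cohen's d on the raw %TIV scale (covariate-residualized raw values
        # under Models 2/3)
        vals = y if cov is None else _ols_residuals(y, cov)
        d = cohens_d(g, vals)
        ci = None
        if n_boot:
            i1, i0 = np.flatnonzero(g), np.flatnonzero(~g)
            boots = np.empty(n_boot)
            for b in range(n_boot):
                ii = np.concatenate([rng.choice(i1, len(i1)),
                                     rng.choice(i0, len(i0))])
                try:
                    vb = y[ii] if cov is None else _ols_residuals(y[ii], cov[ii])
                    boots[b] = cohens_d(g[ii], vb)
                except UndefinedStatisticError:
                    boots[b] = np.nan
            ci = _percentile_ci(boots)
        return EffectEstimate("cohens_d", d, ci, z=z), p


def _ols_residuals(y: np.ndarray, cov: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(cov), cov])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


class RegionalAssociationResults:
    """Fit results: a tidy frame plus convenience accessors."""

    def __init__(self, model: RegionalAssociation, frame: pd.DataFrame,
                 n_perm: int, n_boot: int, seed):
        self.model = model
        self.frame = frame
        self.n_perm = n_perm
        self.n_boot = n_boot
        self.seed = seed

    @property
    def global_row(self) -> pd.DataFrame:
        return self.frame[self.frame["region"] == "global"]

    @property
    def regional(self) -> pd.DataFrame:
        return self.frame[self.frame["region"] != "global"]

    def significant_regions(self, contrast: str | None = None) -> list[int]:
        reg = self.regional
        if contrast is not None:
            reg = reg[reg["contrast"] == contrast]
        return sorted(int(c) for c in reg.loc[reg["significant"], "region"])

    def summary(self) -> str:
        lines = [
            f"Regional WMH association  predictor={self.model.predictor}  "
            f"model={self.model.model} "
            f"(covariate: {self.model.covariate or 'none'})",
            f"permutations={self.n_perm}  bootstrap={self.n_boot}  "
            f"seed={self.seed}",
            "",
        ]
        for _, g in self.frame.groupby("contrast", sort=False):
            glob = g[g["region"] == "global"].iloc[0]
            lines.append(
                f"[{glob['contrast']}]  global effect "
                f"({glob['effect_kind']}): {glob['effect']:+.3f} "
                f"(95% CI {glob['ci_low']:+.3f} to {glob['ci_high']:+.3f}), "
                f"p_perm = {glob['p_perm']:.4g}, n = {int(glob['n'])}")
            sig = g[(g["region"] != "global") & g["significant"]]
            if len(sig):
                regs = ", ".join(f"{r.segment}_L{int(r.layer)}"
                                 for r in sig.itertuples())
                lines.append(f"  significant regions (q < 0.05): {regs}")
            else:
                lines.append("  significant regions (q < 0.05): none")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<RegionalAssociationResults predictor="
                f"{self.model.predictor!r} model={self.model.model}>")


def run_model(cohort: pd.DataFrame, wmh_table: pd.DataFrame, predictor: str,
              model: int = 1, n_perm: int = DEFAULT_N_PERM,
              seed: int | None = None,
              n_boot: int = DEFAULT_N_BOOT) -> RegionalAssociationResults:
    """Convenience wrapper: build the outcome matrix and fit one model."""
    from .quantify import outcome_matrix
    return RegionalAssociation(cohort, outcome_matrix(wmh_table), predictor,
                               model).fit(n_perm=n_perm, n_boot=n_boot,
                                          seed=seed)


def global_association_table(cohort: pd.DataFrame, wmh_table: pd.DataFrame,
                             predictors: list[str], models=(1, 2, 3),
                             n_perm: int = DEFAULT_N_PERM,
                             seed: int | None = None,
                             n_boot: int = DEFAULT_N_BOOT) -> pd.DataFrame:
    """Global-WMH analogue of the published association table.

    One row per predictor contrast x model; FDR is applied across the
    predictor rows within each model (a separate family from the regional
    maps).
    """
    from .quantify import outcome_matrix
    outcomes = outcome_matrix(wmh_table)
    rows = []
    for model in models:
        model_rows = []
        for pred in predictors:
            res = RegionalAssociation(cohort, outcomes, pred, model).fit(
                n_perm=n_perm, n_boot=n_boot, seed=seed, regions=["global"])
            model_rows.append(res.global_row)
        block = pd.concat(model_rows, ignore_index=True)
        block["q_fdr"] = fdr_adjust(block["p_perm"])
        block["significant"] = block["q_fdr"] < 0.05
        rows.append(block)
    return pd.concat(rows, ignore_index=True)
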