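"""Generator parameters: the study conditions of the synthetic cohort.

Defaults are calibrated once so that the default cohort reproduces the
published cohort description (n, median age, hypertension prevalence,
median WMH load in cm^3 and as % of TIV) and the signs of the reported
cross-correlations among risk factors.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

#: Order of the latent copula variables.
COPULA_VARS = (
    "age", "sex", "education", "sbp", "bmi", "chol", "activity", "htn_dx", "wmh",
)

#: Default pairwise Spearman rank-correlation targets on the latent scale.
#: Signs mimic the reported cross-correlation structure (age up with
#: hypertension / hypercholesterolemia / BMI, down with education; male sex up
#: with BMI, education and hypertension).  The age-wmh link defaults to the
#: published global age effect (rho = 0.22).
DEFAULT_RANK_TARGETS: dict[tuple[str, str], float] = {
    ("age", "sbp"): 0.25,
    ("age", "bmi"): 0.10,
    ("age", "chol"): 0.20,
    ("age", "education"): -0.20,
    ("age", "htn_dx"): 0.25,
    ("age", "wmh"): 0.22,
    ("age", "activity"): -0.05,
    ("sex", "bmi"): 0.15,
    ("sex", "education"): 0.10,
    ("sex", "htn_dx"): 0.15,
    ("sex", "sbp"): 0.15,
    ("sbp", "htn_dx"): 0.50,
    ("sbp", "wmh"): 0.10,
    ("htn_dx", "wmh"): 0.12,
    ("chol", "htn_dx"): 0.15,
    ("bmi", "htn_dx"): 0.20,
    ("bmi", "sbp"): 0.20,
    ("bmi", "chol"): 0.15,
}

#: Bullseye segments, in code order (codes 1..36 = 4*segment_index + layer).
SEGMENTS = ("FL", "FR", "PL", "PR", "TL", "TR", "OL", "OR", "BG")

#: Default relative lesion propensity per segment and per depth layer.
#: Periventricular layers and the occipital lobes carry the most mass,
#: matching the reported spatial distribution of lesions.
DEFAULT_SEGMENT_WEIGHTS = {
    "FL": 1.0, "FR": 1.0, "PL": 1.0, "PR": 1.0,
    "TL": 1.0, "TR": 1.0, "OL": 1.5, "OR": 1.5, "BG": 0.5,
}
DEFAULT_LAYER_WEIGHTS = {1: 3.0, 2: 1.5, 3: 1.0, 4: 0.75}


def default_spatial_weights() -> np.ndarray:
    """Length-36 lesion placement weights over region codes, summing to 1."""
    w = np.empty(36)
    for s, seg in enumerate(SEGMENTS):
        for layer in (1, 2, 3, 4):
            w[4 * s + layer - 1] = (
                DEFAULT_SEGMENT_WEIGHTS[seg] * DEFAULT_LAYER_WEIGHTS[layer]
            )
    return w / w.sum()


@dataclass
class GeneratorParams:
    """Parameters of the synthetic cohort + brain generator.

    Marginal distributions and prevalences are calibrated to the published
    cohort table; the dependence structure is a Gaussian copula whose
    pairwise targets are expressed as Spearman rank correlations.
    """

    n: int = 608                  # invited registry size (before exclusions)
    seed: int = 0
    # exclusion cascade counts: non-consent, invalid scans, quality removals
    n_nonconsent: int = 13
    n_invalid_scan: int = 20
    n_quality_exclusion: int = 14

    # marginals
    age_mean: float = 58.0
    age_sd: float = 9.7
    age_range: tuple[float, float] = (45.0, 75.0)
    frac_male: float = 0.389
    education_mean: float = 14.0
    education_sd: float = 4.45
    sbp_mean: float = 125.0
    sbp_sd: float = 15.0
    bmi_log_median: float = float(np.log(26.4))
    bmi_log_sd: float = 0.15
    prev_hchol: float = 0.305
    frac_hchol_medicated: float = 0.6
    prev_htn_dx: float = 0.17     # composite prevalence lands at ~26.2%
    frac_htn_medicated: float = 0.7
    moderate_log_median: float = float(np.log(240.0))
    moderate_log_sd: float = 0.9
    vigorous_log_median: float = float(np.log(45.0))
    vigorous_log_sd: float = 1.2
    frac_activity_missing: float = 0.08

    # WMH total-load model (log-normal, cm^3) and intracranial volume
    wmh_log_median: float = float(np.log(1.94))
    wmh_log_sd: float = 0.88
    tiv_mean: float = 1386.0
    tiv_sd: float = 120.0

    # APOE genotype frequencies (labels sorted allele pairs)
    apoe_freqs: dict = field(default_factory=lambda: {
        "e4/e4": 0.127, "e3/e4": 0.303, "e3/e3": 0.283,
        "e2/e4": 0.080, "e2/e3": 0.194, "e2/e2": 0.012,
    })
    # family history of AD category frequencies (including 'missing')
    famhist_freqs: dict = field(default_factory=lambda: {
        "maternal": 0.339, "paternal": 0.162, "both": 0.029,
        "none": 0.437, "missing": 0.034,
    })

    # copula rank-correlation targets (Spearman scale)
    rank_targets: dict = field(
        default_factory=lambda: dict(DEFAULT_RANK_TARGETS))

    # brain phantom
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spatial_weights: np.ndarray | None = None   # length 36; None -> default
    lesion_increment: float = 0.25              # probability deposited per draw

    def copula_matrix(self) -> np.ndarray:
        """Latent Pearson correlation matrix realizing the Spearman targets.

        Uses the Gaussian-copula identity r = 2 sin(pi * rho_s / 6).
        Raises if the resulting matrix is not positive semidefinite.
        """
        idx = {v: i for i, v in enumerate(COPULA_VARS)}
        R = np.eye(len(COPULA_VARS))
        for (a, b), rho in self.rank_targets.items():
            if a not in idx or b not in idx:
                raise ValueError(f"unknown copula variable in pair ({a}, {b})")
            if not -1.0 <= rho <= 1.0:
                raise ValueError("rank correlations must lie in [-1, 1]")
            r = 2.0 * np.sin(np.pi * rho / 6.0)
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError("rank-correlation matrix is not positive semidefinite")
        return R

    def spatial_weight_vector(self) -> np.ndarray:
        if self.spatial_weights is None:
            return default_spatial_weights()
        w = np.asarray(self.spatial_weights, dtype=float)
        if w.shape != (36,):
            raise ValueError("spatial_weights must have length 36")
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("spatial_weights must be non-negative with positive sum")
        return w / w.sum()

    def total_exclusions(self) -> int:
        return self.n_nonconsent + self.n_invalid_scan + self.n_quality_exclusion

    # ---- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rank_targets"] = {f"{a}|{b}": v for (a, b), v in self.rank_targets.items()}
        if self.spatial_weights is not None:
            d["spatial_weights"] = [float(x) for x in self.spatial_weights]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        d = dict(d)
        if "rank_targets" in d:
            d["rank_targets"] = {
                tuple(k.split("|")): float(v) for k, v in d["rank_targets"].items()
            }
        for key in ("age_range", "voxel_size", "grid_shape"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("spatial_weights") is not None:
            d["spatial_weights"] = np.asarray(d["spatial_weights"], dtype=float)
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "GeneratorParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
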