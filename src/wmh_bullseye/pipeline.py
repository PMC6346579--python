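"""End-to-end orchestration: simulate -> phenotype -> parcellate ->
quantify -> associate -> plot, fully reproducible from (config, seed)."""
from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import apply_exclusion_cascade, generate_registry, write_cohort
from .config import GeneratorParams
from .parcellation import build_parcellation, region_table
from .phantom import build_label_volume
from .phenotypes import derive_phenotypes
from .plotting import plot_bullseye
from .quantify import compute_tiv, outcome_matrix, quantify_cohort
from .stats import (GROUP_PREDICTORS, RegionalAssociation, fdr_adjust,
                    global_association_table)

logger = logging.getLogger(__name__)

DEFAULT_PREDICTORS = ["caide_risk_pct", "age", "hypertension",
                      "hypercholesterolemia", "bmi", "sex_male",
                      "education_years", "active", "apoe_genotype",
                      "family_history"]

DEFAULT_CONFIG = {
    "seed": 0,
    "generator": {},            # overrides for GeneratorParams fields
    "predictors": DEFAULT_PREDICTORS,
    "models": [1, 2, 3],
    "n_perm": 10_000,
    "n_boot": 1_000,
    "outdir": "wmh_bullseye_run",
    "save_volumes": False,      # write one example lesion volume regardless
}


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            loaded = yaml.safe_load(fh) or {}
    else:
        loaded = dict(config or {})
    cfg = {**DEFAULT_CONFIG, **loaded}
    cfg["generator"] = {**DEFAULT_CONFIG["generator"],
                        **(loaded.get("generator") or {})}
    return cfg


def run_pipeline(config=None, outdir: str | Path | None = None) -> Path:
    """Execute the full pipeline; returns the artifact directory.

    A ``manifest.json`` records the completed stages, the seed and library
    versions; on a stage failure the manifest names the stages that did
    complete before the error is re-raised.
    """
    cfg = load_config(config)
    out = Path(outdir or cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)

    params = GeneratorParams(seed=int(cfg["seed"]), **cfg["generator"])
    manifest = {
        "seed": int(cfg["seed"]),
        "n_perm": int(cfg["n_perm"]),
        "config": {k: v for k, v in cfg.items() if k != "generator"},
        "versions": {"wmh_bullseye": __version__,
                     "python": platform.python_version(),
                     "numpy": np.__version__, "pandas": pd.__version__},
        "stages_completed": [],
    }

    def checkpoint(stage: str) -> None:
        manifest["stages_completed"].append(stage)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    try:
        # 1. simulate
        registry = generate_registry(params)
        cohort = apply_exclusion_cascade(registry, params)
        write_cohort(registry, out / "registry.tsv")
        write_cohort(cohort, out / "cohort.tsv")
        cohort.attrs["exclusions"].to_csv(out / "exclusions.tsv", sep="\t",
                                          index=False)
        params.save(out / "generator_params.yaml")
        checkpoint("simulate")

        # 2. phenotype
        cohort = derive_phenotypes(cohort)
        write_cohort(cohort, out / "cohort_phenotypes.tsv")
        checkpoint("phenotype")

        # 3. parcellate
        labels = build_label_volume(params.grid_shape, params.voxel_size)
        parc = build_parcellation(labels)
        labels.save(out / "labels.nii.gz")
        parc.save(out / "parcellation.nii.gz")
        region_table(parc).to_csv(out / "region_table.tsv", sep="\t",
                                  index=False)
        manifest["phantom_tiv_cm3"] = compute_tiv(labels)
        checkpoint("parcellate")

        # 4. quantify
        wmh = quantify_cohort(cohort, params, labels=labels)
        wmh.to_csv(out / "wmh_regional.tsv", sep="\t", index=False,
                   float_format="%.8g")
        if cfg["save_volumes"] and len(cohort):
            from .phantom import generate_brain
            _, prob = generate_brain(cohort.iloc[0], params)
            prob.save(out / f"lesionprob_{cohort.iloc[0]['id']}.nii.gz")
        checkpoint("quantify")

        # 5. associate
        outcomes = outcome_matrix(wmh)
        frames = []
        for model in cfg["models"]:
            for pred in cfg["predictors"]:
                res = RegionalAssociation(cohort, outcomes, pred, model).fit(
                    n_perm=int(cfg["n_perm"]), n_boot=int(cfg["n_boot"]),
                    seed=int(cfg["seed"]))
                frames.append(res.frame)
        assoc = pd.concat(frames, ignore_index=True)
        # cross-predictor FDR family for the global rows, per model
        for model in cfg["models"]:
            sel = (assoc["model"] == model) & (assoc["region"] == "global")
            assoc.loc[sel, "q_fdr"] = fdr_adjust(assoc.loc[sel, "p_perm"])
        assoc["significant"] = assoc["q_fdr"] < 0.05
        assoc.to_csv(out / "associations.tsv", sep="\t", index=False,
                     float_format="%.6g")
        assoc[assoc["region"] == "global"].to_csv(
            out / "global_table.tsv", sep="\t", index=False,
            float_format="%.6g")
        checkpoint("associate")

        # 6. plot
        figdir = out / "figures"
        figdir.mkdir(exist_ok=True)
        for (pred, contrast, model), grp in assoc[
                assoc["region"] != "global"].groupby(
                ["predictor", "contrast", "model"]):
            safe = contrast.replace(" ", "_").replace("/", "")
            plot_bullseye(grp, figdir / f"{safe}_model{model}",
                          title=f"{contrast} (Model {model})")
        checkpoint("plot")
    except Exception as exc:
        manifest["error"] = repr(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise
    return out
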