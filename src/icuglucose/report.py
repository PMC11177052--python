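"""Descriptive outputs and the end-to-end pipeline driver.

Every plotted quantity is first written as a CSV so tests and downstream
consumers assert on data, never on rendered images; figure rendering (if
matplotlib is present) reads those CSVs back.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .curate import curate
from .datamodel import SCHEMAS, TableBundle, read_tables, write_analysis_table
from .gbm import fit_gbm_shap
from .match import build_analysis_table
from .models import MODEL_SEQUENCE, emm_profile, fit_model_sequence, hour_effect_estimates, lrt
from .subgroups import default_subgroup_specs, run_subgroup_analysis, subgroup_counts


def normalise_per_patient(rows: pd.DataFrame, method: str = "centre") -> pd.Series:
    """Per-patient normalised glucose for the crude time-course view.

    ``centre`` (default) subtracts the patient mean; ``zscore`` additionally
    divides by the patient standard deviation (single-measurement patients,
    whose deviation is undefined, keep the centred value).
    """
    g = rows.groupby("stay_id", observed=True)["glucose_mmol_l"]
    centred = rows["glucose_mmol_l"] - g.transform("mean")
    if method == "centre":
        return centred
    if method == "zscore":
        sd = g.transform("std")
        return centred / sd.where(sd > 0, 1.0)
    raise ValueError(f"unknown normalisation method {method!r}")


def crude_hourly_profile(rows: pd.DataFrame, normalised: bool = True) -> pd.DataFrame:
    """Unadjusted hourly mean glucose (per-patient normalised by default)."""
    values = normalise_per_patient(rows) if normalised else rows["glucose_mmol_l"]
    out = (
        pd.DataFrame({"hour": rows["hour_bin"], "value": values})
        .groupby("hour")
        .agg(mean=("value", "mean"), n=("value", "size"))
        .reindex(range(24))
        .reset_index()
    )
    return out


def distribution_tables(rows: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Hourly measurement counts and mean enteral nutrition dosing rate."""
    counts = (
        rows.groupby("hour_bin").size().reindex(range(24), fill_value=0).rename("n_measurements").reset_index()
    )
    dosing = (
        rows.groupby("hour_bin")["carb_rate_g_h"].mean().reindex(range(24)).rename("mean_carb_rate_g_h").reset_index()
    )
    return {"measurement_counts": counts, "nutrition_dosing": dosing}


@dataclass
class PipelineConfig:
    """Input table paths plus run options for the full pipeline."""

    table_paths: dict[str, str]
    out_dir: str
    seed: int = 0
    emm_weighting: str = "equal"
    run_gbm: bool = True
    run_subgroups: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, bundle: TableBundle | None = None) -> dict:
    """curate -> match -> fit -> subgroups -> report, with a run manifest.

    Returns the manifest dict; all artifacts are written under
    ``config.out_dir``.  Fully reproducible given the seed and inputs.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    stage = "read"
    try:
        if bundle is None:
            missing = [t for t in SCHEMAS if not os.path.exists(config.table_paths.get(t, ""))]
            if missing:
                raise FileNotFoundError(f"missing input table(s): {', '.join(missing)}")
            bundle = read_tables(config.table_paths)

        stage = "curate"
        curated, included, creport = curate(bundle)
        with open(os.path.join(config.out_dir, "curation_report.json"), "w") as fh:
            json.dump(creport.to_dict(), fh, indent=2)

        stage = "match"
        rows = build_analysis_table(bundle, curated, included)
        write_analysis_table(rows, os.path.join(config.out_dir, "analysis_table.csv"))

        stage = "fit"
        fits = fit_model_sequence(rows)
        model_summary = {
            mid: {
                "n_fixed_params": fits[mid]["REML"].n_fixed_params,
                "log_likelihood_reml": fits[mid]["REML"].log_likelihood,
                "log_likelihood_ml": fits[mid]["ML"].log_likelihood,
                "random_intercept_variance": fits[mid]["REML"].random_intercept_variance,
                "residual_variance": fits[mid]["REML"].residual_variance,
                "coefficients": {
                    t: {k: float(v) for k, v in rec.items()}
                    for t, rec in fits[mid]["REML"].coefficients.to_dict("index").items()
                },
            }
            for mid in MODEL_SEQUENCE
        }
        with open(os.path.join(config.out_dir, "model_fits.json"), "w") as fh:
            json.dump(model_summary, fh, indent=2)
        lrts = [
            lrt(fits[a]["ML"], fits[b]["ML"])
            for a, b in zip(MODEL_SEQUENCE[:-1], MODEL_SEQUENCE[1:])
        ]
        with open(os.path.join(config.out_dir, "lrt.json"), "w") as fh:
            json.dump([vars(r) for r in lrts], fh, indent=2)
        profile = emm_profile(fits["m4"]["ML"], rows, config.emm_weighting)
        profile.table.to_csv(os.path.join(config.out_dir, "emm_profile.csv"), index=False)
        crude_hourly_profile(rows).to_csv(os.path.join(config.out_dir, "crude_hourly_profile.csv"), index=False)
        for name, table in distribution_tables(rows).items():
            table.to_csv(os.path.join(config.out_dir, f"{name}.csv"), index=False)

        shap_peak = None
        if config.run_gbm:
            stage = "gbm"
            shap = fit_gbm_shap(rows, seed=config.seed)
            shap.hourly_mean.to_csv(os.path.join(config.out_dir, "shap_profile.csv"), index=False)
            shap.feature_importance.rename("mean_abs_attribution").to_csv(
                os.path.join(config.out_dir, "shap_importance.csv")
            )
            shap_peak = shap.peak_hour

        if config.run_subgroups:
            stage = "subgroups"
            specs = default_subgroup_specs(bundle.stays, bundle.medication_events)
            results = run_subgroup_analysis(rows, specs, config.emm_weighting)
            subgroup_counts(results).to_csv(os.path.join(config.out_dir, "subgroup_counts.csv"), index=False)
            for r in results:
                if r.profile is not None:
                    slug = f"{r.axis}_{r.level}".replace(" ", "_").replace("(", "").replace(")", "").replace("<", "lt").replace(">", "gt").replace("=", "")
                    r.profile.table.to_csv(os.path.join(config.out_dir, f"emm_profile_{slug}.csv"), index=False)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "input_hashes": {
                t: _sha256(p) for t, p in sorted(config.table_paths.items()) if os.path.exists(p)
            },
            "n_analysis_rows": int(len(rows)),
            "n_included_stays": int(len(included)),
            "emm_peak_hour": profile.peak_hour,
            "emm_trough_hour": profile.trough_hour,
            "emm_cosinor_peak_hour": profile.cosinor.peak_hour,
            "emm_cosinor_peak_to_trough": profile.cosinor.peak_to_trough,
            "shap_peak_hour": shap_peak,
        }
        with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
        return manifest
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err


def render_figures(out_dir: str) -> list[str]:
    """Render figures from the written CSVs; no-op if matplotlib is absent."""
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # pragma: no cover
        return []
    written = []
    emm_path = os.path.join(out_dir, "emm_profile.csv")
    if os.path.exists(emm_path):
        emm = pd.read_csv(emm_path)
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.errorbar(emm["hour"], emm["emm"],
                    yerr=[emm["emm"] - emm["ci_low"], emm["ci_high"] - emm["emm"]],
                    fmt="o-", capsize=2)
        ax.set_xlabel("hour of day")
        ax.set_ylabel("estimated marginal mean glucose (mmol/L)")
        path = os.path.join(out_dir, "emm_profile.png")
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
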