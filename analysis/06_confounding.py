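"""Show that covariate adjustment removes schedule-driven 24-h structure.

Generates a cohort with a *zero* true clock-time effect but diurnal exposure
schedules (dextrose infusions 06:00-12:00, day-high nutrition rates, morning
glucocorticoid courses, each on a subset of patients).  The crude hourly
profile then shows a clear 24-h swing that the fully adjusted model
attributes to the exposures, leaving a near-flat hourly effect.

Writes results/confounding/{crude_profile.csv, adjusted_hour_effects.csv}.
"""

import argparse
import os
import warnings

import pandas as pd

from icuglucose.curate import curate
from icuglucose.match import build_analysis_table
from icuglucose.models import cosinor_summary, fit_model, hour_effect_estimates
from icuglucose.report import crude_hourly_profile
from icuglucose.synth import generate_confounded_cohort, null_config


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-patients", type=int, default=1500)
    ap.add_argument("--out", default="results/confounding")
    args = ap.parse_args()

    cfg = null_config(
        n_patients=args.n_patients, seed=args.seed,
        diurnal_dextrose=True, diurnal_nutrition=True, diurnal_glucocorticoid=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle, _ = generate_confounded_cohort(cfg)
        curated, included, _ = curate(bundle)
        rows = build_analysis_table(bundle, curated, included)
        m4 = fit_model(rows, "m4", reml=False)

    os.makedirs(args.out, exist_ok=True)
    crude = crude_hourly_profile(rows)
    crude.to_csv(os.path.join(args.out, "crude_profile.csv"), index=False)
    effects = hour_effect_estimates(m4)
    pd.DataFrame({"hour": range(24), "hour_effect": effects}).to_csv(
        os.path.join(args.out, "adjusted_hour_effects.csv"), index=False
    )

    c = cosinor_summary(crude["mean"].to_numpy())
    a = cosinor_summary(effects)
    print(f"confounded cohort: {len(rows)} measurements, true hourly effect = 0")
    print(f"  crude hourly profile: peak-to-trough {c.peak_to_trough:.2f} mmol/L (peak {c.peak_hour:02d}:00)")
    print(f"  adjusted hourly effect: peak-to-trough {a.peak_to_trough:.2f} mmol/L")
    print("  -> the apparent 24-h rhythm is explained by the exposure schedules")


if __name__ == "__main__":
    main()
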