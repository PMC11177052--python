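"""Curate the cohort and build the analysis table.

Applies the inclusion criteria (LOS >= 4 d, no readmission, glucose and
enteral nutrition present), the measurement-cleaning chain (validity limits,
simultaneous-sample deduplication, enteral-nutrition restriction), then
joins each kept measurement to its PK-corrected exposures and derived
covariates.

Reads results/cohort/; writes results/curated/{analysis_table.csv,
curation_report.json}.
"""

import argparse
import json
import os

from icuglucose.curate import curate
from icuglucose.datamodel import SCHEMAS, read_tables, write_analysis_table
from icuglucose.match import build_analysis_table


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--tables", default="results/cohort")
    ap.add_argument("--out", default="results/curated")
    args = ap.parse_args()

    paths = {t: os.path.join(args.tables, f"{t}.csv") for t in SCHEMAS}
    bundle = read_tables(paths)
    curated, included, report = curate(bundle)
    rows = build_analysis_table(bundle, curated, included)

    os.makedirs(args.out, exist_ok=True)
    write_analysis_table(rows, os.path.join(args.out, "analysis_table.csv"))
    with open(os.path.join(args.out, "curation_report.json"), "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)

    print(f"{report.steps['select_cohort'][0]} stays -> {len(included)} included")
    for step, (n_in, n_out) in report.steps.items():
        print(f"  {step}: {n_in} -> {n_out}")
    print(f"analysis table: {len(rows)} rows -> {args.out}/analysis_table.csv")


if __name__ == "__main__":
    main()
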