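#!/usr/bin/env python
"""Run the full epi-mutation-burden pipeline on a user-supplied cohort.

This is the full-cohort companion to the synthetic test suite: it applies
differential probe calling, burden computation, purity-window filtering,
EpiMut classification and the burden-vs-hypomethylation correlation to real
beta matrices (e.g. 450K array cohorts downloaded from a data portal; data
retrieval itself is out of scope).  Expect cohort-dependent results — the
desk-scale suite only guarantees behaviour on data with known ground truth.

Example:
    python scripts/reproduce_full_scale.py \
        --tumors TUMOR_BETAS.tsv --normals NORMAL_BETAS.tsv \
        --samples SAMPLES.tsv --min-frac 0.05 --out-prefix results/cohort
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import pandas as pd

from methet import (
    burden,
    call_probes,
    classify_epimut,
    cancer_pattern,
    correlate,
    narrowest_window,
    normal_reference,
    read_beta_matrix,
    read_sample_table,
    recurrence_filter,
    select_samples,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--tumors", required=True, help="tumor beta matrix TSV")
    ap.add_argument("--normals", required=True, help="matched-normal beta matrix TSV")
    ap.add_argument("--samples", required=True, help="sample table TSV with a purity column")
    ap.add_argument("--purity-col", default="purity")
    ap.add_argument("--min-frac", type=float, default=0.05,
                    help="recurrence fraction (0.05 for array cohorts, 0.10 for cell lines)")
    ap.add_argument("--out-prefix", required=True)
    args = ap.parse_args()

    tumors = read_beta_matrix(args.tumors)
    normals = read_beta_matrix(args.normals)
    samples = read_sample_table(args.samples)

    calls = recurrence_filter(
        call_probes(tumors, normal_reference(normals)), args.min_frac
    )
    burdens = burden(calls)
    burdens.to_csv(f"{args.out_prefix}.burdens.tsv", sep="\t")

    labels = classify_epimut(burdens, method="em_total")
    high_frac = float((labels == "HighEpiMut").mean())
    pattern = cancer_pattern(high_frac)

    purities = samples[args.purity_col].reindex(burdens.index)
    window = narrowest_window(purities)
    inside = select_samples(
        samples.reindex(burdens.index), window, mode="inside", purity_col=args.purity_col
    )
    sub = burdens.loc[burdens.index.intersection(inside)]
    r_all = correlate(burdens["N_hyper"], burdens["N_hypo"])
    r_filt = correlate(sub["N_hyper"], sub["N_hypo"])

    summary = {
        "n_tumors": int(burdens.shape[0]),
        "high_epimut_fraction": round(high_frac, 4),
        "pattern": pattern,
        "purity_window": [window.lo, window.hi],
        "r_hyper_vs_hypo_all": round(r_all.r, 4),
        "r_hyper_vs_hypo_filtered": round(r_filt.r, 4),
        "n_filtered": int(sub.shape[0]),
    }
    Path(f"{args.out_prefix}.summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
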