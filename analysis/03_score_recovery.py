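#!/usr/bin/env python
"""Score the pipeline's calls against the simulator's ground truth.

Compares the DN/DM differential calls from 02_run_pipeline.py with the
planted regulated set and the localization table with the planted sites, and
writes results/recovery_summary.json.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from uevphos.synthetic_data import GroundTruth

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"
PIPE = ROOT / "results" / "pipeline"


def main() -> None:
    if not (PIPE / "differential_DN_vs_DM.tsv").exists():
        sys.exit("run analysis/02_run_pipeline.py first")
    gt = GroundTruth.from_json(SIM / "ground_truth.json")
    diff = pd.read_csv(PIPE / "differential_DN_vs_DM.tsv", sep="\t")
    calls = {
        (r.sequence, r.phospho_count): r.status for r in diff.itertuples(index=False)
    }
    n_correct = n_wrong = n_missed = 0
    for key_str, direction in gt.regulated.items():
        seq, k = key_str.rsplit("/", 1)
        status = calls.get((seq, int(k)))
        if status == direction:
            n_correct += 1
        elif status in ("up", "down"):
            n_wrong += 1
        else:
            n_missed += 1
    false_pos = int(
        (diff["status"].isin(["up", "down"])).sum() - n_correct - n_wrong
    )

    loc = pd.read_csv(PIPE / "localization.tsv", sep="\t")
    loc_idx = {(r.sequence, r.phospho_count): r for r in loc.itertuples(index=False)}
    n_loc_ok = n_loc = 0
    for rec in gt.peptides:
        gap = rec["isomer_gap"]
        if gap is None or gap < 10.0:
            continue
        row = loc_idx.get((rec["sequence"], rec["phospho_count"]))
        if row is None:
            continue
        n_loc += 1
        got = sorted(int(p) for p in str(row.positions).split(";"))
        if row.status == "confident" and got == sorted(rec["true_positions"]):
            n_loc_ok += 1

    summary = {
        "n_planted": len(gt.regulated),
        "n_correct_direction": n_correct,
        "n_wrong_direction": n_wrong,
        "n_missed": n_missed,
        "n_false_positive_calls": false_pos,
        "recovery_pct": round(100.0 * n_correct / len(gt.regulated), 1),
        "localization_checked_gap_ge_10": n_loc,
        "localization_correct": n_loc_ok,
        "localization_accuracy_pct": round(100.0 * n_loc_ok / n_loc, 1) if n_loc else None,
    }
    out = ROOT / "results" / "recovery_summary.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(summary, indent=1))
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
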