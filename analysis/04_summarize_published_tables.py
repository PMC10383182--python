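#!/usr/bin/env python
"""Summarize the curated published tables with the pipeline's own
summarizers.

Feeds the bundled urinary-EV differential phosphopeptide list and the
published site/protein tallies through the same counting code the pipeline
uses on its own outputs, and writes results/published_summaries.json.
Expected output: 23 up / 24 down (DN vs DM); 61.3% pS / 34.6% pT / 4.11% pY
of 292 sites; 14.49% of phosphoproteins seen in all three groups.
"""

import json
from pathlib import Path

from uevphos.datasets import load_differential_phosphopeptides
from uevphos.ident_filter import percent_in_all_groups, residue_distribution
from uevphos.stats_diff import DifferentialResult, summarize_differentials

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    report = {}
    for comparison in ("DN/DM", "DN/NC", "DM/NC"):
        df = load_differential_phosphopeptides(comparison)
        results = [
            DifferentialResult(
                peptide_key=(row.peptide, 1),
                comparison=comparison,
                fold_change=2.0 if row.direction == "up" else 0.5,
                p_value=row.p_value,
                status=row.direction,
            )
            for row in df.itertuples(index=False)
        ]
        report[comparison] = summarize_differentials(results)["comparisons"][comparison]

    total, percents = residue_distribution({"S": 179, "T": 101, "Y": 12})
    report["site_residue_distribution"] = {"n_sites": total, "percent": percents}
    report["pct_phosphoproteins_all_groups"] = percent_in_all_groups(31, 214)

    out = ROOT / "results" / "published_summaries.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(report, indent=1, sort_keys=True))
    print(json.dumps(report, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
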