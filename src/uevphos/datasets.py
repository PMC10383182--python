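"""Bundled reference tables.

``load_differential_phosphopeptides`` returns the curated list of urinary-EV
phosphopeptides reported as significantly changed between the three study
groups (diabetic nephropathy DN, diabetes without nephropathy DM, and normal
controls NC), tagged with comparison and direction.  One transcription
artifact in the source table (a peptide's terminal arginine migrating into
the site column) was repaired during curation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_differential_phosphopeptides"]


def load_differential_phosphopeptides(comparison: str | None = None) -> pd.DataFrame:
    """Load the curated differential-phosphopeptide table.

    Columns: comparison (e.g. ``DN/DM``), direction (``up``/``down``), gene,
    peptide, site (residue + 1-based position, e.g. ``S3``), p_value.
    Optionally filter to one comparison.
    """
    ref = resources.files("uevphos.data") / "uev_differential_phosphopeptides.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    if comparison is not None:
        df = df[df["comparison"] == comparison].reset_index(drop=True)
    return df
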