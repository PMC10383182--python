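"""Significance model and differential phosphopeptide calling.

The error model is a global robust-normal null on per-peptide log2 ratios:
location = median, spread = 1.4826 x median absolute deviation (the normal-
consistent MAD estimate), so a handful of genuinely regulated peptides do
not inflate the null.  Each peptide's two-sided tail probability under that
null is its p-value.  A peptide is called differential when its linear fold
change passes the symmetric threshold (>= 1.5 or <= 1/1.5) and p < 0.05;
no multiple-testing correction is applied by default (Benjamini-Hochberg is
available via a flag).  An optional per-peptide t-test across member scans
is provided for peptides observed in >= 3 scans.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _stats

logger = logging.getLogger(__name__)

__all__ = [
    "NullModel",
    "DifferentialResult",
    "fit_null",
    "ratio_pvalue",
    "call_differential",
    "summarize_differentials",
    "benjamini_hochberg",
    "per_peptide_ttest",
]

MIN_NULL_FIT = 10
DEFAULT_FOLD_THRESHOLD = 1.5
DEFAULT_ALPHA = 0.05
MAD_TO_SIGMA = 1.4826022185056018  # 1 / Phi^-1(3/4)


@dataclass
class NullModel:
    """Robust-normal null for log2 ratios."""

    mu: float
    sigma: float
    method: str = "robust_normal"
    n_fit: int = 0


@dataclass
class DifferentialResult:
    peptide_key: tuple[str, int]
    comparison: str
    fold_change: float
    p_value: float
    status: str  # up | down | not_significant
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD
    alpha: float = DEFAULT_ALPHA


def fit_null(log2_ratios: Iterable[float], sigma_floor: float = 1e-6) -> NullModel:
    """Fit the robust-normal null: median and MAD-based sigma.

    Requires at least 10 finite values.  A degenerate spread (all values
    identical) is floored at ``sigma_floor`` with a warning.
    """
    values = np.asarray([v for v in log2_ratios if np.isfinite(v)], dtype=float)
    if values.size < MIN_NULL_FIT:
        raise ValueError(
            f"need at least {MIN_NULL_FIT} finite log2 ratios to fit the null "
            f"(got {values.size}); provide a larger input"
        )
    mu = float(np.median(values))
    sigma = float(MAD_TO_SIGMA * np.median(np.abs(values - mu)))
    if sigma < sigma_floor:
        warnings.warn(
            f"null spread {sigma:.3g} below floor; using sigma={sigma_floor}",
            RuntimeWarning,
            stacklevel=2,
        )
        sigma = sigma_floor
    return NullModel(mu=mu, sigma=sigma, n_fit=int(values.size))


def ratio_pvalue(log2_ratio: float, null: NullModel) -> float:
    """Two-sided normal tail probability of a log2 ratio under the null."""
    if not np.isfinite(log2_ratio):
        raise ValueError("log2 ratio must be finite")
    z = (log2_ratio - null.mu) / null.sigma
    return float(2.0 * _stats.norm.sf(abs(z)))


def call_differential(
    peptide_key: tuple[str, int],
    comparison: str,
    fold_change: float,
    p_value: float,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> DifferentialResult:
    """Classify one peptide: up / down / not_significant.

    The fold threshold is applied symmetrically on the linear scale:
    up when fold >= threshold, down when fold <= 1/threshold, and in either
    case only when p < alpha.
    """
    if fold_change <= 0:
        raise ValueError("fold change must be positive")
    if p_value < alpha and fold_change >= fold_threshold:
        status = "up"
    elif p_value < alpha and fold_change <= 1.0 / fold_threshold:
        status = "down"
    else:
        status = "not_significant"
    return DifferentialResult(
        peptide_key=peptide_key,
        comparison=comparison,
        fold_change=fold_change,
        p_value=p_value,
        status=status,
        fold_threshold=fold_threshold,
        alpha=alpha,
    )


def summarize_differentials(
    results: Sequence[DifferentialResult],
    protein_map: Mapping[tuple[str, int], str] | None = None,
) -> dict:
    """Tally differential calls by comparison and direction.

    Reports peptide-level counts always; when a peptide-to-protein map is
    supplied, protein-level tallies (distinct parent accessions among the
    significant peptides) are included too.
    """
    summary: dict = {"comparisons": {}, "n_up": 0, "n_down": 0, "n_significant": 0}
    by_cmp: dict[str, list[DifferentialResult]] = {}
    for r in results:
        by_cmp.setdefault(r.comparison, []).append(r)
    for cmp_label, rows in sorted(by_cmp.items()):
        ups = [r for r in rows if r.status == "up"]
        downs = [r for r in rows if r.status == "down"]
        entry = {
            "n_up": len(ups),
            "n_down": len(downs),
            "n_significant": len(ups) + len(downs),
            "n_tested": len(rows),
        }
        if protein_map is not None:
            entry["n_proteins_up"] = len({protein_map.get(r.peptide_key) for r in ups})
            entry["n_proteins_down"] = len({protein_map.get(r.peptide_key) for r in downs})
            entry["n_proteins_significant"] = len(
                {protein_map.get(r.peptide_key) for r in ups + downs}
            )
        summary["comparisons"][cmp_label] = entry
        summary["n_up"] += entry["n_up"]
        summary["n_down"] += entry["n_down"]
        summary["n_significant"] += entry["n_significant"]
    return summary


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    adjusted = np.empty(n)
    running_min = 1.0
    for i in range(n - 1, -1, -1):
        rank = i + 1
        running_min = min(running_min, p[order[i]] * n / rank)
        adjusted[order[i]] = running_min
    return adjusted


def per_peptide_ttest(scan_log2_ratios: Sequence[float]) -> float:
    """One-sample two-sided t-test of per-scan log2 ratios against 0.

    Requires at least 3 scans; an alternative to the global error model for
    peptides with enough replicate scans.
    """
    x = np.asarray(scan_log2_ratios, dtype=float)
    if x.size < 3:
        raise ValueError("per-peptide t-test needs >= 3 scans")
    return float(_stats.ttest_1samp(x, 0.0).pvalue)
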