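"""4-plex iTRAQ reporter-ion quantification.

Per MS/MS scan: pick the most intense peak within the fragment tolerance of
each reporter channel mass, deconvolve isotope-impurity bleed between
channels by solving the purity linear system, and scale channels by
normalization factors derived from reference-run channel totals.  Per
peptide: channel intensities from all member scans are summed first, and
group ratios are taken on the sums (sum-then-ratio), which weights scans by
signal rather than averaging noisy per-scan ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ChannelSet",
    "PurityMatrix",
    "ReporterQuant",
    "NormalizationFactors",
    "PeptideQuant",
    "DEFAULT_REPORTER_MASSES",
    "default_purity_matrix",
    "extract_reporters",
    "correct_impurities",
    "compute_normalization_factors",
    "aggregate_and_ratio",
]

#: Monoisotopic m/z of the 4-plex reporter ions, channels 114-117.
DEFAULT_REPORTER_MASSES: dict[int, float] = {
    114: 114.1112,
    115: 115.1083,
    116: 116.1116,
    117: 117.1150,
}

DEFAULT_GROUP_MAP: dict[int, str] = {114: "NC", 115: "DM", 116: "DN", 117: "reference"}


@dataclass
class ChannelSet:
    """The ordered reporter channels and their group assignment."""

    labels: tuple[int, ...] = (114, 115, 116, 117)
    masses: tuple[float, ...] = tuple(DEFAULT_REPORTER_MASSES[c] for c in (114, 115, 116, 117))
    group_map: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_GROUP_MAP))

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be distinct")
        if any(b <= a for a, b in zip(self.masses, self.masses[1:])):
            raise ValueError("reporter masses must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.labels)

    def channels_for_group(self, group: str) -> list[int]:
        idx = [i for i, c in enumerate(self.labels) if self.group_map.get(c) == group]
        if not idx:
            raise KeyError(f"no channel assigned to group {group!r}")
        return idx


class PurityMatrix:
    """Isotope-impurity mixing matrix for the reporter channels.

    Entry (i, j) is the fraction of channel j's reagent signal observed in
    channel i; columns may sum to less than 1 (bleed outside the detected
    window is lost).  Must be non-negative and invertible.
    """

    def __init__(self, matrix: np.ndarray):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"purity matrix must be 4x4, got {m.shape}")
        if np.any(m < 0):
            raise ValueError("purity matrix has negative entries")
        if np.any(m.sum(axis=0) > 1 + 1e-6):
            raise ValueError("purity matrix column sums exceed 1")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("purity matrix is singular")
        self.matrix = m

    def mix(self, truth: np.ndarray) -> np.ndarray:
        """Forward-mix true channel signals into observed signals."""
        return self.matrix @ np.asarray(truth, dtype=float)


def default_purity_matrix(bleed: float = 0.02) -> PurityMatrix:
    """Purity matrix with symmetric single-channel bleed to neighbours.

    Each reagent loses ``bleed`` of its signal into each adjacent channel;
    bleed past the 114/117 edges leaves the detected window.
    """
    m = np.zeros((4, 4))
    for j in range(4):
        m[j, j] = 1.0 - 2 * bleed
        if j - 1 >= 0:
            m[j - 1, j] = bleed
        if j + 1 < 4:
            m[j + 1, j] = bleed
    return PurityMatrix(m)


@dataclass
class ReporterQuant:
    """Per-scan reporter intensities at the three processing stages."""

    scan_id: str
    raw: np.ndarray
    corrected: np.ndarray | None = None
    normalized: np.ndarray | None = None


@dataclass
class NormalizationFactors:
    factors: np.ndarray
    source: str = "self"

    def apply(self, intensities: np.ndarray) -> np.ndarray:
        return np.asarray(intensities, dtype=float) * self.factors


@dataclass
class PeptideQuant:
    """Aggregated per-peptide channel sums and group ratios."""

    peptide_key: tuple[str, int]
    channel_sums: np.ndarray
    n_scans: int
    ratios: dict[str, float] = field(default_factory=dict)
    log2_ratios: dict[str, float] = field(default_factory=dict)
    zero_denominator: set[str] = field(default_factory=set)


def extract_reporters(
    mz: np.ndarray,
    intensity: np.ndarray,
    channels: ChannelSet,
    tol: float = 0.1,
) -> np.ndarray:
    """Raw reporter 4-vector: per channel, the most intense peak within
    +/- ``tol`` of the channel mass, else 0."""
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    out = np.zeros(channels.n)
    for i, center in enumerate(channels.masses):
        lo = np.searchsorted(mz, center - tol, side="left")
        hi = np.searchsorted(mz, center + tol, side="right")
        if hi > lo:
            out[i] = float(intensity[lo:hi].max())
    return out


def correct_impurities(raw: np.ndarray, purity: PurityMatrix) -> np.ndarray:
    """Solve the purity system for the underlying channel signals.

    Exact negative solutions (possible with noisy raw vectors) are clamped
    to zero; clamping is logged.
    """
    corrected = np.linalg.solve(purity.matrix, np.asarray(raw, dtype=float))
    negative = corrected < 0
    if np.any(negative):
        logger.debug("clamped %d negative corrected intensities", int(negative.sum()))
        corrected = np.where(negative, 0.0, corrected)
    return corrected


def compute_normalization_factors(
    reference_totals: np.ndarray, source: str = "self"
) -> NormalizationFactors:
    """Channel factors that equalize the reference-run channel totals.

    ``factor_c = mean(totals) / totals_c`` — applying the factors to the
    reference totals makes all four channels equal, correcting for minor
    differences in source protein amounts.
    """
    totals = np.asarray(reference_totals, dtype=float)
    if np.any(totals <= 0):
        raise ValueError("all reference channel totals must be positive")
    return NormalizationFactors(factors=totals.mean() / totals, source=source)


def aggregate_and_ratio(
    scans: Sequence[ReporterQuant],
    channels: ChannelSet,
    comparisons: Sequence[tuple[str, str]],
    peptide_key: tuple[str, int] = ("", 0),
) -> PeptideQuant:
    """Sum normalized channel intensities over a peptide's scans, then take
    group ratios on the sums.

    Each comparison is ``(numerator group, denominator group)`` and is
    labelled ``"NUM/DEN"``.  A zero denominator sum flags the peptide for
    that comparison and yields no ratio.
    """
    if not scans:
        raise ValueError("empty scan list")
    stacked = np.vstack([
        s.normalized if s.normalized is not None else
        (s.corrected if s.corrected is not None else s.raw)
        for s in scans
    ])
    sums = stacked.sum(axis=0)
    quant = PeptideQuant(peptide_key=peptide_key, channel_sums=sums, n_scans=len(scans))
    for num_group, den_group in comparisons:
        label = f"{num_group}/{den_group}"
        num = sums[channels.channels_for_group(num_group)].sum()
        den = sums[channels.channels_for_group(den_group)].sum()
        if den == 0:
            quant.zero_denominator.add(label)
            continue
        ratio = num / den
        quant.ratios[label] = ratio
        quant.log2_ratios[label] = math.log2(ratio) if ratio > 0 else -math.inf
    return quant
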