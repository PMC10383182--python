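"""Phosphosite localization by the Mascot delta (MD) score.

For each unique phosphopeptide the MD score is the search-engine score
difference between the best and second-best match of the same sequence with
the same number of phosphates placed on different residues.  A large gap
means the spectrum discriminates between the positional isomers; peptides at
or above the cutoff (default 10) are called confidently localized.  A
peptide with no competing isomer hit — including peptides whose sequence
admits only one site arrangement — is treated as unambiguously localized.
Ambiguous peptides keep their rank-1 positions for reporting, flagged, and
still contribute to quantification (which keys on sequence and phosphate
count, not on the site).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["SiteCandidate", "SiteLocalization", "md_score", "localize"]

DEFAULT_MD_CUTOFF = 10.0


@dataclass(frozen=True)
class SiteCandidate:
    """One site arrangement for a phosphopeptide, with its match score."""

    positions: frozenset[int]
    score: float
    rank: int = 1


@dataclass
class SiteLocalization:
    peptide_key: tuple[str, int]
    best: SiteCandidate
    md_score: float | None
    status: str  # confident | ambiguous | single_candidate
    cutoff: float

    @property
    def is_localized(self) -> bool:
        return self.status in ("confident", "single_candidate")


def md_score(top: SiteCandidate, second: SiteCandidate | None) -> float | None:
    """Score gap between the top and runner-up site arrangements.

    Returns ``None`` when no competitor exists.  Candidates with identical
    position sets are not a localization pair.
    """
    if second is None:
        return None
    if top.positions == second.positions:
        raise ValueError("candidates share the same site arrangement")
    if top.score < second.score:
        raise ValueError("top candidate must have the higher score")
    return top.score - second.score


def localize(
    candidates: Sequence[SiteCandidate],
    cutoff: float = DEFAULT_MD_CUTOFF,
    peptide_key: tuple[str, int] = ("", 0),
) -> SiteLocalization:
    """Call the site assignment for one phosphopeptide.

    ``candidates`` must be non-empty and sorted by score descending.  The
    runner-up is the best-scoring candidate whose positions differ from the
    top hit; with no such competitor the peptide is a single candidate and
    counts as localized.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    top = candidates[0]
    second = next((c for c in candidates[1:] if c.positions != top.positions), None)
    if second is None:
        return SiteLocalization(peptide_key, top, None, "single_candidate", cutoff)
    delta = md_score(top, second)
    status = "confident" if delta >= cutoff else "ambiguous"
    return SiteLocalization(peptide_key, top, delta, status, cutoff)
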