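"""Ground-truth simulator for a 4-plex iTRAQ phosphoproteomics experiment.

Emulates the study design this pipeline targets: three subject groups
(normal control NC, diabetes DM, diabetic nephropathy DN) plus a reference
channel on the four iTRAQ reporters, tryptic phosphopeptides from a protein
database, MS/MS scans carrying reporter ions, reversed-sequence decoy PSMs,
and positional-isomer competitor hits with controlled score gaps.  Every
emitted artifact uses exactly the formats the pipeline reads (MGF, PSM TSV,
purity CSV, FASTA) plus a ground-truth JSON for recovery tests.

The generative model, per phosphopeptide:

* a base abundance (log-normal around ``base_abundance``), identical in all
  channels except for regulated peptides, whose ``regulated_group`` channel
  is multiplied or divided by ``true_fold``;
* a per-channel loading bias shared by all peptides and by the reference
  run, which normalization must undo;
* 1-3 MS/MS scans, splitting the peptide's signal; per scan the true channel
  signals are forward-mixed through the purity matrix and perturbed by
  multiplicative log-normal noise with coefficient of variation ``noise_cv``;
* rank-1 PSM scores ~ Normal(40, 8) for targets, Normal(20, 6) for decoys
  (both clipped at zero), which yields realistic target-decoy score overlap;
* for a configurable fraction of peptides with an alternative acceptor
  residue, a rank-2 positional-isomer hit whose score trails the rank-1 hit
  by a gap drawn once per peptide, so MD-score behaviour is controlled.

Everything is deterministic given the seed: repeated runs write
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .formats_io import ProteinRecord, Spectrum, write_fasta, write_mgf, write_purity_matrix
from .ident_filter import (
    Modification,
    compute_peptide_mass,
    format_modifications,
    PROTON_MASS,
)
from .quant import DEFAULT_GROUP_MAP, DEFAULT_REPORTER_MASSES, default_purity_matrix

__all__ = ["SimConfig", "GroundTruth", "SimulatedExperiment", "digest_protein", "generate_experiment"]

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_ACCEPTORS = set("STY")


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment.

    Defaults describe the benchmark condition used throughout the test
    suite: 2,000 phosphopeptides of which 50 are regulated two-fold in the
    DN channel, 10% reporter noise, 10% decoy PSMs, and half of the eligible
    peptides carrying a positional-isomer competitor hit.
    """

    seed: int
    n_proteins: int = 400
    protein_length: int = 360
    n_phosphopeptides: int = 2000
    n_regulated: int = 50
    true_fold: float = 2.0
    noise_cv: float = 0.1
    decoy_fraction: float = 0.1
    isomer_fraction: float = 0.5
    score_gap_low: float = 1.0
    score_gap_high: float = 30.0
    target_score_mean: float = 40.0
    target_score_sd: float = 8.0
    decoy_score_mean: float = 20.0
    decoy_score_sd: float = 6.0
    base_abundance: float = 1.0e5
    abundance_log_sd: float = 0.5
    doubly_phospho_fraction: float = 0.15
    purity_bleed: float = 0.02
    channel_bias: tuple[float, float, float, float] = (1.0, 1.08, 0.95, 1.02)
    group_map: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_GROUP_MAP))
    regulated_group: str = "DN"
    min_peptide_len: int = 6
    max_peptide_len: int = 40
    decoy_prefix: str = "REV_"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("noise_cv", "decoy_fraction", "isomer_fraction", "doubly_phospho_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_regulated > self.n_phosphopeptides:
            raise ValueError("n_regulated exceeds n_phosphopeptides")
        if self.true_fold <= 0:
            raise ValueError("true_fold must be positive")
        if self.regulated_group not in self.group_map.values():
            raise ValueError(f"regulated_group {self.regulated_group!r} not in group_map")


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery scoring."""

    peptides: list[dict]
    regulated: dict[str, str]  # "SEQ/k" -> "up" | "down"
    decoy_psm_count: int
    target_psm_count: int
    group_map: dict[int, str]
    channel_bias: list[float]
    reference_totals: list[float]
    config: dict

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as out:
            json.dump(payload, out, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as handle:
            payload = json.load(handle)
        return cls(**payload)


@dataclass
class SimulatedExperiment:
    mgf_path: Path
    psm_path: Path
    purity_path: Path
    fasta_path: Path
    ground_truth_path: Path
    reference_totals: np.ndarray
    ground_truth: GroundTruth


def digest_protein(
    sequence: str,
    missed_cleavages: int = 2,
    min_len: int = 6,
    max_len: int = 40,
) -> list[str]:
    """In-silico tryptic digest: cleave C-terminal to K or R except before P.

    Peptides with up to ``missed_cleavages`` internal uncleaved sites are
    included, then filtered to the given length window.
    """
    if not sequence:
        raise ValueError("empty protein sequence")
    cut_after = [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]
    boundaries = [0] + [i + 1 for i in cut_after] + [len(sequence)]
    segments = [
        sequence[boundaries[i] : boundaries[i + 1]] for i in range(len(boundaries) - 1)
    ]
    peptides = []
    for start in range(len(segments)):
        for span in range(1, missed_cleavages + 2):
            if start + span > len(segments):
                break
            pep = "".join(segments[start : start + span])
            if min_len <= len(pep) <= max_len:
                peptides.append(pep)
    return peptides


def _standard_modifications(sequence: str, phospho_positions: tuple[int, ...]) -> tuple[Modification, ...]:
    """Fixed labelling/alkylation mods plus phospho at the given positions."""
    mods = [Modification("itraq4plex", "N-term", 0)]
    for i, aa in enumerate(sequence, start=1):
        if aa == "K":
            mods.append(Modification("itraq4plex", "K", i))
        elif aa == "C":
            mods.append(Modification("carbamidomethyl", "C", i))
    for pos in phospho_positions:
        mods.append(Modification("phospho", sequence[pos - 1], pos))
    return tuple(mods)


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _fragment_peaks(rng: np.random.Generator, n: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Unassigned backbone-fragment stand-in peaks above the reporter region."""
    mz = rng.uniform(200.0, 1400.0, size=n)
    intensity = rng.uniform(50.0, 5000.0, size=n)
    return mz, intensity


def generate_experiment(config: SimConfig, out_dir: str | Path) -> SimulatedExperiment:
    """Simulate one experiment and write all pipeline input files.

    Writes ``spectra.mgf``, ``psms.tsv``, ``purity.csv``, ``proteins.fasta``,
    ``reference_totals.csv`` and ``ground_truth.json`` under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_prot, rng_select, rng_abund, rng_noise, rng_scores, rng_decoy = (
        np.random.default_rng(s) for s in streams
    )

    # -- protein database and tryptic phosphopeptide candidates -------------
    proteins: list[ProteinRecord] = []
    peptide_parent: dict[str, str] = {}
    for i in range(config.n_proteins):
        seq = "".join(rng_prot.choice(list(_RESIDUES), size=config.protein_length))
        acc = f"SYN{i:04d}"
        proteins.append(ProteinRecord(accession=acc, description=f"synthetic protein {i}", sequence=seq))
        for pep in digest_protein(seq, 0, config.min_peptide_len, config.max_peptide_len):
            if any(aa in _ACCEPTORS for aa in pep) and pep not in peptide_parent:
                peptide_parent[pep] = acc
    candidates = sorted(peptide_parent)
    if len(candidates) < config.n_phosphopeptides:
        raise ValueError(
            f"only {len(candidates)} candidate phosphopeptides from "
            f"{config.n_proteins} proteins; raise n_proteins"
        )
    chosen_idx = rng_select.choice(len(candidates), size=config.n_phosphopeptides, replace=False)
    chosen = [candidates[i] for i in sorted(chosen_idx)]

    # -- phospho states, regulation, abundances ------------------------------
    labels = sorted(config.group_map)  # channel order 114..117
    bias = np.asarray(config.channel_bias, dtype=float)
    reg_channel = labels.index(
        next(c for c in labels if config.group_map[c] == config.regulated_group)
    )
    reg_pick = rng_select.choice(config.n_phosphopeptides, size=config.n_regulated, replace=False)
    reg_direction = {
        int(i): ("up" if k < (config.n_regulated + 1) // 2 else "down")
        for k, i in enumerate(reg_pick)
    }

    purity = default_purity_matrix(config.purity_bleed)
    peptide_records: list[dict] = []
    regulated: dict[str, str] = {}
    spectra: list[Spectrum] = []
    psm_rows: list[dict] = []
    scan_counter = 0

    def new_scan_id() -> str:
        nonlocal scan_counter
        scan_counter += 1
        return f"{scan_counter:06d}"

    for idx, seq in enumerate(chosen):
        acceptors = [i for i, aa in enumerate(seq, start=1) if aa in _ACCEPTORS]
        k = 1
        if len(acceptors) >= 2 and rng_select.random() < config.doubly_phospho_fraction:
            k = 2
        true_pos = tuple(sorted(rng_select.choice(acceptors, size=k, replace=False).tolist()))
        mods = _standard_modifications(seq, true_pos)
        mass = compute_peptide_mass(seq, mods)

        abundance = config.base_abundance * rng_abund.lognormal(0.0, config.abundance_log_sd)
        truth = np.full(4, abundance)
        direction = reg_direction.get(idx)
        if direction == "up":
            truth[reg_channel] *= config.true_fold
        elif direction == "down":
            truth[reg_channel] /= config.true_fold

        # positional-isomer competitor, where an alternative acceptor exists
        isomer_gap = None
        alt_pos = None
        free = [p for p in acceptors if p not in true_pos]
        if free and rng_select.random() < config.isomer_fraction:
            isomer_gap = float(
                rng_select.uniform(config.score_gap_low, config.score_gap_high)
            )
            swapped = rng_select.choice(free)
            alt = sorted(set(true_pos[:-1]) | {int(swapped)})
            alt_pos = tuple(alt)

        n_scans = int(rng_select.integers(1, 4))
        charge = int(rng_select.integers(2, 4))
        precursor_mz = (mass + charge * PROTON_MASS) / charge
        scan_ids = []
        for s in range(n_scans):
            scan_id = new_scan_id()
            scan_ids.append(scan_id)
            observed = purity.mix(truth * bias / n_scans) * _lognormal_noise(
                rng_noise, config.noise_cv, 4
            )
            frag_mz, frag_int = _fragment_peaks(rng_noise)
            mz = np.concatenate([[DEFAULT_REPORTER_MASSES[c] for c in labels], frag_mz])
            inten = np.concatenate([observed, frag_int])
            spectra.append(
                Spectrum(
                    scan_id=scan_id,
                    title=f"scan={scan_id} pep={idx}",
                    precursor_mz=precursor_mz,
                    charge=charge,
                    mz=mz,
                    intensity=inten,
                )
            )
            score = float(max(rng_scores.normal(config.target_score_mean, config.target_score_sd), 0.01))
            psm_rows.append(
                dict(
                    spectrum_ref=scan_id,
                    sequence=seq,
                    modifications=format_modifications(mods),
                    score=round(score, 4),
                    rank=1,
                    is_decoy=0,
                    accessions=peptide_parent[seq],
                    charge=charge,
                )
            )
            if isomer_gap is not None and alt_pos is not None:
                alt_mods = _standard_modifications(seq, alt_pos)
                psm_rows.append(
                    dict(
                        spectrum_ref=scan_id,
                        sequence=seq,
                        modifications=format_modifications(alt_mods),
                        score=round(max(score - isomer_gap, 0.0), 4),
                        rank=2,
                        is_decoy=0,
                        accessions=peptide_parent[seq],
                        charge=charge,
                    )
                )

        key = f"{seq}/{k}"
        if direction is not None:
            regulated[key] = direction
        peptide_records.append(
            dict(
                sequence=seq,
                phospho_count=k,
                true_positions=list(true_pos),
                isomer_positions=list(alt_pos) if alt_pos else None,
                isomer_gap=isomer_gap,
                accession=peptide_parent[seq],
                n_scans=n_scans,
                scan_ids=scan_ids,
                abundance=abundance,
                channel_truth=truth.tolist(),
                regulated=direction,
            )
        )

    # -- decoy PSMs on their own spectra -------------------------------------
    n_target_psms = sum(1 for r in psm_rows if r["rank"] == 1)
    n_decoys = round(n_target_psms * config.decoy_fraction / (1.0 - config.decoy_fraction))
    decoy_proteins: list[ProteinRecord] = []
    unchosen = [p for p in candidates if p not in set(chosen)]
    for d in range(n_decoys):
        src = unchosen[int(rng_decoy.integers(0, len(unchosen)))] if unchosen else chosen[
            int(rng_decoy.integers(0, len(chosen)))
        ]
        dseq = src[::-1]
        acceptors = [i for i, aa in enumerate(dseq, start=1) if aa in _ACCEPTORS]
        dpos = (acceptors[0],) if acceptors else ()
        dmods = _standard_modifications(dseq, dpos)
        dmass = compute_peptide_mass(dseq, dmods)
        charge = int(rng_decoy.integers(2, 4))
        scan_id = new_scan_id()
        frag_mz, frag_int = _fragment_peaks(rng_decoy)
        spectra.append(
            Spectrum(
                scan_id=scan_id,
                title=f"scan={scan_id} decoy={d}",
                precursor_mz=(dmass + charge * PROTON_MASS) / charge,
                charge=charge,
                mz=frag_mz,
                intensity=frag_int,
            )
        )
        score = float(max(rng_decoy.normal(config.decoy_score_mean, config.decoy_score_sd), 0.01))
        acc = f"{config.decoy_prefix}SYND{d:04d}"
        psm_rows.append(
            dict(
                spectrum_ref=scan_id,
                sequence=dseq,
                modifications=format_modifications(dmods),
                score=round(score, 4),
                rank=1,
                is_decoy=1,
                accessions=acc,
                charge=charge,
            )
        )
        decoy_proteins.append(
            ProteinRecord(accession=acc, description="reversed decoy", sequence=dseq, is_decoy=True)
        )

    # -- reference run totals: loading bias only -----------------------------
    reference_totals = bias * 4.0e7

    # -- write artifacts ------------------------------------------------------
    import pandas as pd

    mgf_path = out_dir / "spectra.mgf"
    psm_path = out_dir / "psms.tsv"
    purity_path = out_dir / "purity.csv"
    fasta_path = out_dir / "proteins.fasta"
    gt_path = out_dir / "ground_truth.json"
    ref_path = out_dir / "reference_totals.csv"

    write_mgf(spectra, mgf_path)
    df = pd.DataFrame(psm_rows)
    df.to_csv(psm_path, sep="\t", index=False)
    write_purity_matrix(purity, purity_path)
    write_fasta(proteins + decoy_proteins, fasta_path)
    np.savetxt(ref_path, reference_totals.reshape(1, -1), delimiter=",", fmt="%.6f")

    ground_truth = GroundTruth(
        peptides=peptide_records,
        regulated=regulated,
        decoy_psm_count=n_decoys,
        target_psm_count=n_target_psms,
        group_map={int(c): g for c, g in config.group_map.items()},
        channel_bias=list(map(float, bias)),
        reference_totals=reference_totals.tolist(),
        config={
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    )
    ground_truth.to_json(gt_path)
    return SimulatedExperiment(
        mgf_path=mgf_path,
        psm_path=psm_path,
        purity_path=purity_path,
        fasta_path=fasta_path,
        ground_truth_path=gt_path,
        reference_totals=reference_totals,
        ground_truth=ground_truth,
    )
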