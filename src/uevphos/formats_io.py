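"""Readers and writers for every external format the pipeline touches.

MGF spectra, FASTA protein databases, PSM tables (TSV), the iTRAQ purity
matrix (CSV), and the pipeline config (YAML/JSON).  Parsing of MGF and FASTA
is delegated to :mod:`pyteomics`; this module adds strict validation on top:
readers never silently drop records, and structural errors are reported with
the offending line.

PSM table dialect (TSV with header, version ``psm-tsv-1``):

========================  =====================================================
column                    content
========================  =====================================================
``spectrum_ref``          scan id resolving into the companion MGF
``sequence``              peptide string, 20 canonical residues
``modifications``         semicolon-separated ``pos:residue:name`` terms;
                          ``pos`` is 1-based, 0 means the peptide N-terminus
``score``                 search-engine score (float)
``rank``                  hit rank, 1 = best
``is_decoy``              ``0``/``1``
``accessions``            comma-separated protein accessions
``charge``                precursor charge state
========================  =====================================================
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from pyteomics import fasta as _fasta
from pyteomics import mgf as _mgf

__all__ = [
    "Spectrum",
    "ProteinRecord",
    "MGFParseError",
    "ValidationError",
    "read_mgf",
    "write_mgf",
    "read_fasta",
    "write_fasta",
    "read_purity_matrix",
    "write_purity_matrix",
    "read_psm_table",
    "write_psm_table",
    "load_config",
    "PSM_TABLE_COLUMNS",
    "PSM_TABLE_VERSION",
]

PSM_TABLE_VERSION = "psm-tsv-1"
PSM_TABLE_COLUMNS = [
    "spectrum_ref",
    "sequence",
    "modifications",
    "score",
    "rank",
    "is_decoy",
    "accessions",
    "charge",
]

DEFAULT_DECOY_PREFIX = "REV_"


class MGFParseError(ValueError):
    """Raised for structurally invalid MGF input; names the offending line."""


class ValidationError(ValueError):
    """Raised when a parsed record violates its invariants."""


@dataclass
class Spectrum:
    """One MS/MS scan: precursor, charge, and a peak list.

    Peaks are kept as parallel numpy arrays sorted ascending by m/z;
    intensities are non-negative.  Unknown MGF headers survive a round trip
    in ``metadata``.
    """

    scan_id: str
    title: str
    precursor_mz: float
    charge: int
    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValidationError(
                f"spectrum {self.scan_id!r}: mz and intensity lengths differ"
            )
        if self.charge < 1:
            raise ValidationError(f"spectrum {self.scan_id!r}: charge must be >= 1")
        if np.any(self.intensity < 0):
            raise ValidationError(f"spectrum {self.scan_id!r}: negative intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass
class ProteinRecord:
    """A FASTA entry; decoy entries carry a reserved accession prefix."""

    accession: str
    description: str
    sequence: str
    is_decoy: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValidationError(f"protein {self.accession!r}: empty sequence")


def _structural_scan(path: Path) -> None:
    """Pre-scan an MGF file for unbalanced BEGIN IONS / END IONS blocks.

    pyteomics tolerates a truncated final block; the pipeline treats that as
    a hard error so that no spectrum is silently dropped.
    """
    open_line = 0
    in_block = False
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if stripped == "BEGIN IONS":
                if in_block:
                    raise MGFParseError(
                        f"{path}:{lineno}: BEGIN IONS inside an open block "
                        f"started at line {open_line}"
                    )
                in_block, open_line = True, lineno
            elif stripped == "END IONS":
                if not in_block:
                    raise MGFParseError(f"{path}:{lineno}: END IONS without BEGIN IONS")
                in_block = False
            elif in_block and stripped and "=" not in stripped:
                tokens = stripped.split()
                try:
                    [float(t) for t in tokens[:2]]
                except ValueError:
                    raise MGFParseError(
                        f"{path}:{lineno}: non-numeric peak line {stripped!r}"
                    ) from None
    if in_block:
        raise MGFParseError(
            f"{path}: unterminated BEGIN IONS block started at line {open_line}"
        )


_KNOWN_MGF_KEYS = {"title", "pepmass", "charge", "scans", "rtinseconds"}


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Parse an MGF file into a list of :class:`Spectrum`.

    The scan id is taken from the SCANS header when present, else from the
    TITLE.  Headers outside the standard set are preserved in ``metadata``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _structural_scan(path)
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            title = str(params.get("title", ""))
            scan_id = str(params.get("scans", title))
            pepmass = params.get("pepmass", (0.0,))
            charge_field = params.get("charge")
            if charge_field:
                charge = int(charge_field[0])
            else:
                charge = 1
            metadata = {
                k: v for k, v in params.items() if k not in _KNOWN_MGF_KEYS
            }
            spectra.append(
                Spectrum(
                    scan_id=scan_id,
                    title=title,
                    precursor_mz=float(pepmass[0]),
                    charge=charge,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    metadata=metadata,
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra in the common Mascot dialect.

    One ``BEGIN IONS``/``END IONS`` block per spectrum with TITLE, PEPMASS,
    CHARGE (``2+`` style) and SCANS headers, then ``mz intensity`` peak lines.
    Output is deterministic for a given input sequence.
    """
    path = Path(path)
    with open(path, "w") as out:
        for spec in spectra:
            out.write("BEGIN IONS\n")
            out.write(f"TITLE={spec.title}\n")
            out.write(f"PEPMASS={spec.precursor_mz:.6f}\n")
            out.write(f"CHARGE={spec.charge}+\n")
            out.write(f"SCANS={spec.scan_id}\n")
            for key, value in sorted(spec.metadata.items()):
                out.write(f"{key.upper()}={value}\n")
            for mz, inten in zip(spec.mz, spec.intensity):
                out.write(f"{mz:.6f} {inten:.6f}\n")
            out.write("END IONS\n")


def read_fasta(path: str | Path, decoy_prefix: str = DEFAULT_DECOY_PREFIX) -> list[ProteinRecord]:
    """Read a FASTA database, flagging decoy entries by accession prefix."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as handle:
        n_headers = sum(1 for line in handle if line.startswith(">"))
    records: list[ProteinRecord] = []
    with _fasta.FASTA(str(path)) as reader:
        for description, sequence in reader:
            accession = description.split()[0] if description.split() else ""
            rest = description[len(accession):].strip()
            seq = "".join(sequence.split()).upper()
            if not seq:
                raise ValidationError(f"protein {accession!r}: empty sequence")
            records.append(
                ProteinRecord(
                    accession=accession,
                    description=rest,
                    sequence=seq,
                    is_decoy=accession.startswith(decoy_prefix),
                )
            )
    if len(records) != n_headers:
        raise ValidationError(
            f"{path}: parsed {len(records)} records but found {n_headers} "
            f"headers (empty or malformed sequences are not dropped silently)"
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with open(path, "w") as out:
        for rec in records:
            header = rec.accession if not rec.description else f"{rec.accession} {rec.description}"
            out.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


def read_purity_matrix(path: str | Path):
    """Load and validate a 4x4 iTRAQ purity matrix from CSV.

    Entry (i, j) is the fraction of channel j's reagent signal observed in
    channel i.  The matrix must be non-negative, column sums at most 1 (small
    tolerance for rounding), and invertible.
    """
    from .quant import PurityMatrix

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    values = pd.read_csv(path, header=None).to_numpy(dtype=float)
    return PurityMatrix(values)


def write_purity_matrix(purity, path: str | Path) -> None:
    np.savetxt(path, np.asarray(purity.matrix), delimiter=",", fmt="%.6f")


def read_psm_table(path: str | Path, spectra: Sequence[Spectrum] | None = None) -> pd.DataFrame:
    """Read a PSM TSV table into a DataFrame, validating the dialect.

    When ``spectra`` is given, every ``spectrum_ref`` must resolve to a scan
    id in that collection.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"spectrum_ref": str, "sequence": str, "modifications": str, "accessions": str},
        keep_default_na=False,
    )
    missing = [c for c in PSM_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing PSM columns {missing}")
    df["score"] = df["score"].astype(float)
    df["rank"] = df["rank"].astype(int)
    df["charge"] = df["charge"].astype(int)
    df["is_decoy"] = df["is_decoy"].astype(int).astype(bool)
    if (df["rank"] < 1).any():
        raise ValidationError(f"{path}: PSM rank below 1")
    if spectra is not None:
        known = {s.scan_id for s in spectra}
        unresolved = set(df["spectrum_ref"]) - known
        if unresolved:
            raise ValidationError(
                f"{path}: {len(unresolved)} spectrum references do not resolve "
                f"(e.g. {sorted(unresolved)[:3]})"
            )
    return df


def write_psm_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["is_decoy"] = out["is_decoy"].astype(int)
    out.to_csv(path, sep="\t", index=False, columns=[c for c in PSM_TABLE_COLUMNS if c in out.columns])


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON pipeline config into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
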