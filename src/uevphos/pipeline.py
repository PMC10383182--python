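"""End-to-end orchestration: files in, result bundle out.

Stage order: read + validate -> charge/precursor check -> target-decoy FDR
filter -> collapse to unique phosphopeptides -> MD-score localization ->
reporter extraction / impurity correction / normalization -> per-peptide
aggregation and ratios -> error-model fit and differential calls ->
summaries.  Every intermediate is written as TSV/JSON under the output
directory together with a manifest (config hash, seed, versions) that makes
the run reproducible bit-for-bit on the same inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .formats_io import (
    load_config,
    read_mgf,
    read_psm_table,
    read_purity_matrix,
    write_psm_table,
)
from .ident_filter import (
    PSM,
    collapse_unique_phosphopeptides,
    filter_psms_by_fdr,
    parse_modifications,
    format_modifications,
    summarize_identifications,
    validate_precursor,
)
from .localization import SiteCandidate, localize
from .quant import (
    ChannelSet,
    ReporterQuant,
    aggregate_and_ratio,
    compute_normalization_factors,
    correct_impurities,
    extract_reporters,
)
from .stats_diff import (
    benjamini_hochberg,
    call_differential,
    fit_null,
    ratio_pvalue,
    summarize_differentials,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ResultBundle", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run, loadable from YAML/JSON."""

    mgf: Path
    psm_table: Path
    purity: Path
    output_dir: Path
    fasta: Path | None = None
    reference_totals: Path | None = None
    precursor_tol: float = 0.6
    fragment_tol: float = 0.1
    charge_range: tuple[int, int] = (2, 4)
    max_fdr: float = 0.01
    md_cutoff: float = 10.0
    fold_threshold: float = 1.5
    alpha: float = 0.05
    apply_bh: bool = False
    channel_labels: tuple[int, ...] = (114, 115, 116, 117)
    group_map: dict[int, str] = field(
        default_factory=lambda: {114: "NC", 115: "DM", 116: "DN", 117: "reference"}
    )
    comparisons: tuple[tuple[str, str], ...] = (("DN", "DM"), ("DN", "NC"), ("DM", "NC"))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("precursor_tol", "fragment_tol", "max_fdr", "md_cutoff", "fold_threshold", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        groups = set(self.group_map.values())
        for num, den in self.comparisons:
            if num not in groups or den not in groups:
                raise ValueError(f"comparison {num}/{den} references an undefined group")

    @classmethod
    def from_dict(cls, data: dict, base_dir: Path | None = None) -> "PipelineConfig":
        data = dict(data)
        paths = data.pop("paths", {})
        kwargs: dict = {}
        base = Path(base_dir) if base_dir else Path(".")

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        for key in ("mgf", "psm_table", "purity", "fasta", "reference_totals", "output_dir"):
            if key in paths and paths[key] is not None:
                kwargs[key] = resolve(paths[key])
        tol = data.pop("tolerances", {})
        if "precursor_da" in tol:
            kwargs["precursor_tol"] = float(tol["precursor_da"])
        if "fragment_da" in tol:
            kwargs["fragment_tol"] = float(tol["fragment_da"])
        if "charge_range" in data:
            kwargs["charge_range"] = tuple(data.pop("charge_range"))
        channels = data.pop("channels", {})
        if "labels" in channels:
            kwargs["channel_labels"] = tuple(int(c) for c in channels["labels"])
        if "group_map" in channels:
            kwargs["group_map"] = {int(c): g for c, g in channels["group_map"].items()}
        if "comparisons" in data:
            kwargs["comparisons"] = tuple((a, b) for a, b in data.pop("comparisons"))
        for key in ("max_fdr", "md_cutoff", "fold_threshold", "alpha", "apply_bh", "seed"):
            if key in data:
                kwargs[key] = data.pop(key)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        return cls.from_dict(load_config(path), base_dir=path.parent)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        canon = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    config: PipelineConfig
    identification_summary: dict
    differential_summary: dict
    null_models: dict
    peptides: list
    localizations: dict
    peptide_quants: dict
    differential_results: list
    output_dir: Path


def _psm_from_row(row) -> PSM:
    return PSM(
        spectrum_ref=str(row.spectrum_ref),
        sequence=row.sequence,
        modifications=parse_modifications(row.modifications),
        score=float(row.score),
        rank=int(row.rank),
        is_decoy=bool(row.is_decoy),
        accessions=tuple(str(row.accessions).split(",")) if row.accessions else (),
        charge=int(row.charge),
    )


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Execute every stage on the configured inputs and write all outputs."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # ---- stage 1: read and validate inputs ---------------------------------
    logger.info("reading inputs")
    spectra = read_mgf(config.mgf)
    spectrum_by_id = {s.scan_id: s for s in spectra}
    psm_df = read_psm_table(config.psm_table, spectra)
    purity = read_purity_matrix(config.purity)
    channels = ChannelSet(labels=config.channel_labels, group_map=dict(config.group_map))
    logger.info("read %d spectra, %d PSM rows", len(spectra), len(psm_df))

    psms = [_psm_from_row(row) for row in psm_df.itertuples(index=False)]

    # ---- stage 2: precursor/charge validation ------------------------------
    validated: list[PSM] = []
    n_rejected = 0
    for psm in psms:
        spec = spectrum_by_id[psm.spectrum_ref]
        ok, err = validate_precursor(
            psm, spec.precursor_mz, tol=config.precursor_tol, charge_range=config.charge_range
        )
        psm.precursor_error = err
        if ok:
            validated.append(psm)
        else:
            n_rejected += 1
    logger.info("precursor/charge validation: %d kept, %d rejected", len(validated), n_rejected)

    # ---- stage 3: FDR filter ------------------------------------------------
    retained, cutoff, achieved_fdr = filter_psms_by_fdr(validated, config.max_fdr)
    logger.info(
        "FDR filter at %.3g: cutoff %.3f, achieved FDR %.4f, %d PSMs retained",
        config.max_fdr, cutoff, achieved_fdr, len(retained),
    )
    filtered_df = pd.DataFrame(
        dict(
            spectrum_ref=p.spectrum_ref,
            sequence=p.sequence,
            modifications=format_modifications(p.modifications),
            score=p.score,
            rank=p.rank,
            is_decoy=p.is_decoy,
            accessions=",".join(p.accessions),
            charge=p.charge,
        )
        for p in retained
    )
    if not filtered_df.empty:
        write_psm_table(filtered_df, out_dir / "psms_filtered.tsv")
    else:
        logger.warning("no PSMs survive the FDR filter")
        (out_dir / "psms_filtered.tsv").write_text(
            "spectrum_ref\tsequence\tmodifications\tscore\trank\tis_decoy\taccessions\tcharge\n"
        )

    # ---- stage 4: collapse to unique phosphopeptides ------------------------
    peptides = collapse_unique_phosphopeptides(retained)
    logger.info("%d unique phosphopeptides", len(peptides))
    protein_map = {
        p.key: (p.member_psms[0].accessions[0] if p.member_psms[0].accessions else "")
        for p in peptides
    }

    # ---- stage 5: MD-score localization -------------------------------------
    # competitor hits come from the full validated table (any rank), matched
    # on the best member spectrum of each peptide
    by_spectrum: dict[str, list[PSM]] = {}
    for psm in validated:
        by_spectrum.setdefault(psm.spectrum_ref, []).append(psm)
    localizations = {}
    for pep in peptides:
        best_psm = pep.member_psms[0]  # members sorted by score desc
        siblings = [
            q
            for q in by_spectrum.get(best_psm.spectrum_ref, [])
            if q.sequence == pep.sequence and q.phospho_count == pep.phospho_count
        ]
        candidates = sorted(
            (SiteCandidate(q.phospho_positions, q.score, q.rank) for q in siblings),
            key=lambda c: -c.score,
        )
        localizations[pep.key] = localize(candidates, cutoff=config.md_cutoff, peptide_key=pep.key)
    n_confident = sum(1 for l in localizations.values() if l.is_localized)
    logger.info("localization: %d/%d localized at MD cutoff %g", n_confident, len(peptides), config.md_cutoff)
    loc_df = pd.DataFrame(
        dict(
            sequence=key[0],
            phospho_count=key[1],
            positions=";".join(map(str, sorted(loc.best.positions))),
            md_score="" if loc.md_score is None else round(loc.md_score, 4),
            status=loc.status,
        )
        for key, loc in sorted(localizations.items())
    )
    loc_df.to_csv(out_dir / "localization.tsv", sep="\t", index=False)

    # ---- stage 6: reporter extraction, correction, normalization ------------
    scan_quants: dict[str, ReporterQuant] = {}
    for pep in peptides:
        for psm in pep.member_psms:
            if psm.spectrum_ref in scan_quants:
                continue
            spec = spectrum_by_id[psm.spectrum_ref]
            raw = extract_reporters(spec.mz, spec.intensity, channels, tol=config.fragment_tol)
            rq = ReporterQuant(scan_id=psm.spectrum_ref, raw=raw)
            rq.corrected = correct_impurities(raw, purity)
            scan_quants[psm.spectrum_ref] = rq
    if config.reference_totals is not None:
        totals = np.loadtxt(config.reference_totals, delimiter=",").reshape(-1)
        factors = compute_normalization_factors(totals, source=str(config.reference_totals))
    else:
        # documented fallback: normalize on the phosphopeptide data itself
        totals = np.sum([rq.corrected for rq in scan_quants.values()], axis=0)
        factors = compute_normalization_factors(totals, source="self")
    for rq in scan_quants.values():
        rq.normalized = factors.apply(rq.corrected)
    logger.info("normalization factors (%s): %s", factors.source, np.round(factors.factors, 4))
    scan_df = pd.DataFrame(
        dict(
            scan_id=rq.scan_id,
            **{f"raw_{c}": rq.raw[i] for i, c in enumerate(channels.labels)},
            **{f"corrected_{c}": rq.corrected[i] for i, c in enumerate(channels.labels)},
            **{f"normalized_{c}": rq.normalized[i] for i, c in enumerate(channels.labels)},
        )
        for rq in sorted(scan_quants.values(), key=lambda r: r.scan_id)
    )
    scan_df.to_csv(out_dir / "scan_quant.tsv", sep="\t", index=False, float_format="%.6f")

    # ---- stage 7: per-peptide aggregation and ratios -------------------------
    peptide_quants = {}
    for pep in peptides:
        scans = [scan_quants[p.spectrum_ref] for p in pep.member_psms]
        # a peptide's scans are unique spectra; duplicates guarded upstream
        seen, uniq = set(), []
        for s in scans:
            if s.scan_id not in seen:
                seen.add(s.scan_id)
                uniq.append(s)
        peptide_quants[pep.key] = aggregate_and_ratio(
            uniq, channels, config.comparisons, peptide_key=pep.key
        )

    # ---- stage 8: error model and differential calls -------------------------
    null_models = {}
    differential_results = []
    pvalues_by_cmp: dict[str, dict] = {}
    for num, den in config.comparisons:
        label = f"{num}/{den}"
        ratios = {
            key: q.log2_ratios[label]
            for key, q in peptide_quants.items()
            if label in q.log2_ratios and np.isfinite(q.log2_ratios[label])
        }
        if len(ratios) < 10:
            logger.warning("comparison %s: only %d ratios, skipping statistics", label, len(ratios))
            continue
        null = fit_null(ratios.values())
        null_models[label] = null
        pvals = {key: ratio_pvalue(r, null) for key, r in ratios.items()}
        if config.apply_bh:
            keys = list(pvals)
            adjusted = benjamini_hochberg([pvals[k] for k in keys])
            pvals = dict(zip(keys, adjusted))
        pvalues_by_cmp[label] = pvals
        for key, p in pvals.items():
            differential_results.append(
                call_differential(
                    key,
                    label,
                    peptide_quants[key].ratios[label],
                    p,
                    fold_threshold=config.fold_threshold,
                    alpha=config.alpha,
                )
            )

    for num, den in config.comparisons:
        label = f"{num}/{den}"
        rows = [r for r in differential_results if r.comparison == label]
        if not rows:
            continue
        diff_df = pd.DataFrame(
            dict(
                sequence=r.peptide_key[0],
                phospho_count=r.peptide_key[1],
                accession=protein_map.get(r.peptide_key, ""),
                fold_change=round(r.fold_change, 6),
                log2_fold=round(np.log2(r.fold_change), 6),
                p_value=r.p_value,
                status=r.status,
            )
            for r in sorted(rows, key=lambda r: r.peptide_key)
        )
        safe = label.replace("/", "_vs_")
        diff_df.to_csv(out_dir / f"differential_{safe}.tsv", sep="\t", index=False)

    # ---- stage 9: summaries and manifest --------------------------------------
    presence = {}
    groups = sorted({g for g in config.group_map.values() if g != "reference"})
    for key, q in peptide_quants.items():
        present = set()
        for g in groups:
            idx = channels.channels_for_group(g)
            if q.channel_sums[idx].sum() > 0:
                present.add(g)
        presence[key] = present
    ident_summary = summarize_identifications(
        peptides, localizations, protein_map, presence, groups=tuple(groups)
    ).as_dict()
    diff_summary = summarize_differentials(differential_results, protein_map)
    pep_df = pd.DataFrame(
        dict(
            sequence=key[0],
            phospho_count=key[1],
            accession=protein_map.get(key, ""),
            n_scans=q.n_scans,
            **{f"sum_{c}": q.channel_sums[i] for i, c in enumerate(channels.labels)},
            **{
                f"ratio_{label.replace('/', '_')}": q.ratios.get(label, np.nan)
                for label in (f"{a}/{b}" for a, b in config.comparisons)
            },
        )
        for key, q in sorted(peptide_quants.items())
    )
    pep_df.to_csv(out_dir / "peptide_quant.tsv", sep="\t", index=False, float_format="%.6f")
    with open(out_dir / "identification_summary.json", "w") as out:
        json.dump(ident_summary, out, indent=1, sort_keys=True)
    with open(out_dir / "differential_summary.json", "w") as out:
        json.dump(diff_summary, out, indent=1, sort_keys=True)
    manifest = {
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "fdr_cutoff": cutoff,
        "achieved_fdr": achieved_fdr,
        "n_spectra": len(spectra),
        "n_psms_in": len(psms),
        "n_psms_validated": len(validated),
        "n_psms_retained": len(retained),
        "n_phosphopeptides": len(peptides),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(out_dir / "manifest.json", "w") as out:
        json.dump(manifest, out, indent=1, sort_keys=True)

    # headline summary for eyeball comparison with the study's reporting
    logger.info(
        "headline: %d phosphopeptides, %d sites (pS/pT/pY %% = %s), differential: %s",
        ident_summary["n_phosphopeptides"],
        ident_summary["n_sites"],
        ident_summary["residue_percent"],
        {k: (v["n_up"], v["n_down"]) for k, v in diff_summary["comparisons"].items()},
    )
    return ResultBundle(
        config=config,
        identification_summary=ident_summary,
        differential_summary=diff_summary,
        null_models=null_models,
        peptides=peptides,
        localizations=localizations,
        peptide_quants=peptide_quants,
        differential_results=differential_results,
        output_dir=out_dir,
    )
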