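"""Mass bookkeeping, target-decoy FDR filtering, and phosphopeptide
collapsing."""

import math

import numpy as np
import pytest
from pyteomics import mass as pmass

from uevphos.ident_filter import (
    MOD_DELTAS,
    NOMINAL_MOD_DELTAS,
    PROTON_MASS,
    WATER_MASS,
    Modification,
    PSM,
    collapse_unique_phosphopeptides,
    compute_peptide_mass,
    filter_psms_by_fdr,
    parse_modifications,
    format_modifications,
    percent_in_all_groups,
    residue_distribution,
    validate_precursor,
)


def _psm(sequence="AKSPR", mods=(), score=40.0, rank=1, decoy=False, ref="s1", charge=2):
    return PSM(
        spectrum_ref=ref,
        sequence=sequence,
        modifications=mods,
        score=score,
        rank=rank,
        is_decoy=decoy,
        accessions=("P1",),
        charge=charge,
    )


class TestPeptideMass:
    def test_unmodified_mass_matches_residue_table_sum(self):
        # independent hand-sum from the published monoisotopic residue table
        expected = pmass.std_aa_mass["A"] + pmass.std_aa_mass["G"] + 18.010565
        assert compute_peptide_mass("AG") == pytest.approx(expected, abs=1e-5)

    def test_phospho_additivity(self):
        mods = (Modification("phospho", "S", 3),)
        delta = compute_peptide_mass("AKSPR", mods) - compute_peptide_mass("AKSPR")
        assert delta == pytest.approx(MOD_DELTAS["phospho"], abs=1e-12)

    def test_fixed_labels_hand_sum(self):
        # carbamidomethyl on C plus iTRAQ on the N-terminus and on K
        mods = (
            Modification("carbamidomethyl", "C", 2),
            Modification("itraq4plex", "N-term", 0),
            Modification("itraq4plex", "K", 3),
        )
        base = sum(pmass.std_aa_mass[a] for a in "ACK") + WATER_MASS
        expected = base + 57.02146 + 2 * 144.10207
        assert compute_peptide_mass("ACK", mods) == pytest.approx(expected, abs=1e-4)

    def test_unknown_residue_and_disallowed_site_rejected(self):
        with pytest.raises(ValueError, match="unknown residue"):
            compute_peptide_mass("AXZ")
        with pytest.raises(ValueError, match="not allowed"):
            Modification("phospho", "A", 1)

    def test_nominal_deltas_accepted_via_override(self):
        mods = (Modification("phospho", "S", 3),)
        m = compute_peptide_mass("AKSPR", mods, mod_deltas=NOMINAL_MOD_DELTAS)
        assert m - compute_peptide_mass("AKSPR") == pytest.approx(80.0)

    def test_modification_string_round_trip(self):
        mods = parse_modifications("0:N-term:itraq4plex;3:S:phospho;5:K:itraq4plex")
        assert parse_modifications(format_modifications(mods)) == mods


class TestPrecursorValidation:
    def test_exact_match_passes_with_zero_error(self):
        psm = _psm()
        mass = compute_peptide_mass(psm.sequence)
        mz = (mass + 2 * PROTON_MASS) / 2
        ok, err = validate_precursor(psm, mz)
        assert ok and err == pytest.approx(0.0, abs=1e-9)

    def test_one_dalton_off_fails(self):
        psm = _psm()
        mass = compute_peptide_mass(psm.sequence) + 1.0
        mz = (mass + 2 * PROTON_MASS) / 2
        ok, err = validate_precursor(psm, mz)
        assert not ok and err == pytest.approx(1.0, abs=1e-9)

    def test_charge_outside_acquired_range_flagged(self):
        psm = _psm(charge=5)
        mass = compute_peptide_mass(psm.sequence)
        mz = (mass + 5 * PROTON_MASS) / 5
        ok, _ = validate_precursor(psm, mz)
        assert not ok

    def test_constructed_errors_split_exactly_at_tolerance(self, rng):
        # 200 PSMs with uniform error in [-0.6, 0.6] all pass, shifted into
        # (0.6, 1.2] all fail
        for offset, expect in ((0.0, True), (0.6, False)):
            for _ in range(100):
                sign = 1 if rng.random() < 0.5 else -1
                err = sign * (rng.uniform(1e-6, 0.6) + offset)
                psm = _psm(charge=3)
                mass = compute_peptide_mass(psm.sequence) + err
                mz = (mass + 3 * PROTON_MASS) / 3
                ok, _ = validate_precursor(psm, mz)
                assert ok is expect


def brute_force_fdr(psms, max_fdr):
    """Independent oracle: exhaustive scan over every candidate cutoff."""
    rank1 = [p for p in psms if p.rank == 1]
    best = None
    for cand in sorted({p.score for p in rank1}):
        targets = sum(1 for p in rank1 if not p.is_decoy and p.score >= cand)
        decoys = sum(1 for p in rank1 if p.is_decoy and p.score >= cand)
        if targets > 0 and decoys / targets <= max_fdr:
            best = cand
            break  # lowest qualifying score
    if best is None:
        return [], math.inf
    return [p for p in rank1 if not p.is_decoy and p.score >= best], best


class TestFDRFilter:
    def test_no_decoys_retains_everything(self):
        psms = [_psm(score=s, ref=f"s{i}") for i, s in enumerate((10, 20, 30))]
        retained, cutoff, fdr = filter_psms_by_fdr(psms)
        assert len(retained) == 3 and fdr == 0.0

    def test_all_decoys_retains_nothing(self):
        psms = [_psm(score=s, decoy=True, ref=f"s{i}") for i, s in enumerate((10, 20, 30))]
        retained, cutoff, _ = filter_psms_by_fdr(psms)
        assert retained == [] and cutoff == math.inf

    def test_decoys_never_retained(self, rng):
        psms = [
            _psm(score=float(rng.normal(30, 10)), decoy=bool(rng.random() < 0.3), ref=f"s{i}")
            for i in range(500)
        ]
        retained, _, _ = filter_psms_by_fdr(psms, 0.05)
        assert all(not p.is_decoy for p in retained)

    def test_rank2_hits_ignored(self):
        psms = [_psm(score=50.0, ref="a"), _psm(score=45.0, rank=2, ref="a")]
        retained, _, _ = filter_psms_by_fdr(psms)
        assert len(retained) == 1 and retained[0].rank == 1

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        n_t, n_d = int(rng.integers(20, 500)), int(rng.integers(5, 50))
        psms = [
            _psm(score=float(max(rng.normal(40, 8), 0.0)), ref=f"t{i}") for i in range(n_t)
        ] + [
            _psm(score=float(max(rng.normal(20, 6), 0.0)), decoy=True, ref=f"d{i}")
            for i in range(n_d)
        ]
        retained, cutoff, _ = filter_psms_by_fdr(psms, 0.01)
        oracle, oracle_cutoff = brute_force_fdr(psms, 0.01)
        assert {p.spectrum_ref for p in retained} == {p.spectrum_ref for p in oracle}
        assert cutoff == pytest.approx(oracle_cutoff)

    def test_tied_scores_resolved_conservatively(self):
        # a decoy tied at the cutoff score counts against that cutoff
        psms = [_psm(score=10.0, ref=f"t{i}") for i in range(50)] + [
            _psm(score=10.0, decoy=True, ref="d0")
        ]
        retained, _, fdr = filter_psms_by_fdr(psms, max_fdr=0.01)
        assert retained == []  # 1/50 = 2% > 1%
        psms_ok = [_psm(score=10.0, ref=f"t{i}") for i in range(200)] + [
            _psm(score=10.0, decoy=True, ref="d0")
        ]
        retained, _, fdr = filter_psms_by_fdr(psms_ok, max_fdr=0.01)
        assert len(retained) == 200 and fdr == pytest.approx(1 / 200)


def _phospho_psm(seq, positions, ref, score=40.0):
    mods = tuple(Modification("phospho", seq[p - 1], p) for p in positions)
    return _psm(sequence=seq, mods=mods, score=score, ref=ref)


class TestCollapse:
    def test_positional_isomers_counted_once(self):
        psms = [
            _phospho_psm("AKSPSPR", (3,), "s1"),
            _phospho_psm("AKSPSPR", (5,), "s2"),
        ]
        peptides = collapse_unique_phosphopeptides(psms)
        assert len(peptides) == 1
        assert len(peptides[0].member_psms) == 2
        assert sorted(map(sorted, peptides[0].site_candidates)) == [[3], [5]]

    def test_different_phospho_counts_enumerated_separately(self):
        psms = [
            _phospho_psm("AKSPSPR", (3,), "s1"),
            _phospho_psm("AKSPSPR", (3, 5), "s2"),
        ]
        peptides = collapse_unique_phosphopeptides(psms)
        assert [(p.sequence, p.phospho_count) for p in peptides] == [
            ("AKSPSPR", 1),
            ("AKSPSPR", 2),
        ]

    def test_empty_input(self):
        assert collapse_unique_phosphopeptides([]) == []

    def test_non_phospho_psms_excluded(self):
        psms = [_psm(ref="s1"), _phospho_psm("AKSPSPR", (3,), "s2")]
        peptides = collapse_unique_phosphopeptides(psms)
        assert len(peptides) == 1
        assert sum(len(p.member_psms) for p in peptides) == 1

    def test_permutation_invariant_and_idempotent(self, rng):
        psms = [
            _phospho_psm("AKSPSPR", (3,), "s1", 10.0),
            _phospho_psm("AKSPSPR", (5,), "s2", 20.0),
            _phospho_psm("TTYK", (3,), "s3", 30.0),
            _phospho_psm("TTYK", (1,), "s4", 15.0),
            _phospho_psm("TTYK", (1, 3), "s5", 25.0),
        ]
        base = collapse_unique_phosphopeptides(psms)
        for _ in range(5):
            perm = list(psms)
            rng.shuffle(perm)
            again = collapse_unique_phosphopeptides(perm)
            assert [(p.key, len(p.member_psms)) for p in again] == [
                (p.key, len(p.member_psms)) for p in base
            ]
        # member totals conserve the phospho-bearing input PSMs
        assert sum(len(p.member_psms) for p in base) == len(psms)


class TestSummaries:
    def test_residue_distribution_printed_precision(self):
        total, percents = residue_distribution({"S": 179, "T": 101, "Y": 12})
        assert total == 292
        assert percents == {"S": 61.3, "T": 34.6, "Y": 4.11}
        assert sum(percents.values()) == pytest.approx(100.0, abs=0.1)

    def test_single_serine_site(self):
        total, percents = residue_distribution({"S": 1})
        assert total == 1 and percents == {"S": 100.0, "T": 0.0, "Y": 0.0}

    def test_percent_in_all_groups(self):
        assert percent_in_all_groups(31, 214) == 14.49
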