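"""I/O round trips and strict validation of the external formats."""

import numpy as np
import pytest

from uevphos.formats_io import (
    MGFParseError,
    ProteinRecord,
    Spectrum,
    ValidationError,
    read_fasta,
    read_mgf,
    read_psm_table,
    read_purity_matrix,
    write_fasta,
    write_mgf,
    write_psm_table,
)


def _random_spectra(rng, n):
    out = []
    for i in range(n):
        k = int(rng.integers(1, 30))
        out.append(
            Spectrum(
                scan_id=f"{i:05d}",
                title=f"scan {i}",
                precursor_mz=float(rng.uniform(300, 1500)),
                charge=int(rng.integers(1, 5)),
                mz=np.sort(rng.uniform(100, 2000, k)),
                intensity=rng.uniform(0, 1e6, k),
            )
        )
    return out


class TestMGF:
    def test_empty_file_yields_no_spectra(self, tmp_path):
        path = tmp_path / "empty.mgf"
        path.write_text("")
        assert read_mgf(path) == []

    def test_two_blocks_parsed_with_peak_counts(self, tmp_path):
        path = tmp_path / "two.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=a\nPEPMASS=500.25\nCHARGE=2+\n"
            "114.11 10\n115.11 20\nEND IONS\n"
            "BEGIN IONS\nTITLE=b\nPEPMASS=600.5\nCHARGE=3+\n"
            "200.0 5\nEND IONS\n"
        )
        spectra = read_mgf(path)
        assert [s.n_peaks for s in spectra] == [2, 1]
        assert spectra[0].charge == 2
        assert spectra[1].precursor_mz == pytest.approx(600.5)

    def test_round_trip_preserves_peaks(self, tmp_path, rng):
        spectra = _random_spectra(rng, 50)
        path = tmp_path / "rt.mgf"
        write_mgf(spectra, path)
        back = read_mgf(path)
        assert len(back) == 50
        for orig, parsed in zip(spectra, back):
            assert parsed.scan_id == orig.scan_id
            assert parsed.charge == orig.charge
            np.testing.assert_allclose(parsed.mz, orig.mz, rtol=1e-6)
            np.testing.assert_allclose(parsed.intensity, orig.intensity, rtol=1e-6)

    def test_unterminated_block_is_an_error_naming_the_line(self, tmp_path):
        path = tmp_path / "bad.mgf"
        path.write_text("BEGIN IONS\nTITLE=x\nPEPMASS=500\n100.0 1\n")
        with pytest.raises(MGFParseError, match="line 1"):
            read_mgf(path)

    def test_non_numeric_peak_is_an_error(self, tmp_path):
        path = tmp_path / "bad2.mgf"
        path.write_text("BEGIN IONS\nTITLE=x\nPEPMASS=500\nabc def\nEND IONS\n")
        with pytest.raises(MGFParseError, match="non-numeric"):
            read_mgf(path)

    def test_spectrum_invariants_enforced(self):
        with pytest.raises(ValidationError):
            Spectrum("1", "t", 500.0, 0, np.array([1.0]), np.array([1.0]))
        with pytest.raises(ValidationError):
            Spectrum("1", "t", 500.0, 2, np.array([1.0]), np.array([-1.0]))
        s = Spectrum("1", "t", 500.0, 2, np.array([300.0, 100.0]), np.array([1.0, 2.0]))
        assert list(s.mz) == [100.0, 300.0]  # sorted on construction


class TestFASTA:
    def test_decoy_prefix_flags(self, tmp_path):
        path = tmp_path / "db.fasta"
        path.write_text(">P1 real protein\nMKTAYR\n>REV_P1 reversed\nRYATKM\n")
        records = read_fasta(path)
        assert [r.is_decoy for r in records] == [False, True]

    def test_lowercase_sequence_stored_uppercase(self, tmp_path):
        path = tmp_path / "lc.fasta"
        path.write_text(">P1\nmktayr\n")
        assert read_fasta(path)[0].sequence == "MKTAYR"

    def test_round_trip_100_records(self, tmp_path, rng):
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        records = [
            ProteinRecord(
                accession=f"ACC{i:03d}",
                description=f"protein {i}",
                sequence="".join(rng.choice(letters, size=int(rng.integers(10, 200)))),
            )
            for i in range(100)
        ]
        path = tmp_path / "rt.fasta"
        write_fasta(records, path)
        back = read_fasta(path)
        assert [(r.accession, r.description, r.sequence) for r in back] == [
            (r.accession, r.description, r.sequence) for r in records
        ]

    def test_empty_sequence_rejected(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">P1 empty\n\n>P2\nMK\n")
        with pytest.raises(ValidationError):
            read_fasta(path)


class TestPurityMatrix:
    def test_identity_accepted(self, tmp_path):
        path = tmp_path / "id.csv"
        np.savetxt(path, np.eye(4), delimiter=",")
        purity = read_purity_matrix(path)
        np.testing.assert_allclose(purity.matrix, np.eye(4))

    def test_negative_entry_rejected(self, tmp_path):
        m = np.eye(4)
        m[0, 1] = -0.01
        path = tmp_path / "neg.csv"
        np.savetxt(path, m, delimiter=",")
        with pytest.raises(ValueError, match="negative"):
            read_purity_matrix(path)

    def test_neighbour_bleed_matrix_accepted_and_invertible(self, tmp_path):
        b = 0.02
        m = np.zeros((4, 4))
        for j in range(4):
            m[j, j] = 1 - 2 * b
            if j > 0:
                m[j - 1, j] = b
            if j < 3:
                m[j + 1, j] = b
        path = tmp_path / "bleed.csv"
        np.savetxt(path, m, delimiter=",")
        purity = read_purity_matrix(path)
        assert abs(np.linalg.det(purity.matrix)) > 1e-6

    def test_wrong_shape_rejected(self, tmp_path):
        path = tmp_path / "shape.csv"
        np.savetxt(path, np.eye(3), delimiter=",")
        with pytest.raises(ValueError, match="4x4"):
            read_purity_matrix(path)


class TestPSMTable:
    def test_round_trip_and_validation(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {
                "spectrum_ref": ["000001", "000002"],
                "sequence": ["AKSPR", "TESTK"],
                "modifications": ["0:N-term:itraq4plex;3:S:phospho", ""],
                "score": [42.5, 18.0],
                "rank": [1, 1],
                "is_decoy": [False, True],
                "accessions": ["P1", "REV_P2"],
                "charge": [2, 3],
            }
        )
        path = tmp_path / "psms.tsv"
        write_psm_table(df, path)
        back = read_psm_table(path)
        assert list(back["sequence"]) == ["AKSPR", "TESTK"]
        assert back["is_decoy"].tolist() == [False, True]

    def test_unresolved_spectrum_reference_rejected(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {
                "spectrum_ref": ["missing"],
                "sequence": ["AK"],
                "modifications": [""],
                "score": [1.0],
                "rank": [1],
                "is_decoy": [False],
                "accessions": ["P1"],
                "charge": [2],
            }
        )
        path = tmp_path / "psms.tsv"
        write_psm_table(df, path)
        spectra = [
            Spectrum("other", "t", 500.0, 2, np.array([100.0]), np.array([1.0]))
        ]
        with pytest.raises(ValidationError, match="do not resolve"):
            read_psm_table(path, spectra)
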