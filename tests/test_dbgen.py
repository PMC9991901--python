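"""Search-space construction: digestion, subtraction, SAAA/fusion, pI."""
import itertools

import numpy as np
import pandas as pd
import pytest

from proteorelapse import dbgen
from proteorelapse.dbgen import (
    CanonicalIndex,
    assign_hirief_fraction,
    build_novel_db,
    digest_tryptic,
    filter_expressed,
    generate_decoys,
    make_fusion_peptides,
    make_saaa_peptides,
    peptide_charge,
    predict_pi,
    PeptideRecord,
)
from proteorelapse.models import TranscriptModel, VariantRecord, translate_nt


class TestExpressionFilter:
    def test_tpm_exactly_one_excluded(self):
        expr = pd.Series({"t1": 1.0, "t2": 1.0000001, "t3": 5.0, "t4": 0.2})
        assert filter_expressed(expr) == {"t2", "t3"}

    def test_empty_table(self):
        assert filter_expressed(pd.Series(dtype=float)) == set()

    def test_missing_tpm_names_transcript(self):
        with pytest.raises(ValueError, match="t9"):
            filter_expressed(pd.Series({"t9": np.nan}))


class TestDigestion:
    def test_no_cleavage_sites(self):
        assert digest_tryptic("AAAAAAA", max_missed=2) == [("AAAAAAA", 0)]

    def test_kp_not_cleaved(self):
        assert digest_tryptic("AAAKPAAAAAA", max_missed=0) == [("AAAKPAAAAAA", 0)]

    def test_length_bounds(self):
        peps = [p for p, _ in digest_tryptic("AAARCCCCCCK" + "D" * 50, max_missed=2)]
        assert all(7 <= len(p) <= 40 for p in peps)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_cleavage_subset_oracle(self, seed):
        """Union over all cleavage-site subsets of fragments bounded by chosen
        sites with <= max_missed unchosen internal sites."""
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        max_missed = 2
        sites = [
            i + 1 for i in range(len(seq) - 1) if seq[i] in "KR" and seq[i + 1] != "P"
        ]
        oracle = set()
        for r in range(len(sites) + 1):
            for chosen in itertools.combinations(sites, r):
                bounds = [0, *chosen, len(seq)]
                for a, b in zip(bounds[:-1], bounds[1:]):
                    internal = sum(1 for s in sites if a < s < b)
                    if internal <= max_missed and 7 <= b - a <= 40:
                        oracle.add((seq[a:b], a))
        assert set(digest_tryptic(seq, max_missed=max_missed)) == oracle

    def test_cross_check_against_pyteomics(self):
        pyteomics_parser = pytest.importorskip("pyteomics.parser")
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))
        ours = {p for p, _ in digest_tryptic(seq, max_missed=2, min_len=1, max_len=1000)}
        theirs = pyteomics_parser.cleave(seq, pyteomics_parser.expasy_rules["trypsin"], 2)
        assert ours == set(theirs)


class TestNovelDb:
    def _fixture(self):
        transcripts = {
            "t1": "ATG" + "GCT" * 30,  # translates to M + A*30 in frame 0
        }
        expr = pd.Series({"t1": 10.0})
        return transcripts, expr

    def test_canonical_peptide_excluded(self):
        transcripts, expr = self._fixture()
        frame0 = translate_nt(transcripts["t1"])
        canonical = {"p1": frame0}
        recs = build_novel_db(transcripts, expr, canonical)
        assert all(r.frame != 0 for r in recs)

    def test_il_collapsed_match_excluded(self):
        transcripts = {"t1": "AAAATTCTGGATGAGGCCTTCGAT" * 3}
        expr = pd.Series({"t1": 10.0})
        no_sub = build_novel_db(transcripts, expr, {})
        assert no_sub
        pep = no_sub[0].sequence
        swapped = pep.replace("L", "#").replace("I", "L").replace("#", "I")
        subtracted = build_novel_db(transcripts, expr, {"p": "GGG" + swapped + "GGG"})
        assert pep not in {r.sequence for r in subtracted}

    def test_unexpressed_transcript_contributes_nothing(self):
        transcripts, _ = self._fixture()
        recs = build_novel_db(transcripts, pd.Series({"t1": 0.5}), {})
        assert recs == []

    def test_records_are_reachable_from_provenance(self, cohort):
        """Re-translating the source transcript at the recorded frame/offset
        reproduces every sampled novel-candidate sequence."""
        peps = cohort.peptides
        novel = peps[peps["pep_class"] == "novel_candidate"].sample(
            n=min(200, len(peps)), random_state=0
        )
        for row in novel.itertuples():
            seq = cohort.reference.transcripts[row.transcript_id]
            frame_aa = translate_nt(seq[row.frame :])
            assert frame_aa[row.offset : row.offset + len(row.sequence)] == row.sequence

    def test_no_db_entry_collides_with_canonical(self, cohort):
        index = CanonicalIndex(cohort.reference.canonical)
        peps = cohort.peptides
        for cls in ("novel_candidate", "saaa", "fusion"):
            sub = peps.loc[peps["pep_class"] == cls, "sequence"]
            assert not any(s in index for s in sub)


class TestSaaa:
    def _micro(self):
        # CDS: ATG CGT AAA GAA ... -> protein M R K E...; SNV at codon 2 pos 2
        cds = "ATG" + "CGT" + "AAAGAATTTGGGCATCTGAAA" + "GCC" * 10
        transcripts = {"t1": cds}
        model = TranscriptModel("t1", "g1", "chr1", "+", exons=[(0, len(cds))])
        return transcripts, {"t1": model}, cds

    def test_missense_creates_substituted_peptide(self):
        transcripts, models, cds = self._micro()
        # CGT (R) -> CAT (H): genomic pos of codon-2 base 2 is index 4 -> 1-based 5
        var = VariantRecord("chr1", 5, "G", "A", transcript_id="t1")
        recs = make_saaa_peptides([var], transcripts, models, {"p": translate_nt(cds)})
        frame0 = [r for r in recs if r.frame == 0]
        assert frame0
        pep = frame0[0]
        assert pep.sequence.startswith("MHK")
        assert pep.sub_pos == 2
        assert pep.pep_class == "saaa"

    def test_synonymous_yields_nothing_in_coding_frame(self):
        transcripts, models, cds = self._micro()
        # CGT -> CGA: both arginine
        var = VariantRecord("chr1", 6, "T", "A", transcript_id="t1")
        recs = make_saaa_peptides([var], transcripts, models, {"p": translate_nt(cds)})
        assert all(r.frame != 0 for r in recs)

    def test_variant_outside_transcript_skipped(self):
        transcripts, models, _ = self._micro()
        var = VariantRecord("chr1", 5000, "A", "T", transcript_id=None)
        assert make_saaa_peptides([var], transcripts, models, {}) == []

    def test_every_truth_missense_yields_a_saaa_peptide(self, cohort):
        """Each planted missense SNV in an expressed transcript produces >=1
        database SAAA peptide of tryptic length."""
        truth = cohort.variant_truth
        missense = truth[truth["consequence"] == "missense"]
        saaa = cohort.peptides[cohort.peptides["pep_class"] == "saaa"]
        expr = cohort.reference.expression_series
        for row in missense.itertuples():
            if expr[row.transcript_id] <= 1.0:
                continue
            sub = saaa[saaa["transcript_id"] == row.transcript_id]
            assert len(sub) > 0
            assert all(7 <= len(s) <= 40 for s in sub["sequence"])


class TestFusions:
    def test_all_peptides_cross_junction(self, cohort):
        fus = cohort.peptides[cohort.peptides["pep_class"] == "fusion"]
        assert len(fus) > 0
        for row in fus.itertuples():
            nt_start = row.frame + 3 * row.offset
            nt_end = nt_start + 3 * len(row.sequence)
            assert nt_start < row.junction < nt_end

    def test_in_frame_fusion_translates_as_partner_concatenation(self):
        cds_a = "ATG" + "AAA" * 12  # M + K*12
        cds_b = "GAA" * 12 + "TTT" * 4  # E*12 F*4
        fusion = pd.DataFrame(
            [{"fusion_id": "F1", "gene5": "A", "gene3": "B",
              "junction": len(cds_a), "sequence": cds_a + cds_b}]
        )
        recs = make_fusion_peptides(fusion, {})
        frame0 = [r for r in recs if r.frame == 0]
        assert frame0
        manual = translate_nt(cds_a + cds_b)
        for r in frame0:
            assert manual[r.offset : r.offset + len(r.sequence)] == r.sequence
            assert "K" in r.sequence and "E" in r.sequence  # spans both partners

    def test_junction_outside_sequence_is_error(self):
        fusion = pd.DataFrame(
            [{"fusion_id": "F1", "gene5": "A", "gene3": "B", "junction": 900,
              "sequence": "ATG" * 100}]
        )
        with pytest.raises(ValueError):
            make_fusion_peptides(fusion, {})

    def test_canonical_junction_peptide_excluded(self):
        cds_a = "ATG" + "AAA" * 12
        cds_b = "GAA" * 12 + "TTT" * 4
        fusion = pd.DataFrame(
            [{"fusion_id": "F1", "gene5": "A", "gene3": "B",
              "junction": len(cds_a), "sequence": cds_a + cds_b}]
        )
        canonical = {"p": translate_nt(cds_a + cds_b)}
        assert all(r.frame != 0 for r in make_fusion_peptides(fusion, canonical))


class TestIsoelectricPoint:
    def test_symmetric_pka_midpoint(self):
        # glycine-only peptide: only termini ionize; symmetric pKas around 7
        pka = dict(dbgen.PKA_BJELLQVIST, n_term=10.0, c_term=4.0)
        assert predict_pi("GGGGGGG", pka=pka) == pytest.approx(7.0, abs=1e-3)

    def test_returned_ph_has_near_zero_charge(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pep = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=12))
            pi = predict_pi(pep)
            assert abs(peptide_charge(pep, pi)) < 1e-4

    def test_acidic_residue_decreases_basic_increases(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            pep = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=10))
            assert predict_pi(pep + "E") < predict_pi(pep)
            assert predict_pi(pep + "K") > predict_pi(pep)

    def test_bisection_matches_grid_scan_oracle(self):
        rng = np.random.default_rng(2)
        grid = np.arange(0.0, 14.0, 0.001)
        for _ in range(50):
            pep = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=15))
            charges = np.abs([peptide_charge(pep, ph) for ph in grid])
            assert abs(predict_pi(pep) - grid[np.argmin(charges)]) <= 0.01


class TestFractionAssignment:
    def test_half_open_bins(self):
        boundaries = [float(b) for b in range(3, 11)]
        assert assign_hirief_fraction(4.0, boundaries) == 1  # bin [4,5)
        assert assign_hirief_fraction(3.0, boundaries) == 0
        assert assign_hirief_fraction(9.999, boundaries) == 6

    def test_out_of_range_sentinel(self):
        boundaries = [float(b) for b in range(3, 11)]
        assert assign_hirief_fraction(2.5, boundaries) == dbgen.OUT_OF_RANGE
        assert assign_hirief_fraction(10.0, boundaries) == dbgen.OUT_OF_RANGE

    def test_unsorted_boundaries_rejected(self):
        with pytest.raises(ValueError):
            assign_hirief_fraction(5.0, [3.0, 5.0, 4.0])

    def test_uniform_pi_fills_bins_by_width(self):
        rng = np.random.default_rng(4)
        boundaries = [3.0, 4.0, 6.0, 10.0]  # widths 1, 2, 4
        pis = rng.uniform(3.0, 10.0, size=5000)
        bins = np.array([assign_hirief_fraction(p, boundaries) for p in pis])
        observed = np.bincount(bins, minlength=3)
        from scipy import stats

        expected = 5000 * np.array([1, 2, 4]) / 7
        assert stats.chisquare(observed, expected).pvalue > 0.01


class TestDecoys:
    def test_pseudo_reverse_keeps_cterm(self):
        target = PeptideRecord("ACDEFGK", "novel_candidate", "t1")
        (decoy,) = generate_decoys([target])
        assert decoy.sequence == "GFEDCAK"
        assert decoy.pep_class == "decoy"

    def test_colliding_decoy_discarded(self):
        target = PeptideRecord("AAAAAAK", "novel_candidate", "t1")
        assert generate_decoys([target]) == []

    def test_composition_preserved_and_size_bounded(self):
        rng = np.random.default_rng(5)
        targets = [
            PeptideRecord(
                "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=10)),
                "novel_candidate", "t1",
            )
            for _ in range(50)
        ]
        decoys = generate_decoys(targets)
        assert len(decoys) <= len(targets)
        by_target = {t.sequence[:-1][::-1] + t.sequence[-1]: t for t in targets}
        for d in decoys:
            assert sorted(d.sequence) == sorted(by_target[d.sequence].sequence)
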