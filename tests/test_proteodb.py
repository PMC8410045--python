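"""Database construction: translation, variant application, windows, assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neoforge.examples import RAF9_MINIGENE, RTF9_MINIGENE, tubb_like_transcript
from neoforge.proteodb import (
    SomaticVariant,
    TranscriptRecord,
    apply_missense,
    apply_variant_to_cds,
    build_database,
    frameshift_window,
    missense_window,
    read_database_fasta,
    translate_cds,
    variant_entry,
    write_database_fasta,
)

class TestTranslateCds:
    @pytest.mark.parametrize(
        "cds,expected",
        [
            (RAF9_MINIGENE, "RYLAVAAVF"),
            (RTF9_MINIGENE, "RYLTVAAVF"),
            ("ATGTAA", "M"),
            ("ATGAAATAGAAA", "MK"),  # stop terminates translation
            ("ATGGCC" + "C", "MA"),  # trailing partial codon ignored
        ],
    )
    def test_examples(self, cds, expected):
        assert translate_cds(cds) == expected

    def test_from_codon_offset(self):
        assert translate_cds("AAA" + RAF9_MINIGENE, from_codon=2) == "RYLAVAAVF"

    def test_rejects_non_acgt(self):
        with pytest.raises(ValueError):
            translate_cds("ATGNNNTAA")

    def test_rejects_too_short(self):
        with pytest.raises(ValueError):
            translate_cds("AT")


class TestApplyMissense:
    def test_c994_maps_to_residue_332(self):
        transcript, variant = tubb_like_transcript(seed=0)
        mutant, idx = apply_missense(transcript, variant)
        wt = translate_cds(transcript.cds)
        assert idx == 332
        assert wt[331] == "T" and mutant[331] == "A"
        assert sum(a != b for a, b in zip(wt, mutant)) == 1

    def test_ref_mismatch_is_error(self):
        transcript, _ = tubb_like_transcript(seed=0)
        bad = SomaticVariant("TUBB_like", 994, "C", "G", "missense", 1, 10)
        with pytest.raises(ValueError, match="does not match"):
            apply_missense(transcript, bad)

    def test_synonymous_rejected(self):
        # GGA -> GGG is Gly -> Gly
        t = TranscriptRecord("t", "g", "ATGGGATAA", {"s": 1.0})
        v = SomaticVariant("t", 6, "A", "G", "missense", 1, 10)
        with pytest.raises(ValueError, match="synonymous"):
            apply_missense(t, v)

    def test_stop_gain_rejected(self):
        # TAC -> TAA would be nonsense
        t = TranscriptRecord("t", "g", "ATGTACAAATAA", {"s": 1.0})
        v = SomaticVariant("t", 6, "C", "A", "missense", 1, 10)
        with pytest.raises(ValueError, match="nonsense"):
            apply_missense(t, v)

    def test_brute_force_oracle_residue_index(self, transcripts, variants):
        """Mutate the CDS string, retranslate, diff: same residue index."""
        for v in (v for v in variants if v.vtype == "missense"):
            t = next(t for t in transcripts if t.transcript_id == v.transcript_id)
            mutant, idx = apply_missense(t, v)
            wt = translate_cds(t.cds)
            diff = [i + 1 for i, (a, b) in enumerate(zip(wt, mutant)) if a != b]
            assert diff == [idx]


class TestWindows:
    def test_interior_missense_window_is_61mer_centred(self):
        protein = "A" * 331 + "W" + "A" * 68  # 400 residues, substitution at 332
        entry = missense_window(protein, 332)
        assert len(entry.sequence) == 61
        assert entry.mutated_region == (31, 31)
        assert entry.sequence[30] == "W"

    def test_left_truncation(self):
        entry = missense_window("M" + "A" * 399, 10)
        assert len(entry.sequence) == 40  # residues 1..40
        assert entry.mutated_region == (10, 10)

    def test_right_truncation_at_terminus(self):
        protein = "A" * 100
        entry = missense_window(protein, 100)
        assert len(entry.sequence) == 31
        assert entry.mutated_region == (31, 31)

    def test_frameshift_entry_matches_mutant_translation(self, transcripts, variants):
        """Oracle containment: the entry is a suffix-bounded substring of the
        full mutant translation, ending at its C-terminus."""
        for v in (v for v in variants if v.vtype == "frameshift"):
            t = next(t for t in transcripts if t.transcript_id == v.transcript_id)
            entry = frameshift_window(t, v)
            if entry is None:
                continue
            mutant = translate_cds(apply_variant_to_cds(t.cds, v))
            assert mutant.endswith(entry.sequence)
            a, b = entry.mutated_region
            assert b == len(entry.sequence)
            # region start = first divergence from wild type
            wt = translate_cds(t.cds)
            offset = len(mutant) - len(entry.sequence)
            p = offset + a
            assert wt[: p - 1] == mutant[: p - 1]
            assert p > len(wt) or wt[p - 1] != mutant[p - 1]

    def test_frameshift_random_oracle(self):
        """500 random indels: window is always contained in the mutant protein."""
        rng = np.random.default_rng(5)
        from neoforge.synthdata import SimulationConfig, gen_reference, gen_variants

        cfg = SimulationConfig(seed=17, n_transcripts=25, cds_length_range=(150, 450),
                               n_missense=0, n_frameshift=0)
        pool = gen_reference(cfg)
        checked = 0
        while checked < 500:
            cfg2 = SimulationConfig(seed=int(rng.integers(2**31)), n_transcripts=25,
                                    cds_length_range=(150, 450),
                                    n_missense=0, n_frameshift=20)
            for v in gen_variants(pool, cfg2):
                t = next(t for t in pool if t.transcript_id == v.transcript_id)
                entry = frameshift_window(t, v)
                mutant = translate_cds(apply_variant_to_cds(t.cds, v))
                if entry is not None:
                    assert entry.sequence in mutant
                    checked += 1

    def test_immediate_stop_dropped(self):
        # deletion brings a TAA immediately into frame right after the ATG
        t = TranscriptRecord("t", "g", "ATGCTAAGCAAAGGGCCCAAATTTGGGTAA", {"s": 1.0})
        v = SomaticVariant("t", 4, "CT", "C", "frameshift", 1, 10)
        mutant = translate_cds(apply_variant_to_cds(t.cds, v))
        entry = frameshift_window(t, v)
        if mutant == "M":  # nothing novel beyond the shared prefix
            assert entry is None


class TestBuildDatabase:
    def _toy(self):
        rng = np.random.default_rng(0)
        from neoforge.synthdata import SimulationConfig, gen_reference, gen_variants

        cfg = SimulationConfig(seed=23, n_transcripts=10, cds_length_range=(150, 240),
                               fraction_zero_tpm=0.2, n_missense=5, n_frameshift=0)
        transcripts = gen_reference(cfg)
        variants = gen_variants(transcripts, cfg)
        return transcripts, variants

    def test_expression_gate_filters_both_sets(self):
        transcripts, variants = self._toy()
        entries = build_database(transcripts, variants, "tumor")
        zero_ids = {t.transcript_id for t in transcripts if t.tpm["tumor"] == 0.0}
        n_can = sum(not e.is_variant_only for e in entries)
        n_var = sum(e.is_variant_only for e in entries)
        assert n_can == len(transcripts) - len(zero_ids)
        expected_var = [v for v in variants if v.transcript_id not in zero_ids]
        assert n_var == len(expected_var)
        for e in entries:
            for s in e.sources:
                assert s.transcript_id not in zero_ids

    def test_all_expressed_keeps_everything(self):
        transcripts, variants = self._toy()
        lifted = [
            type(t)(t.transcript_id, t.gene, t.cds,
                    {k: max(v, 1.0) for k, v in t.tpm.items()})
            for t in transcripts
        ]
        entries = build_database(lifted, variants, "tumor")
        assert sum(not e.is_variant_only for e in entries) == len(transcripts)
        assert sum(e.is_variant_only for e in entries) == len(variants)

    def test_all_zero_is_hard_error(self):
        transcripts, variants = self._toy()
        silenced = [
            type(t)(t.transcript_id, t.gene, t.cds, {k: 0.0 for k in t.tpm})
            for t in transcripts
        ]
        with pytest.raises(ValueError, match="empty database"):
            build_database(silenced, variants, "tumor")

    def test_duplicate_sequences_collapse_with_merged_provenance(self):
        # engineered collision: a second transcript whose translation equals
        # the missense window of the first
        t1, v1 = tubb_like_transcript(seed=1)
        mutant, idx = apply_missense(t1, v1)
        window = missense_window(mutant, idx).sequence
        # construct a CDS encoding exactly `window` then a stop
        codon_for = {"A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
                     "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
                     "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
                     "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT"}
        cds2 = "".join(codon_for[aa] for aa in window) + "TAA"
        t2 = TranscriptRecord("COLL", "COLL", cds2, {"tumor": 5.0})
        entries = build_database([t1, t2], [v1], "tumor")
        collided = [e for e in entries if e.sequence == window]
        assert len(collided) == 1
        assert set(collided[0].provenance.split("+")) == {"canonical", "missense_window"}
        assert not collided[0].is_variant_only

    def test_order_independence(self):
        transcripts, variants = self._toy()
        a = build_database(transcripts, variants, "tumor")
        b = build_database(transcripts[::-1], variants[::-1], "tumor")
        assert {e.sequence for e in a} == {e.sequence for e in b}
        assert [e.sequence for e in a] == [e.sequence for e in b]  # idempotent layout

    def test_fasta_round_trip(self, tmp_path, db_entries):
        path = tmp_path / "db.fasta"
        write_database_fasta(db_entries, path, "tumor")
        back = read_database_fasta(path)
        assert [e.sequence for e in back] == [e.sequence for e in db_entries]
        assert [e.mutated_region for e in back] == [e.mutated_region for e in db_entries]
        assert [e.is_variant_only for e in back] == [e.is_variant_only for e in db_entries]


@given(st.integers(min_value=1, max_value=400), st.integers(min_value=400, max_value=800))
@settings(deadline=None, max_examples=60, derandomize=True)
def test_missense_window_invariants(i, L):
    """Window length <= 61 and the altered residue sits at position 31 in the interior."""
    protein = "A" * (i - 1) + "W" + "A" * (L - i)
    entry = missense_window(protein, i)
    assert len(entry.sequence) <= 61
    a, b = entry.mutated_region
    assert a == b and entry.sequence[a - 1] == "W"
    if i > 30 and i + 30 <= L:
        assert a == 31 and len(entry.sequence) == 61
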