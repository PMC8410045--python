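"""Mass arithmetic, fragment ladders, the no-enzyme index, search and FDR."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neoforge.constants import MET_OXIDATION, PROTON, RESIDUE_MASS, WATER
from neoforge.msident import (
    PSM,
    Spectrum,
    build_index,
    filter_fdr,
    fragment_ions,
    peptide_mass,
    precursor_mz,
    qvalues,
    reverse_entry,
    search,
)
from neoforge.proteodb import EntrySource, ProteinEntry
from neoforge.synthdata import gen_spectra

peptides = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=11)


class TestMasses:
    def test_glycine(self):
        assert peptide_mass("G") == pytest.approx(75.03203, abs=1e-4)

    def test_raf9_monoisotopic_mass(self):
        # independent oracle: explicit residue-mass summation
        table = {"R": 156.10111, "Y": 163.06333, "L": 113.08406, "A": 71.03711,
                 "V": 99.06841, "F": 147.06841}
        expected = sum(table[aa] for aa in "RYLAVAAVF") + 18.010565
        assert expected == pytest.approx(1008.5756, abs=1e-3)
        assert peptide_mass("RYLAVAAVF") == pytest.approx(expected, abs=1e-3)

    def test_oxidation_additivity(self):
        assert peptide_mass("AMK", mods=(2,)) - peptide_mass("AMK") == pytest.approx(
            MET_OXIDATION
        )

    def test_oxidation_only_on_met(self):
        with pytest.raises(ValueError):
            peptide_mass("AAK", mods=(1,))

    def test_unknown_residue(self):
        with pytest.raises(ValueError):
            peptide_mass("AXK")

    def test_precursor_mz_charges(self):
        m = peptide_mass("RYLAVAAVF")
        assert precursor_mz(m, 1) == pytest.approx(m + PROTON)
        assert precursor_mz(m, 2) == pytest.approx((m + 2 * PROTON) / 2)


class TestFragments:
    def test_b2_of_raf9(self):
        b, y = fragment_ions("RYLAVAAVF")
        assert b[1] == pytest.approx(320.1717, abs=1e-3)  # R + Y + proton

    def test_ladder_lengths(self):
        b, y = fragment_ions("AG")
        assert len(b) == len(y) == 1

    @given(peptides)
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_complementarity_identity(self, pep):
        """b_k + y_(L-k) equals the neutral mass plus two protons, every k."""
        b, y = fragment_ions(pep)
        total = peptide_mass(pep)
        L = len(pep)
        for k in range(1, L):
            assert b[k - 1] + y[L - k - 1] == pytest.approx(total + 2 * PROTON, abs=1e-9)

    def test_modified_ladder_shifts_prefixes(self):
        b0, y0 = fragment_ions("AMKK")
        b1, y1 = fragment_ions("AMKK", mods=(2,))
        assert b1[0] == pytest.approx(b0[0])  # b1 before the M unchanged
        assert b1[1] == pytest.approx(b0[1] + MET_OXIDATION)
        assert y1[-1] == pytest.approx(y0[-1] + MET_OXIDATION)  # y3 spans the M


def _entries(seqs, variant=False):
    out = []
    for i, s in enumerate(seqs):
        src = (
            EntrySource("missense_window", f"TX{i}", "c.1A>G", (1, 1))
            if variant
            else EntrySource("canonical", f"TX{i}")
        )
        out.append(ProteinEntry(f"e{i}", s, [src]))
    return out


class TestIndex:
    def test_single_entry_substring_count(self):
        entries = _entries(["A" * 30 + "CDEFGHIKLMNPQRSTVWY" + "A" * 12])  # 61-mer
        idx = build_index(entries, with_decoys=False)
        # distinct substrings can collapse duplicates, so compare to brute force
        seq = entries[0].sequence
        brute = {seq[i : i + L] for L in (8, 9, 10, 11) for i in range(len(seq) - L + 1)}
        no_met = [r for r in idx.records if not r.mods]
        assert len(no_met) == len(brute)
        # the raw placement count is the (L-k+1) summation
        assert sum(len(seq) - L + 1 for L in (8, 9, 10, 11)) == 210

    def test_brute_force_oracle_on_random_entries(self):
        rng = np.random.default_rng(8)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        seqs = ["".join(rng.choice(aas, int(rng.integers(12, 40)))) for _ in range(20)]
        idx = build_index(_entries(seqs), with_decoys=False)
        brute = set()
        for s in seqs:
            for L in (8, 9, 10, 11):
                for i in range(len(s) - L + 1):
                    brute.add(s[i : i + L])
        assert {r.peptide for r in idx.records} == brute

    def test_shared_peptide_keeps_all_sources(self):
        entries = _entries(["KKKWWWRRRAAA", "CCKKKWWWRRR"])
        idx = build_index(entries, with_decoys=False)
        rec = next(r for r in idx.records if r.peptide == "KKKWWWRRR")
        assert len(rec.sources) == 2

    def test_target_decoy_assignment(self):
        # palindromic peptide appears in both target and reversed decoy
        entries = _entries(["AACDEDCAA" + "KLMNPQRST"])
        idx = build_index(entries, with_decoys=True)
        rec = next(r for r in idx.records if r.peptide == "AACDEDCAA")
        assert not rec.is_decoy

    def test_oxidation_variants_bounded(self):
        entries = _entries(["MMMKLANPQRST"])
        idx = build_index(entries, with_decoys=False, max_ox=2)
        recs = [r for r in idx.records if r.peptide == "MMMKLANP"]
        # 0 ox: 1; 1 ox: 3 positions; 2 ox: 3 pairs -> 7 variants, none with 3
        assert len(recs) == 7
        assert max(len(r.mods) for r in recs) == 2


class TestSearch:
    def _spectrum_for(self, pep, mods=(), z=2, jitter=0.0, rng=None):
        b, y = fragment_ions(pep, mods)
        ions = np.concatenate([b, y])
        if rng is not None and jitter:
            ions = ions + rng.normal(0, jitter, len(ions))
        peaks = [(float(m), 100.0) for m in ions]
        return Spectrum("s1", precursor_mz(peptide_mass(pep, mods), z), z, peaks)

    def test_noiseless_planted_peptide_top_ranked(self, db_entries):
        idx = build_index(db_entries)
        pep = next(r.peptide for r in idx.records if not r.is_decoy and not r.mods)
        psms = search([self._spectrum_for(pep)], idx)
        assert len(psms) == 1 and psms[0].peptide == pep and not psms[0].is_decoy

    def test_no_candidate_is_unidentified(self, db_entries):
        idx = build_index(db_entries)
        sp = Spectrum("s1", 5000.0, 1, [(200.0, 10.0)])
        assert search([sp], idx) == []

    def test_widening_frag_tol_never_loses_ions(self, db_entries):
        idx = build_index(db_entries)
        rng = np.random.default_rng(0)
        pep = next(r.peptide for r in idx.records if not r.is_decoy and not r.mods)
        sp = self._spectrum_for(pep, jitter=0.01, rng=rng)
        narrow = search([sp], idx, frag_tol=0.02)
        wide = search([sp], idx, frag_tol=0.5)
        assert wide[0].matched_ions >= narrow[0].matched_ions

    def test_oxidized_spectrum_assigned_modified_peptide(self, db_entries):
        idx = build_index(db_entries)
        rec = next(
            (r for r in idx.records if not r.is_decoy and len(r.mods) == 1), None
        )
        if rec is None:
            pytest.skip("no methionine peptide in this fixture database")
        psms = search([self._spectrum_for(rec.peptide, rec.mods)], idx)
        assert psms[0].peptide == rec.peptide and psms[0].mods == rec.mods


def _psm(score, decoy, pep="AAAAAAAA"):
    return PSM("s", pep, (), decoy, score, 4)


class TestQvalues:
    def test_hand_computed_oracle(self):
        """targets {10,9,8,6}, decoys {7}: q(6)=1/4, q at >=8 is 0."""
        psms = [_psm(10, False), _psm(9, False), _psm(8, False),
                _psm(6, False), _psm(7, True)]
        out = {p.score: p.q_value for p in qvalues(psms)}
        assert out[6] == pytest.approx(0.25)
        assert out[8] == out[9] == out[10] == 0.0
        # min over thresholds <= 7 includes the 0.25 reached at score 6
        assert out[7] == pytest.approx(0.25)

    def test_no_decoys_all_zero(self):
        out = qvalues([_psm(s, False) for s in (5, 4, 3)])
        assert all(p.q_value == 0.0 for p in out)

    def test_monotone_nonincreasing_in_score(self):
        rng = np.random.default_rng(1)
        psms = [_psm(float(rng.normal()), bool(rng.integers(2))) for _ in range(300)]
        out = sorted(qvalues(psms), key=lambda p: -p.score)
        qs = [p.q_value for p in out]
        assert all(a <= b for a, b in zip(qs, qs[1:]))

    def test_filter_shrinks_with_alpha(self):
        rng = np.random.default_rng(2)
        psms = [_psm(float(rng.normal()), bool(rng.integers(2)), f"AAAAAAA{c}")
                for c, _ in zip("ACDEFGHIKLMNPQRSTVWY" * 20, range(300))]
        strict = filter_fdr(psms, 0.01, peptide_level=False)
        loose = filter_fdr(psms, 0.2, peptide_level=False)
        assert len(strict) <= len(loose)

    def test_zero_targets_is_error(self):
        with pytest.raises(ValueError):
            filter_fdr([_psm(1.0, True)], 0.01)


class TestEndToEnd:
    def test_noiseless_recall_and_zero_fdr(self, db_entries):
        """Noiseless planted spectra: 100% recall, empirical FDR 0."""
        idx = build_index(db_entries)
        true_peps = sorted({r.peptide for r in idx.records if not r.is_decoy})[:80]
        spectra, truth = gen_spectra(
            true_peps, seed=99, mz_jitter_sd=0.0, n_noise_peaks=0,
            precursor_jitter_ppm=0.0, ox_probability=0.0,
        )
        accepted = filter_fdr(search(spectra, idx), 0.01)
        got = {p.peptide for p in accepted}
        assert got == set(true_peps)

    def test_neoantigen_classification(self, db_entries):
        idx = build_index(db_entries)
        variant_only = [e for e in db_entries if e.is_variant_only]
        target = None
        for e in variant_only:
            a, b = e.mutated_region
            if b - a >= 0 and len(e.sequence) >= 9:
                start = max(0, a - 5)
                pep = e.sequence[start : start + 9]
                if len(pep) == 9 and not any(
                    pep in o.sequence for o in db_entries if o is not e
                ):
                    target = pep
                    break
        assert target is not None
        spectra, _ = gen_spectra([target], seed=1, mz_jitter_sd=0.0,
                                 n_noise_peaks=0, precursor_jitter_ppm=0.0,
                                 ox_probability=0.0)
        accepted = filter_fdr(search(spectra, idx), 0.01)
        assert len(accepted) == 1
        hit = accepted[0]
        a, b = dict((e.entry_id, e.mutated_region) for e in variant_only)[
            hit.sources[0][0].entry_id
        ]
        overlap = hit.sources[0][1] <= b and hit.sources[0][1] + len(target) - 1 >= a
        assert hit.is_neoantigen == overlap
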