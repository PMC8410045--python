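"""Simplified no-enzyme MS/MS identification with target-decoy FDR.

The search mirrors a standard closed search at immunopeptidome settings:
every distinct 8-11-mer substring of every database entry is a candidate
(no enzyme), methionine oxidation (+15.994915 Da) is a variable
modification (at most two per peptide), precursor matching is +/-10 ppm on
the neutral mass and fragment matching +/-0.02 Da on singly protonated b/y
ions.  Scoring is a log-hyperscore: log of the summed matched-peak
intensity plus log-factorials of the matched b and y counts.  Decoys are
whole-entry sequence reversals searched concatenated with targets;
q-values are the monotonized decoy/target tail-count ratio, and peptides
accepted at q <= 0.01 are classified as neoantigens when every source
entry is a mutation-altered window overlapped by the peptide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np

from .constants import MET_OXIDATION, PROTON, RESIDUE_MASS, WATER
from .proteodb import CANONICAL, EntrySource, ProteinEntry


@dataclass
class Spectrum:
    """One centroided MS/MS spectrum; peaks kept sorted by m/z."""

    spectrum_id: str
    precursor_mz: float
    charge: int
    peaks: list  # (mz, intensity)

    def __post_init__(self):
        if not 1 <= self.charge <= 4:
            raise ValueError("precursor charge must be 1-4")
        if any(i <= 0 for _, i in self.peaks):
            raise ValueError("peak intensities must be positive")
        self.peaks = sorted(self.peaks)

    @property
    def neutral_mass(self) -> float:
        return (self.precursor_mz - PROTON) * self.charge


@dataclass
class PSM:
    spectrum_id: str
    peptide: str
    mods: tuple  # 1-based positions of oxidized methionines
    is_decoy: bool
    score: float
    matched_ions: int
    sources: tuple = ()
    q_value: float = float("nan")
    is_neoantigen: bool = False


def peptide_mass(peptide: str, mods=()) -> float:
    """Monoisotopic neutral mass: residue masses + water + 15.994915 per oxidation."""
    try:
        m = sum(RESIDUE_MASS[aa] for aa in peptide)
    except KeyError as e:
        raise ValueError(f"unknown residue symbol {e.args[0]!r}") from None
    for pos in mods:
        if peptide[pos - 1] != "M":
            raise ValueError("oxidation is only defined on methionine")
    return m + WATER + MET_OXIDATION * len(mods)


def precursor_mz(mass: float, z: int) -> float:
    """m/z of a neutral mass at charge ``z`` (protonation)."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return (mass + z * PROTON) / z


def fragment_ions(peptide: str, mods=()):
    """Singly protonated b- and y-ion ladders (k = 1..L-1).

    b_k is the k-residue prefix plus a proton; y_k the k-residue suffix plus
    water and a proton, so b_k + y_(L-k) = neutral mass + 2 protons.
    """
    L = len(peptide)
    if L < 2:
        raise ValueError("fragments require at least 2 residues")
    delta = [RESIDUE_MASS[aa] for aa in peptide]
    for pos in mods:
        delta[pos - 1] += MET_OXIDATION
    prefix = np.cumsum(delta)
    b = prefix[:-1] + PROTON
    total = prefix[-1]
    y = (total - prefix[:-1])[::-1] + WATER + PROTON
    return b, y


@dataclass(frozen=True)
class IndexRecord:
    peptide: str
    mods: tuple
    mass: float
    is_decoy: bool
    sources: tuple  # (entry, 1-based start within entry) pairs


class PeptideIndex:
    """All distinct modified 8-11-mers of a database, keyed by neutral mass."""

    def __init__(self, records):
        self.records = sorted(records, key=lambda r: r.mass)
        self.masses = np.array([r.mass for r in self.records])

    def candidates(self, neutral_mass: float, tol_ppm: float):
        """Records whose neutral mass is within +/-``tol_ppm`` of the query."""
        tol = neutral_mass * tol_ppm * 1e-6
        lo = np.searchsorted(self.masses, neutral_mass - tol, side="left")
        hi = np.searchsorted(self.masses, neutral_mass + tol, side="right")
        return self.records[lo:hi]


def reverse_entry(entry: ProteinEntry) -> ProteinEntry:
    """Whole-entry sequence reversal: the decoy counterpart of an entry."""
    sources = [replace(s, transcript_id=f"rev_{s.transcript_id}") for s in entry.sources]
    return ProteinEntry(f"rev_{entry.entry_id}", entry.sequence[::-1], sources, entry.flags)


def build_index(entries, lengths=(8, 9, 10, 11), max_ox: int = 2,
                with_decoys: bool = True) -> PeptideIndex:
    """Digest the database (plus reversed decoys) into a mass-sorted index.

    Every substring with length in ``lengths`` is indexed once per oxidation
    variant (0..min(#M, max_ox) oxidized methionines, every position
    combination).  A peptide seen in both target and decoy sequences is
    assigned to the target side.
    """
    if not entries:
        raise ValueError("empty database")
    pool = [(e, False) for e in entries]
    if with_decoys:
        pool += [(reverse_entry(e), True) for e in entries]
    hits: dict[str, dict] = {}
    for entry, is_decoy in pool:
        seq = entry.sequence
        for L in lengths:
            for start in range(len(seq) - L + 1):
                pep = seq[start : start + L]
                rec = hits.setdefault(pep, {"targets": [], "decoys": []})
                rec["decoys" if is_decoy else "targets"].append((entry, start + 1))
    records = []
    for pep, rec in hits.items():
        is_decoy = not rec["targets"]
        sources = tuple(rec["targets"] or rec["decoys"])
        m_positions = [i + 1 for i, aa in enumerate(pep) if aa == "M"]
        base = peptide_mass(pep)
        for k in range(min(len(m_positions), max_ox) + 1):
            for mods in combinations(m_positions, k):
                records.append(
                    IndexRecord(pep, mods, base + MET_OXIDATION * k, is_decoy, sources)
                )
    return PeptideIndex(records)


def _match_count(theoretical: np.ndarray, peak_mz: np.ndarray,
                 peak_int: np.ndarray, frag_tol: float):
    """Count theoretical ions landing within ``frag_tol`` of an observed peak.

    Each theoretical ion claims at most the single nearest peak; intensity
    of claimed peaks is summed (a peak may support both a b and a y ion, as
    in real ladders where series overlap).
    """
    idx = np.searchsorted(peak_mz, theoretical)
    matched = 0
    intensity = 0.0
    for ion, j in zip(theoretical, idx):
        best = None
        for k in (j - 1, j):
            if 0 <= k < len(peak_mz) and abs(peak_mz[k] - ion) <= frag_tol:
                if best is None or abs(peak_mz[k] - ion) < abs(peak_mz[best] - ion):
                    best = k
        if best is not None:
            matched += 1
            intensity += peak_int[best]
    return matched, intensity


def score_candidate(spectrum: Spectrum, record: IndexRecord, frag_tol: float):
    """Log-hyperscore of one candidate against one spectrum."""
    peak_mz = np.array([mz for mz, _ in spectrum.peaks])
    peak_int = np.array([i for _, i in spectrum.peaks])
    b, y = fragment_ions(record.peptide, record.mods)
    nb, ib = _match_count(b, peak_mz, peak_int, frag_tol)
    ny, iy = _match_count(y, peak_mz, peak_int, frag_tol)
    matched = nb + ny
    if matched == 0:
        return None
    score = math.log(ib + iy) + math.lgamma(nb + 1) + math.lgamma(ny + 1)
    return score, matched


def search(spectra, index: PeptideIndex, prec_tol_ppm: float = 10.0,
           frag_tol: float = 0.02) -> list:
    """Best PSM per spectrum under the precursor/fragment tolerances.

    Spectra with no candidate in the precursor window (or no matched
    fragment) are simply unidentified.  Exact score ties break toward the
    target, then the lexicographically smallest peptide, for determinism.
    """
    psms = []
    for spectrum in spectra:
        best = best_key = None
        for rec in index.candidates(spectrum.neutral_mass, prec_tol_ppm):
            scored = score_candidate(spectrum, rec, frag_tol)
            if scored is None:
                continue
            score, matched = scored
            key = (score, not rec.is_decoy)  # higher score, then target over decoy
            if (
                best is None
                or key > best_key
                or (key == best_key and rec.peptide < best[0].peptide)
            ):
                best, best_key = (rec, score, matched), key
        if best is not None:
            rec, score, matched = best
            psms.append(
                PSM(spectrum.spectrum_id, rec.peptide, rec.mods, rec.is_decoy,
                    score, matched, rec.sources)
            )
    return psms


def qvalues(psms) -> list:
    """Annotate PSMs with target-decoy q-values.

    For a score threshold s, raw FDR(s) = #decoys >= s / max(1, #targets >= s);
    the q-value is the monotonized minimum of raw FDR over all thresholds at
    or below s, so q is nonincreasing in score.
    """
    if not psms:
        return []
    order = sorted(range(len(psms)), key=lambda i: -psms[i].score)
    n_t = n_d = 0
    raw = []
    for i in order:
        if psms[i].is_decoy:
            n_d += 1
        else:
            n_t += 1
        raw.append(n_d / max(1, n_t))
    # monotonize from the low-score end
    q = [0.0] * len(raw)
    running = math.inf
    for j in range(len(raw) - 1, -1, -1):
        running = min(running, raw[j])
        q[j] = running
    out = list(psms)
    for rank, i in enumerate(order):
        out[i] = replace(psms[i], q_value=q[rank])
    return out


def classify_neoantigen(psm: PSM) -> bool:
    """A peptide is a neoantigen hit iff every source is a variant window
    and the peptide overlaps that window's mutated region."""
    if not psm.sources:
        return False
    for entry, start in psm.sources:
        if not entry.is_variant_only:
            return False
        a, b = entry.mutated_region
        end = start + len(psm.peptide) - 1
        if end < a or start > b:
            return False
    return True


def filter_fdr(psms, alpha: float = 0.01, peptide_level: bool = True) -> list:
    """Targets accepted at q <= alpha, annotated with neoantigen status.

    With ``peptide_level`` (default) only the best-scoring PSM per distinct
    peptide string is reported.
    """
    if not any(not p.is_decoy for p in psms):
        raise ValueError("no target PSMs to filter")
    annotated = qvalues(psms)
    accepted = [p for p in annotated if not p.is_decoy and p.q_value <= alpha]
    if peptide_level:
        best: dict[str, PSM] = {}
        for p in accepted:
            if p.peptide not in best or p.score > best[p.peptide].score:
                best[p.peptide] = p
        accepted = sorted(best.values(), key=lambda p: -p.score)
    return [replace(p, is_neoantigen=classify_neoantigen(p)) for p in accepted]
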