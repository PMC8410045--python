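"""Seeded synthetic inputs with the statistical structure the analysis assumes.

Every downstream stage (database construction, binding prediction, MS/MS
identification, ligandome comparison, assays, repertoire analysis) is
exercised here against data with planted, recoverable truth:

* coding transcripts (ATG...stop, no internal stop) with log-normal TPM and
  a configurable fraction of exactly-zero expression;
* verified-nonsynonymous missense SNVs and frame-shifting 1-2 nt indels
  with per-variant read support;
* tumor/normal ligandomes realized with exact sharing counts, plus planted
  tumor-associated-antigen (TAA) peptides whose source genes are given a
  configured tumor/normal expression fold;
* b/y-ion MS/MS spectra with Gaussian m/z jitter and uniform noise peaks,
  optionally mixed with "foreign" spectra from shuffled peptides absent
  from the database (makes target-decoy competition nontrivial);
* 4PL dose-response titrations and multinomial clonotype tables with
  planted expanded clones.

All randomness flows from one integer seed; each stage derives its own
child generator from ``seed`` plus a CRC32 of the stage name, so stages
can be rerun independently and outputs are byte-identical per seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .constants import STOP_CODONS
from .msident import Spectrum, fragment_ions, peptide_mass, precursor_mz
from .ligandome import LigandomeSet
from .assays import DoseResponse
from .proteodb import SomaticVariant, TranscriptRecord, translate_cds

_BASES = "ACGT"
_CODONS = ["".join((a, b, c)) for a in _BASES for b in _BASES for c in _BASES]
_SENSE_CODONS = [c for c in _CODONS if c not in STOP_CODONS]


def child_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator: seed + CRC32(stage name)."""
    return np.random.default_rng((int(seed) + zlib.crc32(stage.encode())) % 2**31)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults emulate the analyzed conditions
    at desk scale (a hypermutated tumor has mostly missense and a minority of
    frameshift events, ~85:15 here as in the 3367:600 ratio)."""

    seed: int = 0
    n_transcripts: int = 50
    cds_length_range: tuple = (300, 900)  # nt, multiples of 3
    fraction_zero_tpm: float = 0.1
    tpm_lognormal: tuple = (3.0, 1.5)  # (mu, sigma) of log TPM
    samples: tuple = ("tumor", "normal")
    n_missense: int = 30
    n_frameshift: int = 6
    mz_jitter_sd: float = 0.004  # Da; below a third of the 0.02 Da fragment tolerance
    n_noise_peaks: int = 10
    charges: tuple = (1, 2, 3)

    def validate(self):
        lo, hi = self.cds_length_range
        if lo < 120:
            raise ValueError("cds_length_range below 120 nt is degenerate")
        if lo % 3 or hi % 3 or hi < lo:
            raise ValueError("cds_length_range must be multiples of 3 with lo <= hi")
        if not 0.0 <= self.fraction_zero_tpm <= 1.0:
            raise ValueError("fraction_zero_tpm must lie in [0, 1]")
        return self


# ---------------------------------------------------------------- reference

def gen_reference(config: SimulationConfig) -> list:
    """Random coding transcripts with per-sample log-normal TPM.

    Each CDS is ATG + random sense codons + one stop codon, so translation
    is guaranteed (no internal in-frame stop).  Exactly
    ``round(fraction_zero_tpm * n)`` transcripts get TPM = 0 in every
    sample; tumor and normal TPM are correlated log-normals otherwise.
    """
    config.validate()
    rng = child_rng(config.seed, "reference")
    lo, hi = config.cds_length_range
    mu, sigma = config.tpm_lognormal
    n_zero = round(config.fraction_zero_tpm * config.n_transcripts)
    zero_idx = set(rng.choice(config.n_transcripts, size=n_zero, replace=False).tolist())
    transcripts = []
    for i in range(config.n_transcripts):
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
        cds = "ATG" + "".join(_SENSE_CODONS[j] for j in body) + \
            list(STOP_CODONS)[int(rng.integers(3))]
        base = float(rng.lognormal(mu, sigma))
        tpm = {}
        for s in config.samples:
            tpm[s] = 0.0 if i in zero_idx else base * float(rng.lognormal(0.0, 0.3))
        transcripts.append(
            TranscriptRecord(f"TX{i + 1:04d}", f"GENE{i + 1:04d}", cds, tpm)
        )
    return transcripts


# ----------------------------------------------------------------- variants

def _draw_missense(cds: str, rng) -> SomaticVariant | None:
    n_codons = len(cds) // 3
    codon_idx = int(rng.integers(2, n_codons))  # skip start codon and stop codon
    within = int(rng.integers(3))
    pos = 3 * (codon_idx - 1) + within + 1
    ref = cds[pos - 1]
    codon = cds[3 * (codon_idx - 1): 3 * codon_idx]
    wt_aa = str(Seq(codon).translate())
    for alt in rng.permutation(list(_BASES)):
        if alt == ref:
            continue
        mut_codon = codon[:within] + alt + codon[within + 1:]
        mut_aa = str(Seq(mut_codon).translate())
        if mut_aa != wt_aa and mut_aa != "*":
            return pos, ref, str(alt)
    return None


def gen_variants(transcripts, config: SimulationConfig) -> list:
    """Somatic variants with verified consequences and read support.

    Missense SNVs are re-translated to confirm they are nonsynonymous and
    not stop-gain; frameshifts are anchored 1-2 nt insertions/deletions
    placed clear of the start and stop codons.  Read depth is drawn per
    variant with ``depth >= alt_reads >= 0``.
    """
    if not transcripts:
        raise ValueError("no transcripts to mutate")
    rng = child_rng(config.seed, "variants")
    variants, used = [], set()

    def read_support():
        depth = int(rng.integers(100, 600))
        return int(rng.binomial(depth, float(rng.uniform(0.05, 0.5)))), depth

    for _ in range(config.n_missense):
        for _attempt in range(2000):
            t = transcripts[int(rng.integers(len(transcripts)))]
            drawn = _draw_missense(t.cds, rng)
            if drawn is None or (t.transcript_id, drawn[0]) in used:
                continue
            pos, ref, alt = drawn
            used.add((t.transcript_id, pos))
            alt_reads, depth = read_support()
            variants.append(
                SomaticVariant(t.transcript_id, pos, ref, alt, "missense", alt_reads, depth)
            )
            break
        else:
            raise ValueError("could not place the requested number of missense variants")

    for _ in range(config.n_frameshift):
        for _attempt in range(2000):
            t = transcripts[int(rng.integers(len(transcripts)))]
            size = int(rng.integers(1, 3))  # 1 or 2 nt
            is_del = bool(rng.integers(2))
            span = 1 + size if is_del else 1
            pos = int(rng.integers(4, len(t.cds) - 2 - span))
            if (t.transcript_id, pos) in used:
                continue
            anchor = t.cds[pos - 1]
            if is_del:
                ref, alt = t.cds[pos - 1: pos - 1 + 1 + size], anchor
            else:
                ins = "".join(_BASES[j] for j in rng.integers(0, 4, size=size))
                ref, alt = anchor, anchor + ins
            used.add((t.transcript_id, pos))
            alt_reads, depth = read_support()
            variants.append(
                SomaticVariant(t.transcript_id, pos, ref, alt, "frameshift", alt_reads, depth)
            )
            break
        else:
            raise ValueError("could not place the requested number of frameshift variants")
    return variants


# --------------------------------------------------------------- ligandomes

@dataclass
class LigandomeDesign:
    """Exact-construction design of tumor/normal peptide repertoires."""

    n_tumor: int = 100
    n_normal: int = 100
    n_shared: int = 40  # peptides present in the tumor set and >= 1 normal set
    n_normal_samples: int = 1
    n_taa: int = 5  # planted tumor-only peptides from overexpressed genes
    taa_fold: float = 25.0
    length_weights: dict = field(
        default_factory=lambda: {8: 0.1, 9: 0.6, 10: 0.2, 11: 0.1}
    )


def gen_ligandomes(transcripts, design: LigandomeDesign, seed: int):
    """Per-sample ligandomes with exact sharing counts and planted TAAs.

    Peptides are 8-11-mer substrings of the translated proteome, each
    required to occur in exactly one protein so that gene attribution (and
    hence TAA recovery) is unambiguous.  Gene-level TPM tables are emitted
    with non-TAA genes at folds within [0.5, 2] and each TAA source gene at
    exactly ``taa_fold``.

    Returns ``(sets, truth)`` where truth holds the planted shared/TAA
    peptides, the peptide->gene map, and the two TPM tables.
    """
    if not transcripts:
        raise ValueError("empty proteome")
    rng = child_rng(seed, "ligandomes")
    proteome = {t.gene: translate_cds(t.cds) for t in transcripts}
    genes = sorted(proteome)
    lengths = sorted(design.length_weights)
    weights = np.array([design.length_weights[L] for L in lengths], dtype=float)
    weights /= weights.sum()

    taa_genes = [str(g) for g in rng.choice(genes, size=design.n_taa, replace=False)]

    def occurs_once(pep: str) -> str | None:
        host = None
        for g, prot in proteome.items():
            if pep in prot:
                if host is not None:
                    return None
                host = g
        return host

    def draw(n: int, from_genes=None, taken=frozenset()):
        out, hosts = [], []
        pool = list(from_genes) if from_genes else genes
        for _ in range(n):
            for _attempt in range(5000):
                g = pool[int(rng.integers(len(pool)))]
                prot = proteome[g]
                L = lengths[int(rng.choice(len(lengths), p=weights))]
                if len(prot) < L:
                    continue
                start = int(rng.integers(len(prot) - L + 1))
                pep = prot[start: start + L]
                if pep in taken or pep in out:
                    continue
                host = occurs_once(pep)
                if host is None or (from_genes and host not in from_genes):
                    continue
                out.append(pep)
                hosts.append(host)
                break
            else:
                raise ValueError("substring diversity exhausted for the requested design")
        return out, hosts

    taken: set = set()
    taa_peps, taa_hosts = draw(design.n_taa, from_genes=taa_genes, taken=frozenset(taken))
    taken.update(taa_peps)
    shared, _ = draw(design.n_shared, taken=frozenset(taken))
    taken.update(shared)
    n_tumor_only = design.n_tumor - design.n_shared - design.n_taa
    n_normal_only = design.n_normal - design.n_shared
    if n_tumor_only < 0 or n_normal_only < 0:
        raise ValueError("sharing design exceeds the per-sample peptide budgets")
    # tumor-only background peptides must come from non-TAA genes so that
    # fold-change selection recovers exactly the planted TAA set
    non_taa = [g for g in genes if g not in taa_genes]
    tumor_only, tumor_only_hosts = draw(n_tumor_only, from_genes=non_taa,
                                        taken=frozenset(taken))
    taken.update(tumor_only)
    normal_only, _ = draw(n_normal_only, taken=frozenset(taken))

    tumor = LigandomeSet("tumor_1", "tumor", set(shared) | set(tumor_only) | set(taa_peps))
    normal_sets = []
    for k in range(design.n_normal_samples):
        peps = set(shared[k::design.n_normal_samples] if design.n_normal_samples > 1 else shared)
        peps |= set(normal_only[k::design.n_normal_samples])
        normal_sets.append(LigandomeSet(f"normal_{k + 1}", "normal", peps))

    peptide_genes: dict[str, list] = {}
    for pep in taken | set(normal_only):
        peptide_genes[pep] = [g for g, prot in proteome.items() if pep in prot]

    tpm_tumor, tpm_normal = {}, {}
    for g in genes:
        base = float(rng.lognormal(3.0, 1.0))
        if g in taa_hosts:
            tpm_normal[g] = base
            tpm_tumor[g] = base * design.taa_fold
        else:
            tpm_normal[g] = base
            tpm_tumor[g] = base * float(rng.uniform(0.5, 2.0))

    truth = {
        "shared": set(shared),
        "taa_peptides": list(taa_peps),
        "taa_genes": sorted(set(taa_hosts)),
        "peptide_genes": peptide_genes,
        "tpm_tumor": tpm_tumor,
        "tpm_normal": tpm_normal,
    }
    return [tumor, *normal_sets], truth


# ------------------------------------------------------------------ spectra

def shuffle_peptide(peptide: str, rng, avoid=()) -> str:
    """Shuffle interior residues until the result is absent from ``avoid``."""
    interior = list(peptide[1:-1])
    for _ in range(200):
        rng.shuffle(interior)
        cand = peptide[0] + "".join(interior) + peptide[-1]
        if cand != peptide and not any(cand in seq for seq in avoid):
            return cand
    raise ValueError(f"could not derange peptide {peptide}")


def gen_spectra(
    true_peptides,
    seed: int,
    mz_jitter_sd: float = 0.004,
    n_noise_peaks: int = 10,
    foreign_fraction: float = 0.0,
    charges=(1, 2, 3),
    precursor_jitter_ppm: float = 2.0,
    ox_probability: float = 0.2,
    avoid_sequences=(),
):
    """MS/MS spectra for the given peptides plus optional foreign spectra.

    Fragment peaks sit at the theoretical singly protonated b/y m/z with
    Gaussian jitter (``mz_jitter_sd``); ``n_noise_peaks`` uniform noise
    peaks are added at lower intensity.  Methionine-containing peptides are
    oxidized with probability ``ox_probability``.  A ``foreign_fraction``
    of additional spectra is generated from shuffled true peptides checked
    to be absent from ``avoid_sequences`` (e.g. the search database), which
    makes the target-decoy competition honest.

    Returns ``(spectra, truth)``; truth columns: spectrum_id, peptide,
    mods, charge, is_foreign.
    """
    rng = child_rng(seed, "spectra")
    jobs = [(pep, False) for pep in true_peptides]
    n_foreign = round(foreign_fraction * len(jobs))
    if n_foreign:
        picks = rng.choice(len(true_peptides), size=n_foreign, replace=True)
        for i in picks:
            jobs.append((shuffle_peptide(true_peptides[int(i)], rng, avoid_sequences), True))
    spectra, rows = [], []
    for k, (pep, foreign) in enumerate(jobs):
        mods = ()
        if ox_probability and "M" in pep and rng.random() < ox_probability:
            m_pos = [i + 1 for i, aa in enumerate(pep) if aa == "M"]
            mods = (m_pos[int(rng.integers(len(m_pos)))],)
        z = int(charges[int(rng.integers(len(charges)))])
        mass = peptide_mass(pep, mods)
        mz = precursor_mz(mass, z)
        mz *= 1.0 + rng.normal(0.0, precursor_jitter_ppm) * 1e-6
        b, y = fragment_ions(pep, mods)
        ions = np.concatenate([b, y])
        peaks = [
            (float(i + rng.normal(0.0, mz_jitter_sd)), float(rng.lognormal(4.0, 0.5)))
            for i in ions
        ]
        top = max(float(mz), 1200.0)
        peaks += [
            (float(rng.uniform(100.0, top)), float(rng.lognormal(2.0, 0.5)))
            for _ in range(n_noise_peaks)
        ]
        sid = f"scan={k + 1}"
        spectra.append(Spectrum(sid, float(mz), z, peaks))
        rows.append({"spectrum_id": sid, "peptide": pep,
                     "mods": ",".join(map(str, mods)), "charge": z,
                     "is_foreign": foreign})
    return spectra, pd.DataFrame(rows)


# ------------------------------------------------------- dose response, TCR

def gen_dose_response(ec50, hill, top, bottom, concentrations, noise_sd, seed,
                      n_replicates: int = 3) -> DoseResponse:
    """4PL curve plus Gaussian noise; warns if EC50 sits outside the doses.

    Each concentration is measured ``n_replicates`` times (triplicate wells
    by default, the standard dose-response plate layout), with independent
    noise per well.
    """
    x = np.repeat(np.asarray(concentrations, dtype=float), n_replicates)
    if (x <= 0).any():
        raise ValueError("concentrations must be positive")
    if not x.min() <= ec50 <= x.max():
        import warnings

        warnings.warn("EC50 lies outside the concentration range; fit will extrapolate")
    rng = child_rng(seed, "dose_response")
    r = bottom + (top - bottom) / (1.0 + (ec50 / x) ** hill)
    r = r + rng.normal(0.0, noise_sd, size=len(x))
    return DoseResponse(tuple(x), tuple(float(v) for v in r))


_V_GENES = [f"TRBV{i}" for i in (2, 4, 5, 6, 7, 9, 11, 12, 15, 19, 20, 27, 28, 30)]
_D_GENES = ["TRBD1", "TRBD2"]
_J_GENES = [f"TRBJ{i}-{j}" for i in (1, 2) for j in (1, 2, 3, 5)]


def _random_cdr3(rng) -> str:
    middle = "".join("ACDEFGHIKLMNPQRSTVWY"[int(j)] for j in rng.integers(0, 20, rng.integers(4, 9)))
    return "CASS" + middle + "QYF"


def gen_clonotypes(n_clones: int, planted_expanded, seed: int,
                   total_counts: int = 100_000) -> pd.DataFrame:
    """Clonotype table with planted expanded clones at configured frequencies.

    ``planted_expanded`` is a list of ``(clonotype_dict, frequency)`` pairs
    (frequencies summing to <= 1); the background clones share the
    remaining mass with power-law weights.  Counts are one multinomial draw
    over the whole repertoire; zero-count clones are dropped.
    """
    planted = list(planted_expanded)
    mass = sum(f for _, f in planted)
    if mass > 1.0:
        raise ValueError("planted frequencies must sum to <= 1")
    rng = child_rng(seed, "clonotypes")
    clones = [dict(c) for c, _ in planted]
    for _ in range(n_clones - len(planted)):
        clones.append({
            "cdr3_aa": _random_cdr3(rng),
            "v_gene": _V_GENES[int(rng.integers(len(_V_GENES)))],
            "d_gene": _D_GENES[int(rng.integers(len(_D_GENES)))],
            "j_gene": _J_GENES[int(rng.integers(len(_J_GENES)))],
            "c_gene": "TRBC1",
        })
    background = np.arange(1, n_clones - len(planted) + 1, dtype=float) ** -1.2
    background = background / background.sum() * (1.0 - mass)
    probs = np.array([f for _, f in planted] + background.tolist())
    counts = rng.multinomial(total_counts, probs / probs.sum())
    rows = [dict(c, count=int(n)) for c, n in zip(clones, counts) if n > 0]
    return pd.DataFrame(rows, columns=["cdr3_aa", "v_gene", "d_gene", "j_gene",
                                       "c_gene", "count"])


# ------------------------------------------------------------------ file IO

def write_transcripts_fasta(transcripts, path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.transcript_id} gene={t.gene}\n{t.cds}\n")


def read_transcripts_fasta(path, tpm_table: pd.DataFrame | None = None) -> list:
    from Bio import SeqIO

    tpm_map: dict[str, dict] = {}
    if tpm_table is not None:
        for _, row in tpm_table.iterrows():
            tpm_map.setdefault(row["transcript_id"], {})[row["sample"]] = float(row["tpm"])
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = dict(
            kv.split("=") for kv in rec.description.split()[1:] if "=" in kv
        ).get("gene", rec.id)
        out.append(TranscriptRecord(rec.id, gene, str(rec.seq), tpm_map.get(rec.id, {})))
    return out


def write_tpm_tsv(transcripts, path) -> None:
    rows = [
        {"transcript_id": t.transcript_id, "gene": t.gene, "sample": s, "tpm": v}
        for t in transcripts
        for s, v in sorted(t.tpm.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_variants_tsv(variants, path) -> None:
    rows = [
        {"transcript_id": v.transcript_id, "cds_pos_1based": v.cds_pos, "ref": v.ref,
         "alt": v.alt, "type": v.vtype, "alt_reads": v.alt_reads, "depth": v.depth}
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [
        SomaticVariant(r["transcript_id"], int(r["cds_pos_1based"]), str(r["ref"]),
                       str(r["alt"]), str(r["type"]), int(r["alt_reads"]), int(r["depth"]))
        for _, r in df.iterrows()
    ]


def write_ligandomes_tsv(sets, path) -> None:
    rows = [
        {"sample": s.sample_id, "tissue": s.tissue, "peptide": p}
        for s in sets
        for p in sorted(s.peptides)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_mgf(spectra, path) -> None:
    from pyteomics import mgf

    entries = [
        {
            "m/z array": np.array([mz for mz, _ in sp.peaks]),
            "intensity array": np.array([i for _, i in sp.peaks]),
            "params": {"title": sp.spectrum_id, "pepmass": sp.precursor_mz,
                       "charge": sp.charge},
        }
        for sp in spectra
    ]
    mgf.write(entries, str(path), file_mode="w")


def read_mgf(path) -> list:
    from pyteomics import mgf

    out = []
    with mgf.read(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            charge = int(params["charge"][0])
            peaks = list(zip(entry["m/z array"].tolist(),
                             entry["intensity array"].tolist()))
            pepmass = params["pepmass"]
            mz = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            out.append(Spectrum(str(params["title"]), mz, charge, peaks))
    return out
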