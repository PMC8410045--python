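"""End-to-end orchestration: simulate -> build-db -> predict -> search ->
compare -> assays -> repertoire, with a machine-readable run report.

Each stage writes its outputs under the run directory and the report holds
only counts re-derivable from those files, so stages can be rerun and
audited independently.  Everything is deterministic under the config seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import assays, ligandome, mhcrank, msident, proteodb, repertoire, synthdata
from .synthdata import LigandomeDesign, SimulationConfig, child_rng


@dataclass
class PipelineConfig:
    """One structured config for the whole run; thresholds default to the
    analysis' operating points (%rank 2.0/0.5, FDR 0.01, 10 ppm / 0.02 Da,
    20-fold TAA, 2% clonotype expansion)."""

    seed: int = 0
    n_transcripts: int = 40
    n_missense: int = 25
    n_frameshift: int = 5
    n_spectra: int = 120
    foreign_fraction: float = 0.3
    rank_threshold: float = 2.0
    rank_threshold_strict: float = 0.5
    fdr_alpha: float = 0.01
    prec_tol_ppm: float = 10.0
    frag_tol_da: float = 0.02
    taa_fold_threshold: float = 20.0
    expansion_threshold: float = 0.02
    n_clones: int = 400
    planted_clone_freq: float = 0.027
    ec50_nM: float = 1.5
    hill: float = 1.0
    dose_noise_sd: float = 2.0

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage and return the report (also written as report.json)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    # -- simulate ----------------------------------------------------------
    sim = SimulationConfig(
        seed=config.seed,
        n_transcripts=config.n_transcripts,
        n_missense=config.n_missense,
        n_frameshift=config.n_frameshift,
    )
    transcripts = synthdata.gen_reference(sim)
    variants = synthdata.gen_variants(transcripts, sim)
    synthdata.write_transcripts_fasta(transcripts, out / "transcripts.fasta")
    synthdata.write_tpm_tsv(transcripts, out / "tpm.tsv")
    synthdata.write_variants_tsv(variants, out / "variants.tsv")
    report["stages"]["simulate"] = {
        "n_transcripts": len(transcripts),
        "n_missense": sum(v.vtype == "missense" for v in variants),
        "n_frameshift": sum(v.vtype == "frameshift" for v in variants),
    }

    # -- build-db ----------------------------------------------------------
    entries = proteodb.build_database(transcripts, variants, "tumor")
    proteodb.write_database_fasta(entries, out / "database.fasta", "tumor")
    report["stages"]["build_db"] = {
        "n_entries": len(entries),
        "n_canonical": sum(not e.is_variant_only for e in entries),
        "n_variant": sum(e.is_variant_only for e in entries),
    }

    # -- predict -----------------------------------------------------------
    proteome_freqs = _aa_freqs(entries)
    rank_model = mhcrank.RankModel(aa_freqs=proteome_freqs, seed=7)
    tpm = {t.transcript_id: t.tpm.get("tumor", 0.0) for t in transcripts}
    cands, summary, fraction = mhcrank.predict_neoantigens(
        entries, tpm, rank_model, config.rank_threshold
    )
    cands_strict, _, _ = mhcrank.predict_neoantigens(
        entries, tpm, rank_model, config.rank_threshold_strict
    )
    cands.to_csv(out / "candidates.tsv", sep="\t", index=False)
    summary.to_csv(out / "mutation_summary.tsv", sep="\t", index=False)
    report["stages"]["predict"] = {
        "n_candidates_rank2": len(cands),
        "n_candidates_rank05": len(cands_strict),
        "pct_mutations_with_candidate": fraction,
    }

    # -- search ------------------------------------------------------------
    index = msident.build_index(entries)
    true_peptides = _sample_db_peptides(entries, config, rank_model)
    spectra, truth = synthdata.gen_spectra(
        true_peptides,
        seed=config.seed,
        foreign_fraction=config.foreign_fraction,
        avoid_sequences=[e.sequence for e in entries],
    )
    synthdata.write_mgf(spectra, out / "spectra.mgf")
    truth.to_csv(out / "spectra_truth.tsv", sep="\t", index=False)
    psms = msident.search(spectra, index, config.prec_tol_ppm, config.frag_tol_da)
    accepted = msident.filter_fdr(psms, config.fdr_alpha)
    _write_psms(accepted, out / "psms.tsv")
    report["stages"]["search"] = {
        "n_spectra": len(spectra),
        "n_psms": len(psms),
        "n_accepted_peptides": len(accepted),
        "n_neoantigen_peptides": sum(p.is_neoantigen for p in accepted),
    }

    # -- compare -----------------------------------------------------------
    sets, lig_truth = synthdata.gen_ligandomes(
        transcripts, LigandomeDesign(n_normal_samples=2), seed=config.seed
    )
    synthdata.write_ligandomes_tsv(sets, out / "ligandomes.tsv")
    tumor_set = next(s for s in sets if s.tissue == "tumor")
    normal_sets = [s for s in sets if s.tissue == "normal"]
    overlap = ligandome.overlap_summary(sets)
    shared, tumor_only = ligandome.tumor_normal_partition(tumor_set, normal_sets)
    taa = ligandome.select_taa(
        tumor_only,
        lig_truth["peptide_genes"],
        lig_truth["tpm_tumor"],
        lig_truth["tpm_normal"],
        config.taa_fold_threshold,
    )
    report["stages"]["compare"] = {
        "union": overlap["union"],
        "shared_2plus": overlap["shared_2plus"],
        "tumor_total": len(tumor_set.peptides),
        "shared_or_normal": shared,
        "tumor_only": len(tumor_only),
        "n_taa": len(taa),
        "taa_genes": sorted({t.source_gene for t in taa}),
    }

    # -- assays ------------------------------------------------------------
    doses = tuple(float(c) for c in np.geomspace(0.01, 1000.0, 8))
    dr = synthdata.gen_dose_response(
        config.ec50_nM, config.hill, 100.0, 0.0, doses, config.dose_noise_sd,
        seed=config.seed,
    )
    fit = assays.fit_4pl(dr, seed=config.seed)
    plate = assays.LdhPlate(
        experimental=1.20, effector_spontaneous=0.15, target_minimal=0.20,
        target_maximal=1.60, et_ratio=10.0,
    )
    lysis, _ = assays.ldh_release_pct(plate)
    v0 = variants[0]
    report["stages"]["assays"] = {
        "ec50_nM": fit.ec50,
        "hill": fit.hill,
        "ldh_pct": lysis,
        "vaf_first_variant": assays.vaf(v0.alt_reads, v0.depth),
    }

    # -- repertoire --------------------------------------------------------
    planted = {
        "cdr3_aa": "CASSLGQAYEQYF", "v_gene": "TRBV2", "d_gene": "TRBD1",
        "j_gene": "TRBJ2-7", "c_gene": "TRBC2",
    }
    clones = synthdata.gen_clonotypes(
        config.n_clones, [(planted, config.planted_clone_freq)], seed=config.seed
    )
    clones.to_csv(out / "clonotypes.tsv", sep="\t", index=False)
    freqs = repertoire.clonotype_frequencies(clones)
    expanded = repertoire.expanded_clonotypes(freqs, config.expansion_threshold)
    matches = repertoire.match_clonotype(planted, freqs)
    report["stages"]["repertoire"] = {
        "n_clonotypes": len(freqs),
        "n_expanded": len(expanded),
        "planted_matched": len(matches),
        "planted_frequency": float(matches["frequency"].iloc[0]) if len(matches) else 0.0,
    }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _aa_freqs(entries) -> dict:
    from collections import Counter

    counts = Counter()
    for e in entries:
        counts.update(e.sequence)
    total = sum(counts.values())
    return {aa: c / total for aa, c in counts.items()}


def _sample_db_peptides(entries, config: PipelineConfig, rank_model) -> list:
    """True peptides for spectrum generation: predicted binders from variant
    entries plus random canonical substrings, up to ``n_spectra``."""
    rng = child_rng(config.seed, "spectrum_peptides")
    peptides: list = []
    for e in entries:
        if e.is_variant_only:
            for cand in mhcrank.enumerate_mutant_peptides(e):
                if rank_model.percent_rank(cand.peptide) < config.rank_threshold:
                    peptides.append(cand.peptide)
    rng.shuffle(peptides)
    peptides = list(dict.fromkeys(peptides))[: config.n_spectra // 2]
    canonical = [e for e in entries if not e.is_variant_only]
    while len(peptides) < config.n_spectra and canonical:
        e = canonical[int(rng.integers(len(canonical)))]
        L = int(rng.integers(8, 12))
        if len(e.sequence) < L:
            continue
        start = int(rng.integers(len(e.sequence) - L + 1))
        pep = e.sequence[start : start + L]
        if pep not in peptides:
            peptides.append(pep)
    return peptides


def _write_psms(psms, path) -> None:
    import pandas as pd

    rows = [
        {
            "spectrum_id": p.spectrum_id,
            "peptide": p.peptide,
            "mods": ",".join(map(str, p.mods)),
            "score": p.score,
            "is_decoy": p.is_decoy,
            "q_value": p.q_value,
            "sources": ";".join(e.entry_id for e, _ in p.sources),
            "is_neoantigen": p.is_neoantigen,
        }
        for p in psms
    ]
    pd.DataFrame(rows, columns=["spectrum_id", "peptide", "mods", "score",
                                "is_decoy", "q_value", "sources",
                                "is_neoantigen"]).to_csv(path, sep="\t", index=False)
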