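"""Simplified immunopeptidome MS/MS identification: generate spectra for
database peptides (plus foreign spectra from shuffled peptides), search them
against the target+decoy index, and accept peptides at q <= 0.01."""

from common import stage_args
from neoforge import msident, proteodb, synthdata
from neoforge.pipeline import PipelineConfig, _sample_db_peptides, _write_psms
from neoforge import mhcrank

args = stage_args(__doc__)
entries = proteodb.read_database_fasta(args.results / "database.fasta")
index = msident.build_index(entries)

cfg = PipelineConfig(seed=args.seed)
model = mhcrank.RankModel(seed=7)
true_peptides = _sample_db_peptides(entries, cfg, model)
spectra, truth = synthdata.gen_spectra(
    true_peptides, seed=args.seed, foreign_fraction=cfg.foreign_fraction,
    avoid_sequences=[e.sequence for e in entries],
)
synthdata.write_mgf(spectra, args.results / "spectra.mgf")
truth.to_csv(args.results / "spectra_truth.tsv", sep="\t", index=False)

psms = msident.search(spectra, index, cfg.prec_tol_ppm, cfg.frag_tol_da)
accepted = msident.filter_fdr(psms, cfg.fdr_alpha)
_write_psms(accepted, args.results / "psms.tsv")

truth_peps = set(truth.loc[~truth["is_foreign"], "peptide"])
n_false = sum(p.peptide not in truth_peps for p in accepted)
print(f"searched {len(spectra)} spectra ({truth['is_foreign'].sum()} foreign): "
      f"{len(accepted)} peptides at q<=0.01, "
      f"{sum(p.is_neoantigen for p in accepted)} classified neoantigen, "
      f"{n_false} not among the planted truth "
      f"(empirical FDR {n_false / max(1, len(accepted)):.3f})")
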