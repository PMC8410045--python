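"""Generate the synthetic study inputs: coding transcripts with expression,
somatic variants, tumor/normal ligandomes with planted TAAs, a dose-response
titration, and a clonotype table with a planted expanded clone."""

import numpy as np
import pandas as pd

from common import stage_args
from neoforge import synthdata
from neoforge.synthdata import LigandomeDesign, SimulationConfig

args = stage_args(__doc__)
cfg = SimulationConfig(seed=args.seed, n_transcripts=40, n_missense=25, n_frameshift=5)

transcripts = synthdata.gen_reference(cfg)
variants = synthdata.gen_variants(transcripts, cfg)
synthdata.write_transcripts_fasta(transcripts, args.results / "transcripts.fasta")
synthdata.write_tpm_tsv(transcripts, args.results / "tpm.tsv")
synthdata.write_variants_tsv(variants, args.results / "variants.tsv")

sets, truth = synthdata.gen_ligandomes(
    transcripts, LigandomeDesign(n_normal_samples=2), seed=args.seed
)
synthdata.write_ligandomes_tsv(sets, args.results / "ligandomes.tsv")
pd.DataFrame(
    [{"gene": g, "tumor_tpm": truth["tpm_tumor"][g], "normal_tpm": truth["tpm_normal"][g]}
     for g in sorted(truth["tpm_tumor"])]
).to_csv(args.results / "ligandome_gene_tpm.tsv", sep="\t", index=False)
pd.DataFrame(
    [{"peptide": p, "genes": ";".join(gs)} for p, gs in sorted(truth["peptide_genes"].items())]
).to_csv(args.results / "peptide_genes.tsv", sep="\t", index=False)

doses = np.geomspace(0.01, 1000.0, 8)
dr = synthdata.gen_dose_response(1.5, 1.0, 100.0, 0.0, tuple(doses), noise_sd=2.0,
                                 seed=args.seed)
pd.DataFrame({"concentration": dr.concentrations, "response": dr.responses}).to_csv(
    args.results / "dose_response.tsv", sep="\t", index=False
)

planted = {"cdr3_aa": "CASSLGQAYEQYF", "v_gene": "TRBV2", "d_gene": "TRBD1",
           "j_gene": "TRBJ2-7", "c_gene": "TRBC2"}
clones = synthdata.gen_clonotypes(400, [(planted, 0.027)], seed=args.seed)
clones.to_csv(args.results / "clonotypes.tsv", sep="\t", index=False)

n_zero = sum(t.tpm["tumor"] == 0.0 for t in transcripts)
print(f"simulated {len(transcripts)} transcripts ({n_zero} silent in tumor), "
      f"{sum(v.vtype == 'missense' for v in variants)} missense + "
      f"{sum(v.vtype == 'frameshift' for v in variants)} frameshift variants")
print(f"ligandomes: tumor {len(sets[0].peptides)} peptides, "
      f"{len(truth['shared'])} shared with normals, "
      f"{len(truth['taa_peptides'])} planted TAA peptides "
      f"from genes {truth['taa_genes']}")
print(f"clonotype table: {len(clones)} clones, planted clone at 2.7%")
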