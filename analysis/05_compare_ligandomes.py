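"""Tumor vs. normal immunopeptidome comparison: sharing summary, tumor-only
partition, and >20-fold TAA candidate selection."""

import json

import pandas as pd

from common import stage_args
from neoforge import ligandome as lig

args = stage_args(__doc__)
sets = lig.read_ligandome_tsv(args.results / "ligandomes.tsv")
tumor = next(s for s in sets if s.tissue == "tumor")
normals = [s for s in sets if s.tissue == "normal"]

overlap = lig.overlap_summary(sets)
shared, tumor_only = lig.tumor_normal_partition(tumor, normals)

gene_tpm = pd.read_csv(args.results / "ligandome_gene_tpm.tsv", sep="\t")
tpm_tumor = dict(zip(gene_tpm["gene"], gene_tpm["tumor_tpm"]))
tpm_normal = dict(zip(gene_tpm["gene"], gene_tpm["normal_tpm"]))
pg = pd.read_csv(args.results / "peptide_genes.tsv", sep="\t")
peptide_genes = {r["peptide"]: r["genes"].split(";") for _, r in pg.iterrows()}

taa = lig.select_taa(tumor_only, peptide_genes, tpm_tumor, tpm_normal, 20.0)
pd.DataFrame([t.__dict__ for t in taa]).to_csv(
    args.results / "taa_candidates.tsv", sep="\t", index=False
)
payload = {
    "overlap": overlap,
    "tumor_total": len(tumor.peptides),
    "shared_or_normal": shared,
    "tumor_only": len(tumor_only),
    "n_taa": len(taa),
}
(args.results / "ligandome_summary.json").write_text(
    json.dumps(payload, indent=2, sort_keys=True)
)

pct = 100.0 * shared / len(tumor.peptides)
print(f"{overlap['union']} nonredundant peptides across {len(sets)} samples; "
      f"{overlap['shared_2plus']} ({overlap['shared_2plus_pct']:.1f}%) in >=2 samples")
print(f"tumor: {shared} of {len(tumor.peptides)} ({pct:.1f}%) shared or found in "
      f"normal tissue, {len(tumor_only)} tumor-only")
print(f"{len(taa)} TAA candidates with >20-fold overexpressed source genes: "
      f"{sorted({t.source_gene for t in taa})}")
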