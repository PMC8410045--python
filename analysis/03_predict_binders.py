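"""In-silico neoantigen prediction: enumerate mutation-overlapping 8-11-mers
and keep peptides with binding %rank < 2.0 (and, for comparison, < 0.5)."""

import pandas as pd

from common import stage_args
from neoforge import mhcrank, proteodb

args = stage_args(__doc__)
entries = proteodb.read_database_fasta(args.results / "database.fasta")
tpm_df = pd.read_csv(args.results / "tpm.tsv", sep="\t")
tpm = {r["transcript_id"]: float(r["tpm"])
       for _, r in tpm_df[tpm_df["sample"] == "tumor"].iterrows()}

model = mhcrank.RankModel(seed=7)
loose, summary, fraction = mhcrank.predict_neoantigens(entries, tpm, model, 2.0)
strict, _, _ = mhcrank.predict_neoantigens(entries, tpm, model, 0.5)
loose.to_csv(args.results / "candidates_rank2.tsv", sep="\t", index=False)
strict.to_csv(args.results / "candidates_rank05.tsv", sep="\t", index=False)
summary.to_csv(args.results / "mutation_summary.tsv", sep="\t", index=False)

print(f"predicted {len(loose)} candidates at %rank<2.0 and {len(strict)} at <0.5; "
      f"{fraction:.1f}% of mutations encode at least one candidate")
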