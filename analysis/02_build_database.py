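"""Build the personalized tumor search database: canonical translations of
expressed transcripts plus 30-aa mutation windows, TPM > 0 gated."""

import pandas as pd

from common import stage_args
from neoforge import proteodb, synthdata

args = stage_args(__doc__)
tpm = pd.read_csv(args.results / "tpm.tsv", sep="\t")
transcripts = synthdata.read_transcripts_fasta(args.results / "transcripts.fasta", tpm)
variants = synthdata.read_variants_tsv(args.results / "variants.tsv")

entries = proteodb.build_database(transcripts, variants, "tumor")
proteodb.write_database_fasta(entries, args.results / "database.fasta", "tumor")

n_can = sum(not e.is_variant_only for e in entries)
print(f"database: {len(entries)} entries ({n_can} canonical, "
      f"{len(entries) - n_can} mutation windows); "
      f"{len(transcripts) - n_can} transcripts excluded by the TPM > 0 gate "
      f"or duplicate collapse")
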