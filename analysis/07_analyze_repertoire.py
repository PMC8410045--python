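"""TCRβ repertoire analysis: clonotype frequencies, the >2% expansion
filter, and matching the planted TIL-clone TCR into the repertoire."""

import pandas as pd

from common import stage_args
from neoforge import repertoire as rep

args = stage_args(__doc__)
table = pd.read_csv(args.results / "clonotypes.tsv", sep="\t")
freqs = rep.clonotype_frequencies(table)
expanded = rep.expanded_clonotypes(freqs, 0.02)
expanded.to_csv(args.results / "expanded_clonotypes.tsv", sep="\t", index=False)

planted = {"cdr3_aa": "CASSLGQAYEQYF", "v_gene": "TRBV2", "d_gene": "TRBD1",
           "j_gene": "TRBJ2-7", "c_gene": "TRBC2"}
matches = rep.match_clonotype(planted, freqs)

print(f"{len(freqs)} clonotypes; {len(expanded)} above 2% of the repertoire")
if len(matches):
    print(f"planted TIL clonotype matched at frequency "
          f"{matches['frequency'].iloc[0]:.3%} "
          f"({'expanded' if matches['frequency'].iloc[0] > 0.02 else 'not expanded'})")
else:
    print("planted TIL clonotype not found in the repertoire")
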