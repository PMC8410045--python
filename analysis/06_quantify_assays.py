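"""Functional readouts: 4PL EC50 from the titration, an LDH lysis example,
and variant allele frequencies from the simulated read support."""

import json

import pandas as pd

from common import stage_args
from neoforge import assays, synthdata

args = stage_args(__doc__)
dr_table = pd.read_csv(args.results / "dose_response.tsv", sep="\t")
fit = assays.fit_4pl(
    assays.DoseResponse(tuple(dr_table["concentration"]), tuple(dr_table["response"])),
    seed=args.seed,
)

plate = assays.LdhPlate(experimental=1.20, effector_spontaneous=0.15,
                        target_minimal=0.20, target_maximal=1.60, et_ratio=10.0)
lysis, clipped = assays.ldh_release_pct(plate)

variants = synthdata.read_variants_tsv(args.results / "variants.tsv")
vafs = [{"variant": v.key, "transcript_id": v.transcript_id,
         "vaf": assays.vaf(v.alt_reads, v.depth)} for v in variants]
pd.DataFrame(vafs).to_csv(args.results / "vaf.tsv", sep="\t", index=False)

payload = {"ec50_nM": fit.ec50, "hill": fit.hill, "top": fit.top,
           "bottom": fit.bottom, "ldh_pct": lysis}
(args.results / "assays.json").write_text(json.dumps(payload, indent=2, sort_keys=True))

print(f"EC50 = {fit.ec50:.3g} nM (hill {fit.hill:.2f}), generating curve EC50 = 1.5 nM")
print(f"LDH example plate: {lysis:.1f}% specific lysis")
print(f"VAF range across {len(vafs)} variants: "
      f"{min(v['vaf'] for v in vafs):.3f}-{max(v['vaf'] for v in vafs):.3f}")
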