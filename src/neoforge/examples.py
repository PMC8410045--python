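"""Worked-example inputs: the published minigene inserts and a synthetic
TUBB-like transcript carrying the c.994 A>G (p.T332A) missense variant.

The two 27-nt minigene inserts encode the mutant 9-mer neoantigen RAF9
(RYLAVAAVF) and its wild-type counterpart RTF9 (RYLTVAAVF); they differ by
a single nucleotide that lands at peptide position 4.  The transcript
builder plants the wild-type 9-mer at codons 329-337 of a random coding
sequence so that CDS position 994 is the A of the ACC (Thr-332) codon:
applying c.994 A>G reproduces the Thr->Ala substitution at residue 332.
The surrounding sequence is synthetic; only the planted codons and the
variant arithmetic mirror the published case.
"""

from __future__ import annotations

import numpy as np

from .constants import STOP_CODONS
from .proteodb import SomaticVariant, TranscriptRecord

#: 27-nt minigene insert encoding the mutant neoantigen RAF9 (RYLAVAAVF)
RAF9_MINIGENE = "CGATACCTCGCCGTGGCTGCTGTCTTC"

#: 27-nt minigene insert encoding the wild-type counterpart RTF9 (RYLTVAAVF)
RTF9_MINIGENE = "CGATACCTCACCGTGGCTGCTGTCTTC"

#: variant-supporting / total read counts reported for the tumor and normal tissue
TUMOR_READS = (94, 434)
NORMAL_READS = (0, 544)

_SENSE_CODONS = [
    "".join((a, b, c))
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if "".join((a, b, c)) not in STOP_CODONS
]


def tubb_like_transcript(seed: int = 0, n_codons: int = 450):
    """A synthetic transcript reproducing the c.994 A>G -> p.T332A arithmetic.

    Returns ``(transcript, variant)``: codons 329-337 encode RYLTVAAVF (the
    wild-type 9-mer), CDS position 994 is the first base of the Thr-332
    codon, and the variant carries the reported tumor read support.
    """
    if n_codons < 340:
        raise ValueError("need at least 340 codons to host the planted 9-mer")
    rng = np.random.default_rng(seed)

    def random_codons(n):
        return "".join(_SENSE_CODONS[int(i)] for i in rng.integers(0, len(_SENSE_CODONS), n))

    cds = (
        "ATG"
        + random_codons(327)          # codons 2..328
        + RTF9_MINIGENE               # codons 329..337: R Y L T V A A V F
        + random_codons(n_codons - 338)
        + "TAA"
    )
    transcript = TranscriptRecord(
        "TUBB_like", "TUBB", cds, {"tumor": 474.5, "normal": 474.5}
    )
    assert cds[993] == "A"  # c.994 is the A of the ACC (Thr) codon
    variant = SomaticVariant("TUBB_like", 994, "A", "G", "missense", *TUMOR_READS)
    return transcript, variant
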