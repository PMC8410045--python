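"""Physical constants and shared vocabularies for mass spectrometry and sequences.

Monoisotopic residue masses come from pyteomics' standard table; the
numerical anchors (proton, water, Met oxidation) are frozen here so every
module computes masses from the same values.
"""

from pyteomics import mass as _pmass

#: Monoisotopic mass of a proton (Da), used for m/z <-> neutral-mass conversion.
PROTON = 1.007276466622

#: Monoisotopic mass of water (Da), the peptide-bond condensation remainder.
WATER = 18.0105646863

#: Monoisotopic mass shift of methionine oxidation (Da).
MET_OXIDATION = 15.994915

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: residue -> monoisotopic mass (Da), standard 20 residues only.
RESIDUE_MASS = {aa: _pmass.std_aa_mass[aa] for aa in AMINO_ACIDS}

#: DNA alphabet accepted in coding sequences.
DNA_ALPHABET = frozenset("ACGT")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
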