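"""Personalized proteogenomic search databases.

For each sample the search database holds two sequence sets: (a) canonical
translations of all expressed coding transcripts and (b) mutation-altered
windows, one per somatic variant on an expressed transcript.  A missense
window spans up to 30 residues on either side of the substituted residue;
a frameshift window spans up to 30 residues upstream of the first altered
residue and the entire novel reading frame up to (excluding) the novel stop.
Only transcripts with expression strictly above zero (TPM > 0) contribute
to either set, and exact duplicate sequences are collapsed with merged
provenance.

Coordinates are 1-based throughout: CDS positions follow HGVS c. notation,
residue indices follow p. notation (residue = ceil(cds_pos / 3)), and
``mutated_region`` is a 1-based inclusive interval within an entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

from .constants import DNA_ALPHABET

CANONICAL = "canonical"
MISSENSE_WINDOW = "missense_window"
FRAMESHIFT_WINDOW = "frameshift_window"

#: residues of flanking context retained around an altered residue
DEFAULT_FLANK = 30


@dataclass(frozen=True)
class TranscriptRecord:
    """A coding sequence with per-sample expression.

    ``cds`` runs from the ATG through (and including) the stop codon;
    ``tpm`` maps sample name -> transcript abundance in TPM.
    """

    transcript_id: str
    gene: str
    cds: str
    tpm: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.cds) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {len(self.cds)} not a multiple of 3"
            )
        if set(self.cds) - DNA_ALPHABET:
            raise ValueError(f"{self.transcript_id}: CDS contains non-ACGT characters")
        for sample, v in self.tpm.items():
            if v < 0:
                raise ValueError(f"{self.transcript_id}: negative TPM for {sample}")


@dataclass(frozen=True)
class SomaticVariant:
    """A somatic nucleotide change in CDS coordinates.

    Replacement semantics: the CDS bases at ``cds_pos .. cds_pos+len(ref)-1``
    (1-based) equal ``ref`` and are replaced by ``alt``.  Missense SNVs have
    ``len(ref) == len(alt) == 1``; frameshift indels are anchored on a
    matching base (VCF style) with a length change not divisible by 3.
    """

    transcript_id: str
    cds_pos: int
    ref: str
    alt: str
    vtype: str  # "missense" | "frameshift"
    alt_reads: int = 0
    depth: int = 0

    def __post_init__(self):
        if self.vtype not in ("missense", "frameshift"):
            raise ValueError(f"unknown variant type {self.vtype!r}")
        if self.cds_pos < 1:
            raise ValueError("cds_pos is 1-based and must be >= 1")
        if self.vtype == "missense" and not (len(self.ref) == len(self.alt) == 1):
            raise ValueError("missense variants must be single-nucleotide substitutions")
        if self.vtype == "frameshift" and (len(self.ref) - len(self.alt)) % 3 == 0:
            raise ValueError("frameshift variants must change CDS length by a non-multiple of 3")
        if not 0 <= self.alt_reads <= max(self.depth, 0):
            raise ValueError("require 0 <= alt_reads <= depth")

    @property
    def key(self) -> str:
        """HGVS-flavoured identifier, e.g. ``c.994A>G``."""
        return f"c.{self.cds_pos}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class EntrySource:
    """Provenance of one database entry (merged entries carry several)."""

    provenance: str
    transcript_id: str
    variant_key: str | None = None
    mutated_region: tuple | None = None  # 1-based inclusive within the entry


@dataclass
class ProteinEntry:
    entry_id: str
    sequence: str
    sources: list
    flags: tuple = ()

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty protein entry")
        if "*" in self.sequence:
            raise ValueError("protein entries must not contain stop symbols")
        for s in self.sources:
            if s.mutated_region is not None:
                a, b = s.mutated_region
                if not (1 <= a <= b <= len(self.sequence)):
                    raise ValueError("mutated_region out of bounds")
            if s.provenance == CANONICAL and s.variant_key is not None:
                raise ValueError("canonical entries carry no variant link")

    @property
    def provenance(self) -> str:
        return "+".join(sorted({s.provenance for s in self.sources}))

    @property
    def is_variant_only(self) -> bool:
        """True when every source is a mutation-altered window."""
        return all(s.provenance != CANONICAL for s in self.sources)

    @property
    def mutated_region(self) -> tuple | None:
        for s in self.sources:
            if s.mutated_region is not None:
                return s.mutated_region
        return None


def translate_cds(cds: str, from_codon: int = 1) -> str:
    """Translate a CDS with the standard genetic code, stopping at the first stop.

    Translation starts at codon ``from_codon`` (1-based); a trailing partial
    codon is ignored.  Returns the residues before the first stop codon, or
    every complete codon if no stop occurs.
    """
    if set(cds) - DNA_ALPHABET:
        raise ValueError("CDS contains non-ACGT characters")
    offset = 3 * (from_codon - 1)
    sub = cds[offset:]
    if len(sub) < 3:
        raise ValueError("fewer than one codon downstream of the start offset")
    sub = sub[: len(sub) - len(sub) % 3]
    return str(Seq(sub).translate(to_stop=True))


def apply_variant_to_cds(cds: str, variant: SomaticVariant) -> str:
    """Return the mutant CDS string after applying the replacement."""
    i = variant.cds_pos - 1
    if cds[i : i + len(variant.ref)] != variant.ref:
        raise ValueError(
            f"{variant.key}: reference {variant.ref!r} does not match CDS "
            f"({cds[i:i + len(variant.ref)]!r}) — coordinate or dialect error"
        )
    return cds[:i] + variant.alt + cds[i + len(variant.ref):]


def apply_missense(transcript: TranscriptRecord, variant: SomaticVariant):
    """Apply a missense SNV and return ``(mutant_protein, residue_index)``.

    The residue index is ``ceil(cds_pos / 3)``, matching c./p. notation
    (c.994 falls in codon 332).  Start-loss, stop-loss, nonsense and
    synonymous outcomes are rejected: they are not missense events.
    """
    if variant.vtype != "missense":
        raise ValueError("apply_missense requires a missense variant")
    wt = translate_cds(transcript.cds)
    mutant_cds = apply_variant_to_cds(transcript.cds, variant)
    residue_index = math.ceil(variant.cds_pos / 3)
    if residue_index == 1 and not mutant_cds.startswith("ATG"):
        raise ValueError(f"{variant.key}: start-loss variants are not accepted")
    if residue_index > len(wt):
        raise ValueError(f"{variant.key}: stop-loss or 3'-of-stop variants are not accepted")
    mutant = translate_cds(mutant_cds)
    if len(mutant) < residue_index:
        raise ValueError(f"{variant.key}: nonsense (stop-gain) variants are not accepted")
    if mutant == wt:
        raise ValueError(f"{variant.key}: synonymous at the protein level — invalid input")
    if mutant[residue_index - 1] == wt[residue_index - 1]:
        raise ValueError(f"{variant.key}: protein change is not at residue {residue_index}")
    return mutant, residue_index


def missense_window(
    protein: str,
    residue_index: int,
    *,
    variant: SomaticVariant | None = None,
    transcript_id: str = "",
    entry_id: str | None = None,
    flank: int = DEFAULT_FLANK,
) -> ProteinEntry:
    """Cut the +/- ``flank`` residue window around a substituted residue.

    The window covers residues ``[max(1, i-flank), min(L, i+flank)]`` of the
    mutant protein; ``mutated_region`` marks the altered residue's position
    within the window (position ``flank+1 == 31`` in the interior case).
    """
    L = len(protein)
    if not 1 <= residue_index <= L:
        raise ValueError("residue_index outside the protein")
    lo = max(1, residue_index - flank)
    hi = min(L, residue_index + flank)
    pos_in_window = residue_index - lo + 1
    src = EntrySource(
        MISSENSE_WINDOW,
        transcript_id,
        variant.key if variant is not None else None,
        (pos_in_window, pos_in_window),
    )
    eid = entry_id or f"{transcript_id}|{src.variant_key or 'mw'}"
    return ProteinEntry(eid, protein[lo - 1 : hi], [src])


def frameshift_window(
    transcript: TranscriptRecord,
    variant: SomaticVariant,
    *,
    entry_id: str | None = None,
    flank: int = DEFAULT_FLANK,
) -> ProteinEntry | None:
    """Build the frameshift entry: upstream context plus the novel frame.

    The mutant CDS is retranslated from codon 1; the first altered residue
    ``p`` is the first position where mutant and wild-type translations
    differ.  The entry spans mutant residues ``[max(1, p-flank), C-terminus]``
    with the novel stop excluded and ``mutated_region = [p, end]``.  Returns
    ``None`` when the shifted frame hits a stop immediately (no novel
    residues, hence no mutation-specific sequence).  Entries whose shifted
    frame never reaches a stop before the transcript end are flagged
    ``no_stop``.
    """
    if variant.vtype != "frameshift":
        raise ValueError("frameshift_window requires a frameshift variant")
    wt = translate_cds(transcript.cds)
    mutant_cds = apply_variant_to_cds(transcript.cds, variant)
    mutant = translate_cds(mutant_cds)
    # stop codon is excluded by translate_cds; detect a missing novel stop
    tail = mutant_cds[3 * len(mutant) :]
    has_stop = len(tail) >= 3 and str(Seq(tail[:3]).translate()) == "*"
    p = next(
        (i + 1 for i, (a, b) in enumerate(zip(wt, mutant)) if a != b),
        min(len(wt), len(mutant)) + 1,
    )
    if p > len(mutant):  # immediate stop in the shifted frame: nothing novel
        return None
    lo = max(1, p - flank)
    src = EntrySource(
        FRAMESHIFT_WINDOW,
        transcript.transcript_id,
        variant.key,
        (p - lo + 1, len(mutant) - lo + 1),
    )
    eid = entry_id or f"{transcript.transcript_id}|{variant.key}"
    flags = () if has_stop else ("no_stop",)
    return ProteinEntry(eid, mutant[lo - 1 :], [src], flags)


def variant_entry(transcript: TranscriptRecord, variant: SomaticVariant, flank: int = DEFAULT_FLANK):
    """Dispatch a variant to its window builder; ``None`` if the entry is degenerate."""
    if variant.vtype == "missense":
        mutant, idx = apply_missense(transcript, variant)
        return missense_window(
            mutant, idx, variant=variant, transcript_id=transcript.transcript_id, flank=flank
        )
    return frameshift_window(transcript, variant, flank=flank)


def build_database(
    transcripts,
    variants,
    sample: str,
    *,
    flank: int = DEFAULT_FLANK,
) -> list:
    """Assemble the per-sample database: expressed canonicals + variant windows.

    Transcripts (and variants on transcripts) with ``tpm[sample] == 0`` are
    excluded from both sets; exact duplicate sequences are collapsed with
    merged provenance.  Raises if the resulting database is empty.
    """
    by_id = {t.transcript_id: t for t in transcripts}
    for v in variants:
        if v.transcript_id not in by_id:
            raise KeyError(f"variant {v.key} references unknown transcript {v.transcript_id}")

    by_seq: dict[str, ProteinEntry] = {}

    def add(entry: ProteinEntry):
        if entry.sequence in by_seq:
            prev = by_seq[entry.sequence]
            prev.sources = list(prev.sources) + list(entry.sources)
            prev.flags = tuple(sorted(set(prev.flags) | set(entry.flags)))
        else:
            by_seq[entry.sequence] = entry

    for t in sorted(transcripts, key=lambda t: t.transcript_id):
        if t.tpm.get(sample, 0.0) <= 0.0:
            continue
        protein = translate_cds(t.cds)
        if protein:
            add(ProteinEntry(t.transcript_id, protein, [EntrySource(CANONICAL, t.transcript_id)]))

    for v in sorted(variants, key=lambda v: (v.transcript_id, v.cds_pos, v.alt)):
        t = by_id[v.transcript_id]
        if t.tpm.get(sample, 0.0) <= 0.0:
            continue
        entry = variant_entry(t, v, flank=flank)
        if entry is not None:
            add(entry)

    if not by_seq:
        raise ValueError(f"empty database for sample {sample!r}: no expressed sequences")
    return list(by_seq.values())


def format_header(entry: ProteinEntry, sample: str) -> str:
    """Bit-stable FASTA header: ``{sample}|{provenance}|{transcript}|{variant}|mutreg={a}-{b}``."""
    transcripts = "+".join(sorted({s.transcript_id for s in entry.sources}))
    variant_keys = sorted({s.variant_key for s in entry.sources if s.variant_key})
    var = "+".join(variant_keys) if variant_keys else "NA"
    reg = entry.mutated_region
    mutreg = f"{reg[0]}-{reg[1]}" if reg else "NA"
    head = f"{sample}|{entry.provenance}|{transcripts}|{var}|mutreg={mutreg}"
    if entry.flags:
        head += "|" + ",".join(entry.flags)
    return head


def write_database_fasta(entries, path, sample: str) -> None:
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f">{format_header(e, sample)}\n{e.sequence}\n")


def parse_header(header: str) -> ProteinEntry | None:
    """Inverse of :func:`format_header`; returns sources with string variant keys."""
    parts = header.split("|")
    sample, provenance, transcripts, var, mutreg = parts[:5]
    flags = tuple(parts[5].split(",")) if len(parts) > 5 else ()
    reg = None
    field = mutreg.removeprefix("mutreg=")
    if field != "NA":
        a, b = field.split("-")
        reg = (int(a), int(b))
    sources = []
    variant_keys = [] if var == "NA" else var.split("+")
    for prov in provenance.split("+"):
        if prov == CANONICAL:
            sources.append(EntrySource(CANONICAL, transcripts.split("+")[0]))
        else:
            for vk in variant_keys or [None]:
                sources.append(EntrySource(prov, transcripts.split("+")[0], vk, reg))
    return sources, flags


def read_database_fasta(path) -> list:
    """Read a database FASTA written by :func:`write_database_fasta`."""
    from Bio import SeqIO

    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        sources, flags = parse_header(rec.description)
        entries.append(ProteinEntry(rec.id.split("|")[2], str(rec.seq), sources, flags))
    return entries
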