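"""Tumor vs. normal immunopeptidome comparison and TAA candidate selection.

A ligandome is the set of HLA-presented peptides detected in one tissue.
Comparing tumor and matched-normal ligandomes partitions tumor peptides
into those shared with (or found in) any normal tissue versus tumor-only
candidates; tumor-only peptides whose source genes are strongly
overexpressed in the tumor (>20-fold by default, with a 0.1-TPM
pseudocount against division by zero) become nonmutated tumor-associated
antigen (TAA) candidates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import AMINO_ACIDS

#: pseudocount (TPM) guarding fold changes against zero normal expression
DEFAULT_EPSILON = 0.1


@dataclass
class LigandomeSet:
    sample_id: str
    tissue: str  # "tumor" | "normal"
    peptides: set = field(default_factory=set)

    def __post_init__(self):
        if self.tissue not in ("tumor", "normal"):
            raise ValueError("tissue must be 'tumor' or 'normal'")
        self.peptides = set(self.peptides)
        bad = [p for p in self.peptides if not 8 <= len(p) <= 11]
        if bad:
            raise ValueError(f"ligandome peptides must be 8-11-mers (got {bad[:3]})")


@dataclass(frozen=True)
class TaaCandidate:
    peptide: str
    source_gene: str
    tumor_tpm: float
    normal_tpm: float
    fold_change: float
    normal_zero: bool = False


def overlap_summary(sets) -> dict:
    """Union size, peptides shared by >= 2 samples, and per-sample private counts."""
    sets = list(sets)
    if len(sets) < 2:
        raise ValueError("overlap summary needs at least 2 ligandome sets")
    counts = Counter(p for s in sets for p in set(s.peptides))
    union = len(counts)
    shared = sum(1 for c in counts.values() if c >= 2)
    private = {
        s.sample_id: sum(1 for p in s.peptides if counts[p] == 1) for s in sets
    }
    return {
        "union": union,
        "shared_2plus": shared,
        "shared_2plus_pct": 100.0 * shared / union if union else 0.0,
        "private": private,
    }


def tumor_normal_partition(tumor_set: LigandomeSet, normal_sets):
    """Split tumor peptides into shared-or-normal vs. tumor-only.

    A tumor peptide counts as shared/normal iff it appears in ANY normal
    set; the remainder are the tumor-only candidates.  Returns
    ``(shared_count, tumor_only_set)`` with
    shared + |tumor_only| == |tumor| exactly.
    """
    normal_union = set().union(*(s.peptides for s in normal_sets)) if normal_sets else set()
    tumor_only = set(tumor_set.peptides) - normal_union
    return len(tumor_set.peptides) - len(tumor_only), tumor_only


def select_taa(
    tumor_only,
    peptide_genes: dict,
    tpm_tumor: dict,
    tpm_normal: dict,
    fold_threshold: float = 20.0,
    epsilon: float = DEFAULT_EPSILON,
) -> list:
    """Tumor-only peptides from >``fold_threshold``-fold overexpressed genes.

    ``peptide_genes`` maps peptide -> iterable of source genes; a multi-gene
    peptide is judged by its maximal fold change.  fold =
    tumor_tpm / max(normal_tpm, epsilon); candidates with zero normal TPM
    are flagged ``normal_zero``.
    """
    out = []
    for pep in sorted(tumor_only):
        genes = peptide_genes.get(pep)
        if not genes:
            raise KeyError(f"no source gene mapped for peptide {pep}")
        best = None
        for g in genes:
            if g not in tpm_tumor or g not in tpm_normal:
                raise KeyError(f"missing expression record for gene {g}")
            fold = tpm_tumor[g] / max(tpm_normal[g], epsilon)
            if best is None or fold > best[1]:
                best = (g, fold)
        gene, fold = best
        if fold > fold_threshold:
            out.append(
                TaaCandidate(pep, gene, tpm_tumor[gene], tpm_normal[gene], fold,
                             normal_zero=tpm_normal[gene] == 0.0)
            )
    return out


def motif_summary(peptides, length: int = 9):
    """Length histogram plus a position-frequency matrix for one length.

    Returns ``(length_counts, pfm)`` where ``pfm`` is a 20 x ``length``
    DataFrame (rows = amino acids) with columns summing to 1.
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("empty peptide list")
    length_counts = Counter(len(p) for p in peptides)
    chosen = [p for p in peptides if len(p) == length]
    mat = np.zeros((len(AMINO_ACIDS), length))
    idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for p in chosen:
        for j, aa in enumerate(p):
            mat[idx[aa], j] += 1
    if chosen:
        mat /= len(chosen)
    pfm = pd.DataFrame(mat, index=list(AMINO_ACIDS),
                       columns=[f"P{j + 1}" for j in range(length)])
    return dict(sorted(length_counts.items())), pfm


def read_ligandome_tsv(path) -> list:
    """Read a ligandome table (columns: sample, tissue, peptide) into sets."""
    df = pd.read_csv(path, sep="\t")
    sets = []
    for (sample, tissue), grp in df.groupby(["sample", "tissue"], sort=True):
        sets.append(LigandomeSet(str(sample), str(tissue), set(grp["peptide"])))
    return sets
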