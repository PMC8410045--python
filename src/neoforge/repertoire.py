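"""TCRβ clonotype summaries, the >2% expansion filter, and clone matching.

Clonotype tables are MiXCR-like: CDR3 amino-acid sequence plus V/D/J/C
gene calls and a read/UMI count.  Frequencies are count shares of the
whole repertoire; a clonotype is "expanded" when its frequency strictly
exceeds the threshold (2% by default, i.e. *over* 2%).  Matching a TIL
clone's TCRβ into a tissue repertoire requires equality on CDR3, V and J,
and on D/C only when both records report them.
"""

from __future__ import annotations

import pandas as pd

REQUIRED_COLUMNS = ("cdr3_aa", "v_gene", "j_gene", "count")
OPTIONAL_GENES = ("d_gene", "c_gene")


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"clonotype table missing columns: {missing}")
    if len(table) == 0:
        raise ValueError("empty clonotype table")
    if (table["count"] < 1).any():
        raise ValueError("clonotype counts must be positive integers")
    return table


def clonotype_frequencies(table: pd.DataFrame) -> pd.DataFrame:
    """Annotate each clonotype with its repertoire frequency.

    frequency = count / total count; rows ordered by descending count then
    lexicographic CDR3 for a stable, reproducible layout.
    """
    table = _validate(table).copy()
    table["frequency"] = table["count"] / table["count"].sum()
    return table.sort_values(
        ["count", "cdr3_aa"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def expanded_clonotypes(table: pd.DataFrame, threshold: float = 0.02) -> pd.DataFrame:
    """Clonotypes accounting for strictly more than ``threshold`` of the repertoire."""
    if "frequency" not in table.columns:
        table = clonotype_frequencies(table)
    return table[table["frequency"] > threshold].reset_index(drop=True)


def match_clonotype(query: dict, repertoire: pd.DataFrame) -> pd.DataFrame:
    """Rows of ``repertoire`` matching the query clonotype.

    Requires equality on cdr3_aa, v_gene and j_gene; d_gene/c_gene must
    agree when present (non-empty) on both sides.  An optional
    nucleotide-level CDR3 (``cdr3_nt``) is honored the same way.
    """
    for key in ("cdr3_aa", "v_gene", "j_gene"):
        if not query.get(key):
            raise ValueError(f"query clonotype must define {key}")
    mask = (
        (repertoire["cdr3_aa"] == query["cdr3_aa"])
        & (repertoire["v_gene"] == query["v_gene"])
        & (repertoire["j_gene"] == query["j_gene"])
    )
    for key in (*OPTIONAL_GENES, "cdr3_nt"):
        q = query.get(key)
        if q and key in repertoire.columns:
            present = repertoire[key].notna() & (repertoire[key] != "")
            mask &= ~present | (repertoire[key] == q)
    return repertoire[mask].reset_index(drop=True)
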