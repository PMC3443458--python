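"""1:1 orthology as reciprocal best hits from directional hit tables.

Hits below the bit-score cutoff are discarded; multiple HSPs for a
(query, subject) pair are collapsed to their best score; ties break by
higher bit score, then lower e-value, then lexicographically smallest
subject id.  Self hits (shared id namespaces) are ignored.
"""

from __future__ import annotations

import os

import pandas as pd

from .arrayio import HitTable

DEFAULT_MIN_BITS = 50.0


def best_hits(hits: HitTable, min_bits: float = DEFAULT_MIN_BITS) -> dict[str, str]:
    """Single best subject per query after score filtering and HSP collapse."""
    df = hits.rows
    df = df[(df["bit_score"] >= min_bits) & (df["query_id"] != df["subject_id"])]
    if df.empty:
        return {}
    # collapse HSPs: best (max bits, min e-value) per (query, subject)
    collapsed = (df.groupby(["query_id", "subject_id"], sort=False)
                   .agg(bit_score=("bit_score", "max"), e_value=("e_value", "min"))
                   .reset_index())
    collapsed = collapsed.sort_values(
        ["query_id", "bit_score", "e_value", "subject_id"],
        ascending=[True, False, True, True], kind="mergesort")
    top = collapsed.drop_duplicates("query_id", keep="first")
    return dict(zip(top["query_id"], top["subject_id"]))


def reciprocal_best(map_ab: dict[str, str], map_ba: dict[str, str]
                    ) -> list[tuple[str, str]]:
    """Pairs (a, b) with map_ab[a] == b and map_ba[b] == a, sorted by a."""
    pairs = [(a, b) for a, b in map_ab.items() if map_ba.get(b) == a]
    pairs.sort()
    return pairs


def restrict_to_arrays(pairs: list[tuple[str, str]],
                       genes_on_array_a: set[str],
                       genes_on_array_b: set[str]) -> list[tuple[str, str]]:
    return [(a, b) for a, b in pairs
            if a in genes_on_array_a and b in genes_on_array_b]


def find_orthologs(hits_ab: HitTable, hits_ba: HitTable,
                   min_bits: float = DEFAULT_MIN_BITS) -> list[tuple[str, str]]:
    return reciprocal_best(best_hits(hits_ab, min_bits), best_hits(hits_ba, min_bits))


def write_pairs(pairs: list[tuple[str, str]], path: str | os.PathLike) -> None:
    pd.DataFrame(pairs, columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)


def read_pairs(path: str | os.PathLike) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return list(df[["gene_a", "gene_b"]].itertuples(index=False, name=None))
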