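"""Scaffold-to-Muller-element assignment from gene-hit tables.

Scaffolds of a draft assembly inherit their Muller element from the
reference genes they carry: hits are filtered to scores strictly above a
threshold, each query gene keeps only its single best location, and each
scaffold takes the element held by the majority of its genes.  Scaffolds
whose top elements tie are excluded.  Reciprocal-best-hit pairing builds
1:1 ortholog tables for the expression analyses.
"""

from __future__ import annotations

import pandas as pd

#: sentinel labels used in the assigned_element column
EXCLUDED_TIE = "EXCLUDED_TIE"
UNASSIGNED = "UNASSIGNED"
UNKNOWN_ELEMENT = "unknown"

HIT_COLUMNS = ("query_gene_id", "scaffold_id", "score", "gene_element")


def filter_hits(hits: pd.DataFrame, min_score: float = 50.0) -> pd.DataFrame:
    """Keep hits scoring strictly above ``min_score``, then each gene's
    single highest-scoring hit.

    A gene whose two top hits tie on score is dropped entirely: a tied best
    location is ambiguous and carries no positional information.
    """
    if hits.empty:
        return hits.copy()
    kept = hits[hits["score"] > min_score]
    if kept.empty:
        return kept.copy()
    best = kept.groupby("query_gene_id")["score"].transform("max")
    kept = kept[kept["score"] == best]
    # drop genes with a tied best score
    n_best = kept.groupby("query_gene_id")["query_gene_id"].transform("size")
    return kept[n_best == 1].reset_index(drop=True)


def assign_scaffold_elements(filtered_hits: pd.DataFrame) -> pd.DataFrame:
    """Majority-vote element per scaffold from best-hit-filtered genes.

    Genes with an unknown reference element count toward ``n_genes`` but cast
    no vote.  An exact tie among the top vote counts yields ``EXCLUDED_TIE``;
    a scaffold whose genes are all of unknown element yields ``UNASSIGNED``.
    Scaffolds with no hits do not appear (callers treat them as unassigned).

    Returns a table with scaffold_id, assigned_element, n_genes and one
    ``votes_<element>`` column per element observed.
    """
    cols = ["scaffold_id", "assigned_element", "n_genes"]
    if filtered_hits.empty:
        return pd.DataFrame(columns=cols)

    n_genes = filtered_hits.groupby("scaffold_id").size().rename("n_genes")
    voting = filtered_hits[filtered_hits["gene_element"] != UNKNOWN_ELEMENT]
    votes = (
        voting.groupby(["scaffold_id", "gene_element"]).size().unstack(fill_value=0)
        if not voting.empty
        else pd.DataFrame(index=n_genes.index)
    )
    votes = votes.reindex(n_genes.index, fill_value=0)

    def _verdict(row: pd.Series) -> str:
        if row.empty or row.max() == 0:
            return UNASSIGNED
        top = row.max()
        winners = row[row == top]
        return winners.index[0] if len(winners) == 1 else EXCLUDED_TIE

    assigned = votes.apply(_verdict, axis=1) if not votes.empty else pd.Series(
        UNASSIGNED, index=n_genes.index
    )
    out = pd.DataFrame(
        {"scaffold_id": n_genes.index, "assigned_element": assigned.values,
         "n_genes": n_genes.values}
    )
    for el in sorted(votes.columns):
        out[f"votes_{el}"] = votes[el].values
    return out.sort_values("scaffold_id", kind="mergesort").reset_index(drop=True)


def pair_orthologs(hits_forward: pd.DataFrame, hits_reverse: pd.DataFrame) -> pd.DataFrame:
    """1:1 ortholog pairs by reciprocal best hit.

    Both inputs must already be best-hit filtered (one hit per query).  A pair
    (a, b) is emitted iff a's best hit is b and b's best hit is a; each gene
    therefore appears in at most one pair.  In the forward table the query is
    the focal-species gene and the subject (scaffold_id column) the reference
    gene, and vice versa in the reverse table.
    """
    cols = ["gene_a", "gene_b"]
    if hits_forward.empty or hits_reverse.empty:
        return pd.DataFrame(columns=cols)
    fwd = hits_forward[["query_gene_id", "scaffold_id"]].rename(
        columns={"query_gene_id": "gene_a", "scaffold_id": "gene_b"}
    )
    rev = hits_reverse[["query_gene_id", "scaffold_id"]].rename(
        columns={"query_gene_id": "gene_b", "scaffold_id": "gene_a"}
    )
    pairs = fwd.merge(rev, on=["gene_a", "gene_b"], how="inner")
    return pairs.drop_duplicates().sort_values(cols, kind="mergesort").reset_index(drop=True)


def read_gene_hits(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene-hit table missing columns: {sorted(missing)}")
    return df


def write_assignments(assignments: pd.DataFrame, path) -> None:
    assignments.to_csv(path, sep="\t", index=False)


def read_assignments(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
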