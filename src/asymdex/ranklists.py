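"""Top-k gene-list overlap and its hypergeometric significance.

Two analyses of the same collection produce ranked gene lists; the
size of the intersection of their top-k genes, referred to a
hypergeometric null over a shared gene universe of size N, measures how
strongly the methods agree beyond chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

__all__ = [
    "RankedGeneList",
    "OverlapReport",
    "topk_overlap",
    "hypergeom_overlap_p",
    "overlap_grid",
]


@dataclass
class RankedGeneList:
    """Genes ordered by decreasing |score|, with their scores."""

    genes: list[str]
    scores: list[float]
    tag: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must align")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def top(self, k: int) -> list[str]:
        return self.genes[: min(k, len(self.genes))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.genes) + 1),
                "gene_id": self.genes,
                "score": self.scores,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, tag: str = "") -> "RankedGeneList":
        df = pd.read_csv(path, sep="\t")
        return cls(genes=list(df["gene_id"]), scores=list(df["score"]), tag=tag)


def rank_genes(scores: pd.Series, k: int, tag: str = "") -> RankedGeneList:
    """Top-k genes by |score|, descending; ties broken by gene id.

    When fewer than k genes are available the full list is returned
    (a list may legitimately be shorter than the nominal cutoff, e.g.
    when only 338 genes pass a significance filter against a 400 cutoff).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = pd.DataFrame({"gene_id": scores.index, "score": scores.to_numpy(dtype=float)})
    df["abs"] = df["score"].abs()
    df = df.sort_values(["abs", "gene_id"], ascending=[False, True], kind="mergesort")
    df = df.head(min(k, len(df)))
    return RankedGeneList(genes=list(df["gene_id"]), scores=list(df["score"]), tag=tag)


def topk_overlap(a: RankedGeneList, b: RankedGeneList, k: int) -> int:
    """Size of the intersection of the two lists' top-k genes."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return len(set(a.top(k)) & set(b.top(k)))


def hypergeom_overlap_p(overlap: int, k1: int, k2: int, n_universe: int) -> float:
    """Upper-tail P(X >= overlap) for the overlap of two fixed-size lists.

    X is hypergeometric: ``n_universe`` genes, ``k1`` marked, ``k2`` drawn.
    Summed in log space so tail probabilities far below float underflow of
    individual terms (p < 1e-200) remain accurate.
    """
    if not (0 <= overlap <= min(k1, k2) <= n_universe):
        raise ValueError(
            f"inconsistent counts: overlap={overlap}, k1={k1}, k2={k2}, N={n_universe}"
        )
    if overlap == 0:
        return 1.0
    support = np.arange(overlap, min(k1, k2) + 1)
    logp = hypergeom.logpmf(support, n_universe, k1, k2)
    return float(np.exp(logsumexp(logp)))


@dataclass
class OverlapReport:
    """Overlap of two ranked lists over a grid of cutoffs."""

    tag_a: str
    tag_b: str
    universe_size: int
    rows: pd.DataFrame = field(default_factory=pd.DataFrame)
    # rows columns: k, k_eff_a, k_eff_b, overlap, p


def overlap_grid(
    a: RankedGeneList,
    b: RankedGeneList,
    ks: Sequence[int],
    n_universe: int,
) -> OverlapReport:
    """Overlap and hypergeometric p at each cutoff in ``ks``.

    Cutoffs exceeding a list's length are truncated to it and the
    effective k recorded per list.
    """
    if list(ks) != sorted(set(ks)):
        raise ValueError("ks must be strictly increasing")
    records = []
    for k in ks:
        ka, kb = min(k, len(a)), min(k, len(b))
        ov = topk_overlap(a, b, k)
        records.append(
            {
                "k": k,
                "k_eff_a": ka,
                "k_eff_b": kb,
                "overlap": ov,
                "p": hypergeom_overlap_p(ov, ka, kb, n_universe),
            }
        )
    return OverlapReport(
        tag_a=a.tag, tag_b=b.tag, universe_size=n_universe, rows=pd.DataFrame(records)
    )
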