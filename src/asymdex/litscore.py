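"""Literature-hit enrichment of a ranked gene list.

A gene counts as a *hit* when an offline gene-to-abstract-count table
records at least one qualifying abstract for it (the canonical query per
gene being ``<SYMBOL> AND cancer NOT microarray``; only its formatting is
provided here — no network access ever happens).  The observed number of
hits in a list is referred to a resampling null: the same count over
random equal-size gene lists drawn from the platform's universe, whose
mean and standard deviation parameterise a normal upper-tail p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .ranklists import RankedGeneList

__all__ = [
    "LitScoreReport",
    "build_query",
    "load_hit_table",
    "save_hit_table",
    "annotate_hits",
    "random_list_null",
    "lit_pvalue",
    "score_list",
]


@dataclass
class LitScoreReport:
    """Literature-enrichment verdict for one ranked list."""

    tag: str
    list_size: int
    observed_hits: int
    null_mean: float
    null_sd: float
    p: float
    n_iterations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "tag": self.tag,
            "list_size": self.list_size,
            "observed_hits": self.observed_hits,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "p": self.p,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
        }


def build_query(gene_symbol: str) -> str:
    """Format the per-gene abstract query; no lookup is performed.

    The symbol is used verbatim (no case folding); embedded whitespace is
    rejected since it would silently change the query semantics.
    """
    if not gene_symbol:
        raise ValueError("gene symbol must be non-empty")
    if any(c.isspace() for c in gene_symbol):
        raise ValueError(f"gene symbol contains whitespace: {gene_symbol!r}")
    return f"{gene_symbol} AND cancer NOT microarray"


def load_hit_table(path: str | Path) -> dict[str, int]:
    """Read ``gene_id<TAB>abstract_count`` rows."""
    table: dict[str, int] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, count = line.split("\t")[:2]
            table[gene] = int(count)
    return table


def save_hit_table(table: Mapping[str, int], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for gene in sorted(table):
            fh.write(f"{gene}\t{table[gene]}\n")


def annotate_hits(genes: Sequence[str] | RankedGeneList, hits: Mapping[str, int]) -> int:
    """Count list genes with at least one qualifying abstract.

    Genes absent from the hit table count as zero hits (a platform
    universe always exceeds any curated table).
    """
    if isinstance(genes, RankedGeneList):
        genes = genes.genes
    return sum(1 for g in genes if hits.get(g, 0) >= 1)


def random_list_null(
    universe: Sequence[str],
    list_size: int,
    hits: Mapping[str, int],
    n_iter: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean and SD of the hit count over random equal-size gene lists.

    Lists are drawn uniformly without replacement from the universe;
    the SD uses the n-1 denominator.
    """
    universe = sorted(universe)
    if list_size > len(universe):
        raise ValueError("list_size exceeds the universe")
    if n_iter < 2:
        raise ValueError("need >= 2 iterations for a standard deviation")
    rng = np.random.default_rng(seed)
    is_hit = np.array([hits.get(g, 0) >= 1 for g in universe])
    counts = np.empty(n_iter)
    for b in range(n_iter):
        idx = rng.choice(len(universe), size=list_size, replace=False)
        counts[b] = is_hit[idx].sum()
    return float(counts.mean()), float(counts.std(ddof=1))


def lit_pvalue(observed: int, null_mean: float, null_sd: float) -> float:
    """Upper-tail normal p for the observed hit count against the null."""
    if null_sd < 0:
        raise ValueError("null_sd must be >= 0")
    if null_sd == 0:
        return 0.0 if observed > null_mean else 1.0
    return float(norm.sf(observed, loc=null_mean, scale=null_sd))


def score_list(
    genes: Sequence[str] | RankedGeneList,
    universe: Sequence[str],
    hits: Mapping[str, int],
    n_iter: int = 100,
    seed: int = 0,
) -> LitScoreReport:
    """Full literature score of one gene list.

    Null lists always use the list's *effective* size — a list truncated
    below its nominal cutoff (e.g. 338 significant genes against a 400
    cutoff) is compared against random lists of 338 genes.
    """
    tag = genes.tag if isinstance(genes, RankedGeneList) else ""
    gene_seq = genes.genes if isinstance(genes, RankedGeneList) else list(genes)
    observed = annotate_hits(gene_seq, hits)
    null_mean, null_sd = random_list_null(universe, len(gene_seq), hits, n_iter, seed)
    return LitScoreReport(
        tag=tag,
        list_size=len(gene_seq),
        observed_hits=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        p=lit_pvalue(observed, null_mean, null_sd),
        n_iterations=n_iter,
        seed=seed,
    )
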