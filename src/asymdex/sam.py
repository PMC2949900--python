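"""Two-class unpaired significance analysis of microarrays (SAM).

The statistic for gene i is the moderated difference

    d_i = r_i / (s_i + s0)

with ``r_i`` the disease-minus-normal mean difference, ``s_i`` the
gene-specific scatter

    s_i = sqrt{ (1/n1 + 1/n2) * [ SS_1 + SS_2 ] / (n1 + n2 - 2) }

(SS_k the within-class sums of squared deviations), and ``s0`` a small
"fudge" constant chosen to minimise the coefficient of variation of d's
spread across the range of s — stabilising scores of low-variance genes.

Significance is assessed against a label-permutation null: samples are
relabelled (ignoring study membership, so samples merged from many
studies exchange freely), d is recomputed with the observed s0, and the
expected order statistics of d define, for a chosen threshold delta, the
called gene set and an estimated false discovery rate (the median number
of permuted scores falling beyond the calling cutoffs, over the number of
genes called).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb, inf
from typing import Mapping

import numpy as np
import pandas as pd

from .manifest import DISEASE, NORMAL
from .ranklists import RankedGeneList, rank_genes

__all__ = [
    "SamConfig",
    "SamResult",
    "sam_scores",
    "estimate_s0",
    "permutation_null",
    "call_genes",
    "run_sam",
    "rank_genes",
]


@dataclass
class SamConfig:
    """Test parameters.

    ``s0_method``: ``"tusher_percentile"`` (CV-minimising percentile
    search), ``"zero"`` (plain t-like statistic), or
    ``("fixed_percentile", q)`` to pin s0 at the q-th percentile of s.
    ``fdr_target`` is the estimated-FDR level at which genes are called;
    0 asks for the largest call set whose estimated FDR is exactly 0
    under the finite permutation set.
    """

    n_permutations: int = 100
    s0_method: object = "tusher_percentile"
    fdr_target: float = 0.0
    seed: int = 0
    pi0_scaling: bool = False  # multiply FDR by a null-proportion estimate

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 <= self.fdr_target <= 1:
            raise ValueError("fdr_target must lie in [0, 1]")


def _split_labels(
    table: pd.DataFrame, labels: Mapping[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    missing = [s for s in table.columns if s not in labels]
    if missing:
        raise KeyError(f"samples without class labels: {missing[:5]}")
    lab = np.array([labels[s] for s in table.columns])
    bad = set(lab) - {NORMAL, DISEASE}
    if bad:
        raise ValueError(f"unknown class labels: {sorted(bad)}")
    return np.flatnonzero(lab == DISEASE), np.flatnonzero(lab == NORMAL)


def _scores_from_matrix(
    values: np.ndarray, dis_idx: np.ndarray, norm_idx: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n1, n2 = len(dis_idx), len(norm_idx)
    x1 = values[:, dis_idx]
    x2 = values[:, norm_idx]
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    r = m1 - m2
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    denom = s + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, r / np.where(denom > 0, denom, 1.0), 0.0)
    return r, s, d


def sam_scores(
    table: pd.DataFrame, labels: Mapping[str, str], s0: float = 0.0
) -> pd.DataFrame:
    """Per-gene numerator r, scatter s and score d = r/(s+s0).

    Requires at least two samples per class.  Genes with s + s0 = 0 get
    d = 0 (no evidence either way from a zero-variance gene).
    """
    dis_idx, norm_idx = _split_labels(table, labels)
    if len(dis_idx) < 2 or len(norm_idx) < 2:
        raise ValueError(
            f"each class needs >= 2 samples, got {len(dis_idx)} disease "
            f"and {len(norm_idx)} normal"
        )
    r, s, d = _scores_from_matrix(table.to_numpy(dtype=float), dis_idx, norm_idx, s0)
    return pd.DataFrame({"r": r, "s": s, "d": d}, index=table.index)


def estimate_s0(r: np.ndarray, s: np.ndarray, n_windows: int = 100) -> float:
    """Fudge factor minimising the coefficient of variation of d's spread.

    Candidates are the percentiles {0, 5, ..., 100} of s.  For each
    candidate the genes are windowed by s-quantile and the median absolute
    deviation of d = r/(s+s0) computed per window; the candidate whose
    window MADs have the smallest CV wins.  Fully deterministic.
    """
    r = np.asarray(r, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.ptp(s) == 0:
        return 0.0
    candidates = np.percentile(s, np.arange(0, 101, 5))
    order = np.argsort(s, kind="mergesort")
    n = len(s)
    n_windows = min(n_windows, n)
    bounds = np.linspace(0, n, n_windows + 1).astype(int)
    best_s0, best_cv = 0.0, inf
    for s0 in candidates:
        denom = s[order] + s0
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(denom > 0, r[order] / np.where(denom > 0, denom, 1.0), 0.0)
        mads = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if hi > lo:
                w = d[lo:hi]
                mads.append(np.median(np.abs(w - np.median(w))))
        mads = np.asarray(mads)
        mean = mads.mean()
        if mean == 0:
            continue
        cv = mads.std(ddof=1) / mean if len(mads) > 1 else 0.0
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _resolve_s0(config: SamConfig, r: np.ndarray, s: np.ndarray) -> float:
    method = config.s0_method
    if method == "zero":
        return 0.0
    if method == "tusher_percentile":
        return estimate_s0(r, s)
    if isinstance(method, tuple) and method[0] == "fixed_percentile":
        return float(np.percentile(s, method[1]))
    raise ValueError(f"unknown s0_method {method!r}")


def _enumerate_arrangements(n: int, n1: int) -> list[np.ndarray]:
    return [np.array(c) for c in combinations(range(n), n1)]


def permutation_null(
    table: pd.DataFrame,
    labels: Mapping[str, str],
    config: SamConfig,
    s0: float,
) -> np.ndarray:
    """Row-sorted d scores under label permutation; shape (B, n_genes).

    When the number of distinct label arrangements C(n, n1) is at most
    10x the requested permutation count, arrangements are drawn uniformly
    without replacement (all of them if few enough); otherwise sampled
    with replacement.  s0 is held fixed at the observed-data value.
    """
    dis_idx, norm_idx = _split_labels(table, labels)
    values = table.to_numpy(dtype=float)
    n = values.shape[1]
    n1 = len(dis_idx)
    rng = np.random.default_rng(config.seed)
    total = comb(n, n1)
    if total <= 10 * config.n_permutations:
        arrangements = _enumerate_arrangements(n, n1)
        if total > config.n_permutations:
            keep = rng.choice(total, size=config.n_permutations, replace=False)
            arrangements = [arrangements[i] for i in sorted(keep)]
    else:
        arrangements = []
        for _ in range(config.n_permutations):
            arrangements.append(rng.choice(n, size=n1, replace=False))
    null = np.empty((len(arrangements), values.shape[0]))
    all_idx = np.arange(n)
    for b, dis in enumerate(arrangements):
        dis = np.asarray(dis)
        norm = np.setdiff1d(all_idx, dis)
        _, _, d = _scores_from_matrix(values, dis, norm, s0)
        null[b] = np.sort(d)
    return null


def call_genes(
    observed: pd.Series, null: np.ndarray, delta: float
) -> tuple[set[str], float, tuple[float, float]]:
    """SAM delta-thresholding: called genes, estimated FDR, and cutoffs.

    The observed scores are ordered and compared with the permutation-mean
    order statistics d-bar.  The smallest ordered score whose deviation
    exceeds +delta sets the upper cutoff (all genes scoring at or above it
    are called up-regulated); the largest whose deviation falls below
    -delta sets the lower cutoff.  The estimated FDR is the median, over
    permutations, of the count of permuted scores beyond the cutoffs,
    divided by the number of called genes (0/0 -> 0).
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    order = np.argsort(observed.to_numpy(), kind="mergesort")
    d_sorted = observed.to_numpy()[order]
    dbar = null.mean(axis=0)
    diff = d_sorted - dbar
    up = np.flatnonzero(diff > delta)
    lo = np.flatnonzero(diff < -delta)
    cut_up = d_sorted[up[0]] if up.size else inf
    cut_lo = d_sorted[lo[-1]] if lo.size else -inf
    if cut_up <= cut_lo:
        # degenerate overlap of the two calling regions; tighten to keep
        # the calls disjoint by score
        mid = (cut_up + cut_lo) / 2
        cut_up = np.nextafter(mid, inf)
        cut_lo = np.nextafter(mid, -inf)
    called_mask = (observed.to_numpy() >= cut_up) | (observed.to_numpy() <= cut_lo)
    called = set(observed.index[called_mask])
    if called:
        false_counts = ((null >= cut_up) | (null <= cut_lo)).sum(axis=1)
        fdr = float(np.median(false_counts)) / len(called)
    else:
        fdr = 0.0
    return called, fdr, (cut_lo, cut_up)


def _pi0(observed: np.ndarray, null: np.ndarray) -> float:
    q25, q75 = np.percentile(null, [25, 75])
    inside = np.sum((observed > q25) & (observed < q75))
    return min(1.0, 2.0 * inside / len(observed))


@dataclass
class SamResult:
    """Everything a SAM run produces."""

    scores: pd.DataFrame  # columns r, s, d; index gene_id
    s0: float
    delta_table: pd.DataFrame  # columns delta, n_called, median_false, fdr
    delta_used: float
    called_genes: set[str] = field(default_factory=set)
    fdr: float = 0.0
    ranking: RankedGeneList | None = None


def run_sam(
    table: pd.DataFrame,
    labels: Mapping[str, str],
    config: SamConfig | None = None,
    top_k: int = 400,
    n_delta_grid: int = 50,
) -> SamResult:
    """Full SAM analysis of one (possibly merged) expression table.

    Scores, fudge factor, permutation null, a delta table over a grid of
    thresholds, the call set at the smallest delta achieving the target
    estimated FDR, and the top-k ranking by |d| restricted to called
    genes (falling back to all genes when nothing is called).
    """
    config = config or SamConfig()
    scores = sam_scores(table, labels, s0=0.0)
    s0 = _resolve_s0(config, scores["r"].to_numpy(), scores["s"].to_numpy())
    denom = scores["s"] + s0
    scores["d"] = np.where(denom > 0, scores["r"] / denom.where(denom > 0, 1.0), 0.0)
    null = permutation_null(table, labels, config, s0)

    d = scores["d"]
    dbar = null.mean(axis=0)
    dev = np.abs(np.sort(d.to_numpy()) - dbar)
    deltas = np.unique(
        np.quantile(dev[dev > 0], np.linspace(0, 1, n_delta_grid))
        if np.any(dev > 0)
        else np.array([0.0])
    )
    pi0 = _pi0(d.to_numpy(), null) if config.pi0_scaling else 1.0
    rows = []
    best = None  # smallest delta meeting the FDR target
    for delta in deltas:
        called, fdr, _ = call_genes(d, null, float(delta))
        fdr *= pi0
        rows.append(
            {
                "delta": float(delta),
                "n_called": len(called),
                "median_false": fdr * len(called),
                "fdr": fdr,
            }
        )
        if best is None and fdr <= config.fdr_target and called:
            best = (float(delta), called, fdr)
    if best is None:
        best = (float(deltas[-1]), set(), 0.0)
    delta_used, called, fdr = best
    ranked_pool = d.loc[sorted(called)] if called else d
    ranking = rank_genes(ranked_pool, top_k, tag="SAM")
    return SamResult(
        scores=scores,
        s0=s0,
        delta_table=pd.DataFrame(rows),
        delta_used=delta_used,
        called_genes=called,
        fdr=fdr,
        ranking=ranking,
    )
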