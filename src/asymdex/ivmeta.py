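"""Fixed-effect inverse-variance meta-analysis of standardized effects.

Each symmetric study contributes, per gene, the standardized mean
difference

    d = (xbar_disease - xbar_normal) / s,
    s = sqrt{ [(n1-1) s1^2 + (n2-1) s2^2] / (n1 + n2 - 2) }

with the usual large-sample variance

    var(d) = (n1 + n2)/(n1 n2) + d^2 / (2 (n1 + n2)).

Studies are pooled per gene with weights 1/var(d); the pooled effect's
normal z gives a two-sided p, thresholded by Benjamini-Hochberg.  This
engine requires every study to contain both classes — an asymmetric
study has no within-study contrast and is rejected with an explicit
error, which is exactly the limitation merged analyses work around.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .manifest import DISEASE, NORMAL
from .ranklists import RankedGeneList, rank_genes

__all__ = [
    "study_effect",
    "effect_variance",
    "hedges_correction",
    "iv_pool",
    "fdr_threshold",
    "run_ivmeta",
]


class AsymmetricStudyError(ValueError):
    """Raised when a study lacking one class is offered to the IV engine."""


def _class_matrices(table: pd.DataFrame, labels: Mapping[str, str]):
    lab = []
    for s in table.columns:
        if s not in labels:
            raise KeyError(f"sample {s!r} has no class label")
        lab.append(labels[s])
    lab = np.array(lab)
    dis = table.to_numpy(dtype=float)[:, lab == DISEASE]
    nor = table.to_numpy(dtype=float)[:, lab == NORMAL]
    return dis, nor


def study_effect(
    table: pd.DataFrame, labels: Mapping[str, str], study_id: str = ""
) -> pd.DataFrame:
    """Per-gene standardized effect of one study (disease minus normal).

    Returns a DataFrame indexed by gene with columns
    ``d, var_d, n1, n2, s``; genes whose pooled SD is exactly 0 get
    ``d = NaN`` and are excluded from pooling with a warning.
    """
    dis, nor = _class_matrices(table, labels)
    n1, n2 = dis.shape[1], nor.shape[1]
    if n1 < 2 or n2 < 2:
        raise AsymmetricStudyError(
            f"study {study_id or '<unnamed>'}: inverse-variance pooling needs "
            f">= 2 samples per class, got {n1} disease / {n2} normal"
        )
    m1, m2 = dis.mean(axis=1), nor.mean(axis=1)
    v1 = dis.var(axis=1, ddof=1)
    v2 = nor.var(axis=1, ddof=1)
    s = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(s > 0, (m1 - m2) / np.where(s > 0, s, 1.0), np.nan)
    if np.isnan(d).any():
        warnings.warn(
            f"{int(np.isnan(d).sum())} gene(s) with zero pooled SD flagged "
            "undefined and excluded from pooling"
        )
    out = pd.DataFrame({"d": d, "n1": n1, "n2": n2, "s": s}, index=table.index)
    out["var_d"] = effect_variance(out["d"].to_numpy(), n1, n2)
    if study_id:
        out["study_id"] = study_id
    return out


def effect_variance(d: np.ndarray | float, n1: int, n2: int) -> np.ndarray | float:
    """Large-sample variance of a standardized mean difference."""
    if n1 < 2 or n2 < 2:
        raise ValueError("variance of d requires >= 2 samples per class")
    return (n1 + n2) / (n1 * n2) + np.square(d) / (2 * (n1 + n2))


def hedges_correction(d: np.ndarray | float, n1: int, n2: int):
    """Small-sample (Hedges' g) shrinkage factor applied to d; optional."""
    j = 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0)
    return d * j


def iv_pool(effects: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Pool per-study effect tables gene-by-gene with weights 1/var(d).

    Genes measured by only some studies are pooled over the studies that
    measure them; ``k_studies`` records how many contributed.  Genes with
    no usable (finite) effect anywhere are omitted with a warning.
    Returns columns ``pooled_d, se, z, p, k_studies``.
    """
    long = pd.concat(effects, axis=0)
    long = long[np.isfinite(long["d"])]
    if long.empty:
        raise ValueError("no usable study effects to pool")
    w = 1.0 / long["var_d"]
    grouped = pd.DataFrame({"wd": w * long["d"], "w": w}).groupby(long.index)
    agg = grouped.sum()
    k = grouped.size()
    pooled = agg["wd"] / agg["w"]
    se = 1.0 / np.sqrt(agg["w"])
    z = pooled / se
    p = 2.0 * norm.sf(np.abs(z))
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    out = pd.DataFrame(
        {"pooled_d": pooled, "se": se, "z": z, "p": p, "k_studies": k}
    ).sort_index()
    n_total = len(set().union(*[set(e.index) for e in effects]))
    if len(out) < n_total:
        warnings.warn(f"{n_total - len(out)} gene(s) had no usable effect and were omitted")
    return out


def fdr_threshold(p: pd.Series, q_star: float) -> tuple[set[str], pd.Series]:
    """Benjamini-Hochberg step-up at level ``q_star``.

    Returns the significant gene set and the per-gene adjusted q values.
    """
    if not 0 < q_star < 1:
        raise ValueError("q_star must lie in (0, 1)")
    reject, q, _, _ = multipletests(p.to_numpy(), alpha=q_star, method="fdr_bh")
    qs = pd.Series(q, index=p.index, name="q")
    return set(p.index[reject]), qs


def run_ivmeta(
    tables: Sequence[pd.DataFrame],
    labels: Sequence[Mapping[str, str]],
    study_ids: Sequence[str] | None = None,
    q_star: float = 1e-5,
    top_k: int = 400,
    hedges: bool = False,
) -> tuple[pd.DataFrame, RankedGeneList]:
    """Per-study effects -> inverse-variance pooling -> BH -> top-k ranking.

    The ranking is by |pooled d| restricted to BH-significant genes and
    truncated to ``top_k`` — so the returned list may be shorter than the
    nominal cutoff when fewer genes pass.  Default ``q_star`` of 1e-5
    corresponds to an FDR of 0.001%.
    """
    if study_ids is None:
        study_ids = [f"study{i + 1}" for i in range(len(tables))]
    effects = []
    for table, lab, sid in zip(tables, labels, study_ids):
        eff = study_effect(table, lab, study_id=sid)
        if hedges:
            eff["d"] = hedges_correction(eff["d"].to_numpy(), eff["n1"].iat[0], eff["n2"].iat[0])
            eff["var_d"] = effect_variance(eff["d"].to_numpy(), eff["n1"].iat[0], eff["n2"].iat[0])
        effects.append(eff)
    meta = iv_pool(effects)
    sig, q = fdr_threshold(meta["p"], q_star)
    meta["q"] = q
    meta["significant"] = meta.index.isin(sig)
    pool = meta.loc[meta["significant"], "pooled_d"]
    if pool.empty:
        pool = meta["pooled_d"].iloc[0:0]
    ranking = rank_genes(pool, top_k, tag="IV") if not pool.empty else RankedGeneList([], [], tag="IV")
    return meta, ranking
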