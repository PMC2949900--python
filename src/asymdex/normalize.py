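"""RMA-style preprocessing and frozen-reference normalization.

Two preprocessing routes are provided for probe-level intensity tables:

* :func:`rma_summarize` — classic per-cohort RMA: background adjustment,
  quantile normalization across the cohort's arrays, log2 transform, and
  per-gene median polish.
* :func:`refrma_train` / :func:`refrma_apply` — frozen-reference RMA:
  a training cohort fixes a reference quantile vector and per-probe
  affinity estimates; new arrays are then normalized one at a time
  against those frozen vectors, so arrays from many studies end up on a
  common scale and can be merged before testing.

The underlying additive model on the log2 scale is

    T(PM_ij) = e_i + a_j + eps_ij

with ``e_i`` the expression of array i (per gene), ``a_j`` the affinity of
probe j, and ``eps_ij`` noise; median polish estimates ``e`` and ``a``
robustly.

Tables are pandas DataFrames: probes/genes on the index, samples on the
columns; probe tables hold linear-scale intensities, expression tables
log2-scale values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import json

import numpy as np
import pandas as pd

from .manifest import PlatformMap

__all__ = [
    "ReferenceModel",
    "QQStat",
    "background_adjust",
    "quantile_normalize",
    "median_polish",
    "rma_summarize",
    "refrma_train",
    "refrma_apply",
    "qq_concordance",
]

#: linear-intensity floor keeping log2 defined after background subtraction
INTENSITY_FLOOR = 1.0


@dataclass
class ReferenceModel:
    """Frozen vectors produced by training on a reference cohort.

    ``reference_quantiles`` is the mean sorted (background-adjusted) intensity
    vector over the training arrays; ``probe_affinities`` holds the per-probe
    log2 affinity effects ``a_j``, median-centred within each gene.
    """

    platform_id: str
    probe_affinities: pd.Series  # index: probe_id, log2 units
    reference_quantiles: np.ndarray  # non-decreasing, linear scale
    probe_to_gene: Mapping[str, str]
    n_training_arrays: int

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "model.json").write_text(
            json.dumps(
                {
                    "platform_id": self.platform_id,
                    "n_training_arrays": self.n_training_arrays,
                }
            )
        )
        self.probe_affinities.rename("affinity").to_frame().assign(
            gene_id=[self.probe_to_gene[p] for p in self.probe_affinities.index]
        ).to_csv(directory / "probe_affinities.tsv", sep="\t", index_label="probe_id")
        pd.Series(self.reference_quantiles, name="intensity").to_csv(
            directory / "reference_quantiles.tsv", sep="\t", index=False
        )

    @classmethod
    def load(cls, directory: str | Path) -> "ReferenceModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        aff = pd.read_csv(directory / "probe_affinities.tsv", sep="\t", index_col="probe_id")
        quants = pd.read_csv(directory / "reference_quantiles.tsv", sep="\t")["intensity"]
        return cls(
            platform_id=meta["platform_id"],
            probe_affinities=aff["affinity"],
            reference_quantiles=quants.to_numpy(),
            probe_to_gene=aff["gene_id"].to_dict(),
            n_training_arrays=int(meta["n_training_arrays"]),
        )


@dataclass(frozen=True)
class QQStat:
    """Concordance of two samples' empirical distributions."""

    max_abs_quantile_diff: float  # log2 units
    quantile_correlation: float  # Pearson r of the paired quantiles


def background_adjust(table: pd.DataFrame, offset: float = 0.0) -> pd.DataFrame:
    """Subtract a constant background, flooring at 1 so log2 stays defined."""
    if offset < 0:
        raise ValueError("background offset must be non-negative")
    return (table - offset).clip(lower=INTENSITY_FLOOR)


def _map_to_sorted_target(column: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Assign sorted target values to a column by rank; ties get the mean
    of their target quantiles, so the result is permutation-invariant."""
    order = np.argsort(column, kind="mergesort")
    out = np.empty_like(target, dtype=float)
    out[order] = target
    # average target values over tied input blocks
    vals = column[order]
    boundaries = np.flatnonzero(np.diff(vals) != 0) + 1
    for lo, hi in zip(np.r_[0, boundaries], np.r_[boundaries, len(vals)]):
        if hi - lo > 1:
            out[order[lo:hi]] = target[lo:hi].mean()
    return out


def quantile_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the across-column mean empirical distribution.

    After normalization each column's sorted values equal the row-wise mean
    of the columns' sorted values; within-column ranks are preserved and
    tied values receive the mean of their target quantiles.
    """
    if table.shape[1] < 2:
        raise ValueError(
            "quantile normalization needs >= 2 samples; use refrma_apply "
            "with a trained ReferenceModel to normalize a single array"
        )
    values = table.to_numpy(dtype=float)
    target = np.sort(values, axis=0).mean(axis=1)
    out = np.column_stack(
        [_map_to_sorted_target(values[:, j], target) for j in range(values.shape[1])]
    )
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def median_polish(
    block: np.ndarray, max_iter: int = 10, tol: float = 0.01
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Tukey median polish of a probes x arrays block (log2 scale).

    Decomposes ``block[j, i] ~ m + a[j] + e[i]`` with probe effects ``a``
    median-centred.  Iteration alternates row- and column-median sweeps and
    stops when both sweeps move less than ``tol`` or after ``max_iter``
    rounds.

    Returns ``(array_effects e, probe_effects a, overall m, residuals)``.
    """
    resid = np.asarray(block, dtype=float).copy()
    n_probes, n_arrays = resid.shape
    row = np.zeros(n_probes)  # probe effects a_j
    col = np.zeros(n_arrays)  # array effects e_i
    overall = 0.0
    for _ in range(max_iter):
        row_med = np.median(resid, axis=1)
        row += row_med
        resid -= row_med[:, None]
        col_adj = np.median(col)
        overall += col_adj
        col -= col_adj

        col_med = np.median(resid, axis=0)
        col += col_med
        resid -= col_med[None, :]
        row_adj = np.median(row)
        overall += row_adj
        row -= row_adj
        if np.abs(row_med).max() < tol and np.abs(col_med).max() < tol:
            break
    return col, row, overall, resid


def _check_probes_mapped(probes: pd.Index, pmap: PlatformMap) -> None:
    orphans = [p for p in probes if p not in pmap.probe_to_gene]
    if orphans:
        raise KeyError(f"probes absent from platform map: {orphans[:10]}"
                       + (" ..." if len(orphans) > 10 else ""))


def _gene_blocks(probes: pd.Index, pmap: PlatformMap) -> dict[str, list[str]]:
    blocks: dict[str, list[str]] = {}
    for p in probes:
        blocks.setdefault(pmap.probe_to_gene[p], []).append(p)
    return {g: blocks[g] for g in sorted(blocks)}


def rma_summarize(
    table: pd.DataFrame,
    pmap: PlatformMap,
    offset: float = 0.0,
    max_iter: int = 10,
    tol: float = 0.01,
) -> pd.DataFrame:
    """Classic per-cohort RMA: background -> quantile -> log2 -> median polish.

    The gene-level value for array i is ``m + e_i`` from the per-gene polish.
    """
    _check_probes_mapped(table.index, pmap)
    adj = background_adjust(table, offset)
    if table.shape[1] >= 2:
        adj = quantile_normalize(adj)
    log_table = np.log2(adj)
    blocks = _gene_blocks(table.index, pmap)
    rows = {}
    for gene, probes in blocks.items():
        e, _, m, _ = median_polish(
            log_table.loc[probes].to_numpy(), max_iter=max_iter, tol=tol
        )
        rows[gene] = m + e
    out = pd.DataFrame.from_dict(rows, orient="index", columns=table.columns)
    return out.sort_index()


def refrma_train(
    tables: Sequence[pd.DataFrame],
    pmap: PlatformMap,
    offset: float = 0.0,
    max_iter: int = 10,
    tol: float = 0.01,
) -> ReferenceModel:
    """Fit the frozen reference vectors on a training cohort.

    All training arrays (across all supplied tables) are pooled: the
    reference quantile vector is the mean sorted background-adjusted
    intensity vector, and the probe affinities come from per-gene median
    polish of the pooled quantile-normalized log2 data.
    """
    if not tables:
        raise ValueError("need at least one training table")
    probes = tables[0].index
    for t in tables[1:]:
        if not t.index.equals(probes):
            raise ValueError("training tables have inconsistent probe sets")
    _check_probes_mapped(probes, pmap)
    pooled = pd.concat(tables, axis=1)
    if pooled.shape[1] < 2:
        raise ValueError("need >= 2 training arrays")
    adj = background_adjust(pooled, offset)
    reference_quantiles = np.sort(adj.to_numpy(), axis=0).mean(axis=1)
    log_table = np.log2(quantile_normalize(adj))
    affinities = pd.Series(0.0, index=probes)
    for gene, gene_probes in _gene_blocks(probes, pmap).items():
        _, a, _, _ = median_polish(
            log_table.loc[gene_probes].to_numpy(), max_iter=max_iter, tol=tol
        )
        affinities.loc[gene_probes] = a
    return ReferenceModel(
        platform_id=pmap.platform_id,
        probe_affinities=affinities,
        reference_quantiles=reference_quantiles,
        probe_to_gene=dict(pmap.probe_to_gene),
        n_training_arrays=pooled.shape[1],
    )


def refrma_apply(
    table: pd.DataFrame, model: ReferenceModel, offset: float = 0.0
) -> pd.DataFrame:
    """Normalize arrays one at a time against a frozen reference model.

    Each array is background-adjusted, rank-mapped onto the reference
    quantile vector (linearly interpolated when the array carries fewer
    probes than the reference), log2-transformed, and summarized per gene
    as the median of ``log2(value) - a_j`` over the gene's probes.  Arrays
    are processed independently: adding an array never changes another's
    output.
    """
    unknown = [p for p in table.index if p not in model.probe_affinities.index]
    if unknown:
        raise KeyError(f"probes absent from reference model: {unknown[:10]}")
    n = table.shape[0]
    ref = model.reference_quantiles
    if n == len(ref):
        target = ref
    else:
        # empirical quantile function of the reference, evaluated at the
        # array's n plotting positions
        target = np.interp(
            np.linspace(0, 1, n), np.linspace(0, 1, len(ref)), ref
        )
    aff = model.probe_affinities.loc[table.index].to_numpy()
    blocks: dict[str, list[int]] = {}
    for i, p in enumerate(table.index):
        blocks.setdefault(model.probe_to_gene[p], []).append(i)
    genes = sorted(blocks)
    out = np.empty((len(genes), table.shape[1]))
    adj = background_adjust(table, offset).to_numpy()
    for j in range(table.shape[1]):
        mapped = _map_to_sorted_target(adj[:, j], target)
        corrected = np.log2(mapped) - aff
        for gi, gene in enumerate(genes):
            out[gi, j] = np.median(corrected[blocks[gene]])
    return pd.DataFrame(out, index=genes, columns=table.columns)


def qq_concordance(x: Sequence[float], y: Sequence[float]) -> QQStat:
    """Compare two samples' distributions on the quantile-quantile scale.

    Evaluates both empirical quantile functions at ``min(len(x), len(y))``
    evenly spaced probabilities (linear interpolation) and reports the
    maximum absolute difference and the Pearson correlation of the pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n = min(x.size, y.size)
    probs = np.linspace(0, 1, n)
    qx = np.quantile(x, probs)
    qy = np.quantile(y, probs)
    if np.ptp(qx) == 0 or np.ptp(qy) == 0:
        corr = 1.0 if np.allclose(qx - qx.mean(), qy - qy.mean()) else 0.0
    else:
        corr = float(np.corrcoef(qx, qy)[0, 1])
    return QQStat(
        max_abs_quantile_diff=float(np.abs(qx - qy).max()),
        quantile_correlation=corr,
    )
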