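"""Workflow orchestration: merged-SAM and meta-analysis end to end.

Three workflows cover the standard study designs:

* ``iv`` — per-study standardized effects pooled by inverse variance
  (symmetric studies only; asymmetric input is an error by design).
* ``sam_symmetric`` — merge the symmetric studies' samples into one table
  and run a single SAM test on the pooled two-class design.
* ``sam_all`` — the same merge, but additionally admitting asymmetric
  (single-condition) studies, which is the point of the merged approach.

A design-perturbation experiment turns every symmetric study asymmetric
in all 2**k ways, reruns the merged analysis per variant, and scores the
resulting lists against the literature-hit null — probing how much the
merged test depends on having a symmetric core.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io
from .litscore import LitScoreReport, lit_pvalue, random_list_null, score_list
from .manifest import (
    DISEASE,
    NORMAL,
    Manifest,
    classify_studies,
    enumerate_asymmetric_variants,
    load_manifest,
)
from .ranklists import RankedGeneList, rank_genes
from .sam import SamConfig, SamResult, run_sam, sam_scores
from .ivmeta import run_ivmeta

__all__ = [
    "RunConfig",
    "merge_tables",
    "merged_sam",
    "run_workflow",
    "run_asymmetric_experiment",
]

WORKFLOWS = ("iv", "sam_symmetric", "sam_all")


@dataclass
class RunConfig:
    """File-based run description (also loadable from YAML)."""

    manifest: str
    expr_dir: str
    workflow: str  # iv | sam_symmetric | sam_all
    out_dir: str
    tissue: str | None = None
    top_k: int = 400
    q_star: float = 1e-5
    n_permutations: int = 100
    fdr_target: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.workflow not in WORKFLOWS:
            raise ValueError(f"workflow must be one of {WORKFLOWS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def merge_tables(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Column-concatenate per-study tables over their common genes.

    Genes are intersected (merging across platforms sacrifices genes not
    shared by all) and returned in lexicographic order.
    """
    if not tables:
        raise ValueError("nothing to merge")
    genes = set(tables[0].index)
    for t in tables[1:]:
        genes &= set(t.index)
    if not genes:
        raise ValueError("merged studies share no genes")
    order = sorted(genes)
    return pd.concat([t.loc[order] for t in tables], axis=1)


def _merge_labels(label_maps: Sequence[Mapping[str, str]]) -> dict[str, str]:
    merged: dict[str, str] = {}
    for m in label_maps:
        merged.update(m)
    return merged


def _normalize_merged(merged: pd.DataFrame, normalization: str | None) -> pd.DataFrame:
    """Put all merged samples on a common distribution before testing.

    Merging studies only makes sense once every sample shares one scale;
    with gene-level input this is a joint quantile normalization of the
    merged columns (the gene-level analogue of normalizing every array
    against one frozen reference).  ``None`` skips it, for input already
    on a common scale (e.g. the output of ``refrma_apply``).
    """
    if normalization is None or normalization == "none":
        return merged
    if normalization == "quantile":
        from .normalize import quantile_normalize

        return quantile_normalize(merged)
    raise ValueError(f"unknown merged normalization {normalization!r}")


def merged_sam(
    tables: Sequence[pd.DataFrame],
    label_maps: Sequence[Mapping[str, str]],
    config: SamConfig | None = None,
    top_k: int = 400,
    normalization: str | None = "quantile",
) -> SamResult:
    """One SAM test over the pooled samples of many studies.

    Study-level location shifts (lab effects) are confounded with class
    once asymmetric studies join the merge, so by default the merged
    columns are jointly quantile-normalized before testing; pass
    ``normalization=None`` when the input is already reference-normalized.
    """
    merged = _normalize_merged(merge_tables(tables), normalization)
    return run_sam(merged, _merge_labels(label_maps), config=config, top_k=top_k)


def _labels_from_manifest(manifest: Manifest) -> dict[str, str]:
    return {s.sample_id: s.class_label for s in manifest.samples}


def _load_study_tables(
    manifest: Manifest, expr_dir: str | Path
) -> tuple[list[str], list[pd.DataFrame], list[dict[str, str]]]:
    expr_dir = Path(expr_dir)
    ids, tables, label_maps = [], [], []
    for sid in sorted(manifest.studies):
        table = io.read_table(expr_dir / f"{sid}.tsv")
        members = {s.sample_id: s.class_label for s in manifest.study_samples(sid)}
        keep = [c for c in table.columns if c in members]
        ids.append(sid)
        tables.append(table[keep])
        label_maps.append({c: members[c] for c in keep})
    return ids, tables, label_maps


def run_workflow(config: RunConfig) -> dict:
    """Execute one workflow from files; returns an artifact bundle summary.

    Writes ``ranked.tsv`` (rank, gene_id, score) and ``report.json`` under
    ``out_dir``; every artifact records the config digest and seed.
    """
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = load_manifest(config.manifest)
    if config.tissue is not None:
        manifest = manifest.subset(tissue=config.tissue)
    parts = classify_studies(manifest)
    if config.workflow == "sam_symmetric":
        manifest = manifest.subset(studies=parts["symmetric"])
    elif config.workflow == "iv":
        asym = parts["disease_only"] + parts["normal_only"]
        if asym:
            raise ValueError(
                f"inverse-variance meta-analysis cannot use asymmetric "
                f"studies: {asym} (use a merged SAM workflow instead)"
            )
    ids, tables, label_maps = _load_study_tables(manifest, config.expr_dir)

    report: dict = {
        "workflow": config.workflow,
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_studies": len(ids),
        "n_samples": manifest.n_samples,
    }
    if config.workflow == "iv":
        meta, ranking = run_ivmeta(
            tables, label_maps, study_ids=ids, q_star=config.q_star, top_k=config.top_k
        )
        meta.to_csv(out_dir / "ivmeta.tsv", sep="\t", index_label="gene_id")
        report["n_significant"] = int(meta["significant"].sum())
    else:
        sam_cfg = SamConfig(
            n_permutations=config.n_permutations,
            fdr_target=config.fdr_target,
            seed=config.seed,
        )
        result = merged_sam(tables, label_maps, config=sam_cfg, top_k=config.top_k)
        ranking = result.ranking
        result.delta_table.to_csv(out_dir / "delta_table.tsv", sep="\t", index=False)
        report["s0"] = result.s0
        report["n_called"] = len(result.called_genes)
        report["fdr"] = result.fdr
    ranking.to_tsv(out_dir / "ranked.tsv")
    report["n_ranked"] = len(ranking)
    report["elapsed_s"] = round(time.time() - t0, 3)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report


def _rank_only_sam(
    tables: Sequence[pd.DataFrame],
    label_maps: Sequence[Mapping[str, str]],
    top_k: int,
    normalization: str | None = "quantile",
) -> RankedGeneList:
    """Merged SAM scoring + ranking without the permutation machinery."""
    merged = _normalize_merged(merge_tables(tables), normalization)
    scores = sam_scores(merged, _merge_labels(label_maps), s0=0.0)
    from .sam import estimate_s0  # local import avoids cycle at module load

    s0 = estimate_s0(scores["r"].to_numpy(), scores["s"].to_numpy())
    d = scores["r"] / (scores["s"] + s0)
    return rank_genes(d, top_k, tag="SAM")


def run_asymmetric_experiment(
    tables: Sequence[pd.DataFrame],
    label_maps: Sequence[Mapping[str, str]],
    hits: Mapping[str, int],
    universe: Sequence[str],
    top_k: int = 400,
    n_iter: int = 100,
    seed: int = 0,
    rank_only: bool = True,
    sam_config: SamConfig | None = None,
) -> dict:
    """Purely-asymmetric design perturbation, literature-scored.

    Every symmetric study is stripped of one condition in all 2**k ways;
    each feasible variant (still >= 2 samples per class after merging) is
    re-analysed, its top-k list annotated with literature hits, and the
    average hit count referred to the random-list null.  Returns the per-
    variant hit counts, their mean, and the derived p-value.
    """
    merged_labels = _merge_labels(label_maps)
    # reconstruct a manifest-like view: one study per table
    from .manifest import SampleRecord, manifest_from_samples

    records = []
    for i, (table, labs) in enumerate(zip(tables, label_maps)):
        for s in table.columns:
            records.append(SampleRecord(s, f"study{i + 1}", "t", labs[s], "sim"))
    manifest = manifest_from_samples(records)
    k_sym = len(classify_studies(manifest)["symmetric"])
    if k_sym > 12:
        raise ValueError(
            f"{k_sym} symmetric studies imply 2^{k_sym} variants; "
            "downsample the design or sample variants instead"
        )
    variants = enumerate_asymmetric_variants(manifest)
    hit_counts: list[int] = []
    list_sizes: list[int] = []
    for variant in variants:
        keep = {s.sample_id for s in variant.samples}
        v_tables = [t[[c for c in t.columns if c in keep]] for t in tables]
        v_tables = [t for t in v_tables if t.shape[1] > 0]
        v_labels = {s: merged_labels[s] for t in v_tables for s in t.columns}
        counts = pd.Series(v_labels).value_counts()
        if counts.get(NORMAL, 0) < 2 or counts.get(DISEASE, 0) < 2:
            warnings.warn("skipping variant without two samples of each class")
            continue
        maps = [{c: v_labels[c] for c in t.columns} for t in v_tables]
        if rank_only:
            ranking = _rank_only_sam(v_tables, maps, top_k)
        else:
            ranking = merged_sam(v_tables, maps, config=sam_config, top_k=top_k).ranking
        report = score_list(ranking, universe, hits, n_iter=n_iter, seed=seed)
        hit_counts.append(report.observed_hits)
        list_sizes.append(report.list_size)
    if not hit_counts:
        raise ValueError("no feasible asymmetrized variant")
    mean_hits = float(np.mean(hit_counts))
    null_mean, null_sd = random_list_null(
        universe, int(round(np.mean(list_sizes))), hits, n_iter=n_iter, seed=seed
    )
    return {
        "n_variants": len(hit_counts),
        "hit_counts": hit_counts,
        "mean_hits": mean_hits,
        "null_mean": null_mean,
        "null_sd": null_sd,
        "p": lit_pvalue(mean_hits, null_mean, null_sd),
    }
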