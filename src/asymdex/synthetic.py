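"""Seeded generators for multi-study two-class expression data.

The gene-level generator emulates the structure merged-analysis methods
must cope with: several studies ("labs") measuring the same genes, each
with its own additive location shift on the log2 scale, a two-class
design of arbitrary asymmetry (any mix of normal and disease samples,
including none of one class), and a planted fraction of differentially
expressed genes with specified standardized effects.

The probe-level generator adds Affymetrix-like probe structure on top:
each gene is measured by several probes whose linear intensity follows

    PM_ij = 2 ** (e_i + a_j + eps_ij) + background

with a probe affinity ``a_j`` drawn once and held fixed across arrays —
exactly the additive model the RMA/frozen-reference normalizers estimate.

A companion generator produces an offline gene-to-literature hit table in
which planted DE genes are enriched for hits, for exercising the
literature-score validation statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .manifest import DISEASE, NORMAL, PlatformMap

__all__ = [
    "StudyDesign",
    "SimConfig",
    "SimTruth",
    "simulate_gene_level",
    "simulate_probe_level",
    "simulate_hit_table",
]


@dataclass(frozen=True)
class StudyDesign:
    """One simulated study: tissue tag, class sizes, and lab-shift scale."""

    tissue: str
    n_normal: int
    n_disease: int
    study_shift_sd: float = 0.5  # log2 units


@dataclass
class SimConfig:
    """Parameters of the multi-study simulation.

    Effects are standardized: a DE gene's class-mean difference equals
    ``delta_g * noise_sd`` log2 units, so ``delta_g`` is directly
    comparable to a standardized mean difference d.
    """

    n_genes: int = 1000
    probes_per_gene: int = 4
    studies: Sequence[StudyDesign] = field(
        default_factory=lambda: (
            StudyDesign("tissue1", 10, 10),
            StudyDesign("tissue2", 10, 10),
            StudyDesign("tissue3", 10, 10),
        )
    )
    de_fraction: float = 0.05
    effect_mean: float = 1.5  # mean |delta| in within-class-SD units
    effect_sd: float = 0.0
    probe_affinity_sd: float = 0.5  # log2 units
    noise_sd: float = 0.25  # within-class log2 SD
    background_mean: float = 0.0  # linear intensity units
    background_sd: float = 0.0
    baseline_mean: float = 8.0  # log2 units, centre of gene baselines
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.probes_per_gene < 1:
            raise ValueError("probes_per_gene must be >= 1")
        for name in ("effect_sd", "probe_affinity_sd", "noise_sd", "background_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SimTruth:
    """Ground truth of a simulation: which genes are DE and how strongly."""

    de_genes: set[str]
    effect_by_gene: dict[str, float]  # signed delta in SD units; 0 for non-DE


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


def _plant_truth(config: SimConfig, rng: np.random.Generator) -> tuple[list[str], SimTruth, np.ndarray]:
    genes = _gene_ids(config.n_genes)
    n_de = round(config.de_fraction * config.n_genes)
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    delta = np.zeros(config.n_genes)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    delta[de_idx] = signs * rng.normal(config.effect_mean, config.effect_sd, size=n_de)
    truth = SimTruth(
        de_genes={genes[i] for i in de_idx},
        effect_by_gene={g: float(d) for g, d in zip(genes, delta)},
    )
    return genes, truth, delta


def _study_gene_values(
    config: SimConfig,
    design: StudyDesign,
    baseline: np.ndarray,
    delta: np.ndarray,
    rng: np.random.Generator,
    study_id: str,
) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Noise-free-per-sample mean matrix plus sample ids and labels."""
    shift = rng.normal(0.0, design.study_shift_sd) if design.study_shift_sd > 0 else 0.0
    sample_ids = [f"{study_id}_N{i + 1:03d}" for i in range(design.n_normal)] + [
        f"{study_id}_C{i + 1:03d}" for i in range(design.n_disease)
    ]
    labels = {
        s: (NORMAL if i < design.n_normal else DISEASE) for i, s in enumerate(sample_ids)
    }
    n = len(sample_ids)
    means = np.tile((baseline + shift)[:, None], (1, n))
    means[:, design.n_normal:] += (delta * config.noise_sd)[:, None]
    return means, sample_ids, labels


def simulate_gene_level(
    config: SimConfig,
) -> tuple[list[pd.DataFrame], list[dict[str, str]], SimTruth]:
    """Generate per-study log2 expression tables.

    Returns one genes x samples DataFrame per study, the matching
    per-study ``{sample_id: class}`` label maps, and the planted truth.
    Identical config (including seed) reproduces identical output.
    """
    rng = np.random.default_rng(config.seed)
    genes, truth, delta = _plant_truth(config, rng)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    tables: list[pd.DataFrame] = []
    label_maps: list[dict[str, str]] = []
    for k, design in enumerate(config.studies):
        means, sample_ids, labels = _study_gene_values(
            config, design, baseline, delta, rng, f"study{k + 1}"
        )
        noise = rng.normal(0.0, config.noise_sd, size=means.shape) if config.noise_sd > 0 else 0.0
        tables.append(pd.DataFrame(means + noise, index=genes, columns=sample_ids))
        label_maps.append(labels)
    return tables, label_maps, truth


def simulate_probe_level(
    config: SimConfig,
    return_gene_values: bool = False,
):
    """Generate per-study linear-intensity probe tables.

    Probe j of gene g on array i has intensity
    ``2**(e_gi + a_j + eps_ij) + max(0, N(background_mean, background_sd))``
    where ``e_gi`` is the gene-level log2 value (same model as
    :func:`simulate_gene_level`) and the affinity ``a_j`` is drawn once per
    probe and shared by every array.  Also returns the probe-to-gene
    platform map.
    """
    rng = np.random.default_rng(config.seed)
    genes, truth, delta = _plant_truth(config, rng)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    P = config.probes_per_gene
    probe_ids = [f"{g}_p{j + 1}" for g in genes for j in range(P)]
    if config.probe_affinity_sd > 0:
        affinities = rng.normal(0.0, config.probe_affinity_sd, size=len(probe_ids))
        # median-centre within each gene: affinities and gene values are only
        # jointly identifiable, and the summarizers use this same convention
        affinities -= np.median(affinities.reshape(config.n_genes, P), axis=1).repeat(P)
    else:
        affinities = np.zeros(len(probe_ids))
    pmap = PlatformMap(
        platform_id="simchip",
        probe_to_gene={p: p.rsplit("_p", 1)[0] for p in probe_ids},
    )
    tables: list[pd.DataFrame] = []
    label_maps: list[dict[str, str]] = []
    gene_values: list[pd.DataFrame] = []
    for k, design in enumerate(config.studies):
        means, sample_ids, labels = _study_gene_values(
            config, design, baseline, delta, rng, f"study{k + 1}"
        )
        gene_values.append(pd.DataFrame(means, index=genes, columns=sample_ids))
        e = np.repeat(means, P, axis=0)  # probes x samples gene value
        eps = rng.normal(0.0, config.noise_sd, size=e.shape) if config.noise_sd > 0 else 0.0
        intensity = np.exp2(e + affinities[:, None] + eps)
        if config.background_sd > 0 or config.background_mean > 0:
            bg = rng.normal(config.background_mean, config.background_sd, size=e.shape)
            intensity = intensity + np.maximum(bg, 0.0)
        tables.append(pd.DataFrame(intensity, index=probe_ids, columns=sample_ids))
        label_maps.append(labels)
    if return_gene_values:
        return tables, pmap, label_maps, truth, gene_values
    return tables, pmap, label_maps, truth


def simulate_hit_table(
    universe: Sequence[str],
    base_rate: float,
    de_boost: float,
    truth: SimTruth | None = None,
    seed: int = 0,
) -> dict[str, int]:
    """Generate an offline gene-to-abstract-count table.

    Every gene has a qualifying abstract (count >= 1) with probability
    ``base_rate``, raised to ``base_rate + de_boost`` for planted DE genes.
    Positive counts are ``1 + Poisson(2)`` — the statistic downstream only
    asks whether the count is >= 1.
    """
    if not (0 <= base_rate <= 1 and 0 <= de_boost <= 1 and base_rate + de_boost <= 1):
        raise ValueError("rates must lie in [0, 1] with base_rate + de_boost <= 1")
    rng = np.random.default_rng(seed)
    de = truth.de_genes if truth is not None else set()
    table: dict[str, int] = {}
    for gene in sorted(universe):
        p = base_rate + (de_boost if gene in de else 0.0)
        if rng.random() < p:
            table[gene] = 1 + int(rng.poisson(2))
    return table
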