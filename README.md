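# asymdex

Cross-study differential expression for *asymmetric* microarray
collections — studies that contain only diseased or only control
samples — together with the classical inverse-variance meta-analysis
such data cannot use, and two statistics for validating the resulting
gene lists.

## The problem

Public cancer microarray repositories are dominated by asymmetric
datasets: a study profiles 60 tumours and no normal tissue, while the
matching normal samples sit in a different lab's submission. Standard
meta-analysis pools *within-study* contrasts, so an asymmetric study
contributes nothing. The alternative implemented here is the **merged
SAM** design: normalize every array from every study against one frozen
reference, pool all samples into a single two-class table regardless of
origin, and run one significance analysis of microarrays (SAM) test on
the merged design. Asymmetric studies then add statistical power instead
of being discarded.

## What is implemented

- **Frozen-reference RMA normalization** (`asymdex.normalize`): classic
  per-cohort RMA (background → quantile normalization → log₂ → per-gene
  median polish of the model `T(PM_ij) = e_i + a_j + ε_ij`) plus a
  train/apply route that freezes a reference quantile vector and probe
  affinity vector on a training cohort and normalizes new arrays one at
  a time — arrays from different studies end up with near-identical
  distributions.
- **SAM** (`asymdex.sam`): the moderated statistic `d_i = r_i/(s_i + s0)`
  with the coefficient-of-variation–minimising fudge factor `s0`, a
  label-permutation null (full enumeration on small designs, 100
  permutations by default), delta-threshold calling and the
  median-false-count FDR estimate.
- **Inverse-variance meta-analysis** (`asymdex.ivmeta`): per-study
  standardized effects `d = (x̄₁ − x̄₂)/s` with pooled SD
  `s = √[((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2)]`, fixed-effect pooling with
  weights `1/var(d)`, normal z/p and Benjamini–Hochberg thresholding
  (default level 10⁻⁵, i.e. an FDR of 0.001%).
- **List validation** (`asymdex.ranklists`, `asymdex.litscore`): top-k
  overlap of two rankings with an upper-tail hypergeometric p-value
  (computed in log space), and a literature-hit score — the count of
  list genes with at least one qualifying abstract in an offline hit
  table, referred to the mean ± SD of the same count over 100 random
  equal-size gene lists.
- **Collection bookkeeping** (`asymdex.manifest`, `asymdex.resources`):
  manifests, symmetric/asymmetric classification, replicate averaging,
  gene-universe intersection across platforms, and the bundled
  accounting inventory of a 36-study, five-cancer compendium
  (colon/kidney/liver/lung/pancreas; 31 Affymetrix + 5 cDNA studies).
- **Synthetic data** (`asymdex.synthetic`): seeded generators for
  multi-study two-class gene- and probe-level data with lab shifts and
  planted standardized effects, plus synthetic literature hit tables,
  so every analysis is testable offline.
- **Workflows** (`asymdex.pipeline`, CLI `asymdex`): merged SAM over
  symmetric studies only or over all studies, the IV workflow, and the
  purely-asymmetric design-perturbation experiment that strips one
  condition from every symmetric study in all 2^k ways.

## Worked example

Simulate a colon-like collection — two symmetric studies (8 normal vs 8
tumour each), one tumour-only study (12) and one normal-only study (12),
800 genes of which 5% carry a 1.5-SD effect — then run the merged SAM
over all four studies, the IV meta-analysis over the two symmetric ones,
and both validation statistics:

```python
from asymdex import (SamConfig, SimConfig, StudyDesign, simulate_gene_level,
                     simulate_hit_table)
from asymdex.pipeline import merged_sam
from asymdex.ivmeta import run_ivmeta
from asymdex.ranklists import overlap_grid
from asymdex.litscore import score_list

cfg = SimConfig(
    n_genes=800,
    studies=[StudyDesign("colon", 8, 8), StudyDesign("colon", 8, 8),
             StudyDesign("colon", 0, 12), StudyDesign("colon", 12, 0)],
    de_fraction=0.05, effect_mean=1.5, seed=42,
)
tables, labels, truth = simulate_gene_level(cfg)

sam = merged_sam(tables, labels, SamConfig(n_permutations=100,
                                           fdr_target=0.0, seed=42), top_k=80)
print(f"SAM: s0={sam.s0:.4f}, called={len(sam.called_genes)} genes "
      f"at estimated FDR {sam.fdr}")

meta, iv_list = run_ivmeta(tables[:2], labels[:2], q_star=1e-3, top_k=80)
print(f"IV meta-analysis (symmetric studies only): "
      f"{int(meta['significant'].sum())} significant genes")
print(overlap_grid(sam.ranking, iv_list, [10, 40, 80], n_universe=800)
      .rows.to_string(index=False))

hits = simulate_hit_table(list(tables[0].index), 0.3, 0.4, truth, seed=42)
lit = score_list(sam.ranking, list(tables[0].index), hits, seed=42)
print(f"literature hits: {lit.observed_hits}/{lit.list_size} vs null "
      f"{lit.null_mean:.1f}±{lit.null_sd:.1f}, p={lit.p:.2e}")
```

Output:

```
SAM: s0=0.0875, called=34 genes at estimated FDR 0.0
IV meta-analysis (symmetric studies only): 10 significant genes
 k  k_eff_a  k_eff_b  overlap            p
10       10       10        8 5.017885e-16
40       34       10       10 4.689056e-15
80       34       10       10 4.689056e-15
literature hits: 21/34 vs null 9.9±2.8, p=4.10e-05
```

Reading the numbers: the merged SAM calls 34 genes at an estimated FDR
of 0 (so its ranked list stops at 34, short of the nominal 80 — list
truncation is expected behaviour when fewer genes pass). The IV test,
restricted to the 32 symmetric samples, finds only 10 significant genes;
all 10 also appear in the SAM list, an overlap that a hypergeometric
null over the 800-gene universe puts at p ≈ 5×10⁻¹⁵. The SAM list hits
the (synthetic) literature far above the 100-random-list null
(21 vs 9.9 ± 2.8, p ≈ 4×10⁻⁵), and 85% of the planted genes are in it.

The same steps are available from the shell:

```bash
asymdex simulate --n-genes 800 --studies 8v8,8v8,0v12,12v0 --seed 42 --out sim/
asymdex sam --expr sim/merged.tsv --labels sim/labels.csv --permutations 100 \
        --fdr 0 --seed 42 --top 400 --out ranked.tsv
asymdex overlap --list-a ranked.tsv --list-b other.tsv --universe 9409 --out table.tsv
```

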