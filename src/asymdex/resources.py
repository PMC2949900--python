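"""Bundled study inventory for the five-cancer microarray compendium.

The inventory lists, for each public study (GEO / ArrayExpress accession),
its tissue, normal and cancer sample counts, and platform code:

* ``A``  — Affymetrix HG-U133A
* ``A2`` — Affymetrix HG-U133A 2.0
* ``P2`` — Affymetrix HG-U133 Plus 2.0
* ``cDNA`` — two-colour cDNA arrays (meta-analysis only)

Only the accounting (who contributed how many samples of which condition)
is bundled; expression values are not.  The inventory drives sample-count
bookkeeping, symmetric/asymmetric classification, and design-perturbation
experiments without any download.
"""

from __future__ import annotations

from .manifest import DISEASE, NORMAL, Manifest, SampleRecord, manifest_from_samples

#: (study_id, tissue, n_normal, n_disease, platform_id, block)
#: block: "core" = symmetric studies used by every analysis,
#: "asym" = asymmetric Affymetrix studies (merged analyses only),
#: "cdna" = cDNA studies (meta-analysis only).
STUDY_INVENTORY: list[tuple[str, str, int, int, str, str]] = [
    # symmetric Affymetrix core
    ("E-MTAB-57", "colon", 22, 25, "A", "core"),
    ("GSE4107", "colon", 10, 12, "P2", "core"),
    ("GSE4183", "colon", 8, 15, "P2", "core"),
    ("E-TABM-282", "kidney", 11, 16, "P2", "core"),
    ("GSE11024", "kidney", 12, 60, "P2", "core"),
    ("GSE11151", "kidney", 3, 57, "P2", "core"),
    ("GSE14762", "kidney", 12, 10, "P2", "core"),
    ("GSE15641", "kidney", 23, 57, "A", "core"),
    ("GSE6344", "kidney", 10, 10, "A", "core"),
    ("GSE7023", "kidney", 12, 35, "P2", "core"),
    ("GSE14323", "liver", 19, 47, "A", "core"),
    ("GSE6764", "liver", 10, 35, "P2", "core"),
    ("E-MEXP-231", "lung", 9, 49, "A", "core"),
    ("GSE10072", "lung", 49, 58, "A", "core"),
    ("GSE7670", "lung", 27, 27, "A", "core"),
    ("E-MEXP-1121", "pancreas", 6, 17, "A", "core"),
    ("E-MEXP-950", "pancreas", 11, 14, "A", "core"),
    ("GSE15471", "pancreas", 39, 39, "P2", "core"),
    ("GSE16515", "pancreas", 15, 36, "P2", "core"),
    # asymmetric Affymetrix additions
    ("E-MEXP-1224", "colon", 0, 55, "A", "asym"),
    ("E-MEXP-383", "colon", 0, 36, "A", "asym"),
    ("E-TABM-176", "colon", 55, 0, "P2", "asym"),
    ("GSE12945", "colon", 0, 36, "A", "asym"),
    ("GSE17538", "colon", 0, 232, "P2", "asym"),
    ("GSE10320", "kidney", 0, 144, "A", "asym"),
    ("GSE11904", "kidney", 0, 21, "A2", "asym"),
    ("E-TABM-292", "liver", 0, 32, "A", "asym"),
    ("E-TABM-36", "liver", 0, 57, "A", "asym"),
    ("GSE9843", "liver", 0, 69, "P2", "asym"),
    ("GSE10445", "lung", 0, 72, "P2", "asym"),
    ("GSE12667", "lung", 0, 75, "P2", "asym"),
    # cDNA studies (meta-analysis extension)
    ("GSE6988", "colon", 28, 52, "cDNA", "cdna"),
    ("GSE3", "kidney", 81, 90, "cDNA", "cdna"),
    ("GSE7367", "lung", 24, 24, "cDNA", "cdna"),
    ("GSE2088", "lung", 30, 57, "cDNA", "cdna"),
    ("GSE8596", "lung", 6, 69, "cDNA", "cdna"),
]

AFFYMETRIX_PLATFORMS = ("A", "A2", "P2")


def compendium_manifest(
    blocks: tuple[str, ...] = ("core", "asym"),
    tissue: str | None = None,
) -> Manifest:
    """Expand the study inventory to a per-sample Manifest.

    Sample ids are synthesized as ``<study>_N###`` / ``<study>_C###`` since
    the inventory carries counts, not individual array identifiers.
    Default blocks cover the 31 Affymetrix studies; pass
    ``("core",)`` for the 19 symmetric studies or add ``"cdna"`` for the
    meta-analysis-only cDNA studies.
    """
    records: list[SampleRecord] = []
    for study, study_tissue, n_norm, n_dis, platform, block in STUDY_INVENTORY:
        if block not in blocks:
            continue
        if tissue is not None and study_tissue != tissue:
            continue
        for i in range(n_norm):
            records.append(
                SampleRecord(f"{study}_N{i + 1:03d}", study, study_tissue, NORMAL, platform)
            )
        for i in range(n_dis):
            records.append(
                SampleRecord(f"{study}_C{i + 1:03d}", study, study_tissue, DISEASE, platform)
            )
    return manifest_from_samples(records)
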