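"""Bookkeeping for multi-study microarray collections.

A *collection* is a set of studies, each contributing samples from one or
both of two conditions (``normal`` and ``disease``).  A study with samples
from both conditions is *symmetric* and supports a within-study contrast;
a study with samples from only one condition is *asymmetric* and can only
be used by analyses that merge samples across studies before testing.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

NORMAL = "normal"
DISEASE = "disease"
#: accepted spellings for the disease condition in input files
_DISEASE_ALIASES = {"disease", "cancer", "tumor", "tumour"}
_NORMAL_ALIASES = {"normal", "control", "healthy"}

MANIFEST_COLUMNS = ["study_id", "sample_id", "tissue", "class_label", "platform_id"]


class ManifestError(ValueError):
    """Raised for structurally invalid manifests."""


@dataclass(frozen=True)
class SampleRecord:
    """One microarray sample and its study/condition annotation."""

    sample_id: str
    study_id: str
    tissue: str
    class_label: str  # NORMAL or DISEASE
    platform_id: str

    def __post_init__(self) -> None:
        if self.class_label not in (NORMAL, DISEASE):
            raise ManifestError(
                f"sample {self.sample_id!r}: class_label must be "
                f"{NORMAL!r} or {DISEASE!r}, got {self.class_label!r}"
            )


@dataclass(frozen=True)
class StudyRecord:
    """Per-study sample accounting."""

    study_id: str
    tissue: str
    platform_id: str
    n_normal: int
    n_disease: int

    @property
    def n_samples(self) -> int:
        return self.n_normal + self.n_disease

    @property
    def is_symmetric(self) -> bool:
        return self.n_normal > 0 and self.n_disease > 0


@dataclass
class Manifest:
    """A validated collection of studies and their samples."""

    studies: dict[str, StudyRecord] = field(default_factory=dict)
    samples: list[SampleRecord] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def study_samples(self, study_id: str) -> list[SampleRecord]:
        return [s for s in self.samples if s.study_id == study_id]

    def subset(
        self,
        tissue: str | None = None,
        platforms: Iterable[str] | None = None,
        studies: Iterable[str] | None = None,
    ) -> "Manifest":
        """Restrict the manifest by tissue, platform and/or study id."""
        plat = set(platforms) if platforms is not None else None
        keep_studies = set(studies) if studies is not None else None
        recs = [
            s
            for s in self.samples
            if (tissue is None or s.tissue == tissue)
            and (plat is None or s.platform_id in plat)
            and (keep_studies is None or s.study_id in keep_studies)
        ]
        return manifest_from_samples(recs)


def _normalize_label(raw: str, row_desc: str) -> str:
    label = raw.strip().lower()
    if label in _DISEASE_ALIASES:
        return DISEASE
    if label in _NORMAL_ALIASES:
        return NORMAL
    raise ManifestError(f"unknown class_label {raw!r} in {row_desc}")


def manifest_from_samples(records: Sequence[SampleRecord]) -> Manifest:
    """Build a Manifest from sample records, deriving per-study counts."""
    seen: set[str] = set()
    for rec in records:
        if rec.sample_id in seen:
            raise ManifestError(f"duplicate sample_id {rec.sample_id!r}")
        seen.add(rec.sample_id)

    studies: dict[str, StudyRecord] = {}
    for sid in sorted({r.study_id for r in records}):
        members = [r for r in records if r.study_id == sid]
        tissues = {r.tissue for r in members}
        platforms = {r.platform_id for r in members}
        if len(tissues) > 1:
            raise ManifestError(f"study {sid!r} spans multiple tissues: {sorted(tissues)}")
        studies[sid] = StudyRecord(
            study_id=sid,
            tissue=members[0].tissue,
            platform_id="/".join(sorted(platforms)),
            n_normal=sum(r.class_label == NORMAL for r in members),
            n_disease=sum(r.class_label == DISEASE for r in members),
        )
    ordered = sorted(records, key=lambda r: (r.study_id, r.sample_id))
    return Manifest(studies=studies, samples=list(ordered))


def load_manifest(path: str | Path) -> Manifest:
    """Read a sample manifest CSV.

    Expected header: ``study_id,sample_id,tissue,class_label,platform_id``.
    ``cancer`` (and ``tumor``) are accepted aliases for ``disease``;
    ``control``/``healthy`` for ``normal``.
    """
    path = Path(path)
    records: list[SampleRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ManifestError(f"manifest {path} missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            label = _normalize_label(row["class_label"], f"{path.name} line {i}")
            records.append(
                SampleRecord(
                    sample_id=row["sample_id"].strip(),
                    study_id=row["study_id"].strip(),
                    tissue=row["tissue"].strip(),
                    class_label=label,
                    platform_id=row["platform_id"].strip(),
                )
            )
    return manifest_from_samples(records)


def save_manifest(manifest: Manifest, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for s in manifest.samples:
            writer.writerow([s.study_id, s.sample_id, s.tissue, s.class_label, s.platform_id])


def classify_studies(manifest: Manifest) -> dict[str, list[str]]:
    """Partition study ids into symmetric / disease_only / normal_only.

    A study qualifies as symmetric iff it has at least one sample of each
    condition; the three lists are disjoint and cover every study.
    """
    out: dict[str, list[str]] = {"symmetric": [], "disease_only": [], "normal_only": []}
    for sid in sorted(manifest.studies):
        st = manifest.studies[sid]
        if st.is_symmetric:
            out["symmetric"].append(sid)
        elif st.n_disease > 0:
            out["disease_only"].append(sid)
        else:
            out["normal_only"].append(sid)
    return out


def summarize(
    manifest: Manifest,
    tissue: str | None = None,
    platforms: Iterable[str] | None = None,
    symmetric_only: bool = False,
) -> pd.DataFrame:
    """Per-tissue sample accounting, with a ``total`` row.

    Returns a DataFrame indexed by tissue with columns
    ``n_studies, n_normal, n_disease, n_samples``.
    """
    sub = manifest.subset(tissue=tissue, platforms=platforms)
    if symmetric_only:
        keep = [sid for sid, st in sub.studies.items() if st.is_symmetric]
        sub = sub.subset(studies=keep)
    rows = {}
    for t in sorted({st.tissue for st in sub.studies.values()}):
        sts = [st for st in sub.studies.values() if st.tissue == t]
        rows[t] = {
            "n_studies": len(sts),
            "n_normal": sum(st.n_normal for st in sts),
            "n_disease": sum(st.n_disease for st in sts),
        }
    table = pd.DataFrame.from_dict(rows, orient="index").astype(int)
    if table.empty:
        table = pd.DataFrame(columns=["n_studies", "n_normal", "n_disease"], dtype=int)
    table["n_samples"] = table.get("n_normal", 0) + table.get("n_disease", 0)
    table.loc["total"] = table.sum()
    return table.astype(int)


@dataclass(frozen=True)
class PlatformMap:
    """Probe-to-gene mapping for one array platform.

    Each probe maps to exactly one gene; the platform's gene universe is
    the set of distinct mapped genes.
    """

    platform_id: str
    probe_to_gene: Mapping[str, str]

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.probe_to_gene.values()))

    @property
    def probes(self) -> list[str]:
        return sorted(self.probe_to_gene)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PlatformMap":
        """Read ``probe_id<TAB>gene_id`` rows; filename stem is the platform id."""
        path = Path(path)
        mapping: dict[str, str] = {}
        with path.open() as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                probe, gene = line.split("\t")[:2]
                if probe in mapping and mapping[probe] != gene:
                    raise ManifestError(
                        f"probe {probe!r} maps to both {mapping[probe]!r} and {gene!r}"
                    )
                mapping[probe] = gene
        return cls(platform_id=path.stem, probe_to_gene=mapping)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for probe in self.probes:
                fh.write(f"{probe}\t{self.probe_to_gene[probe]}\n")


def common_genes(maps: Sequence[PlatformMap]) -> list[str]:
    """Intersection of the platforms' gene universes, lexicographically sorted."""
    if not maps:
        raise ValueError("need at least one platform map")
    genes = set(maps[0].genes)
    for m in maps[1:]:
        genes &= set(m.genes)
    if not genes:
        warnings.warn("platform maps share no genes; returning empty universe")
    return sorted(genes)


def average_replicates(
    table: pd.DataFrame, groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Collapse technical replicates to one column per group (arithmetic mean).

    ``groups`` maps a replicate-group id to the member sample ids; samples
    not named in any group pass through unchanged.  Column order: grouped
    columns (by group id) follow ungrouped ones, lexicographically.
    """
    grouped: set[str] = set()
    for gid, members in groups.items():
        missing = [m for m in members if m not in table.columns]
        if missing:
            raise KeyError(f"replicate group {gid!r} references missing samples {missing}")
        grouped.update(members)
    passthrough = sorted(c for c in table.columns if c not in grouped)
    out = {c: table[c] for c in passthrough}
    for gid in sorted(groups):
        out[gid] = table[list(groups[gid])].mean(axis=1)
    return pd.DataFrame(out, index=table.index)


def load_replicate_groups(path: str | Path) -> dict[str, list[str]]:
    """Read ``group_id<TAB>sample_id`` rows (one row per member)."""
    groups: dict[str, list[str]] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gid, sample = line.split("\t")[:2]
            groups.setdefault(gid, []).append(sample)
    return groups


DROP_NORMAL = "drop_normal"
DROP_DISEASE = "drop_disease"


def asymmetrize(manifest: Manifest, choices: Mapping[str, str]) -> Manifest:
    """Delete one condition's samples from each chosen symmetric study.

    ``choices`` maps a symmetric study id to ``drop_normal`` or
    ``drop_disease``.  Enumerating all 2**k choice vectors over k symmetric
    studies yields every purely-asymmetric variant of the collection.
    """
    for sid, choice in choices.items():
        if sid not in manifest.studies:
            raise ManifestError(f"choice for unknown study {sid!r}")
        if not manifest.studies[sid].is_symmetric:
            raise ManifestError(f"study {sid!r} is not symmetric; cannot asymmetrize")
        if choice not in (DROP_NORMAL, DROP_DISEASE):
            raise ManifestError(f"invalid choice {choice!r} for study {sid!r}")
    dropped_label = {
        sid: (NORMAL if c == DROP_NORMAL else DISEASE) for sid, c in choices.items()
    }
    kept = [
        s
        for s in manifest.samples
        if dropped_label.get(s.study_id) != s.class_label
    ]
    return manifest_from_samples(kept)


def enumerate_asymmetric_variants(manifest: Manifest) -> list[Manifest]:
    """All 2**k asymmetrized variants over the k symmetric studies."""
    sym = classify_studies(manifest)["symmetric"]
    variants = []
    for mask in range(2 ** len(sym)):
        choices = {
            sid: (DROP_NORMAL if (mask >> i) & 1 else DROP_DISEASE)
            for i, sid in enumerate(sym)
        }
        variants.append(asymmetrize(manifest, choices))
    return variants
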