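"""TSV readers/writers for expression and probe tables.

Layout: first column ``gene_id`` (or ``probe_id``), remaining columns one
per sample, header row of sample ids, tab-separated.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a genes-or-probes x samples TSV into a float DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def write_table(table: pd.DataFrame, path: str | Path, index_label: str = "gene_id") -> None:
    table.to_csv(path, sep="\t", index_label=index_label)


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample_id,class_label`` CSV into a mapping."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    return dict(zip(df[cols[0]].astype(str), df[cols[1]].astype(str)))


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(labels), "class_label": list(labels.values())}
    ).to_csv(path, index=False)
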