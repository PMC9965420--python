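"""Small-format I/O helpers: GMT gene-set files and sidecar tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["read_gmt", "write_gmt", "read_labels", "read_embedding"]


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file into {set name: member genes}.

    Format: one set per line, tab-separated: name, description, genes...
    """
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line!r}")
        name, _desc, *genes = fields
        genes = [g for g in genes if g]
        if not genes:
            raise ValueError(f"empty gene set {name!r}")
        if name in sets:
            raise ValueError(f"duplicate gene set name {name!r}")
        sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path, descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for name, genes in sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *map(str, genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_labels(path) -> pd.Series:
    """Two-column TSV (cell id, label) or one labeled column; returns a Series."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.shape[1] != 1:
        raise ValueError("labels file must have exactly one label column")
    return frame.iloc[:, 0].astype(str)


def read_embedding(path) -> pd.DataFrame:
    """TSV with cell id index and two coordinate columns."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.shape[1] != 2:
        raise ValueError("embedding file must have exactly two coordinate columns")
    return frame.astype(float)
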