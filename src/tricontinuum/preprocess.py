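"""Turn a (possibly probe-level) expression table into the gene x sample matrix.

Covers the three bookkeeping steps that precede any modeling: collapsing
probe-sets to genes (max-mean rule), log / z-score standardization, and
flagging samples that sit far from the rest of the cohort in PCA space.
Array summarization itself (e.g. RMA of raw CEL files) is upstream of this
package; the input here is an already-summarized table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["ProbeMap", "collapse_probes", "standardize", "flag_outliers"]


@dataclass
class ProbeMap:
    """Many-to-one probe -> gene mapping."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("empty probe map")
        self.mapping = {str(p): str(g) for p, g in self.mapping.items()}

    @classmethod
    def from_tsv(cls, path) -> "ProbeMap":
        """Two-column TSV: probe id, gene id (header optional and ignored)."""
        frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if frame.shape[1] < 2:
            raise ValueError("probe map needs two columns: probe, gene")
        first = frame.iloc[0]
        if first.str.lower().isin(["probe", "probe_id", "gene", "gene_id"]).any():
            frame = frame.iloc[1:]
        return cls(dict(zip(frame.iloc[:, 0], frame.iloc[:, 1])))


def collapse_probes(probe_table: ExpressionMatrix, probe_map: ProbeMap) -> ExpressionMatrix:
    """Collapse a probe-level table to one row per gene by the max-mean rule.

    For each gene, keep the single probe whose mean across all samples is
    maximal; the retained row is copied verbatim (never averaged). Ties are
    broken toward the lexicographically smallest probe identifier. Probes
    absent from the map, and mapped probes absent from the table, are dropped
    (counts logged).
    """
    table = probe_table.data
    mapped = {p: g for p, g in probe_map.mapping.items() if p in table.index}
    if not mapped:
        raise ValueError("no probe in the map matches the probe-level table")
    n_unmapped_probes = probe_table.n_genes - len(mapped)

    means = table.mean(axis=1)
    by_gene: dict[str, str] = {}
    for probe in sorted(mapped):  # sorted => lexicographic tie-break for free
        gene = mapped[probe]
        best = by_gene.get(gene)
        if best is None or means[probe] > means[best]:
            by_gene[gene] = probe

    genes = sorted(by_gene)
    collapsed = table.loc[[by_gene[g] for g in genes]].copy()
    collapsed.index = pd.Index(genes, name=table.index.name)
    logger.info(
        "collapse_probes: %d genes from %d mapped probes (%d unmapped probes dropped)",
        len(genes), len(mapped), n_unmapped_probes,
    )
    return ExpressionMatrix(collapsed, allow_negative=probe_table.allow_negative)


def standardize(m: ExpressionMatrix, mode: str = "log2") -> ExpressionMatrix:
    """Apply the declared transform: ``log2`` (log2(x+1)), ``zscore_rows`` or ``none``.

    Row z-scores use the n-1 denominator; constant rows become all-zero with
    a warning. z-scored output may contain negatives and is flagged as such.
    """
    values = m.values
    if mode == "none":
        return ExpressionMatrix(m.data.copy(), allow_negative=m.allow_negative)
    if mode == "log2":
        if (values < 0).any():
            raise ValueError("log2 standardization requires non-negative input")
        out = np.log2(values + 1.0)
        allow_negative = False
    elif mode == "zscore_rows":
        mean = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, ddof=1, keepdims=True)
        constant = (sd == 0).ravel()
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant rows set to 0 under z-scoring",
                UserWarning,
                stacklevel=2,
            )
        sd[sd == 0] = 1.0
        out = (values - mean) / sd
        out[constant, :] = 0.0
        allow_negative = True
    else:
        raise ValueError("mode must be 'log2', 'zscore_rows' or 'none'")
    frame = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(frame, allow_negative=allow_negative)


def flag_outliers(embedding, n_pcs: int = 3, z_cut: float = 4.0) -> list[str]:
    """Flag samples far from the cohort in the first ``n_pcs`` principal components.

    Each sample's distance to the cohort center is computed in variance-scaled
    PC coordinates (a diagonal Mahalanobis distance), then converted to a
    robust z-score via median/MAD; samples with z > ``z_cut`` are returned.
    The threshold is deliberately explicit and configurable — cohort outlier
    removal is a judgment call and should be auditable.
    """
    coords = np.asarray(embedding.coords, dtype=float)
    n = coords.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples to estimate spread")
    if n_pcs > coords.shape[1]:
        raise ValueError(f"n_pcs={n_pcs} exceeds available components ({coords.shape[1]})")
    sub = coords[:, :n_pcs]
    sd = sub.std(axis=0, ddof=1)
    if (sd == 0).all():
        return []
    sd[sd == 0] = 1.0
    dist = np.sqrt(((sub / sd) ** 2).sum(axis=1))
    med = np.median(dist)
    mad = np.median(np.abs(dist - med))
    scale = 1.4826 * mad if mad > 0 else dist.std(ddof=1)
    if scale == 0:
        return []
    z = (dist - med) / scale
    flagged = [sid for sid, zi in zip(embedding.sample_ids, z) if zi > z_cut]
    if flagged:
        logger.info("flag_outliers: %d of %d samples flagged at z>%g", len(flagged), n, z_cut)
    return flagged
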