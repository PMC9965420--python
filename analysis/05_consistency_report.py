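"""Align the three characterizations and quantify their agreement.

For each of the three components, reports the Pearson correlation across
samples between (a) proximity to the fitted archetype and the matched topic
loading, and (b) the topic loading and the matched cell-type proportion.
High correlations mean the three independent views describe the same
continuum.

Reads results/{archetypes,topics,deconvolution,data}/; writes
results/consistency/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import tricontinuum as tc

parser = argparse.ArgumentParser()
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()
out = args.results / "consistency"
out.mkdir(parents=True, exist_ok=True)

coords = pd.read_csv(args.results / "archetypes/pca_coords.tsv", sep="\t", index_col=0)
vertices = pd.read_csv(args.results / "archetypes/vertices.tsv", sep="\t", index_col=0)
L = pd.read_csv(args.results / "topics/loadings.tsv", sep="\t", index_col=0)
F = pd.read_csv(args.results / "topics/factors.tsv", sep="\t", index_col=0)
props = pd.read_csv(args.results / "deconvolution/type_proportions.tsv", sep="\t",
                    index_col=0)

k = vertices.shape[0]
emb = tc.LatentEmbedding(
    coords=coords.to_numpy(), loadings=np.zeros((1, 2)), center=np.zeros(1),
    explained_variance_ratio=np.full(2, 0.5),
    sample_ids=coords.index.tolist(), gene_ids=["na"],
)
arch = tc.ArchetypeSet(vertices=vertices.to_numpy(), gene_profiles=np.zeros((k, 1)),
                       labels=vertices.index.tolist())
fit = tc.TopicFit(L=L.to_numpy(), F=F.to_numpy(), k=k, loglik_trace=np.zeros(1),
                  seed=0, gene_ids=F.index.tolist(), sample_ids=L.index.tolist())

report = tc.consistency_metrics(arch, emb, fit, type_proportions=props)
summary = pd.merge(report.alignment, report.correlations, on="archetype")
print(summary.to_string(index=False))
print(f"minimum aligned correlation: {report.min_correlation():.3f}")

report.per_sample.to_csv(out / "per_sample.tsv", sep="\t")
summary.to_csv(out / "summary.tsv", sep="\t", index=False)
print(f"written to {out}/")
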