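"""Generate the ground-truthed study cohort every later step analyzes.

Emulates the study design: a bulk expression cohort whose samples are convex
mixtures of three extreme expression programs (Dirichlet(1,1,1) weights,
Poisson counts at depth 10^4), plus a labeled single-cell reference whose
three cell types jitter around those same programs, so archetype inference,
topic modeling, and deconvolution can all be checked against one planted
composition.

Writes under results/data/: expression.tsv, true_markers.gmt, truth.json,
reference.tsv, labels.tsv, embedding.tsv.
"""

import argparse
from pathlib import Path

import tricontinuum as tc

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=17)
parser.add_argument("--n-samples", type=int, default=200)
parser.add_argument("--n-genes", type=int, default=400)
parser.add_argument("--out", type=Path, default=Path("results/data"))
args = parser.parse_args()

truth = tc.make_mixture_truth(
    n_samples=args.n_samples, n_genes=args.n_genes, k=3, alpha=(1.0, 1.0, 1.0),
    marker_block_size=25, depth=1e4, noise_model="poisson", seed=args.seed,
)
matrix, truth = tc.simulate_bulk_cohort(truth)
paths = tc.synthetic.write_cohort(args.out, matrix, truth)

ref_truth = tc.make_linked_reference(truth, cells_per_type=100)
reference, labels, embedding, _ = tc.simulate_reference_and_bulk(ref_truth)
reference.to_tsv(args.out / "reference.tsv")
labels.to_frame().to_csv(args.out / "labels.tsv", sep="\t")
embedding.to_csv(args.out / "embedding.tsv", sep="\t")

print(f"cohort: {matrix.n_genes} genes x {matrix.n_samples} samples "
      f"(Poisson counts, depth 1e4), seed {args.seed}")
print(f"reference: {reference.n_samples} cells, 3 types tied to the 3 archetypes")
print(f"written to {args.out}/")
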