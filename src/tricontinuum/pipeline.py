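"""End-to-end orchestration and the three-way consistency report.

The pipeline runs preprocess -> PCA/archetypes -> topics -> deconvolution on
a single cohort, aligns the three characterizations (archetype proximity,
topic loading, cell-type proportion) into a bijection over the k components,
and reports per-component Pearson correlations. When all three views are
driven by the same underlying composition — as in the planted synthetic
cohorts — the aligned correlations should be strongly positive; on real
cohorts the report quantifies how consistently the three methods describe
the same continuum.

All numeric outputs are written with a fixed float format and hashed into a
manifest, so a rerun with the same config reproduces every file byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import cdist

from . import synthetic
from .deconvolution import ReferenceAtlas, cpm_deconvolve
from .io import read_embedding, read_gmt, read_labels, write_gmt
from .latent import ArchetypeSet, LatentEmbedding, archetype_markers, fit_simplex, pca_embed, score_markers
from .matrix import ExpressionMatrix
from .preprocess import ProbeMap, collapse_probes, flag_outliers, standardize
from .topics import TopicFit, fit_topics, topic_gene_lists, topic_posteriors
from .utils import pearson_columns

logger = logging.getLogger(__name__)

__all__ = ["ConsistencyReport", "consistency_metrics", "run_pipeline"]

_FLOAT_FMT = "%.10g"


@dataclass
class ConsistencyReport:
    """Aligned per-sample table, component bijection, and correlation summary."""

    per_sample: pd.DataFrame
    alignment: pd.DataFrame  # one row per component: archetype / topic / type group
    correlations: pd.DataFrame  # per component: archetype<->topic r, topic<->type r

    def min_correlation(self) -> float:
        vals = self.correlations[["archetype_topic_r", "topic_type_r"]].to_numpy().ravel()
        vals = vals[~np.isnan(vals)]
        return float(vals.min()) if vals.size else float("nan")


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def consistency_metrics(
    archetypes: ArchetypeSet,
    emb: LatentEmbedding,
    fit: TopicFit,
    type_proportions: pd.DataFrame | None = None,
    type_groups: dict[str, str] | None = None,
) -> ConsistencyReport:
    """Align the three views and correlate them across samples.

    Topics are matched to archetypes by maximizing the summed correlation
    between topic loadings and negative distance-to-vertex (an assignment
    problem); cell types are grouped onto topics either by a user-supplied
    ``type_groups`` mapping (type name -> archetype label) or by assigning
    each type to its maximally correlated topic. Degenerate (constant)
    columns yield NaN correlations.
    """
    from scipy.optimize import linear_sum_assignment

    coords = emb.coords
    dist = cdist(coords, archetypes.vertices)  # n x k
    L = fit.L
    k = archetypes.k
    if L.shape[1] != k:
        raise ValueError("topic count does not match archetype count")

    r_at = pearson_columns(-dist, L)  # k x k: archetype a vs topic t
    cost = np.where(np.isnan(r_at), 0.0, r_at)
    arch_idx, topic_idx = linear_sum_assignment(-cost)

    rows = []
    per_sample = pd.DataFrame(index=pd.Index(emb.sample_ids, name="sample"))
    for a in range(k):
        per_sample[f"dist_{archetypes.labels[a]}"] = dist[:, a]
    for t in range(k):
        per_sample[f"loading_topic{t + 1}"] = L[:, t]

    group_prop = None
    type_of_topic: dict[int, str] = {}
    if type_proportions is not None:
        props = type_proportions.reindex(emb.sample_ids)
        if props.isna().any().any():
            raise ValueError("type proportions missing for some samples")
        if type_groups is not None:
            arch_of_type = dict(type_groups)
        else:
            r_tt = pearson_columns(L, props.to_numpy())  # topics x types
            arch_of_type = {}
            for j, tname in enumerate(props.columns):
                col = r_tt[:, j]
                best_topic = int(np.nanargmax(col)) if not np.isnan(col).all() else 0
                arch_of_type[tname] = archetypes.labels[
                    arch_idx[list(topic_idx).index(best_topic)]
                ]
        group_prop = np.zeros((len(emb.sample_ids), k))
        for j, tname in enumerate(props.columns):
            label = arch_of_type[tname]
            a = archetypes.labels.index(label)
            group_prop[:, a] += props.to_numpy()[:, j]
        for a in range(k):
            per_sample[f"proportion_{archetypes.labels[a]}"] = group_prop[:, a]
        type_of_topic = {
            int(t): ",".join(sorted(n for n, lab in arch_of_type.items()
                                    if lab == archetypes.labels[a]))
            for a, t in zip(arch_idx, topic_idx)
        }

    for a, t in sorted(zip(arch_idx, topic_idx)):
        r1 = _safe_pearson(-dist[:, a], L[:, t])
        r2 = float("nan")
        if group_prop is not None:
            r2 = _safe_pearson(L[:, t], group_prop[:, a])
        rows.append(
            dict(
                archetype=archetypes.labels[a],
                topic=f"topic{t + 1}",
                type_group=type_of_topic.get(int(t), ""),
                archetype_topic_r=r1,
                topic_type_r=r2,
            )
        )
    summary = pd.DataFrame(rows)
    alignment = summary[["archetype", "topic", "type_group"]].copy()
    correlations = summary[["archetype", "archetype_topic_r", "topic_type_r"]].copy()
    return ConsistencyReport(per_sample=per_sample, alignment=alignment,
                             correlations=correlations)


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_df(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _validate(cfg: dict) -> dict:
    cfg.setdefault("seed", 0)
    cfg.setdefault("k", 3)
    arch = cfg.setdefault("archetypes", {})
    arch.setdefault("d", cfg["k"] - 1)
    if cfg["k"] != arch["d"] + 1:
        raise ValueError(
            f"config invalid: k={cfg['k']} must equal d+1 (d={arch['d']}) for the simplex stage"
        )
    if "synthetic" not in cfg and "inputs" not in cfg:
        raise ValueError("config must provide either a 'synthetic' or an 'inputs' block")
    cfg.setdefault("preprocess", {})
    cfg.setdefault("topics", {})
    cfg.setdefault("deconvolution", {})
    return cfg


def run_pipeline(config, output_dir=None) -> dict:
    """Execute all stages per the YAML/dict config; return in-memory results.

    Writes stage outputs plus a manifest (input hashes, parameters, output
    hashes) under ``output_dir``. A stage failure aborts with the stage name
    and moves already-written outputs under a ``failed/`` prefix.
    """
    cfg = _validate(_load_config(config))
    out = Path(output_dir or cfg.get("output_dir", "tricontinuum_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    k = int(cfg["k"])
    results: dict = {"config": cfg}
    manifest: dict = {"parameters": json.loads(json.dumps(cfg, default=str)), "outputs": {}}
    written: list[Path] = []

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = out / name
        _write_df(frame, path)
        written.append(path)
        manifest["outputs"][name] = _sha256(path)

    stage = "inputs"
    try:
        # ---- inputs -----------------------------------------------------
        t0 = time.perf_counter()
        marker_library = None
        reference = None
        truth = None
        if "synthetic" in cfg:
            syn = dict(cfg["synthetic"])
            ref_cfg = syn.pop("reference", {})
            truth = synthetic.make_mixture_truth(seed=seed, **syn)
            matrix, truth = synthetic.simulate_bulk_cohort(truth)
            marker_library = dict(truth.marker_blocks)
            if ref_cfg is not None:
                ref_truth = synthetic.make_linked_reference(truth, **ref_cfg)
                ref_m, labels, emb_df, _ = synthetic.simulate_reference_and_bulk(ref_truth)
                reference = ReferenceAtlas.from_frames(ref_m, labels, emb_df)
            results["truth"] = truth
        else:
            inputs = cfg["inputs"]
            matrix = ExpressionMatrix.from_tsv(inputs["expression"])
            if inputs.get("probe_map"):
                matrix = collapse_probes(matrix, ProbeMap.from_tsv(inputs["probe_map"]))
            if inputs.get("markers_gmt"):
                marker_library = read_gmt(inputs["markers_gmt"])
            if inputs.get("reference"):
                rc = inputs["reference"]
                reference = ReferenceAtlas.from_frames(
                    ExpressionMatrix.from_tsv(rc["matrix"]),
                    read_labels(rc["labels"]),
                    read_embedding(rc["embedding"]),
                )
        logger.info("stage inputs done in %.2fs", time.perf_counter() - t0)

        # ---- preprocess -------------------------------------------------
        stage = "preprocess"
        t0 = time.perf_counter()
        pp = cfg["preprocess"]
        # synthetic cohorts are convex mixtures on the linear scale; log2 is the
        # right default only for real (multiplicative-noise) intensity data
        default_std = "none" if "synthetic" in cfg else "log2"
        processed = standardize(matrix, pp.get("standardize", default_std))
        emit("expression_processed.tsv", processed.data)
        report: dict = {}
        logger.info("stage preprocess done in %.2fs", time.perf_counter() - t0)

        # ---- archetypes -------------------------------------------------
        stage = "archetypes"
        t0 = time.perf_counter()
        ac = cfg["archetypes"]
        emb = pca_embed(processed, int(ac["d"]))
        if pp.get("flag_outliers", False):
            flagged = flag_outliers(emb, n_pcs=int(pp.get("n_pcs", min(3, ac["d"]))),
                                    z_cut=float(pp.get("z_cut", 4.0)))
            report["flagged_samples"] = flagged
            if flagged:
                keep = [s for s in processed.sample_ids if s not in set(flagged)]
                processed = ExpressionMatrix(processed.data[keep],
                                             allow_negative=processed.allow_negative)
                emb = pca_embed(processed, int(ac["d"]))
        archetypes = fit_simplex(
            emb, k, seed=seed,
            penalty_weight=float(ac.get("penalty_weight", 10.0)),
        )
        markers = archetype_markers(
            archetypes, gene_ids=emb.gene_ids,
            fc_threshold=float(ac.get("fc_threshold", 2.0)),
        )
        if marker_library:
            labels_map, enrichment = score_markers(markers, marker_library, emb.gene_ids)
            emit("archetype_enrichment.tsv", enrichment.set_index("archetype"))
            if len(set(labels_map.values())) == k:
                order = np.argsort([labels_map[lab] for lab in archetypes.labels])
                archetypes.vertices = archetypes.vertices[order]
                archetypes.gene_profiles = archetypes.gene_profiles[order]
                markers = {labels_map[old]: genes for old, genes in markers.items()}
                archetypes.labels = sorted(labels_map.values())
            else:
                logger.warning("archetype labels not uniquely resolved (%s); "
                               "keeping positional labels", labels_map)
        emit("archetype_vertices.tsv", pd.DataFrame(
            archetypes.vertices, index=pd.Index(archetypes.labels, name="archetype"),
            columns=[f"pc{j + 1}" for j in range(archetypes.vertices.shape[1])]))
        emit("pca_coords.tsv", pd.DataFrame(
            emb.coords, index=pd.Index(emb.sample_ids, name="sample"),
            columns=[f"pc{j + 1}" for j in range(emb.coords.shape[1])]))
        marker_path = out / "archetype_markers.gmt"
        write_gmt({n: g for n, g in markers.items() if g} or
                  {"empty": ["none"]}, marker_path)
        written.append(marker_path)
        manifest["outputs"]["archetype_markers.gmt"] = _sha256(marker_path)
        results.update(embedding=emb, archetypes=archetypes, archetype_markers=markers,
                       preprocess_report=report)
        logger.info("stage archetypes done in %.2fs", time.perf_counter() - t0)

        # ---- topics -----------------------------------------------------
        stage = "topics"
        t0 = time.perf_counter()
        tc = cfg["topics"]
        fit = fit_topics(
            matrix, k,
            em_iters=int(tc.get("em_iters", 100)),
            cd_iters=int(tc.get("cd_iters", 100)),
            seed=seed,
            n_restarts=int(tc.get("n_restarts", 3)),
        )
        post = topic_posteriors(fit)
        gene_lists = topic_gene_lists(post, cutoff=float(tc.get("posterior_cutoff", 0.5)))
        emit("topic_loadings.tsv", pd.DataFrame(
            fit.L, index=pd.Index(fit.sample_ids, name="sample"),
            columns=[f"topic{t + 1}" for t in range(k)]))
        emit("topic_factors.tsv", pd.DataFrame(
            fit.F, index=pd.Index(fit.gene_ids, name="gene"),
            columns=[f"topic{t + 1}" for t in range(k)]))
        emit("topic_posteriors.tsv", pd.DataFrame(
            post.posterior, index=pd.Index(fit.gene_ids, name="gene"),
            columns=[f"topic{t + 1}" for t in range(k)]))
        results.update(topic_fit=fit, posteriors=post, topic_gene_lists=gene_lists)
        logger.info("stage topics done in %.2fs", time.perf_counter() - t0)

        # ---- deconvolution ----------------------------------------------
        deconv = None
        if reference is not None:
            stage = "deconvolution"
            t0 = time.perf_counter()
            dc = cfg["deconvolution"]
            deconv = cpm_deconvolve(
                matrix, reference,
                model_size=int(dc.get("model_size", 50)),
                min_selection=int(dc.get("min_selection", 5)),
                neighborhood_size=int(dc.get("neighborhood_size", 10)),
                seed=seed,
            )
            emit("cell_abundance.tsv", deconv.cell_abundance)
            emit("type_proportions.tsv", deconv.type_proportions)
            results["deconvolution"] = deconv
            logger.info("stage deconvolution done in %.2fs", time.perf_counter() - t0)

        # ---- consistency ------------------------------------------------
        stage = "consistency"
        t0 = time.perf_counter()
        report_obj = consistency_metrics(
            archetypes, emb, fit,
            type_proportions=None if deconv is None else deconv.type_proportions,
            type_groups=cfg.get("type_groups"),
        )
        emit("consistency_per_sample.tsv", report_obj.per_sample)
        emit("consistency_summary.tsv",
             pd.merge(report_obj.alignment, report_obj.correlations, on="archetype")
             .set_index("archetype"))
        results["consistency"] = report_obj
        logger.info("stage consistency done in %.2fs", time.perf_counter() - t0)
    except Exception as exc:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for path in written:
            if path.exists():
                shutil.move(str(path), str(failed / path.name))
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    results["manifest"] = manifest
    results["output_dir"] = str(out)
    return results
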