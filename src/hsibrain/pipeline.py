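"""End-to-end orchestration of the four-stage detection chain.

Stage 1 pre-processes the raw cube; stage 2 trains/applies the SVM and
KNN-filters its probability map on the one-band embedding; stage 3
segments the cube with hierarchical K-means; stage 4 fuses both maps by
majority voting and renders the MV / OMD / TMD images.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import clustering, embedding, fusion, preprocess, spatial_filter, supervised
from .errors import ConfigError
from .hsdata import (HSCube, LabelMap, ReferenceFrames, SegmentationMap,
                     categorical_palette, write_map_png)
from .labeling import extract_dataset
from .synthetic import PhantomSpec, make_phantom, sample_gold_standard


@dataclass
class PipelineConfig:
    preprocess: preprocess.PreprocessConfig = field(
        default_factory=preprocess.PreprocessConfig)
    kernel: str = "linear"
    svm_C: float = 1.0
    knn_K: int = 40
    knn_lambda: float = 1.0
    n_clusters: int = 24
    embed_max_refs: int = 2000
    embed_perplexity: float = 30.0
    seed: int = 0
    out_dir: str | None = None


@dataclass
class PipelineResult:
    reduced: HSCube
    fullband: HSCube
    prob_map: "supervised.ProbabilityMap"
    filtered_map: "supervised.ProbabilityMap"
    classes: LabelMap
    seg: SegmentationMap
    profiles: fusion.ClusterProfile
    mv_labels: LabelMap
    mv_rgb: np.ndarray
    omd_rgb: np.ndarray
    tmd_rgb: np.ndarray
    manifest: dict


def run_pipeline(raw: HSCube, refs: ReferenceFrames, sparse_labels: LabelMap,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run preprocess -> train -> classify -> embed -> filter -> cluster -> fuse.

    *sparse_labels* is the gold-standard map used to train the SVM and to
    anchor the fixed-reference embedding.  Fully deterministic under
    ``config.seed``.
    """
    cfg = config or PipelineConfig()
    if raw.data.shape != refs.white.shape:
        raise ConfigError("reference frames do not match the cube")
    if sparse_labels.labels.shape != raw.data.shape[:2]:
        raise ConfigError("label map does not match the cube grid")
    times: dict[str, float] = {}

    t0 = time.perf_counter()
    reduced, fullband = preprocess.run_chain(raw, refs, cfg.preprocess)
    times["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    dataset = extract_dataset([(reduced, sparse_labels)])
    model = supervised.train_svm(dataset, kernel=cfg.kernel, C=cfg.svm_C,
                                 seed=cfg.seed)
    prob_map = supervised.predict_proba_cube(model, reduced)
    times["svm"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    full_ds = extract_dataset([(fullband, sparse_labels)])
    refs_spectra = embedding.subsample_references(full_ds, cfg.embed_max_refs,
                                                  seed=cfg.seed)
    ref_model = embedding.fit_reference(refs_spectra, seed=cfg.seed,
                                        perplexity=cfg.embed_perplexity)
    guidance = embedding.embed_cube(fullband, ref_model)
    times["embedding"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    F = spatial_filter.build_features(guidance, lam=cfg.knn_lambda)
    filtered = spatial_filter.knn_filter(prob_map, F, K=cfg.knn_K)
    classes = spatial_filter.filtered_class_map(filtered)
    times["knn_filter"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    seg, tree = clustering.hkm_segment(reduced, n_clusters=cfg.n_clusters,
                                       seed=cfg.seed)
    times["clustering"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    profiles = fusion.compute_profiles(seg, classes)
    mv_labels, mv_rgb, ties = fusion.mv_map(profiles, seg)
    omd_rgb = fusion.omd_map(profiles, seg)
    tmd_rgb = fusion.tmd_map(profiles, seg)
    times["fusion"] = time.perf_counter() - t0

    manifest = {
        "seed": cfg.seed,
        "parameters": {"kernel": cfg.kernel, "C": cfg.svm_C, "K": cfg.knn_K,
                       "lambda": cfg.knn_lambda, "n_clusters": cfg.n_clusters,
                       "preprocess": asdict(cfg.preprocess)},
        "cube_shape": list(raw.shape),
        "reduced_bands": reduced.n_bands,
        "fullband_bands": fullband.n_bands,
        "n_training_signatures": len(dataset),
        "mv_tied_clusters": ties,
        "stage_seconds": {k: round(v, 3) for k, v in times.items()},
    }

    result = PipelineResult(reduced=reduced, fullband=fullband, prob_map=prob_map,
                            filtered_map=filtered, classes=classes, seg=seg,
                            profiles=profiles, mv_labels=mv_labels, mv_rgb=mv_rgb,
                            omd_rgb=omd_rgb, tmd_rgb=tmd_rgb, manifest=manifest)
    if cfg.out_dir:
        write_outputs(result, cfg.out_dir, seed=cfg.seed)
    return result


def write_outputs(result: PipelineResult, out_dir: str, seed: int = 0) -> None:
    """Write the MV/OMD/TMD PNGs, segmentation PNG, per-cluster CSV and
    the run manifest into *out_dir*."""
    os.makedirs(out_dir, exist_ok=True)
    write_map_png(result.mv_rgb, os.path.join(out_dir, "mv.png"))
    write_map_png(result.omd_rgb, os.path.join(out_dir, "omd.png"))
    write_map_png(result.tmd_rgb, os.path.join(out_dir, "tmd.png"))
    write_map_png(result.seg, os.path.join(out_dir, "segmentation.png"),
                  palette=categorical_palette(result.seg.n_clusters, seed=seed))
    result.profiles.to_frame().to_csv(os.path.join(out_dir, "cluster_profiles.csv"),
                                      index=False)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2)


def run_phantom_pipeline(spec: PhantomSpec | None = None,
                         config: PipelineConfig | None = None
                         ) -> tuple[PipelineResult, LabelMap]:
    """Convenience wrapper: simulate a phantom, sparse-label it, run the
    pipeline; returns the result and the full ground truth."""
    spec = spec or PhantomSpec()
    cfg = config or PipelineConfig()
    raw, refs, truth = make_phantom(spec)
    sparse = sample_gold_standard(truth, spec.label_fraction, seed=spec.seed)
    return run_pipeline(raw, refs, sparse, cfg), truth
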