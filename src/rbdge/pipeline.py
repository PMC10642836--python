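"""End-to-end orchestration: normalize -> DE -> clinical table -> scoring -> CTree -> pathways.

One config object drives the whole run; a single global seed is fanned out
to the stochastic stages (simulation, bootstrap) by fixed offsets so each
stage is reproducible in isolation.  Every stage writes its artifact before
the next begins, and a manifest records parameters, seeds and per-stage
record counts; identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import build_table1
from .ctree import CTreeParams, grow, loocv
from .de import cluster, mean_variance_qc, pca, run_de
from .normalization import normalize_pipeline
from .pathways import load_gene_sets, node_states, ora_test, states_frame
from .rcc import (
    CountMatrix,
    assemble_matrix,
    read_annotations,
    read_matrix_csv,
    read_rcc,
    write_matrix_csv,
)
from .scoring import (
    bootstrap_auc,
    composite_score,
    fit_probability_model,
    score_performance,
    select_markers,
)
from .simulate import SimulationConfig, simulate_dataset, write_dataset

log = logging.getLogger("rbdge")

# fixed per-stage seed offsets keep stages independently reproducible
SEED_OFFSET_SIMULATE = 0
SEED_OFFSET_BOOTSTRAP = 101


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str
    rcc_dir: str | None = None
    matrix_csv: str | None = None
    annotations_csv: str | None = None
    gene_sets_json: str | None = None
    simulate: dict | None = None          # SimulationConfig fields; simulate instead of load
    alpha: float = 0.05
    bootstrap_iterations: int = 1000
    top_k: int = 5
    score_threshold: int | None = None
    ctree: dict = field(default_factory=dict)
    seed: int = 20231030

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise PipelineError("config", "alpha must lie in (0, 1)")
        if self.simulate is None:
            if self.rcc_dir is None and self.matrix_csv is None:
                raise PipelineError("config", "need rcc_dir, matrix_csv, or simulate block")
            if self.annotations_csv is None:
                raise PipelineError("config", "annotations_csv is required")
            for label, p in (("rcc_dir", self.rcc_dir), ("matrix_csv", self.matrix_csv),
                             ("annotations_csv", self.annotations_csv)):
                if p is not None and not Path(p).exists():
                    raise PipelineError("config", f"{label} path does not exist: {p}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        sim_payload = dict(config.simulate)
        sim_payload.setdefault("seed", config.seed + SEED_OFFSET_SIMULATE)
        sim = SimulationConfig(**{
            k: (tuple(v) if k == "baseline_log_mean_range" else v)
            for k, v in sim_payload.items()
        })
        dataset = simulate_dataset(sim)
        return dataset.counts, dataset.annotations, dataset
    if config.rcc_dir is not None:
        lanes = [read_rcc(p) for p in sorted(Path(config.rcc_dir).glob("*.RCC"))]
        if not lanes:
            raise PipelineError("load", f"no RCC files in {config.rcc_dir}")
        matrix = assemble_matrix(lanes, lanes[0].codeset)
    else:
        matrix = read_matrix_csv(config.matrix_csv)
    annotations = read_annotations(config.annotations_csv)
    return matrix, annotations, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "alpha": config.alpha,
            "bootstrap_iterations": config.bootstrap_iterations,
            "top_k": config.top_k,
        },
        "stages": {},
    }

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                if exc is not None:
                    log.error("stage %s: failed after %.2fs", name, dt)
                    _write_manifest(out, manifest)
                    raise PipelineError(name, str(exc)) from exc
                log.info("stage %s: done in %.2fs", name, dt)
                return False

        return _Timer()

    with stage("load"):
        matrix, annotations, dataset = _load_inputs(config)
        if dataset is not None:
            write_dataset(dataset, out / "simulated")
        manifest["stages"]["load"] = {
            "n_samples": len(matrix.sample_ids),
            "n_probes": len(matrix.codeset.probes),
        }

    with stage("normalize"):
        normalized, tfac, rfac, noise_calls, backgrounds = normalize_pipeline(matrix)
        write_matrix_csv(normalized, out / "normalized.csv")
        audit = {
            "technical_factors": dict(zip(tfac.sample_ids, tfac.factors.tolist())),
            "reference_factors": dict(zip(rfac.sample_ids, rfac.factors.tolist())),
            "backgrounds": [
                {"sample_id": b.sample_id, "mean": b.mean, "sd": b.sd,
                 "threshold": b.threshold}
                for b in backgrounds
            ],
            "noise_calls": [
                {"gene": c.gene, "t": c.t_statistic, "p": c.p_value,
                 "above_noise": c.above_noise}
                for c in noise_calls
            ],
        }
        (out / "normalization_audit.json").write_text(json.dumps(audit, indent=2))
        manifest["stages"]["normalize"] = {
            "n_above_noise": sum(c.above_noise for c in noise_calls),
            "n_endogenous": len(noise_calls),
        }

    with stage("de"):
        de_results = run_de(normalized, annotations, noise_calls)
        de_results.to_csv(out / "de.csv", index=False)
        qc = mean_variance_qc(normalized)
        qc.gene_stats.to_csv(out / "qc_gene_stats.csv")
        pca_res = pca(normalized)
        pca_res.scores.to_csv(out / "pca_scores.csv")
        clus = cluster(normalized, mode="unsupervised")
        (out / "cluster_leaf_order.json").write_text(json.dumps(clus.leaf_order))
        manifest["stages"]["de"] = {
            "n_tested": int(len(de_results)),
            "n_significant": int(de_results["significant"].sum()),
        }

    with stage("table1"):
        table1 = build_table1(annotations)
        pd.DataFrame(
            [
                {"characteristic": r.characteristic, "test": r.test,
                 "statistic": r.statistic, "p_value": r.p_value}
                for r in table1
            ]
        ).to_csv(out / "table1.csv", index=False)
        manifest["stages"]["table1"] = {"n_tests": len(table1)}

    with stage("score"):
        markers = select_markers(de_results, normalized, annotations, top_k=config.top_k)
        by_id = {a.sample_id: a for a in annotations}
        tumor_ids = list(markers[0].binarized.index)
        labels = np.array([by_id[s].subtype for s in tumor_ids])
        score = composite_score(markers)
        threshold = (
            config.score_threshold
            if config.score_threshold is not None
            else (len(markers) + 1) // 2
        )
        sens, spec, sweep = score_performance(score, labels, threshold)
        model = fit_probability_model(score.scores.to_numpy(), labels)
        name_to_row = {p.name: i for i, p in enumerate(normalized.codeset.probes)}
        cols = [normalized.sample_ids.index(s) for s in tumor_ids]
        boot = {}
        for k, m in enumerate(markers):
            vals = np.log2(normalized.values[name_to_row[m.gene], cols] + 1.0)
            est = bootstrap_auc(
                vals, labels, B=config.bootstrap_iterations,
                seed=config.seed + SEED_OFFSET_BOOTSTRAP + k,
            )
            boot[m.gene] = {"auc": est.auc, "ci": [est.ci_low, est.ci_high],
                            "B": est.n_iterations}
        score_payload = {
            "markers": [
                {"gene": m.gene, "cutoff": m.cutoff, "direction": m.direction,
                 "auc": m.auc, "youden_j": m.youden_j,
                 "bootstrap": boot[m.gene]}
                for m in markers
            ],
            "scores": score.scores.to_dict(),
            "threshold": threshold,
            "sensitivity": sens,
            "specificity": spec,
            "sweep": sweep.to_dict(orient="records"),
            "probability_model": {
                "intercept": model.intercept, "slope": model.slope,
                "converged": model.converged,
            },
        }
        (out / "score.json").write_text(json.dumps(score_payload, indent=2))
        manifest["stages"]["score"] = {
            "n_markers": len(markers), "sensitivity": sens, "specificity": spec,
        }

    with stage("ctree"):
        features = pd.DataFrame(
            {
                m.gene: np.log2(
                    normalized.values[name_to_row[m.gene], cols] + 1.0
                )
                for m in markers
            },
            index=tumor_ids,
        )
        features["composite_score"] = score.scores.reindex(tumor_ids).to_numpy()
        params = CTreeParams(alpha=config.alpha, **config.ctree)
        tree = grow(features, labels, params)
        cv = loocv(features, labels, params)
        (out / "tree.json").write_text(
            json.dumps(
                {
                    "tree": tree.to_dict(),
                    "loocv": {
                        "accuracy": cv.accuracy,
                        "confusion": cv.confusion.to_dict(),
                        "predictions": dict(zip(tumor_ids, cv.predictions.tolist())),
                    },
                },
                indent=2,
            )
        )
        manifest["stages"]["ctree"] = {"loocv_accuracy": cv.accuracy}

    with stage("pathway"):
        universe = {
            p.name for p in normalized.codeset.probes if p.code_class == "Endogenous"
        }
        sets = load_gene_sets(config.gene_sets_json, universe=universe)
        states = node_states(de_results, sets)
        frame = states_frame(states)
        sig = set(de_results[de_results["significant"]]["gene"])
        if len(frame):
            frame["ora_p"] = [
                ora_test(sig, set(sets.pathways[s.pathway][s.node]), universe)
                for s in states
            ]
        frame.to_csv(out / "pathway_states.csv", index=False)
        manifest["stages"]["pathway"] = {
            "n_nodes": int(len(frame)),
            "n_active": int((frame["state"] != 0).sum()) if len(frame) else 0,
        }

    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
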