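"""End-to-end orchestration of the quality, extraction, and annotation stages.

Each ``run_*`` function reads its inputs, runs the corresponding library
stage, writes CSV/JSON outputs under ``config.outdir``, and drops a manifest
(parameters, seed, input checksums, package version) sufficient to reproduce
the outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, chemometrics, datasets, fingerprint, msid, rsm
from .exceptions import DegenerateColumnError, HerbQCError

log = logging.getLogger("herbqc")


@dataclass
class PipelineConfig:
    outdir: str | Path = "results"
    # quality stage
    peak_table_path: str | Path | None = None
    rt_window: float = 0.1
    eigen_threshold: float = 0.99
    hca_linkage: str = "ward"
    hca_metric: str = "euclidean"
    n_clusters: int = 3
    similarity_method: str = "cosine"
    # rsm stage
    run_table_path: str | Path | None = None  # None -> packaged design table
    response_columns: list[str] | None = None  # None -> use the OD column
    bounds_source: str = "observed"
    # annotation stage
    compound_table_path: str | Path | None = None  # None -> packaged table
    feature_table_path: str | Path | None = None
    tol_ppm: float = 10.0
    max_depth: int = 3
    seed: int = 0


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(config: PipelineConfig, stage: str, inputs: list[Path], outdir: Path):
    manifest = {
        "stage": stage,
        "herbqc_version": __version__,
        "seed": config.seed,
        "parameters": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in asdict(config).items()
        },
        "input_checksums": {str(p): _sha256(Path(p)) for p in inputs if p is not None},
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_quality(config: PipelineConfig) -> dict:
    """Alignment -> similarity report -> PCA ranking -> HCA labels."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.peak_table_path is None:
        raise HerbQCError("quality stage: peak_table_path is required")
    log.info("quality: aligning peak tables (window %.3g min)", config.rt_window)
    tables = fingerprint.read_peak_tables(config.peak_table_path)
    matrix = fingerprint.match_peaks(tables, window=config.rt_window)
    report = fingerprint.similarity_report(matrix, method=config.similarity_method)

    log.info("quality: PCA ranking (eigenvalue threshold %.3g)", config.eigen_threshold)
    try:
        Xs = chemometrics.autoscale(matrix)
    except DegenerateColumnError:
        # all batches identical: ranking is trivial (everything ties at 0)
        # and all samples fall in one cluster
        log.warning("quality: degenerate (identical) batches; trivial ranking")
        ids = sorted(matrix.sample_ids)
        ranking = pd.DataFrame(
            {"comprehensive_score": 0.0, "rank": range(1, len(ids) + 1)}, index=ids
        )
        ranking.index.name = "sample_id"
        p = None
        tree = None
        labels = np.ones(len(matrix.sample_ids), dtype=int)
    else:
        p = chemometrics.pca(Xs, eigen_threshold=config.eigen_threshold)
        ranking = chemometrics.comprehensive_scores(p, sample_ids=matrix.sample_ids)
        log.info("quality: HCA (%s/%s, k=%d)", config.hca_linkage, config.hca_metric,
                 config.n_clusters)
        tree = chemometrics.hca(Xs, linkage=config.hca_linkage,
                                metric=config.hca_metric,
                                sample_ids=matrix.sample_ids)
        labels = tree.flat_labels(config.n_clusters)

    matrix.to_frame().to_csv(outdir / "fingerprint_matrix.csv")
    report.to_csv(outdir / "similarity_report.csv", index=False)
    ranking.to_csv(outdir / "quality_ranking.csv")
    pd.DataFrame({"sample_id": matrix.sample_ids, "cluster": labels}).to_csv(
        outdir / "hca_labels.csv", index=False
    )
    if tree is not None:
        (outdir / "hca_dendrogram.nwk").write_text(tree.to_newick() + "\n")
    _write_manifest(config, "quality", [Path(config.peak_table_path)], outdir)
    return {
        "matrix": matrix,
        "similarity": report,
        "pca": p,
        "ranking": ranking,
        "hca_labels": labels,
    }


def run_rsm(config: PipelineConfig) -> dict:
    """Desirability (or given OD) -> quadratic fit -> ANOVA -> optimum."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = []
    if config.run_table_path is None:
        df = datasets.load_bbd_table()
    else:
        df = pd.read_csv(config.run_table_path)
        inputs.append(Path(config.run_table_path))
    design, responses = rsm.read_run_table(df)

    if config.response_columns:
        log.info("rsm: computing OD from responses %s", config.response_columns)
        ds = [
            rsm.desirability(responses[c].to_numpy())
            for c in config.response_columns
        ]
        y = rsm.overall_desirability(ds)
    elif "OD" in responses.columns:
        log.info("rsm: using the given OD column as the regression response")
        y = responses["OD"].to_numpy(dtype=float)
    else:
        raise HerbQCError("rsm stage: no OD column and no response_columns given")

    model = rsm.fit_quadratic(design, y)
    table = rsm.anova(model)
    opt = rsm.optimize(model)
    log.info("rsm: optimum %s -> predicted %.4g", np.round(opt.argmax_actual, 3),
             opt.predicted)

    out = {
        "coefficients": {k: round(v, 6) for k, v in model.coef.items()},
        "r_squared": round(model.r_squared, 6),
        "optimum_actual": dict(
            zip([f.name for f in design.factors], np.round(opt.argmax_actual, 4))
        ),
        "optimum_coded": np.round(opt.argmax_coded, 6).tolist(),
        "predicted_at_optimum": round(opt.predicted, 6),
    }
    (outdir / "rsm_model.json").write_text(json.dumps(out, indent=2))
    table.to_csv(outdir / "rsm_anova.csv", index=False)
    for pair in [(0, 1), (0, 2), (1, 2)]:
        grid = rsm.surface_grid(model, pair=pair)
        grid.to_csv(outdir / f"rsm_surface_x{pair[0] + 1}x{pair[1] + 1}.csv", index=False)
    _write_manifest(config, "rsm", inputs, outdir)
    return {"design": design, "model": model, "anova": table, "optimum": opt}


def run_annotation(config: PipelineConfig) -> dict:
    """Mass/ppm verification of the compound table plus feature annotation."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = []
    if config.compound_table_path is None:
        compounds = datasets.load_compound_table()
    else:
        compounds = pd.read_csv(config.compound_table_path)
        inputs.append(Path(config.compound_table_path))

    calc = [
        msid.ion_mz(row.formula, row.adduct) for row in compounds.itertuples()
    ]
    mass_table = compounds.assign(
        calc_mz_recomputed=np.round(calc, 4),
        ppm_recomputed=[
            round(msid.ppm_error(m, c), 2)
            for m, c in zip(compounds["measured_mz"], calc)
        ],
    )
    mass_table.to_csv(outdir / "mass_table.csv", index=False)

    annotations = pd.DataFrame(
        columns=["feature_id", "parent", "modifications", "adduct", "calc_mz", "ppm"]
    )
    if config.feature_table_path is not None:
        feats_df = pd.read_csv(config.feature_table_path)
        inputs.append(Path(config.feature_table_path))
        features = [
            msid.Feature(str(r.feature_id), float(r.mz), str(r.ion_mode))
            for r in feats_df.itertuples()
        ]
        parents = {
            row.name: row.formula
            for row in compounds.itertuples()
        }
        results = msid.annotate_features(
            features,
            parents,
            tol_ppm=config.tol_ppm,
            max_depth=config.max_depth,
        )
        annotations = pd.DataFrame(
            [
                {
                    "feature_id": a.feature_id,
                    "parent": a.parent,
                    "modifications": " + ".join(a.modifications),
                    "adduct": a.adduct,
                    "calc_mz": round(a.calc_mz, 4),
                    "ppm": round(a.ppm, 2),
                }
                for a in results
            ]
        )
        log.info("annotation: %d candidate annotations for %d features",
                 len(annotations), len(features))
    annotations.to_csv(outdir / "annotations.csv", index=False)
    _write_manifest(config, "annotation", inputs, outdir)
    return {"mass_table": mass_table, "annotations": annotations}
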