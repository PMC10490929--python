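"""End-to-end orchestration: generate/load -> similarity -> risk -> classify.

Every stage writes plain TSV so each one can be re-run from its predecessor's
outputs alone; ``manifest.json`` records the config echo, seed, package
version, per-stage record counts and timings, and whether the run completed.
Re-running with the same config and seed reproduces all TSVs byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    DEFrequencySelector,
    build_feature_table,
    build_labels,
    evaluate_side_effect,
    pick_best_model,
)
from .config import RunConfig
from .data import (
    ContrastResult,
    load_database,
    read_contrast_table,
    read_gmt,
    write_contrast_table,
    write_database,
    write_gmt,
)
from .risk import (
    count_shared_pathways,
    null_band,
    randomize_query,
    results_to_frame,
    risk_association,
)
from .similarity import similarity_matrix, write_similarity
from .synth import generate_database, make_query_compound

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _stage(manifest: dict, name: str):
    class _Timer:
        def __enter__(self):
            manifest["stages"].setdefault(name, {})
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            manifest["stages"].setdefault(name, {})["seconds"] = round(
                time.perf_counter() - self.t0, 3
            )
            if exc is not None:
                manifest["status"] = f"failed at stage {name}"
            return False

    return _Timer()


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the configured pipeline; returns the output directory."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": {},
        "status": "incomplete",
    }
    try:
        _run(cfg, out, manifest)
        manifest["status"] = "complete"
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return out


def _run(cfg: RunConfig, out: Path, manifest: dict) -> None:
    # --- stage: data -----------------------------------------------------
    truth = None
    with _stage(manifest, "data"):
        try:
            if cfg.database_dir is None:
                db_dir = out / "database"
                database, pathways, truth = generate_database(cfg.synthetic)
                write_database(database, db_dir)
                write_gmt(pathways, db_dir / "pathways.gmt")
            else:
                database = load_database(
                    Path(cfg.database_dir) / "metadata.tsv",
                    Path(cfg.database_dir) / "contrasts",
                )
                pathways = read_gmt(cfg.gmt_path)
        except Exception as exc:
            raise PipelineError(f"data stage failed: {exc}") from exc
        manifest["stages"]["data"].update(
            n_compounds=database.n_compounds,
            n_clinical=database.n_clinical,
            n_risk=database.n_risk,
            n_contrasts=len(database.contrasts),
            n_pathways=len(pathways),
        )

    # --- stage: queries --------------------------------------------------
    queries: dict[str, dict[str, ContrastResult]] = {}
    with _stage(manifest, "queries"):
        try:
            if truth is not None:
                for profile in cfg.queries.profiles:
                    queries[profile] = make_query_compound(
                        cfg.synthetic, truth, profile, cell_types=tuple(cfg.cell_types)
                    )
            for entry in cfg.queries.files:
                contrast = read_contrast_table(entry["path"], entry["cell_type"])
                queries.setdefault(contrast.treatment_id, {})[entry["cell_type"]] = contrast
        except Exception as exc:
            raise PipelineError(f"queries stage failed: {exc}") from exc
        qdir = out / "queries"
        qdir.mkdir(exist_ok=True)
        for name, by_ct in sorted(queries.items()):
            for ct, contrast in sorted(by_ct.items()):
                write_contrast_table(contrast, qdir / f"{name}__{ct}.tsv")
        manifest["stages"]["queries"]["n_queries"] = len(queries)

    if not queries:
        log.info("no queries configured; stopping after the data stage outputs")

    # --- stage: similarity ----------------------------------------------
    a = cfg.analysis
    all_records: dict[str, list] = {}
    with _stage(manifest, "similarity"):
        try:
            for ct in cfg.cell_types:
                ct_queries = [by_ct[ct] for by_ct in queries.values() if ct in by_ct]
                if not ct_queries:
                    continue
                records = similarity_matrix(
                    ct_queries, database, pathways, ct, alpha=a.alpha, min_genes=a.min_genes
                )
                all_records[ct] = records
                write_similarity(records, out / f"similarity_{ct}.tsv")
        except Exception as exc:
            raise PipelineError(f"similarity stage failed: {exc}") from exc
        manifest["stages"]["similarity"]["n_records"] = sum(map(len, all_records.values()))

    # --- stage: risk ------------------------------------------------------
    with _stage(manifest, "risk"):
        try:
            risk_labels = database.risk_labels()
            results = risk_association(
                [r for recs in all_records.values() for r in recs],
                risk_labels,
                decision_rule=a.decision_rule,
                alpha=a.alpha,
                rho_threshold=a.rho_threshold,
                correction=a.correction,
            )
            frame = results_to_frame(results)
            frame.to_csv(out / "risk_results.tsv", sep="\t", index=False,
                         float_format="%.10g", na_rep=".")
            band = null_band(len(pathways), a.alpha)
            summary_rows = []
            for query_id in sorted({r.query_id for r in results}):
                for ct in cfg.cell_types:
                    n_shared = count_shared_pathways(
                        results, query_id, ct, decision_rule=a.decision_rule, alpha=a.alpha
                    )
                    summary_rows.append(
                        {
                            "query_id": query_id,
                            "cell_type": ct,
                            "n_shared_pathways": n_shared,
                            "n_pathways": len(pathways),
                            "null_band_low": band[0],
                            "null_band_high": band[1],
                        }
                    )
            pd.DataFrame(summary_rows).to_csv(out / "shared_counts.tsv", sep="\t", index=False)

            # gene-name randomization control on the first query, SMC side
            rand_rows = []
            control_source = None
            for by_ct in queries.values():
                if "SMC" in by_ct:
                    control_source = by_ct["SMC"]
                    break
            if control_source is not None and cfg.queries.n_randomizations > 0:
                seeds = (
                    np.random.SeedSequence([cfg.seed, 424242]).generate_state(
                        cfg.queries.n_randomizations
                    )
                    % 2**31
                )
                for s in seeds:
                    rand_query = randomize_query(control_source, int(s))
                    rand_records = similarity_matrix(
                        [rand_query], database, pathways, "SMC",
                        alpha=a.alpha, min_genes=a.min_genes,
                    )
                    rand_results = risk_association(
                        rand_records, risk_labels, decision_rule=a.decision_rule,
                        alpha=a.alpha, rho_threshold=a.rho_threshold, correction=a.correction,
                    )
                    rand_rows.append(
                        {
                            "source_query": control_source.treatment_id,
                            "seed": int(s),
                            "n_shared_pathways": count_shared_pathways(
                                rand_results, rand_query.treatment_id, "SMC",
                                decision_rule=a.decision_rule, alpha=a.alpha,
                            ),
                        }
                    )
                pd.DataFrame(rand_rows).to_csv(
                    out / "randomization_control.tsv", sep="\t", index=False
                )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"risk stage failed: {exc}") from exc
        manifest["stages"]["risk"].update(
            n_results=len(results), n_randomizations=len(rand_rows)
        )

    # --- stage: classify --------------------------------------------------
    with _stage(manifest, "classify"):
        if not cfg.classify.enabled or not database.side_effect_names():
            manifest["stages"]["classify"]["skipped"] = True
            return
        try:
            features, de_fdr = build_feature_table(database, cfg.cell_types)
            selector = DEFrequencySelector(
                de_fdr,
                fdr_threshold=a.fdr_threshold,
                min_fraction=cfg.classify.min_fraction,
                max_features=cfg.classify.max_features,
            )
            side_effects = cfg.classify.side_effects or database.side_effect_names()
            auc_rows, roc_rows, best_rows = [], [], []
            for se in side_effects:
                labels = build_labels(database, se)
                evals = evaluate_side_effect(
                    features, labels, selector, models=cfg.classify.models,
                    k_folds=cfg.classify.k_folds, n_boot=cfg.classify.n_boot, seed=cfg.seed,
                )
                best = pick_best_model(evals)
                best_rows.append(
                    {"side_effect": se, "best_model": best.model_name, "mean_auc": best.mean_auc}
                )
                for ev in evals:
                    for b, auc in enumerate(ev.boot_aucs):
                        auc_rows.append(
                            {"side_effect": se, "model": ev.model_name, "bootstrap": b, "auc": auc}
                        )
                for fpr, tpr in best.roc_curve:
                    roc_rows.append(
                        {"side_effect": se, "model": best.model_name, "fpr": fpr, "tpr": tpr}
                    )
            pd.DataFrame(auc_rows).to_csv(out / "classifier_aucs.tsv", sep="\t",
                                          index=False, float_format="%.10g", na_rep=".")
            pd.DataFrame(roc_rows).to_csv(out / "classifier_roc.tsv", sep="\t",
                                          index=False, float_format="%.10g")
            pd.DataFrame(best_rows).to_csv(out / "classifier_best.tsv", sep="\t",
                                           index=False, float_format="%.10g")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"classify stage failed: {exc}") from exc
        manifest["stages"]["classify"]["n_side_effects"] = len(side_effects)
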