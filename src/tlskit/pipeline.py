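"""End-to-end pipeline driver over the library stages.

Runs (optionally) simulate -> TLS scoring -> survival -> CNA association
-> TICTOC screen -> radiomics -> RPV on one top-level seed, writing every
artifact plus a JSON manifest of the parameters and seeds actually used.
Reruns with the same config are byte-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cna as cna_mod
from . import rpv as rpv_mod
from . import tictoc as tictoc_mod
from .io import write_clinical, write_matrix
from .scoring import TLS_POPULATION, dichotomize_scores, load_default_marker_db, mcp_score, score_all_populations
from .survival import cox_fit, km_estimate, logrank_test
from .synthetic import (
    PhantomConfig,
    SimulationConfig,
    couple_expression_to_cna,
    simulate_cna_survival,
    simulate_ct_phantom,
    simulate_expression,
)
from .radiomics import RadiomicsConfig, extract_feature_vector

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage, exc):
        super().__init__(f"pipeline stage {stage!r} failed: {exc}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    seed: int = 0
    # stage toggles
    run_scoring: bool = True
    run_survival: bool = True
    run_cna: bool = True
    run_tictoc: bool = True
    run_radiomics: bool = True
    run_rpv: bool = True
    # simulation scale (smoke defaults)
    n_samples: int = 50
    n_genes: int = 200
    n_phantoms: int = 10
    marker_effect: float = 2.0
    tls_fraction: float = 0.25
    beta_tls: float = float(np.log(0.55))
    censor_fraction: float = 0.3
    # analysis parameters
    high_quantile: float = 0.75
    q_threshold: float = 0.25
    r_threshold: float = 0.3
    prefilter_threshold: float = 0.1
    cv_folds: int = 5
    phantom_shape: tuple[int, int, int] = (24, 24, 12)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "artifacts": [], "thresholds_used": {}}

    def emit(name):
        manifest["artifacts"].append(name)
        return out / name

    stage = "simulate"
    try:
        markers = next(
            m for m in load_default_marker_db() if m.name == TLS_POPULATION
        )
        sim = SimulationConfig(
            n_samples=config.n_samples,
            n_genes=config.n_genes,
            tls_fraction=config.tls_fraction,
            marker_effect=config.marker_effect,
            planted_locus_genes=["G00001", "G00002"],  # background gene ids
            beta_tls=config.beta_tls,
            censor_fraction=config.censor_fraction,
            seed=config.seed,
        )
        db = load_default_marker_db()
        other_markers = [g for m in db if m.name != TLS_POPULATION for g in m.genes]
        expr, true_labels = simulate_expression(
            sim, list(markers.genes), background_genes=other_markers
        )
        cna, clinical, truth = simulate_cna_survival(
            sim, expr.loc[list(markers.genes)].mean(axis=0), genes=list(expr.index)
        )
        # gene-dosage coupling so CNA hits show the expected expression shift
        expr = couple_expression_to_cna(
            expr, cna, coefficient=0.8,
            genes=[g for g in cna.index if g not in markers.genes],
        )
        write_matrix(expr, emit("expression.tsv"))
        write_matrix(cna, emit("cna.tsv"))
        write_clinical(clinical, emit("clinical.csv"))
        with open(emit("truth.json"), "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)

        tls_scores = labels = None
        if config.run_scoring:
            stage = "scoring"
            tls_scores = mcp_score(expr, markers)
            labels = dichotomize_scores(tls_scores, config.high_quantile)
            pops = score_all_populations(expr, db)
            pd.DataFrame({"score": tls_scores, "tls_label": labels}).to_csv(
                emit("tls_scores.tsv"), sep="\t", index_label="sample_id"
            )
            pops.to_csv(emit("population_scores.tsv"), sep="\t", index_label="sample_id")
            manifest["thresholds_used"]["high_quantile"] = config.high_quantile

        if config.run_survival and labels is not None:
            stage = "survival"
            chi2, p = logrank_test(
                clinical["time_months"], clinical["event"], labels
            )
            z = (tls_scores - tls_scores.mean()) / tls_scores.std(ddof=0)
            fit = cox_fit(
                clinical.assign(tls=z.to_numpy()),
                ["tls", "age_years", "stage", "residual_disease"],
            )
            km = {
                int(g): km_estimate(
                    clinical.loc[labels == g, "time_months"],
                    clinical.loc[labels == g, "event"],
                )
                for g in sorted(labels.unique())
            }
            pd.concat(
                {
                    str(g): pd.DataFrame({"time": r.times, "survival": r.survival})
                    for g, r in km.items()
                },
                names=["tls_group"],
            ).to_csv(emit("km_curves.tsv"), sep="\t")
            with open(emit("survival.json"), "w") as fh:
                json.dump(
                    {
                        "logrank_chi2": chi2,
                        "logrank_p": p,
                        "cox": fit.summary().to_dict(orient="index"),
                        "km_median": {str(g): r.median for g, r in km.items()},
                    },
                    fh, indent=2, sort_keys=True,
                )

        if config.run_cna and labels is not None:
            stage = "cna_association"
            mod = cna_mod.moderated_t_test(cna, labels)
            freq = cna_mod.cna_frequency(cna, labels)
            mod.table.join(freq).to_csv(emit("cna_assoc.tsv"), sep="\t")
            manifest["thresholds_used"]["moderated_t_prior_df"] = mod.prior_df

        if config.run_tictoc and tls_scores is not None:
            stage = "tictoc"
            screen = tictoc_mod.interaction_screen(cna, tls_scores, clinical)
            corr = tictoc_mod.cna_expr_correlation(cna, expr)
            sel = tictoc_mod.classify_tictoc(
                screen, corr,
                r_threshold=config.r_threshold, q_threshold=config.q_threshold,
            )
            screen.to_csv(emit("tictoc_screen.tsv"), sep="\t")
            sel.to_csv(emit("tictoc_genes.tsv"), sep="\t")
            manifest["thresholds_used"]["tictoc_q"] = config.q_threshold
            manifest["thresholds_used"]["tictoc_r"] = config.r_threshold

        feats = None
        if config.run_radiomics:
            stage = "radiomics"
            rc = RadiomicsConfig()
            rows = {}
            phantom_labels = {}
            for i in range(config.n_phantoms):
                lab = i % 2
                pc = PhantomConfig(shape=config.phantom_shape, seed=config.seed + 1000 + i)
                vol = simulate_ct_phantom(pc, tls_label=lab)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rows[f"P{i:03d}"] = extract_feature_vector(vol, rc)
                phantom_labels[f"P{i:03d}"] = lab
            feats = pd.DataFrame(rows).T
            feats.insert(0, "tls_label", pd.Series(phantom_labels))
            feats.to_csv(emit("radiomics_features.tsv"), sep="\t", index_label="case_id")

        if config.run_rpv and feats is not None:
            stage = "rpv"
            y = feats["tls_label"].astype(float)
            X = feats.drop(columns="tls_label").dropna(axis=1)
            factors, Xs = rpv_mod.standardize(X)
            kept = rpv_mod.prefilter_spearman(Xs, y, config.prefilter_threshold)
            if kept:
                model = rpv_mod.lasso_cv(
                    Xs[kept], y, folds=min(config.cv_folds, len(Xs)),
                    seed=config.seed,
                )
                scores = rpv_mod.rpv_score(Xs, model)
                model.to_json(emit("rpv_model.json"))
                scores.to_csv(emit("rpv_scores.tsv"), sep="\t", index_label="case_id")
                manifest["thresholds_used"]["rpv_lambda"] = model.penalty
            manifest["thresholds_used"]["rpv_prefilter"] = config.prefilter_threshold
    except Exception as exc:  # noqa: BLE001 - abort names the failing stage
        raise PipelineError(stage, exc) from exc

    manifest["seed"] = config.seed
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest_path = out / "manifest.json"
    assert manifest_path.exists()
    return manifest
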