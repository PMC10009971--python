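"""End-to-end pipeline driver.

Sequences the analysis stages: simulate (or load) the cohort, fit the WBC
background and partition plasma variants, build the per-sample fragmentomic
feature matrix, train/evaluate by LOOCV with Youden thresholding, and score
the independent validation cohort at the frozen threshold. Identical
config + seed gives identical outputs; every filter logs variants in / kept
/ removed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import background, features, model
from .io import RunConfig, variant_key, write_feature_table, write_metrics
from .simulate import CohortData, SimulationConfig, simulate_cohort

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception | str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(name, e) from e
        return wrapper
    return deco


@_stage("simulate")
def _get_cohort(config: RunConfig) -> CohortData:
    if config.variants_path or config.fragments_path:
        raise ValueError(
            "run_pipeline drives the simulated study; analyse external "
            "tables with the per-stage CLI subcommands "
            "(filter-wbc / featurize / train / evaluate)"
        )
    sim = SimulationConfig(rng_seed=config.rng_seed, **config.simulation)
    log.info("simulating cohort with seed %d", config.rng_seed)
    return simulate_cohort(sim)


@_stage("filter-wbc")
def _partition(cohort: CohortData, config: RunConfig) -> background.VariantPartition:
    params = background.fit_background(cohort.wbc_variants["vaf"].to_numpy())
    log.info(
        "background fit: pi0=%.4f a=%.4f b=%.4f n=%d",
        params.pi0, params.a, params.b, params.n_fit,
    )
    part = background.select_lb_unique(cohort.plasma_variants, params, alpha=config.alpha)
    n_in = len(cohort.plasma_variants)
    log.info(
        "wbc filter: %d variants in, %d LB-unique kept, %d LB-share-WBC removed",
        n_in, len(part.lb_unique), len(part.lb_share_wbc),
    )
    return part


@_stage("featurize")
def _featurize(
    cohort: CohortData, part: background.VariantPartition, config: RunConfig
) -> pd.DataFrame:
    retained = features.filter_for_features(part, vaf_ceiling=config.vaf_ceiling)
    log.info(
        "vaf ceiling %.3g: %d of %d LB-unique variants retained",
        config.vaf_ceiling, len(retained), len(part.lb_unique),
    )
    if len(retained) == 0:
        raise ValueError("no LB-unique variants after filtering; nothing to featurize")
    frag_by_sample = dict(tuple(cohort.fragments.groupby("sample_id")))
    vecs = []
    for row in cohort.samples.itertuples():
        sub = retained[retained["sample_id"] == row.sample_id]
        frags = frag_by_sample.get(row.sample_id)
        if len(sub) == 0 or frags is None:
            raise ValueError(f"sample {row.sample_id!r}: no retained variants or fragments")
        keys = set(variant_key(sub))
        fr = frags[frags["variant_key"].isin(keys)]
        fr = features.restrict_lengths(fr)
        alt = fr.loc[fr["allele"] == "ALT", "length"].to_numpy()
        ref = fr.loc[fr["allele"] == "REF", "length"].to_numpy()
        try:
            vecs.append(
                features.compute_sample_features(
                    alt, ref, row.sample_id, label=row.label,
                    boundary=config.boundary, window=config.enrichment_window,
                    window_width=config.window_width,
                )
            )
        except Exception as e:
            raise ValueError(f"sample {row.sample_id!r}: {e}") from e
    return features.build_feature_matrix(vecs)


@_stage("train")
def _train_discovery(feat: pd.DataFrame, samples: pd.DataFrame, config: RunConfig):
    disc_ids = samples.loc[samples["cohort"] == "discovery", "sample_id"]
    disc = feat[feat["sample_id"].isin(disc_ids)].reset_index(drop=True)
    X, y, ids = features.matrix_from_table(disc)
    mc = model.ModelConfig(rng_seed=config.rng_seed, **(
        {"grid": config.classifier_grid} if config.classifier_grid else {}
    ))
    scores = model.loocv_scores(X, y, mc)
    roc = model.roc_auc(scores, y)
    log.info(
        "discovery LOOCV: AUC=%.4f threshold=%.4f sens=%.3f spec=%.3f",
        roc.auc, roc.youden_threshold, roc.sensitivity, roc.specificity,
    )
    return disc, X, y, ids, mc, roc


@_stage("evaluate")
def _evaluate_validation(feat, samples, X, y, ids, mc, roc):
    val_ids = samples.loc[samples["cohort"] == "validation", "sample_id"]
    val = feat[feat["sample_id"].isin(val_ids)].reset_index(drop=True)
    if len(val) == 0:
        return None, None
    Xv, yv, idv = features.matrix_from_table(val)
    return val, model.external_validate(
        X, y, Xv, yv, mc, roc.youden_threshold, train_ids=ids, val_ids=idv
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> filter-wbc -> featurize -> train -> evaluate.

    Writes ``features.tsv``, ``metrics.json`` and the serialized config under
    ``config.out_dir`` and returns the metrics dict.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = _get_cohort(config)
    part = _partition(cohort, config)
    feat = _featurize(cohort, part, config)
    disc, X, y, ids, mc, roc = _train_discovery(feat, cohort.samples, config)
    val, val_roc = _evaluate_validation(feat, cohort.samples, X, y, ids, mc, roc)

    metrics = {
        "seed": config.rng_seed,
        "thresholds": {
            "alpha": config.alpha,
            "vaf_ceiling": config.vaf_ceiling,
            "boundary": config.boundary,
            "enrichment_window": list(config.enrichment_window),
        },
        "background": {
            "pi0": part.params.pi0, "a": part.params.a, "b": part.params.b,
            "n_fit": part.params.n_fit,
        },
        "counts": {
            "n_samples": len(cohort.samples),
            "n_plasma_variants": len(cohort.plasma_variants),
            "n_lb_unique": len(part.lb_unique),
            "n_lb_share_wbc": len(part.lb_share_wbc),
        },
        "discovery": {
            "auc": roc.auc,
            "youden_threshold": roc.youden_threshold,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
            "scores": {s: float(v) for s, v in zip(disc["sample_id"], roc.scores)},
        },
    }

    if val_roc is not None:
        metrics["validation"] = {
            "auc": val_roc.auc,
            "sensitivity": val_roc.sensitivity,
            "specificity": val_roc.specificity,
            "scores": {s: float(v) for s, v in zip(val["sample_id"], val_roc.scores)},
        }

    truth = cohort.truth_labels
    if truth is not None and len(truth):
        metrics["wbc_model"] = _truth_metrics(cohort, part)

    if config.single_feature_aucs:
        metrics["single_feature_auc"] = _single_feature_aucs(X, y, mc)

    if config.n_permutations:
        rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 9151]))
        perm = model.permutation_null_aucs(X, y, mc, config.n_permutations, rng)
        metrics["permutation_null"] = {
            "n": config.n_permutations,
            "mean_auc": float(perm.mean()),
            "sd_auc": float(perm.std(ddof=1)) if config.n_permutations > 1 else 0.0,
        }

    write_feature_table(feat, out / "features.tsv")
    write_metrics(metrics, out / "metrics.json")
    config.to_yaml(out / "run_config.yaml")
    return metrics


def _truth_metrics(cohort: CohortData, part: background.VariantPartition) -> dict:
    """Concordance of the background partition with generator truth, plus the
    per-sample mean shared-VAF correlation between plasma and matched WBC."""
    conc = background.concordance_rate(part, cohort.truth_labels)
    # per-sample mean VAF of truly shared plasma variants vs their WBC pairs
    wbc = cohort.wbc_variants.assign(variant_key=variant_key(cohort.wbc_variants))
    pv = cohort.plasma_variants.assign(variant_key=variant_key(cohort.plasma_variants))
    truth_shared = cohort.truth_labels[cohort.truth_labels["source"] == "wbc_shared"]
    pairs = (
        pv.merge(truth_shared[["sample_id", "variant_key"]], on=["sample_id", "variant_key"])
        .merge(
            wbc[["sample_id", "variant_key", "vaf"]],
            on=["sample_id", "variant_key"],
            suffixes=("_plasma", "_wbc"),
        )
    )
    out = {"concordance": conc}
    if len(pairs):
        means = pairs.groupby("sample_id")[["vaf_plasma", "vaf_wbc"]].mean()
        if len(means) >= 3:
            r, ci, p = background.vaf_correlation(
                means["vaf_plasma"].to_numpy(), means["vaf_wbc"].to_numpy()
            )
            out["shared_vaf_pearson_r"] = r
            out["shared_vaf_r_ci95"] = list(ci)
            out["shared_vaf_p"] = p
    return out


def _single_feature_aucs(X: np.ndarray, y: np.ndarray, mc) -> dict:
    blocks = {"f1": [0], "f2": [1], "f3": list(range(2, 17))}
    out = {}
    for name, cols in blocks.items():
        s = model.loocv_scores(X[:, cols], y, mc)
        out[name] = model.roc_auc(s, y).auc
    return out
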