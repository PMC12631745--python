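"""End-to-end orchestration: merge -> labels -> DEG -> attribution ranking
-> sign intersection -> specificity elimination -> signature fit ->
holdout evaluation, with every intermediate artifact written to disk and
a run log recording seeds and versions.

Stages halt with a :class:`PipelineError` naming the failing stage;
artifacts written before the failure are retained.  Identical
configuration and seed reproduce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .dataio import IntegratedDataset, filter_low_expression, load_dataset, read_manifest
from .de import deg_table
from .phenotyping import IC50Phenotyper
from .ranking import (
    ShapRanker,
    contributing_genes,
    evaluate_holdout,
    stratified_split,
)
from .selection import SpecificityRFE, sign_intersection, panel_correlation
from .signature import SignatureClassifier, cutoff_sweep, evaluate_signature
from .synthetic import SyntheticConfig, simulate_cohort, write_cohort

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure carrying the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Everything a run needs: inputs, thresholds, CV settings, seeds."""

    # input: either a manifest of delimited files or a synthetic config
    manifest_path: str | None = None
    synthetic: SyntheticConfig | None = None
    outdir: str = "phenosig_run"
    # thresholds
    padj_threshold: float = 0.05
    lfc_threshold: float = 1.0
    shap_epsilon: float = 0.0
    cutoff: float = 0.5
    min_total_count: int = 10
    # clustering
    k_range: tuple[int, int] = (2, 10)
    cluster_log_scale: bool = False
    # CV settings
    n_repeats: int = 12
    n_folds: int = 5
    fraction_test: float = 0.2
    # model settings
    C: float = 1.0
    max_iter: int = 1000
    gbdt_params: dict | None = None
    # seeds
    seed: int = 42
    validate: bool = False  # also run survival/drug validation on synthetic truth

    def __post_init__(self) -> None:
        if not 0 < self.fraction_test < 1:
            raise ValueError("fraction_test must be in (0, 1)")
        for name in ("padj_threshold", "cutoff"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.lfc_threshold < 0 or self.shap_epsilon < 0:
            raise ValueError("thresholds must be nonnegative")

    @classmethod
    def from_ini(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat key-value config with optional [synthetic] section."""
        import configparser

        parser = configparser.ConfigParser()
        parser.read_string("[pipeline]\n" + Path(path).read_text())
        kwargs: dict = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for section in parser.sections():
            if section == "synthetic":
                syn_fields = {f.name: f for f in dataclasses.fields(SyntheticConfig)}
                syn_kwargs = {
                    k: (int(v) if syn_fields[k].type == "int" else float(v))
                    for k, v in parser.items(section)
                }
                kwargs["synthetic"] = SyntheticConfig(**syn_kwargs)
                continue
            for key, value in parser.items(section):
                if key not in fields:
                    raise ValueError(f"unknown config key: {key}")
                ftype = fields[key].type
                if key == "k_range":
                    kwargs[key] = tuple(int(x) for x in value.split(","))
                elif "int" in ftype and "| None" not in ftype:
                    kwargs[key] = int(value)
                elif "float" in ftype:
                    kwargs[key] = float(value)
                elif "bool" in ftype:
                    kwargs[key] = value.strip().lower() in {"1", "true", "yes"}
                else:
                    kwargs[key] = value
        return cls(**kwargs)


def _write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")


def _metrics_dict(m) -> dict:
    return {
        "accuracy": m.accuracy,
        "roc_auc": m.roc_auc,
        "pr_auc": m.pr_auc,
        "confusion": m.confusion.tolist(),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every discovery stage and return the artifact manifest.

    The manifest maps artifact names (labels, deg, shap_summary,
    candidate_panel, trace, panel, model, metrics, report) to file paths
    under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    log_lines = [
        f"phenosig {__version__} python {sys.version.split()[0]}",
        f"seed {config.seed}",
        f"config {dataclasses.asdict(config)}",
    ]

    def _log(stage: str, msg: str) -> None:
        log_lines.append(f"[{stage}] {msg}")

    def _fail(stage: str, exc: Exception):
        (outdir / "run.log").write_text("\n".join(log_lines) + f"\nFAILED [{stage}] {exc}\n")
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: input -----------------------------------------------------
    truth = None
    try:
        if config.synthetic is not None:
            cohort = simulate_cohort(config.synthetic)
            paths = write_cohort(cohort, outdir / "inputs")
            truth = cohort
            dataset = load_dataset(
                {k: paths[k] for k in ("ic50_a", "ic50_b", "counts", "tpm")}
            )
            _log("input", f"synthetic cohort: {dataset.n_samples} complete lines")
        elif config.manifest_path is not None:
            man = read_manifest(config.manifest_path)
            dataset = load_dataset(man, base=Path(config.manifest_path).parent)
            _log("input", f"merged {dataset.n_samples} complete lines from manifest")
        else:
            raise ValueError("config needs either a manifest_path or a synthetic block")
    except PipelineError:
        raise
    except Exception as exc:
        _fail("input", exc)

    # --- stage: phenotype labels -----------------------------------------
    try:
        phenotyper = IC50Phenotyper(
            k_range=config.k_range,
            log_scale=config.cluster_log_scale,
            random_state=config.seed,
        )
        ic50 = pd.DataFrame(
            {"ic50_a": dataset.ic50_a, "ic50_b": dataset.ic50_b},
            index=pd.Index(dataset.sample_ids),
        )
        phenotyper.fit(ic50)
        sens = phenotyper.sensitivity_
        labels_frame = pd.DataFrame(
            {
                "cluster": phenotyper.assignment_.labels,
                "class": sens.labels.reindex(ic50.index).fillna(""),
                "excluded": [i in set(sens.excluded) for i in ic50.index],
            }
        ).rename_axis("id")
        p = outdir / "labels.csv"
        labels_frame.to_csv(p)
        manifest["labels"] = str(p)
        _log(
            "label",
            f"method={phenotyper.method_} k={phenotyper.n_clusters_} "
            f"silhouette={phenotyper.assignment_.silhouette:.4f} "
            f"sensitive={len(sens.sensitive_ids)} resistant={len(sens.resistant_ids)} "
            f"excluded={len(sens.excluded)}",
        )
    except Exception as exc:
        _fail("label", exc)

    labels = sens.labels
    labeled_ids = list(labels.index)

    # --- stage: differential expression ----------------------------------
    try:
        counts = filter_low_expression(
            dataset.counts.loc[:, labeled_ids], config.min_total_count
        )
        deg = deg_table(counts, labels, config.padj_threshold, config.lfc_threshold)
        p = outdir / "deg.csv"
        deg.rename_axis("gene").to_csv(p)
        manifest["deg"] = str(p)
        deg_up = set(deg.index[deg["call"] == "up"])
        deg_down = set(deg.index[deg["call"] == "down"])
        _log("deg", f"{len(counts)} genes tested, {len(deg_up)} up, {len(deg_down)} down")
    except Exception as exc:
        _fail("deg", exc)

    # --- stage: attribution ranking --------------------------------------
    try:
        features = dataset.log_tpm.loc[counts.index, labeled_ids].T  # samples x genes
        split = stratified_split(labels, config.fraction_test, seed=config.seed)
        ranker = ShapRanker(
            n_repeats=config.n_repeats,
            n_folds=config.n_folds,
            base_seed=config.seed,
            hyperparams=config.gbdt_params,
        )
        ranker.fit(features.loc[split.train_ids], labels.loc[split.train_ids])
        p = outdir / "shap_summary.csv"
        ranker.summary_.table().rename_axis("gene").to_csv(p)
        manifest["shap_summary"] = str(p)
        holdout = evaluate_holdout(
            ranker.score_resistant(features.loc[split.test_ids]),
            labels.loc[split.test_ids],
        )
        shap_genes = contributing_genes(ranker.summary_, config.shap_epsilon)
        _log(
            "rank",
            f"{len(shap_genes)} contributing genes; holdout acc={holdout.accuracy:.3f} "
            f"roc_auc={holdout.roc_auc:.3f} pr_auc={holdout.pr_auc:.3f}",
        )
    except Exception as exc:
        _fail("rank", exc)

    # --- stage: candidate panel + elimination -----------------------------
    try:
        panel = sign_intersection(deg_up, deg_down, shap_genes)
        p = outdir / "candidate_panel.csv"
        pd.DataFrame(
            {
                "gene": panel.genes,
                "direction": ["up" if g in panel.up_genes else "down" for g in panel.genes],
            }
        ).to_csv(p, index=False)
        manifest["candidate_panel"] = str(p)
        if len(panel) == 0:
            raise ValueError(
                "empty candidate panel: no overlap between DEG "
                f"({len(deg_up)} up / {len(deg_down)} down) and the "
                f"{len(shap_genes)} attribution-contributing genes"
            )
        rfe = SpecificityRFE(
            n_folds=config.n_folds, seed=config.seed, C=config.C, max_iter=config.max_iter
        )
        rfe.fit(features.loc[split.train_ids, panel.genes], labels.loc[split.train_ids])
        p = outdir / "elimination_trace.csv"
        rfe.trace_.records.to_csv(p, index=False)
        manifest["trace"] = str(p)
        final_genes = sorted(rfe.optimal_genes_)
        p = outdir / "panel.txt"
        p.write_text("\n".join(final_genes) + "\n")
        manifest["panel"] = str(p)
        corr = panel_correlation(features.loc[split.train_ids, final_genes])
        max_off = float(np.nanmax(np.abs(corr.to_numpy() - np.eye(len(corr)))))
        _log(
            "select",
            f"candidate panel {len(panel)} -> optimal {len(final_genes)} genes; "
            f"max off-diagonal |r|={max_off:.3f}",
        )
    except Exception as exc:
        _fail("select", exc)

    # --- stage: signature fit + evaluation --------------------------------
    try:
        model = SignatureClassifier(
            C=config.C, max_iter=config.max_iter, cutoff=config.cutoff,
            random_state=config.seed,
        )
        model.fit(features.loc[split.train_ids, final_genes], labels.loc[split.train_ids])
        p = outdir / "model.txt"
        model.to_text(p)
        manifest["model"] = str(p)
        sig_metrics = evaluate_signature(
            model, features.loc[split.test_ids, final_genes], labels
        )
        sweep = cutoff_sweep(
            model.score_resistant(features.loc[split.test_ids, final_genes]),
            labels.loc[split.test_ids],
        )
        p = outdir / "metrics.json"
        metrics = {
            "gbdt_holdout": _metrics_dict(holdout),
            "signature_holdout": _metrics_dict(sig_metrics),
            "cutoff_sweep": sweep.where(pd.notna(sweep), None).to_dict("records"),
            "n_samples": dataset.n_samples,
            "n_labeled": len(labeled_ids),
            "panel_size": len(final_genes),
        }
        _write_json(p, metrics)
        manifest["metrics"] = str(p)
        _log(
            "fit",
            f"signature roc_auc={sig_metrics.roc_auc:.3f} "
            f"pr_auc={sig_metrics.pr_auc:.3f} acc={sig_metrics.accuracy:.3f}",
        )
    except Exception as exc:
        _fail("fit", exc)

    # --- report ------------------------------------------------------------
    report = {
        "n_samples_merged": dataset.n_samples,
        "clustering": {
            "method": phenotyper.method_,
            "k": phenotyper.n_clusters_,
            "silhouette": phenotyper.assignment_.silhouette,
        },
        "n_sensitive": len(sens.sensitive_ids),
        "n_resistant": len(sens.resistant_ids),
        "n_excluded": len(sens.excluded),
        "n_deg_up": len(deg_up),
        "n_deg_down": len(deg_down),
        "n_contributing": len(shap_genes),
        "candidate_panel_size": len(panel),
        "final_panel_size": len(final_genes),
        "final_panel": final_genes,
        "signature_roc_auc": sig_metrics.roc_auc,
    }
    if truth is not None:
        planted = set(truth.truth_genes.index)
        report["planted_recovery"] = (
            len(planted & set(final_genes)) / len(planted) if planted else None
        )
        report["truth_labels_path"] = str(outdir / "inputs" / "truth_labels.csv")
    p = outdir / "report.json"
    _write_json(p, report)
    manifest["report"] = str(p)

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    _write_json(outdir / "manifest.json", manifest)
    return manifest
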