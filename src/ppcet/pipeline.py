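"""End-to-end pipeline: coverage → differential screen → clustering →
comparator features → panel classifier, with a checksummed result manifest.

Every run is fully determined by the configuration and its seed; outputs
carry no timestamps, so re-running an identical configuration reproduces
checksum-identical result files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as _ann
from . import classifier as _clf
from . import comparators as _cmp
from . import coverage as _cov
from . import differential as _diff
from .fragments import FragmentSet, read_fragments

logger = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_NO_PASSING_GENES = "no_passing_genes"


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    sample_sheet: str
    annotation: str
    outdir: str
    fragments_dir: str | None = None
    annotation_format: str | None = None
    subcompartments: str | None = None
    assembly_chroms: dict[str, int] | None = None
    mito_name: str | None = None
    flank: int = 1000
    fc_threshold: float = 1.5
    fdr_threshold: float = 0.05
    pool_size: int = 20
    max_panel_size: int = 9
    enumeration_budget: int = 1_000_000
    training_fraction: float = 0.7
    normalization: str = "per-million-fragments"
    comparator_bin_size: int = 5_000_000
    svm_kernel: str = "linear"
    svm_c: float = 1.0
    dedup: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("sample_sheet", "annotation"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise ConfigError(f"{name} path missing or not found: {p!r}")
        if self.subcompartments and not Path(self.subcompartments).exists():
            raise ConfigError(f"subcompartments path not found: {self.subcompartments!r}")
        if not 0 < self.training_fraction < 1:
            raise ConfigError("training_fraction must be in (0, 1)")
        for name in ("flank", "pool_size", "max_panel_size"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.fc_threshold < 1:
            raise ConfigError("fc_threshold must be >= 1")

    def assembly(self) -> _ann.GenomeAssembly | None:
        if not self.assembly_chroms:
            return None
        return _ann.GenomeAssembly(
            tuple(self.assembly_chroms), tuple(self.assembly_chroms.values()), self.mito_name
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _load_cohort(config: PipelineConfig):
    samples = _ann.read_sample_sheet(config.sample_sheet)
    base = Path(config.fragments_dir) if config.fragments_dir else Path(config.sample_sheet).parent
    assembly = config.assembly()
    pairs = []
    for rec in samples:
        if rec.fragment_path is None:
            raise ConfigError(f"sample {rec.sample_id} has no fragment_path")
        fpath = Path(rec.fragment_path)
        if not fpath.is_absolute():
            fpath = base / fpath
        if not fpath.exists():
            raise ConfigError(f"fragment file not found: {fpath}")
        fs = read_fragments(fpath, assembly=assembly, dedup=config.dedup)
        pairs.append((rec, fs))
    return pairs, assembly


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run summary (also written as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config_dict = dataclasses.asdict(config)
    (outdir / "config.yaml").write_text(yaml.safe_dump(config_dict, sort_keys=True))
    # hash the analysis-relevant configuration (output location excluded)
    hashed = yaml.safe_dump({k: v for k, v in config_dict.items() if k != "outdir"}, sort_keys=True)

    summary: dict = {
        "status": STATUS_OK,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(hashed.encode()).hexdigest(),
    }

    # --- stage: inputs -----------------------------------------------------
    try:
        pairs, assembly = _load_cohort(config)
        genes = _ann.read_gene_annotation(config.annotation, format=config.annotation_format, assembly=assembly)
        windows = _ann.derive_promoter_windows(genes, flank=config.flank, assembly=assembly)
    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"stage 'inputs' failed: {exc}") from exc
    labels = pd.Series({r.sample_id: r.label for r, _ in pairs})
    summary["n_samples"] = len(pairs)
    summary["n_genes"] = len(genes)

    # --- stage: coverage ---------------------------------------------------
    matrix = _cov.promoter_matrix(pairs, windows, normalization=config.normalization)
    matrix.to_tsv(outdir / "promoter_matrix.tsv")
    profiles = {}
    for anchor in ("TSS", "TTS"):
        prof = _cov.meta_profiles_by_sample(pairs, genes, anchor=anchor, flank=config.flank, assembly=assembly)
        prof.to_csv(outdir / f"meta_profile_{anchor.lower()}.tsv", sep="\t", index_label="sample_id")
        profiles[anchor] = prof
    summary["meta_profile_p"] = {
        anchor: _diff.meta_profile_group_test(prof, labels) for anchor, prof in profiles.items()
    }

    # --- stage: split + differential --------------------------------------
    split = _clf.chronological_split([r for r, _ in pairs], config.training_fraction)
    summary["split"] = {"training": split.training, "validation": split.validation}
    screen = _diff.differential_screen(
        matrix.values[split.training],
        labels,
        fc_threshold=config.fc_threshold,
        fdr_threshold=config.fdr_threshold,
    )
    screen.to_csv(outdir / "differential_promoters.tsv", sep="\t")
    n_passing = int(screen["passes"].sum())
    summary["n_passing_genes"] = n_passing

    # --- stage: z-scores + clustering --------------------------------------
    if n_passing >= 2:
        zmat = _diff.zscore_and_cluster(matrix.values.loc[screen.index[screen["passes"]]])
        zmat.z.to_csv(outdir / "zscore_matrix.tsv", sep="\t", index_label="gene_id")
        _write_json({"row_order": zmat.row_order, "col_order": zmat.col_order}, outdir / "cluster_orders.json")

    # --- stage: comparator features ----------------------------------------
    comparator_tables: dict[str, pd.DataFrame] = {}
    if assembly is not None:
        comparator_tables["5mb"] = _cmp.comparator_feature_table(
            pairs, assembly, "fragment_ratio_5mb", bin_size=config.comparator_bin_size
        )
        if config.subcompartments:
            regions = _cmp.read_region_classes(config.subcompartments)
            comparator_tables["subcompartment"] = _cmp.comparator_feature_table(
                pairs, assembly, "subcompartment_coverage", regions=regions
            )
        if assembly.mito_name is not None:
            comparator_tables["mtdna"] = _cmp.comparator_feature_table(pairs, assembly, "mtdna")
        for name, table in comparator_tables.items():
            table.to_csv(outdir / f"features_{name}.tsv", sep="\t", index_label="sample_id")

    # --- stage: classifier --------------------------------------------------
    if n_passing == 0:
        logger.warning("no promoters pass the differential screen; classifier stage skipped")
        summary["status"] = STATUS_NO_PASSING_GENES
    else:
        features_all = matrix.values.T  # samples × genes
        candidates = _clf.rank_candidates(screen)
        search = _clf.panel_search(
            candidates,
            features_all.loc[split.training],
            labels[split.training],
            max_panel_size=config.max_panel_size,
            pool_size=config.pool_size,
            enumeration_budget=config.enumeration_budget,
            kernel=config.svm_kernel,
            c=config.svm_c,
            seed=config.seed,
        )
        panel = list(search.best.panel)
        threshold = search.best.threshold
        evaluations = {"training": search.best}

        val_scores = _clf.train_and_score(
            features_all.loc[split.training, panel], labels[split.training],
            features_all.loc[split.validation, panel],
            kernel=config.svm_kernel, c=config.svm_c,
        )
        evaluations["validation"] = _clf.evaluate_scores(
            val_scores, labels[split.validation], "validation", panel, threshold=threshold
        )
        all_scores = _clf.loocv_scores(features_all[panel], labels, kernel=config.svm_kernel, c=config.svm_c)
        evaluations["all"] = _clf.evaluate_scores(all_scores, labels, "all", panel, threshold=threshold)

        metrics = {name: ev.metrics() for name, ev in evaluations.items()}
        for name, ev in evaluations.items():
            pd.DataFrame({"fpr": ev.roc.fpr, "tpr": ev.roc.tpr, "threshold": ev.roc.thresholds}).to_csv(
                outdir / f"roc_{name}.tsv", sep="\t", index=False
            )
            ev.scores.to_csv(outdir / f"scores_{name}.tsv", sep="\t", index_label="sample_id")

        comparator_metrics = {}
        for name, table in comparator_tables.items():
            try:
                scores = _clf.loocv_scores(table, labels, kernel=config.svm_kernel, c=config.svm_c)
            except ValueError as exc:
                logger.warning("comparator %s classifier skipped: %s", name, exc)
                continue
            ev = _clf.evaluate_scores(scores, labels, f"all:{name}", list(table.columns))
            comparator_metrics[name] = {
                "auc": ev.auc,
                "auc_ci": list(ev.auc_ci),
                "p_vs_promoter_panel": _clf.compare_auc(all_scores, scores, labels),
            }
        metrics["comparators"] = comparator_metrics
        _write_json(metrics, outdir / "metrics.json")
        summary["panel"] = panel
        summary["metrics"] = metrics

        model = fit_frozen_model(
            features_all.loc[split.training, panel], labels[split.training],
            panel, threshold, kernel=config.svm_kernel, c=config.svm_c,
        )
        _write_json(model, outdir / "frozen_model.json")

    # --- manifest -----------------------------------------------------------
    _write_json(summary, outdir / "summary.json")
    manifest = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name not in ("manifest.json", "config.yaml")
    }
    _write_json(manifest, outdir / "manifest.json")
    return summary


# ---------------------------------------------------------------------------
# frozen model + prediction
# ---------------------------------------------------------------------------

def fit_frozen_model(
    features: pd.DataFrame,
    labels,
    panel: list[str],
    threshold: float,
    kernel: str = "linear",
    c: float = 1.0,
) -> dict:
    """Train on the full labeled cohort and freeze a linear scoring rule.

    Only the linear kernel can be frozen to (w, b); the decision score of
    a new sample x is w · (x − mu) / sd + b, called positive at the
    frozen threshold.
    """
    if kernel != "linear":
        raise ValueError("only linear-kernel models can be frozen to weights")
    y = _clf._binary(pd.Series(labels)[features.index])
    x = features[panel].to_numpy(dtype=np.float64)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    clf = _clf._fit_svm((x - mu) / sd, y, kernel, c)
    return {
        "panel": list(panel),
        "mu": mu.tolist(),
        "sd": sd.tolist(),
        "w": clf.coef_.ravel().tolist(),
        "b": float(clf.intercept_[0]),
        "threshold": float(threshold),
    }


def predict_samples(model: dict, features: pd.DataFrame) -> pd.DataFrame:
    """Score unlabeled samples with a frozen panel model."""
    panel = model["panel"]
    missing = [g for g in panel if g not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks panel genes: {missing[:5]}")
    x = features[panel].to_numpy(dtype=np.float64)
    z = (x - np.asarray(model["mu"])) / np.asarray(model["sd"])
    scores = z @ np.asarray(model["w"]) + model["b"]
    return pd.DataFrame(
        {
            "score": scores,
            "predicted_label": np.where(scores >= model["threshold"], _clf.POSITIVE_LABEL, _clf.NEGATIVE_LABEL),
        },
        index=features.index,
    )
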