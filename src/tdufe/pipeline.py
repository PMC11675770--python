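"""End-to-end orchestration: tensor → HOSVD → factor choice → genes → enrichment.

A run is driven by a :class:`RunConfig` (usually loaded from YAML). Every
stage writes its artifact into the output directory, and a JSON run report
records versions, a hash of the effective configuration, stage timings and the
headline counts. The analysis path itself is deterministic; the only
randomness is the synthetic-data seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import hypergeometric_enrichment, read_gmt
from .factor_selection import choose_factors, groups_from_labels
from .gene_selection import select_genes
from .hosvd import hosvd
from .synthetic import SyntheticSpec, generate_tensor
from .tensor_io import (
    ExpressionTensor,
    filter_features,
    read_expression_matrices,
    save_tensor,
    standardize_tensor,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Effective settings for one pipeline run; every default is documented here.

    ``input_mode`` is ``"synthetic"`` (draw from :class:`SyntheticSpec`) or
    ``"tables"`` (read expression matrices via ``table_paths``/``layout``).
    ``groups`` is a slice-label partition string like ``"A101D:MeWo"``; when
    None and K = 2 the two slices form the contrast. ``l1``/``l2``/``l3``
    override the automatic factor choice. ``threshold`` is the BH-adjusted
    p cutoff (0.01 by default).
    """

    input_mode: str = "synthetic"
    synthetic: dict[str, Any] = field(default_factory=dict)
    table_paths: list[str] = field(default_factory=list)
    layout: dict[str, tuple[str, str]] = field(default_factory=dict)
    normalization_policy: str = "per_column"
    log_offset: float | None = None
    min_nonzero: int = 0
    min_variance: float = 0.0
    l1: int | None = None
    l2: int | None = None
    l3: int | None = None
    groups: str | None = None
    threshold: float = 0.01
    n_bins: int = 100
    exclude_low_p_bins: int = 1
    gmt_paths: list[str] = field(default_factory=list)
    min_overlap: int = 1
    output_dir: str = "tdufe_run"
    seed: int = 0

    def effective_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d.pop("output_dir")  # where results land does not change what they are
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.effective_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_config(path: str | Path) -> tuple[RunConfig | None, list[str]]:
    """Load and validate a YAML config, collecting all errors (not fail-fast)."""
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except (OSError, yaml.YAMLError) as err:
        return None, [f"cannot parse config: {err}"]
    if not isinstance(raw, dict):
        return None, ["config root must be a mapping"]

    errors: list[str] = []
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in raw:
        if key not in known:
            errors.append(f"unknown config key: {key!r}")
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in known})
    if isinstance(cfg.layout, dict):
        cfg.layout = {k: tuple(v) for k, v in cfg.layout.items()}

    if cfg.input_mode not in ("synthetic", "tables"):
        errors.append(f"input_mode: must be 'synthetic' or 'tables', got {cfg.input_mode!r}")
    if cfg.input_mode == "tables":
        if not cfg.table_paths:
            errors.append("table_paths: required for input_mode 'tables'")
        for p in cfg.table_paths:
            if not Path(p).exists():
                errors.append(f"table_paths: {p} does not exist")
        if not cfg.layout:
            errors.append("layout: required for input_mode 'tables'")
    if cfg.input_mode == "synthetic":
        try:
            SyntheticSpec(**cfg.synthetic).validate()
        except (TypeError, ValueError) as err:
            errors.append(f"synthetic: {err}")
    if cfg.normalization_policy not in ("per_column", "per_feature", "global"):
        errors.append(f"normalization_policy: unknown policy {cfg.normalization_policy!r}")
    if not 0 < cfg.threshold < 1:
        errors.append(f"threshold: must be in (0, 1), got {cfg.threshold}")
    if cfg.n_bins < 10:
        errors.append(f"n_bins: must be >= 10, got {cfg.n_bins}")
    if cfg.min_nonzero < 0 or cfg.min_variance < 0:
        errors.append("filter thresholds must be nonnegative")
    for p in cfg.gmt_paths:
        if not Path(p).exists():
            errors.append(f"gmt_paths: {p} does not exist")
    return (None, errors) if errors else (cfg, [])


def _build_tensor(cfg: RunConfig) -> tuple[ExpressionTensor, Any]:
    if cfg.input_mode == "synthetic":
        spec_kwargs = dict(cfg.synthetic)
        spec_kwargs.setdefault("seed", cfg.seed)
        tensor, truth = generate_tensor(SyntheticSpec(**spec_kwargs))
        return tensor, truth
    tensor = read_expression_matrices(cfg.table_paths, cfg.layout)
    return tensor, None


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage, writing all intermediate artifacts and a run report.

    Stage failures abort with the failing stage named; artifacts written by
    completed stages are retained. A missing/empty GMT list skips enrichment
    with a warning rather than failing the run.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "config": config.effective_dict(),
        "stages": {},
    }
    timings: dict[str, float] = {}

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s started", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 4)
                if exc is not None:
                    report["failed_stage"] = name
                    report["stage_timings"] = timings
                    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
                    logger.error("stage %s failed: %s", name, exc)
                return False

        return _Timer()

    with stage("build_tensor"):
        tensor, truth = _build_tensor(config)
        raw_shape = tensor.shape
        tensor, removed = filter_features(tensor, config.min_nonzero, config.min_variance)
        removed.to_csv(out / "removed_features.tsv", sep="\t", index=False)
        tensor = standardize_tensor(tensor, config.normalization_policy, config.log_offset)
        save_tensor(tensor, out / "tensor")
        if truth is not None:
            pd.DataFrame(
                {
                    "feature_id": tensor.feature_ids,
                    "is_signal": truth.signal_mask.astype(int),
                    "direction": truth.planted_directions,
                }
            ).to_csv(out / "truth.tsv", sep="\t", index=False)

    with stage("decompose"):
        result = hosvd(tensor)
        result.save(out / "hosvd")

    with stage("select_factors"):
        groups = (
            groups_from_labels(tensor.slice_labels, config.groups) if config.groups else None
        )
        manual = (
            (config.l1, config.l2, config.l3)
            if any(v is not None for v in (config.l1, config.l2, config.l3))
            else None
        )
        choice = choose_factors(result, groups=groups, manual=manual)
        scores = pd.DataFrame(
            {
                "candidate": range(len(choice.core_magnitudes)),
                "core_magnitude": choice.core_magnitudes,
            }
        )
        scores.to_csv(out / "factor_scores.tsv", sep="\t", index=False)
        report["factor_choice"] = {"l1": choice.l1, "l2": choice.l2, "l3": choice.l3,
                                   "mode": choice.mode}

    with stage("select_genes"):
        u = result.factors[0][:, choice.l1]
        sel = select_genes(
            u,
            threshold=config.threshold,
            n_bins=config.n_bins,
            exclude_low_p_bins=config.exclude_low_p_bins,
        )
        sel.to_frame(tensor.feature_ids, u).to_csv(out / "gene_table.tsv", sep="\t", index=False)
        sel.flatness_profile.to_csv(out / "flatness_profile.tsv", sep="\t", index=False)
        selected_ids = [f for f, s in zip(tensor.feature_ids, sel.selected) if s]
        (out / "selected_genes.txt").write_text("".join(f"{g}\n" for g in selected_ids))
        (out / "universe_genes.txt").write_text("".join(f"{g}\n" for g in tensor.feature_ids))
        report["sigma"] = sel.sigma

    existing_gmts = [p for p in config.gmt_paths if Path(p).exists()]
    if existing_gmts:
        with stage("enrich"):
            frames = []
            for p in existing_gmts:
                coll = read_gmt(p)
                df = hypergeometric_enrichment(
                    selected_ids, tensor.feature_ids, coll, min_overlap=config.min_overlap
                )
                df.insert(0, "collection", Path(p).stem)
                frames.append(df)
            enr = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            report["n_enriched_terms"] = (
                int((enr["p_adjusted"] < 0.05).sum()) if len(enr) else 0
            )
    else:
        if config.gmt_paths:
            logger.warning("GMT files missing: %s — enrichment skipped", config.gmt_paths)
            report["stages"]["enrich"] = "skipped: GMT files missing"
        else:
            report["stages"]["enrich"] = "skipped: no GMT files configured"

    report["tensor_shape_raw"] = list(raw_shape)
    report["counts"] = {
        "N": tensor.shape[0],
        "M": tensor.shape[1],
        "K": tensor.shape[2],
        "n_selected": sel.n_selected,
    }
    report["stage_timings"] = timings
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
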