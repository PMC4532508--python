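"""End-to-end pipeline: simulate → screen → fit → evaluate → project.

RunConfig captures every knob a run depends on (thresholds, averaging
mode, seed); it is serialized, with a content hash, into the run
directory so any output can be traced to its configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluation, mmi, projection, screening, synthetic
from .raster import RasterGrid, write_ascii_raster
from .sites import SiteTable, write_site_table

log = logging.getLogger("mmisdm")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "mmisdm_run"
    seed: int = 0
    correlation_threshold: float = 0.70
    confidence_level: float = 0.95
    averaging_mode: str = "zero"  # zero-substitution | natural
    threshold_rule: str = "sens=spec"  # or "fixed"
    fixed_threshold: float | None = None
    # synthetic-world settings (used when no site CSV is supplied)
    grid_rows: int = 100
    grid_cols: int = 100
    n_sites: int = 204
    sites_csv: str | None = None  # pre-existing site table, else simulate
    synthetic: dict = field(default_factory=dict)  # extra SyntheticConfig kwargs

    def __post_init__(self) -> None:
        if not 0 < self.correlation_threshold <= 1:
            raise ValueError("correlation threshold must be in (0, 1]")
        if not 0 < self.confidence_level <= 1:
            raise ValueError("confidence level must be in (0, 1]")
        if self.averaging_mode not in ("zero", "natural"):
            raise ValueError("averaging mode must be 'zero' or 'natural'")
        if self.threshold_rule not in ("sens=spec", "fixed"):
            raise ValueError("threshold rule must be 'sens=spec' or 'fixed'")
        if self.threshold_rule == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold rule requires fixed_threshold")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _provenance_header(cfg: RunConfig) -> str:
    return f"# mmisdm config_hash={cfg.config_hash()} seed={cfg.seed}\n"


def _write_csv(df, path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(cfg))
        df.to_csv(fh, index=False)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured pipeline; returns the run directory.

    Artifacts written: site tables, screening report, model-selection
    and averaged-coefficient tables, evaluation report, suitability /
    CI / variance-ratio rasters per scenario, binary range rasters and
    the areal-change summary.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "rasters").mkdir(exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    logging.basicConfig(level=logging.INFO)
    log.info("run start: hash=%s seed=%d", cfg.config_hash(), cfg.seed)

    # --- simulate ---------------------------------------------------
    syn_cfg = synthetic.SyntheticConfig(
        nrows=cfg.grid_rows, ncols=cfg.grid_cols, n_sites=cfg.n_sites,
        seed=cfg.seed, **cfg.synthetic,
    )
    rasters = synthetic.generate_predictor_rasters(syn_cfg)
    truth = synthetic.true_suitability(syn_cfg, rasters)
    if cfg.sites_csv is not None:
        from .sites import read_site_table

        sites = read_site_table(cfg.sites_csv)
    else:
        sites = synthetic.sample_sites(
            rasters, syn_cfg.coefficient_vector(), syn_cfg.n_sites, cfg.seed
        )
    write_site_table(sites, out / "sites.csv")
    log.info("sites: n=%d prevalence=%.3f", sites.n_sites, sites.prevalence)

    # --- screen -----------------------------------------------------
    report = screening.screen_predictors(
        sites, threshold=cfg.correlation_threshold
    )
    _write_csv(report.correlation.reset_index(names="predictor"),
               out / "screening_correlations.csv", cfg)
    (out / "screening_decisions.json").write_text(report.to_json())
    retained = report.retained
    log.info("screening retained %d/%d predictors: %s",
             len(retained), len(sites.predictors), retained)

    # --- split + fit ------------------------------------------------
    train, test = synthetic.split_train_test(sites, seed=cfg.seed)
    write_site_table(train, out / "sites_train.csv")
    write_site_table(test, out / "sites_test.csv")
    cands = mmi.enumerate_candidates(train.select_predictors(retained))
    cands = mmi.confidence_set(cands, cfg.confidence_level)
    avg = mmi.average_coefficients(cands, mode=cfg.averaging_mode,
                                   order_hint=retained)
    _write_csv(cands.selection_table(), out / "model_selection.csv", cfg)
    _write_csv(avg.coefficient_table(), out / "averaged_coefficients.csv", cfg)
    for m, flag in zip(cands.models, cands.in_confidence_set):
        log.info("model %-40s converged=%s in_set=%s",
                 " + ".join(m.predictors), m.converged, bool(flag))

    # --- evaluate ---------------------------------------------------
    test_pred = mmi.predict_averaged(
        cands, avg, test.predictor_matrix(avg.predictors)
    )
    scores = np.asarray(test_pred.mean)
    if cfg.threshold_rule == "fixed":
        eval_report = evaluation.evaluate(scores, test.presence,
                                          threshold=cfg.fixed_threshold)
    else:
        eval_report = evaluation.evaluate(scores, test.presence)
    (out / "evaluation.json").write_text(eval_report.to_json())
    _write_csv(eval_report.roc, out / "roc_points.csv", cfg)
    threshold = eval_report.threshold
    log.info("evaluation: AUC=%.3f threshold=%.3f TSS=%.3f",
             eval_report.auc, threshold, eval_report.tss)

    # --- project ----------------------------------------------------
    scenario_stacks: dict[str, dict[str, RasterGrid]] = {"current": rasters}
    for name, deltas in syn_cfg.future_deltas.items():
        scenario_stacks[name] = synthetic.make_future_rasters(rasters, deltas)
    ranges: dict[str, RasterGrid] = {}
    for name, stack in scenario_stacks.items():
        fields = projection.project_suitability(cands, avg, stack)
        for fname in ("mean", "ci_width", "variance_ratio"):
            write_ascii_raster(fields[fname],
                               out / "rasters" / f"{name}_{fname}.asc")
        rng = projection.classify_range(fields["mean"], threshold)
        write_ascii_raster(rng, out / "rasters" / f"{name}_range.asc")
        ranges[name] = rng
    write_ascii_raster(truth.suitability, out / "rasters" / "true_suitability.asc")
    baseline = ranges.pop("current")
    results = projection.area_and_change(baseline, ranges, threshold)
    _write_csv(projection.scenario_table(results), out / "areal_change.csv", cfg)
    for r in results:
        log.info("scenario %-12s area=%.0f km² change=%.2f%%",
                 r.scenario, r.suitable_area_km2, r.percent_change)
    return out
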