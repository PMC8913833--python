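"""End-to-end analysis orchestration.

QC -> per-time-point correlation networks -> small-worldness and local
efficiency over the threshold sweep -> backbone networks -> permutation
group comparisons with FDR correction, all driven by one config and one
master seed.  Two runs with identical config produce identical reports.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import (DegenerateMetricError, InvalidParameterError,
                     UndefinedRatioError)
from .metrics import small_worldness, local_efficiency
from .network import (DEFAULT_SIGN_ALPHA, DEFAULT_THRESHOLDS, backbone,
                      spearman_matrix, threshold_sweep, write_edge_list)
from .panel import MetabolitePanel
from .qc import filter_by_crlb
from .seeding import int_seed
from .stats import (DEFAULT_N_PERM, DEFAULT_N_RANDOM_PERM, apply_fdr,
                    make_backbone_local_eff_auc_metric,
                    make_backbone_sw_auc_metric, make_local_eff_auc_metric,
                    make_sw_auc_metric, permutation_test)
from .synthetic import (CohortConfig, default_cohort_config, generate_cohort,
                        read_cohort_csv)

logger = logging.getLogger("metabnet")


@dataclass
class AnalysisConfig:
    """All constants of the analysis in one place (defaults as in Methods:
    thresholds 0.41-0.49 step 0.01, CRLB < 35%, sign-test alpha 0.025,
    1000 random networks, 1000 permutations)."""

    cohort: CohortConfig | None = None
    input_csv: str | None = None
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    crlb_threshold: float = 35.0
    sign_alpha: float = DEFAULT_SIGN_ALPHA
    backbone_aggregate: str = "min"
    backbone_count_mode: str = "raw"
    n_random: int = 1000
    n_perm: int = DEFAULT_N_PERM
    n_random_perm: int = DEFAULT_N_RANDOM_PERM
    n_swap_per_edge: int = 10
    seed: int = 0
    compare_time_points: tuple[int, ...] | None = None
    compare_metabolites: tuple[str, ...] | None = None
    run_comparisons: bool = True
    run_backbone_comparisons: bool = True

    def __post_init__(self):
        ts = tuple(float(t) for t in self.thresholds)
        if not ts or any(b <= a for a, b in zip(ts, ts[1:])):
            raise InvalidParameterError("thresholds must be non-empty, strictly increasing")
        self.thresholds = ts
        if self.cohort is None and self.input_csv is None:
            self.cohort = default_cohort_config(seed=self.seed)

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict() if self.cohort else None,
            "input_csv": self.input_csv,
            "thresholds": list(self.thresholds),
            "crlb_threshold": self.crlb_threshold,
            "sign_alpha": self.sign_alpha,
            "backbone_aggregate": self.backbone_aggregate,
            "backbone_count_mode": self.backbone_count_mode,
            "n_random": self.n_random,
            "n_perm": self.n_perm,
            "n_random_perm": self.n_random_perm,
            "n_swap_per_edge": self.n_swap_per_edge,
            "seed": self.seed,
            "compare_time_points": (list(self.compare_time_points)
                                    if self.compare_time_points else None),
            "compare_metabolites": (list(self.compare_metabolites)
                                    if self.compare_metabolites else None),
            "run_comparisons": self.run_comparisons,
            "run_backbone_comparisons": self.run_backbone_comparisons,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        cohort = CohortConfig.from_dict(d["cohort"]) if d.get("cohort") else None
        kwargs = {k: d[k] for k in (
            "input_csv", "crlb_threshold", "sign_alpha", "backbone_aggregate",
            "backbone_count_mode", "n_random", "n_perm", "n_random_perm",
            "n_swap_per_edge", "seed", "run_comparisons",
            "run_backbone_comparisons") if k in d}
        if d.get("thresholds"):
            kwargs["thresholds"] = tuple(d["thresholds"])
        if d.get("compare_time_points"):
            kwargs["compare_time_points"] = tuple(int(t) for t in d["compare_time_points"])
        if d.get("compare_metabolites"):
            kwargs["compare_metabolites"] = tuple(d["compare_metabolites"])
        return cls(cohort=cohort, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def sw_sweep_results(mat, thresholds: Sequence[float], n_random: int,
                     n_swap_per_edge: int, seed: int) -> list[dict]:
    """Sigma/gamma/lambda per threshold; an undefined ratio (degenerate null
    ensemble or edgeless network) is recorded as sigma = NaN with
    meets_criterion False rather than aborting the sweep."""
    rows = []
    for i, net in enumerate(threshold_sweep(mat, thresholds)):
        row = {"group": mat.group, "time_point": mat.time_point,
               "threshold": float(net.threshold), "n_edges": net.n_edges}
        try:
            res = small_worldness(net, n_random=n_random,
                                  n_swap_per_edge=n_swap_per_edge,
                                  seed=int_seed(seed, "sweep", mat.group,
                                                mat.time_point, i))
            row.update(sigma=res.sigma, gamma=res.gamma, lam=res.lam,
                       e_global=res.real.e_global,
                       e_local_mean=res.real.e_local_mean,
                       rand_e_global_mean=res.rand_e_global_mean,
                       rand_e_local_mean=res.rand_e_local_mean,
                       meets_criterion=res.meets_criterion)
        except (InvalidParameterError, UndefinedRatioError) as exc:
            logger.info("sigma undefined at %s: %s", row, exc)
            row.update(sigma=math.nan, gamma=math.nan, lam=math.nan,
                       e_global=math.nan, e_local_mean=math.nan,
                       rand_e_global_mean=math.nan, rand_e_local_mean=math.nan,
                       meets_criterion=False)
        rows.append(row)
    return rows


def _local_eff_rows(mat, thresholds: Sequence[float]) -> list[dict]:
    rows = []
    for net in threshold_sweep(mat, thresholds):
        el = local_efficiency(net)
        for name, val in el.items():
            rows.append({"group": mat.group, "time_point": mat.time_point,
                         "threshold": float(net.threshold),
                         "metabolite": name, "e_local": val})
    return rows


def run_full_analysis(config: AnalysisConfig,
                      out_dir: str | Path | None = None) -> dict:
    """Execute all stages; returns the full report as a plain dict and
    optionally writes JSON + CSV + edge-list artifacts under out_dir."""
    t0 = time.time()
    if config.input_csv is not None:
        table = read_cohort_csv(config.input_csv)
    else:
        table = generate_cohort(config.cohort)

    filtered, qc_report = filter_by_crlb(table, config.crlb_threshold)
    panel = MetabolitePanel(tuple(qc_report.retained_metabolites))
    groups = sorted(filtered["group"].unique())
    time_points = sorted(int(t) for t in filtered["time_point"].unique())
    logger.info("QC kept %d metabolites, %d/%d subjects", len(panel),
                qc_report.n_subjects_after, qc_report.n_subjects_before)

    sw_rows: list[dict] = []
    eloc_rows: list[dict] = []
    backbone_info: dict[str, dict] = {}
    matrices: dict[str, list] = {}
    for group in groups:
        mats = [spearman_matrix(filtered, group, tp, panel)
                for tp in time_points]
        matrices[group] = mats
        for mat in mats:
            sw_rows.extend(sw_sweep_results(mat, config.thresholds,
                                            config.n_random,
                                            config.n_swap_per_edge,
                                            config.seed))
            eloc_rows.extend(_local_eff_rows(mat, config.thresholds))
        bb = backbone(mats, alpha=config.sign_alpha,
                      aggregate=config.backbone_aggregate,
                      count_mode=config.backbone_count_mode,
                      count_threshold=config.thresholds[0])
        sw_rows.extend(sw_sweep_results(bb.matrix, config.thresholds,
                                        config.n_random,
                                        config.n_swap_per_edge, config.seed))
        eloc_rows.extend(_local_eff_rows(bb.matrix, config.thresholds))
        backbone_info[group] = {
            "n_eligible_pairs": int(np.triu(bb.eligible, 1).sum()),
            "edges_at": {
                f"{t:.2f}": sorted(map(list, net.edges()))
                for t, net in zip(config.thresholds,
                                  threshold_sweep(bb.matrix, config.thresholds))
            },
            "result": bb,
        }

    comparisons = []
    failed_comparisons: list[dict] = []

    def run_family(jobs):
        """Run one FDR family of permutation tests; a comparison whose
        metric is degenerate even for the observed split (e.g. the sigma of
        a near-empty backbone) is recorded as failed, not fatal."""
        done = []
        for metric, seed_labels, scope in jobs:
            try:
                done.append(permutation_test(
                    filtered, metric, n_perm=config.n_perm,
                    seed=int_seed(config.seed, *seed_labels), scope=scope))
            except DegenerateMetricError as exc:
                logger.warning("comparison %s degenerate: %s", scope, exc)
                failed_comparisons.append({
                    "metric": getattr(metric, "__name__", "metric"),
                    "scope": list(scope), "error": str(exc)})
        comparisons.extend(apply_fdr(done))

    if config.run_comparisons and len(groups) == 2:
        cmp_tps = (list(config.compare_time_points)
                   if config.compare_time_points else time_points)
        cmp_metabs = (list(config.compare_metabolites)
                      if config.compare_metabolites else list(panel.names))
        run_family([
            (make_sw_auc_metric(tp, panel, config.thresholds,
                                n_random=config.n_random_perm,
                                n_swap_per_edge=config.n_swap_per_edge),
             ("cmp-sw", tp), ("sw", tp))
            for tp in cmp_tps])
        run_family([
            (make_local_eff_auc_metric(metab, tp, panel, config.thresholds),
             ("cmp-eloc", tp, metab), ("e_local", tp, metab))
            for tp in cmp_tps for metab in cmp_metabs])
        if config.run_backbone_comparisons:
            run_family([
                (make_backbone_sw_auc_metric(
                    panel, config.thresholds, alpha=config.sign_alpha,
                    aggregate=config.backbone_aggregate,
                    count_mode=config.backbone_count_mode,
                    count_threshold=config.thresholds[0],
                    n_random=config.n_random_perm,
                    n_swap_per_edge=config.n_swap_per_edge),
                 ("cmp-bbsw",), ("backbone_sw",))])
            run_family([
                (make_backbone_local_eff_auc_metric(
                    metab, panel, config.thresholds, alpha=config.sign_alpha,
                    aggregate=config.backbone_aggregate,
                    count_mode=config.backbone_count_mode,
                    count_threshold=config.thresholds[0]),
                 ("cmp-bbeloc", metab), ("backbone_e_local", metab))
                for metab in cmp_metabs])

    report = {
        "version": __version__,
        "config": config.to_dict(),
        "qc": qc_report.to_dict(),
        "groups": groups,
        "time_points": time_points,
        "sw": sw_rows,
        "local_efficiency": eloc_rows,
        "backbone": {g: {"n_eligible_pairs": info["n_eligible_pairs"],
                         "edges_at": info["edges_at"]}
                     for g, info in backbone_info.items()},
        "comparisons": [{
            "metric": c.metric_name, "scope": list(c.scope),
            "groups": list(c.groups),
            "auc_first": c.group_aucs[0], "auc_second": c.group_aucs[1],
            "observed_diff": c.observed_diff,
            "critical_value": c.critical_value,
            "rejects_critical": c.rejects_critical,
            "p_value": c.p_value, "p_fdr": c.p_fdr,
            "n_perm": c.n_perm, "seed": c.seed, "n_redraws": c.n_redraws,
        } for c in comparisons],
        "failed_comparisons": failed_comparisons,
        "elapsed_s": round(time.time() - t0, 3),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        pd.DataFrame(sw_rows).to_csv(out / "sw_metrics.csv", index=False)
        pd.DataFrame(eloc_rows).to_csv(out / "local_efficiency.csv", index=False)
        if report["comparisons"]:
            pd.DataFrame(report["comparisons"]).to_csv(
                out / "comparisons.csv", index=False)
        for group, info in backbone_info.items():
            bb = info["result"]
            for t, net in zip(config.thresholds,
                              threshold_sweep(bb.matrix, config.thresholds)):
                write_edge_list(net, out / f"backbone_{group}_{t:.2f}.tsv",
                                weights=bb.matrix)
    return report
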