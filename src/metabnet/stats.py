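"""Threshold-sweep summaries (AUC) and permutation group comparisons.

A metric curve (small-worldness sigma, or one metabolite's local efficiency)
is evaluated over the correlation-threshold sweep and summarized by its
trapezoidal area under the curve.  Group differences in AUC are tested by
permuting whole subjects between groups — a subject's entire longitudinal
record moves together — recomputing both groups' AUCs each time.  The 95th
percentile of the permutation null is the one-tailed critical value
(nominal type-I error 0.05); a two-sided permutation p-value is reported
alongside, and families of p-values are FDR-adjusted (Benjamini-Hochberg).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import _engine
from .errors import (DegenerateMetricError, InsufficientDataError,
                     InvalidParameterError, UndefinedRatioError)
from .metrics import small_worldness, local_efficiency
from .network import (DEFAULT_THRESHOLDS, _backbone_core,
                      abs_spearman_from_array, backbone, spearman_matrix,
                      threshold_sweep)
from .panel import MetabolitePanel
from .seeding import int_seed, rng_for

DEFAULT_N_PERM = 1000

#: Null-ensemble size used for sigma inside permutation-metric evaluations.
#: Monte-Carlo noise in sigma is shared by observed and permuted statistics,
#: so it does not bias the test's level; this is a compute knob only.
DEFAULT_N_RANDOM_PERM = 100


@dataclass(frozen=True)
class ThresholdCurve:
    thresholds: tuple[float, ...]
    values: tuple[float, ...]
    metric_name: str
    provenance: tuple

    def __post_init__(self):
        ts = tuple(float(t) for t in self.thresholds)
        vs = tuple(float(v) for v in self.values)
        object.__setattr__(self, "thresholds", ts)
        object.__setattr__(self, "values", vs)
        if len(ts) != len(vs):
            raise InvalidParameterError("thresholds and values must have equal length")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise InvalidParameterError("thresholds must be strictly increasing")


@dataclass(frozen=True)
class PermutationComparison:
    """Observed AUC difference (first group minus second) and its
    permutation null."""

    metric_name: str
    scope: tuple
    groups: tuple[str, str]
    observed_diff: float
    group_aucs: tuple[float, float]
    null_diffs: tuple[float, ...]
    critical_value: float
    rejects_critical: bool
    p_value: float
    p_fdr: float
    n_perm: int
    seed: int
    n_redraws: int = 0


def auc_over_thresholds(curve: ThresholdCurve) -> float:
    """Trapezoidal integral of the metric over the threshold grid."""
    if len(curve.thresholds) < 2:
        raise InvalidParameterError("AUC needs >= 2 thresholds")
    return float(np.trapezoid(curve.values, curve.thresholds))


def fdr_correct(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InvalidParameterError("p-values must lie in (0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adj]


# ---------------------------------------------------------------------------
# metric curves

def sw_curve(table: pd.DataFrame, group: str | None, time_point: int,
             panel: MetabolitePanel,
             thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
             n_random: int = DEFAULT_N_RANDOM_PERM,
             n_swap_per_edge: int = 10, seed: int = 0) -> ThresholdCurve:
    """Small-worldness sigma as a function of threshold for one group/time.

    Raises :class:`DegenerateMetricError` if sigma is undefined (edgeless
    network or degenerate null ensemble) at any threshold.
    """
    mat = spearman_matrix(table, group, time_point, panel)
    sigmas = []
    for i, net in enumerate(threshold_sweep(mat, thresholds)):
        try:
            res = small_worldness(net, n_random=n_random,
                                  n_swap_per_edge=n_swap_per_edge,
                                  seed=int_seed(seed, "sw", i))
        except (InvalidParameterError, UndefinedRatioError) as exc:
            raise DegenerateMetricError(
                f"sigma undefined at threshold {net.threshold}: {exc}"
            ) from None
        sigmas.append(res.sigma)
    return ThresholdCurve(thresholds=tuple(thresholds), values=tuple(sigmas),
                          metric_name="sigma", provenance=(group, time_point))


def local_eff_curve(table: pd.DataFrame, group: str | None, time_point: int,
                    metabolite: str, panel: MetabolitePanel,
                    thresholds: Sequence[float] = DEFAULT_THRESHOLDS
                    ) -> ThresholdCurve:
    """One metabolite's local efficiency across the threshold sweep."""
    mat = spearman_matrix(table, group, time_point, panel)
    vals = [local_efficiency(net)[metabolite]
            for net in threshold_sweep(mat, thresholds)]
    return ThresholdCurve(thresholds=tuple(thresholds), values=tuple(vals),
                          metric_name=f"e_local[{metabolite}]",
                          provenance=(group, time_point))


def _backbone_matrix(table: pd.DataFrame, panel: MetabolitePanel,
                     alpha: float, aggregate: str, count_mode: str,
                     count_threshold: float):
    tps = sorted(int(t) for t in table["time_point"].unique())
    if len(tps) < 2:
        raise DegenerateMetricError("backbone needs >= 2 time points")
    mats = [spearman_matrix(table, None, tp, panel) for tp in tps]
    return backbone(mats, alpha=alpha, aggregate=aggregate,
                    count_mode=count_mode, count_threshold=count_threshold).matrix


def backbone_sw_curve(table: pd.DataFrame, panel: MetabolitePanel,
                      thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                      alpha: float = 0.025, aggregate: str = "min",
                      count_mode: str = "raw", count_threshold: float = 0.41,
                      n_random: int = DEFAULT_N_RANDOM_PERM,
                      n_swap_per_edge: int = 10, seed: int = 0) -> ThresholdCurve:
    """Sigma sweep of the time-aggregated backbone network of one group."""
    mat = _backbone_matrix(table, panel, alpha, aggregate, count_mode,
                           count_threshold)
    sigmas = []
    for i, net in enumerate(threshold_sweep(mat, thresholds)):
        try:
            res = small_worldness(net, n_random=n_random,
                                  n_swap_per_edge=n_swap_per_edge,
                                  seed=int_seed(seed, "bbsw", i))
        except (InvalidParameterError, UndefinedRatioError) as exc:
            raise DegenerateMetricError(
                f"backbone sigma undefined at threshold {net.threshold}: {exc}"
            ) from None
        sigmas.append(res.sigma)
    return ThresholdCurve(thresholds=tuple(thresholds), values=tuple(sigmas),
                          metric_name="backbone sigma", provenance=("backbone",))


def backbone_local_eff_curve(table: pd.DataFrame, metabolite: str,
                             panel: MetabolitePanel,
                             thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                             alpha: float = 0.025, aggregate: str = "min",
                             count_mode: str = "raw",
                             count_threshold: float = 0.41) -> ThresholdCurve:
    mat = _backbone_matrix(table, panel, alpha, aggregate, count_mode,
                           count_threshold)
    vals = [local_efficiency(net)[metabolite]
            for net in threshold_sweep(mat, thresholds)]
    return ThresholdCurve(thresholds=tuple(thresholds), values=tuple(vals),
                          metric_name=f"backbone e_local[{metabolite}]",
                          provenance=("backbone",))


# ---------------------------------------------------------------------------
# metric factories: callable(single-group table, seed) -> AUC
#
# Each metric also implements the prepare/evaluate fast path used by
# permutation_test: prepare() reshapes the full table into per-subject
# numpy blocks once, and evaluate() recomputes the AUC for an arbitrary
# subject split without touching pandas — the permutation loop runs a few
# hundred thousand sigma evaluations, so this matters.

MetricFn = Callable[[pd.DataFrame, int], float]


class _ArrayMetric:
    """Base: per-subject concentration blocks -> AUC over the sweep."""

    #: time points needed by prepare(); None = all in the table
    time_points: tuple[int, ...] | None = None

    def __init__(self, panel: MetabolitePanel, thresholds: Sequence[float]):
        self.panel = panel
        self.thresholds = np.asarray(tuple(thresholds), dtype=float)
        if self.thresholds.size < 2:
            raise InvalidParameterError("AUC needs >= 2 thresholds")

    # -- public contract ----------------------------------------------------
    def __call__(self, sub_table: pd.DataFrame, seed: int) -> float:
        state = self.prepare(sub_table)
        return self.evaluate(state, sorted(state), seed)

    def prepare(self, table: pd.DataFrame) -> dict:
        """{subject: (T, M) array} over this metric's time points."""
        tps = self.time_points
        sub = table if tps is None else table[table["time_point"].isin(tps)]
        wide = sub.pivot_table(index=["subject", "time_point"],
                               columns="metabolite", values="concentration",
                               aggfunc="first")
        missing = [m for m in self.panel if m not in wide.columns]
        if missing:
            raise InsufficientDataError(f"metabolites absent: {missing}")
        wide = wide.reindex(columns=list(self.panel.names))
        if wide.isna().any().any():
            raise InsufficientDataError("incomplete records in metric input")
        state: dict = {}
        for subject, block in wide.groupby(level="subject", sort=True):
            block = block.droplevel("subject").sort_index()
            state[subject] = block.to_numpy(dtype=float)
        n_tp = {v.shape[0] for v in state.values()}
        if len(n_tp) != 1:
            raise InsufficientDataError("subjects differ in time points")
        return state

    def _stack(self, state: dict, subjects) -> np.ndarray:
        """(T, n_subjects, M) concentration array for a subject split."""
        if len(subjects) < 3:
            raise DegenerateMetricError("fewer than 3 subjects in split")
        block = np.stack([state[s] for s in subjects])  # (n, T, M)
        return np.swapaxes(block, 0, 1)

    def _auc(self, values: np.ndarray) -> float:
        return float(np.trapezoid(values, self.thresholds))

    def evaluate(self, state: dict, subjects, seed: int) -> float:
        raise NotImplementedError


class _SWAUCMetric(_ArrayMetric):
    """AUC of small-worldness sigma over the sweep at one time point."""

    def __init__(self, time_point: int, panel: MetabolitePanel, thresholds,
                 n_random: int, n_swap_per_edge: int):
        super().__init__(panel, thresholds)
        self.time_points = (int(time_point),)
        self.n_random = int(n_random)
        self.n_swap_per_edge = int(n_swap_per_edge)
        self.__name__ = f"sw_auc_t{time_point}"

    def evaluate(self, state: dict, subjects, seed: int) -> float:
        data = self._stack(state, subjects)[0]
        absrho = abs_spearman_from_array(data)
        sigmas = _engine.sigma_sweep(absrho, self.thresholds, self.n_random,
                                     self.n_swap_per_edge, int(seed))
        if np.isnan(sigmas).any():
            raise DegenerateMetricError(
                "sigma undefined within the threshold sweep")
        return self._auc(sigmas)


class _LocalEffAUCMetric(_ArrayMetric):
    """AUC of one metabolite's local efficiency at one time point."""

    def __init__(self, metabolite: str, time_point: int,
                 panel: MetabolitePanel, thresholds):
        super().__init__(panel, thresholds)
        self.time_points = (int(time_point),)
        self.node = panel.index(metabolite)
        self.__name__ = f"eloc_auc_{metabolite}_t{time_point}"

    def evaluate(self, state: dict, subjects, seed: int) -> float:
        data = self._stack(state, subjects)[0]
        absrho = abs_spearman_from_array(data)
        vals = [
            float(_engine.local_eff((absrho > t).astype(np.uint8))[self.node])
            for t in self.thresholds
        ]
        return self._auc(np.asarray(vals))


class _BackboneMixin:
    def _backbone_absrho(self, state: dict, subjects) -> np.ndarray:
        data = self._stack(state, subjects)  # (T, n, M)
        if data.shape[0] < 2:
            raise DegenerateMetricError("backbone needs >= 2 time points")
        stack = np.stack([abs_spearman_from_array(d) for d in data])
        values, _, _ = _backbone_core(stack, self.alpha, self.aggregate,
                                      self.count_mode, self.count_threshold)
        return values


class _BackboneSWAUCMetric(_BackboneMixin, _ArrayMetric):
    """AUC of the backbone network's sigma over the sweep."""

    def __init__(self, panel: MetabolitePanel, thresholds, alpha: float,
                 aggregate: str, count_mode: str, count_threshold: float,
                 n_random: int, n_swap_per_edge: int):
        super().__init__(panel, thresholds)
        self.alpha = alpha
        self.aggregate = aggregate
        self.count_mode = count_mode
        self.count_threshold = count_threshold
        self.n_random = int(n_random)
        self.n_swap_per_edge = int(n_swap_per_edge)
        self.__name__ = "backbone_sw_auc"

    def evaluate(self, state: dict, subjects, seed: int) -> float:
        absrho = self._backbone_absrho(state, subjects)
        sigmas = _engine.sigma_sweep(absrho, self.thresholds, self.n_random,
                                     self.n_swap_per_edge, int(seed))
        if np.isnan(sigmas).any():
            raise DegenerateMetricError(
                "backbone sigma undefined within the threshold sweep")
        return self._auc(sigmas)


class _BackboneLocalEffAUCMetric(_BackboneMixin, _ArrayMetric):
    """AUC of one metabolite's local efficiency in the backbone network."""

    def __init__(self, metabolite: str, panel: MetabolitePanel, thresholds,
                 alpha: float, aggregate: str, count_mode: str,
                 count_threshold: float):
        super().__init__(panel, thresholds)
        self.alpha = alpha
        self.aggregate = aggregate
        self.count_mode = count_mode
        self.count_threshold = count_threshold
        self.node = panel.index(metabolite)
        self.__name__ = f"backbone_eloc_auc_{metabolite}"

    def evaluate(self, state: dict, subjects, seed: int) -> float:
        absrho = self._backbone_absrho(state, subjects)
        vals = [
            float(_engine.local_eff((absrho > t).astype(np.uint8))[self.node])
            for t in self.thresholds
        ]
        return self._auc(np.asarray(vals))


def make_sw_auc_metric(time_point: int, panel: MetabolitePanel,
                       thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                       n_random: int = DEFAULT_N_RANDOM_PERM,
                       n_swap_per_edge: int = 10) -> MetricFn:
    return _SWAUCMetric(time_point, panel, thresholds, n_random,
                        n_swap_per_edge)


def make_local_eff_auc_metric(metabolite: str, time_point: int,
                              panel: MetabolitePanel,
                              thresholds: Sequence[float] = DEFAULT_THRESHOLDS
                              ) -> MetricFn:
    return _LocalEffAUCMetric(metabolite, time_point, panel, thresholds)


def make_backbone_sw_auc_metric(panel: MetabolitePanel,
                                thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                                alpha: float = 0.025, aggregate: str = "min",
                                count_mode: str = "raw",
                                count_threshold: float = 0.41,
                                n_random: int = DEFAULT_N_RANDOM_PERM,
                                n_swap_per_edge: int = 10) -> MetricFn:
    return _BackboneSWAUCMetric(panel, thresholds, alpha, aggregate,
                                count_mode, count_threshold, n_random,
                                n_swap_per_edge)


def make_backbone_local_eff_auc_metric(metabolite: str, panel: MetabolitePanel,
                                       thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                                       alpha: float = 0.025,
                                       aggregate: str = "min",
                                       count_mode: str = "raw",
                                       count_threshold: float = 0.41) -> MetricFn:
    return _BackboneLocalEffAUCMetric(metabolite, panel, thresholds, alpha,
                                      aggregate, count_mode, count_threshold)


# ---------------------------------------------------------------------------
# permutation test

def permutation_test(table: pd.DataFrame, metric: MetricFn,
                     n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                     scope: tuple = (), max_redraw_frac: float = 0.1
                     ) -> PermutationComparison:
    """Two-group AUC permutation test with whole-subject reallocation.

    Permutations reassign subjects to pseudo-groups of the original sizes;
    the observed difference is metric(first group) - metric(second group)
    with groups ordered alphabetically.  A permutation whose metric
    evaluation is degenerate is redrawn (counted); more than
    ``max_redraw_frac * n_perm`` redraws is an error.
    """
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise InsufficientDataError(f"need exactly 2 groups, got {groups}")
    g1, g2 = groups
    subj1 = sorted(table.loc[table["group"] == g1, "subject"].unique())
    subj2 = sorted(table.loc[table["group"] == g2, "subject"].unique())
    all_subjects = np.array(subj1 + subj2)
    n1 = len(subj1)

    if hasattr(metric, "prepare") and hasattr(metric, "evaluate"):
        state = metric.prepare(table)

        def split_metric(subjects: np.ndarray, eval_seed: int) -> float:
            return metric.evaluate(state, list(subjects), eval_seed)
    else:
        by_subject = dict(tuple(table.groupby("subject", sort=False)))

        def split_metric(subjects: np.ndarray, eval_seed: int) -> float:
            sub = pd.concat([by_subject[s] for s in subjects],
                            ignore_index=True)
            return metric(sub, eval_seed)

    auc1 = split_metric(np.array(subj1), int_seed(seed, "obs", g1))
    auc2 = split_metric(np.array(subj2), int_seed(seed, "obs", g2))
    observed = auc1 - auc2

    rng = rng_for(seed, "perm")
    null = np.empty(n_perm)
    n_redraws = 0
    b = 0
    while b < n_perm:
        perm = rng.permutation(all_subjects)
        s1 = int(rng.integers(2 ** 31))
        s2 = int(rng.integers(2 ** 31))
        try:
            d = (split_metric(perm[:n1], s1) - split_metric(perm[n1:], s2))
        except DegenerateMetricError:
            n_redraws += 1
            if n_redraws > max_redraw_frac * n_perm:
                raise DegenerateMetricError(
                    f"more than {max_redraw_frac:.0%} of permutations degenerate"
                ) from None
            continue
        null[b] = d
        b += 1

    critical = float(np.percentile(null, 95))
    p_value = float((1 + np.sum(np.abs(null) >= abs(observed))) / (n_perm + 1))
    return PermutationComparison(
        metric_name=getattr(metric, "__name__", "metric"),
        scope=tuple(scope),
        groups=(g1, g2),
        observed_diff=float(observed),
        group_aucs=(float(auc1), float(auc2)),
        null_diffs=tuple(float(x) for x in null),
        critical_value=critical,
        rejects_critical=bool(observed > critical),
        p_value=p_value,
        p_fdr=p_value,
        n_perm=int(n_perm),
        seed=int(seed),
        n_redraws=n_redraws,
    )


def apply_fdr(comparisons: Sequence[PermutationComparison]
              ) -> list[PermutationComparison]:
    """Adjust a family of comparisons' p-values jointly (BH)."""
    if not comparisons:
        return []
    adj = fdr_correct([c.p_value for c in comparisons])
    return [replace(c, p_fdr=a) for c, a in zip(comparisons, adj)]
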