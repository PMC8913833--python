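"""Synthetic longitudinal two-group metabolite cohorts.

The generator emulates the shape of an LCModel quantification table from a
longitudinal 1H-MRS experiment: two groups x 11 subjects x 8 time points x
11 metabolites, each record carrying a concentration and a CRLB percentage.

Concentrations are drawn from a Gaussian copula with per-(group, time point)
target Spearman correlation structure, pushed through log-normal marginals
(mean = concentration_scale, coefficient of variation = noise_cv).  Rank
correlations are invariant to the monotone marginal transform, so the
downstream Spearman analysis sees exactly the designed dependence while all
concentrations stay strictly positive.

Designed correlation structure
------------------------------
* control: three disjoint equicorrelated triangles — a Cr-PCr-Gln cluster,
  Glu-NAA-GSH, and Ins-Tau-GABA — at the template strength; Ala and PCh kept
  free of designed associations.  Disjoint blocks are exactly positive
  semidefinite; a node with two strong neighbours would otherwise force
  their mutual correlation up to ~strength**2, which is why the clustered
  background is built from cliques rather than a lattice.
* stress: the control structure with every Cr association removed at all
  time points, and at designated "disrupted" time points all clustered
  structure removed, leaving only the Glu-NAA pair: the Glu-related
  association persists throughout (and survives into the backbone) while
  the network loses its designed clustering entirely.  An empty background
  is the lowest-triangle design achievable: because sample correlation
  matrices are positive semidefinite, any additional strong pair acts as a
  triangle nucleus (a metabolite spuriously correlated with one member is
  correlated with the other too) and pushes small-worldness back up.

CRLB values follow a constant per-metabolite baseline plus explicitly
injected failures; they do not feed back into the concentration noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidParameterError, TemplateError
from .panel import DEFAULT_PANEL, MetabolitePanel
from .seeding import rng_for

# typical mouse-hippocampus concentrations, institutional units (~mM)
DEFAULT_SCALES: dict[str, float] = {
    "Ala": 0.8, "Cr": 4.5, "PCr": 4.0, "GABA": 1.8, "Glu": 8.5, "Gln": 3.5,
    "PCh": 0.6, "GSH": 1.3, "Ins": 5.5, "NAA": 8.0, "Tau": 6.0,
}
DEFAULT_NOISE_CV = 0.15
DEFAULT_CRLB_BASELINE = 5.0
# 0.90 keeps designed edges above the top analysis threshold (0.49) with
# probability ~0.99 per time point at n = 11 subjects
DEFAULT_STRENGTH = 0.90
DEFAULT_N_SUBJECTS = 11
DEFAULT_N_TIME_POINTS = 8
DEFAULT_DISRUPTED = (2, 3, 5)

CONTROL_TRIANGLES = (
    ("Cr", "PCr", "Gln"),
    ("Glu", "NAA", "GSH"),
    ("Ins", "Tau", "GABA"),
)
STRESS_DISRUPTED_PAIRS = (
    ("Glu", "NAA"),
)

TABLE_COLUMNS = ("group", "subject", "time_point", "metabolite",
                 "concentration", "crlb")


@dataclass(frozen=True)
class CorrelationTemplate:
    """Target Spearman correlation matrix for one (group, time point)."""

    target: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.target, dtype=float)
        object.__setattr__(self, "target", t)
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise TemplateError("template must be a square matrix")
        if not np.allclose(t, t.T):
            raise TemplateError("template must be symmetric")
        if not np.all(np.diag(t) == 1.0):
            raise TemplateError("template diagonal must be exactly 1")
        off = t[~np.eye(t.shape[0], dtype=bool)]
        if np.any(np.abs(off) >= 1.0):
            raise TemplateError("off-diagonal template magnitudes must be < 1")


def spearman_to_pearson(rho_s):
    """Pearson correlation of a bivariate Gaussian with Spearman rho_s.

    Closed form 2*sin(pi*rho_s/6); elementwise on arrays.
    """
    rho_s = np.asarray(rho_s, dtype=float)
    if np.any(np.abs(rho_s) > 1.0):
        raise InvalidParameterError("|rho_s| must be <= 1")
    out = 2.0 * np.sin(np.pi * rho_s / 6.0)
    return float(out) if out.ndim == 0 else out


def repair_psd(corr: np.ndarray, eig_floor: float = 1e-8,
               max_shift: float = 0.05) -> np.ndarray:
    """Clip eigenvalues at eig_floor and renormalize to unit diagonal.

    Raises :class:`TemplateError` if the repair moves any entry by more than
    ``max_shift`` — such a template is asking for an infeasible correlation
    structure rather than suffering numerical jitter.
    """
    corr = np.asarray(corr, dtype=float)
    w, v = np.linalg.eigh(corr)
    if w.min() >= eig_floor:
        return corr
    w = np.clip(w, eig_floor, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    shift = np.max(np.abs(fixed - corr))
    if shift > max_shift:
        raise TemplateError(
            f"template not positive semidefinite: repair shifted an entry by "
            f"{shift:.3f} (> {max_shift})"
        )
    return fixed


def _identity_target(m: int) -> np.ndarray:
    return np.eye(m)


def _set(target: np.ndarray, panel: MetabolitePanel, a: str, b: str, value: float):
    i, j = panel.index(a), panel.index(b)
    target[i, j] = target[j, i] = value


def _require(panel: MetabolitePanel, names: Iterable[str]):
    missing = [n for n in names if n not in panel]
    if missing:
        raise InvalidParameterError(f"panel lacks required metabolites: {missing}")


def _control_target(panel: MetabolitePanel, strength: float) -> np.ndarray:
    target = _identity_target(len(panel))
    for tri in CONTROL_TRIANGLES:
        for a, b in ((tri[0], tri[1]), (tri[0], tri[2]), (tri[1], tri[2])):
            _set(target, panel, a, b, strength)
    return target


def control_template(panel: MetabolitePanel = DEFAULT_PANEL,
                     strength: float = DEFAULT_STRENGTH,
                     n_time_points: int = DEFAULT_N_TIME_POINTS
                     ) -> dict[int, CorrelationTemplate]:
    """Per-time-point control-group templates.

    Every time point carries the Cr-PCr-Gln cluster at the given strength
    plus the clustered triangle background; Ala and PCh have no designed
    associations.
    """
    if not 0.0 < strength < 1.0:
        raise InvalidParameterError(f"strength must be in (0, 1), got {strength}")
    if n_time_points < 1:
        raise InvalidParameterError("n_time_points must be >= 1")
    _require(panel, [n for tri in CONTROL_TRIANGLES for n in tri])
    tmpl = CorrelationTemplate(_control_target(panel, strength))
    return {tp: tmpl for tp in range(1, n_time_points + 1)}


def stress_template(panel: MetabolitePanel = DEFAULT_PANEL,
                    strength: float = DEFAULT_STRENGTH,
                    disrupted_time_points: Iterable[int] = DEFAULT_DISRUPTED,
                    n_time_points: int = DEFAULT_N_TIME_POINTS
                    ) -> dict[int, CorrelationTemplate]:
    """Per-time-point stress-group templates.

    Cr-PCr and Cr-Gln (all of Cr's designed associations) are removed at
    every time point, so the backbone Cr cluster can never form; at
    disrupted time points all remaining clustered structure is dropped as
    well, leaving only the Glu-NAA pair at the template strength.
    """
    if len(panel) == 0:
        raise InvalidParameterError("panel must be non-empty")
    if not 0.0 < strength < 1.0:
        raise InvalidParameterError(f"strength must be in (0, 1), got {strength}")
    disrupted = frozenset(int(t) for t in disrupted_time_points)
    if not disrupted <= set(range(1, n_time_points + 1)):
        raise InvalidParameterError(
            f"disrupted time points {sorted(disrupted)} outside 1..{n_time_points}"
        )
    _require(panel, [n for pair in STRESS_DISRUPTED_PAIRS for n in pair])

    base = _control_target(panel, strength)
    _set(base, panel, "Cr", "PCr", 0.0)
    _set(base, panel, "Cr", "Gln", 0.0)
    calm = CorrelationTemplate(base)

    broken = _identity_target(len(panel))
    for a, b in STRESS_DISRUPTED_PAIRS:
        _set(broken, panel, a, b, strength)
    disruptedt = CorrelationTemplate(broken)

    return {tp: (disruptedt if tp in disrupted else calm)
            for tp in range(1, n_time_points + 1)}


def identity_templates(panel: MetabolitePanel,
                       n_time_points: int = DEFAULT_N_TIME_POINTS
                       ) -> dict[int, CorrelationTemplate]:
    """All-independent templates (every off-diagonal target 0)."""
    tmpl = CorrelationTemplate(_identity_target(len(panel)))
    return {tp: tmpl for tp in range(1, n_time_points + 1)}


@dataclass(frozen=True)
class CrlbFailure:
    """One injected quantification failure.

    ``None`` fields are wildcards: e.g. subject=None applies the failure to
    every subject (a metabolite-level failure), time_point=None to every
    time point.
    """

    metabolite: str
    group: str | None = None
    subject: str | None = None
    time_point: int | None = None
    crlb: float = 50.0


@dataclass(frozen=True)
class CrlbModel:
    """Constant per-metabolite CRLB baseline plus injected failures."""

    baseline: float | Mapping[str, float] = DEFAULT_CRLB_BASELINE
    failures: tuple[CrlbFailure, ...] = ()

    def baseline_for(self, metabolite: str) -> float:
        if isinstance(self.baseline, Mapping):
            return float(self.baseline.get(metabolite, DEFAULT_CRLB_BASELINE))
        return float(self.baseline)


@dataclass
class CohortConfig:
    """Everything needed to generate one synthetic cohort deterministically."""

    panel: MetabolitePanel = field(default_factory=lambda: DEFAULT_PANEL)
    groups: tuple[str, ...] = ("control", "stress")
    n_subjects_per_group: int = DEFAULT_N_SUBJECTS
    n_time_points: int = DEFAULT_N_TIME_POINTS
    templates: dict[tuple[str, int], CorrelationTemplate] = field(default_factory=dict)
    concentration_scale: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SCALES))
    noise_cv: float = DEFAULT_NOISE_CV
    crlb_model: CrlbModel = field(default_factory=CrlbModel)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects_per_group < 3:
            raise InvalidParameterError("n_subjects_per_group must be >= 3")
        if self.n_time_points < 1:
            raise InvalidParameterError("n_time_points must be >= 1")
        if not self.noise_cv > 0:
            raise InvalidParameterError("noise_cv must be > 0")
        if not self.groups:
            raise InvalidParameterError("at least one group required")
        for name in self.panel:
            if self.scale_for(name) <= 0:
                raise InvalidParameterError(f"concentration scale for {name} must be > 0")

    def scale_for(self, metabolite: str) -> float:
        return float(self.concentration_scale.get(metabolite, 1.0))

    def subjects(self, group: str) -> list[str]:
        return [f"{group}-{i:02d}" for i in range(1, self.n_subjects_per_group + 1)]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        tmpl: dict[str, dict[str, list]] = {}
        for (group, tp), t in self.templates.items():
            tmpl.setdefault(group, {})[str(tp)] = np.round(t.target, 10).tolist()
        return {
            "panel": list(self.panel.names),
            "groups": list(self.groups),
            "n_subjects_per_group": self.n_subjects_per_group,
            "n_time_points": self.n_time_points,
            "templates": tmpl,
            "concentration_scale": {k: float(v) for k, v in
                                    self.concentration_scale.items()},
            "noise_cv": self.noise_cv,
            "crlb_baseline": (dict(self.crlb_model.baseline)
                              if isinstance(self.crlb_model.baseline, Mapping)
                              else self.crlb_model.baseline),
            "crlb_failures": [
                {"metabolite": f.metabolite, "group": f.group,
                 "subject": f.subject, "time_point": f.time_point,
                 "crlb": f.crlb}
                for f in self.crlb_model.failures
            ],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        panel = MetabolitePanel(tuple(d.get("panel", DEFAULT_PANEL.names)))
        templates: dict[tuple[str, int], CorrelationTemplate] = {}
        for group, per_tp in d.get("templates", {}).items():
            for tp, mat in per_tp.items():
                templates[(group, int(tp))] = CorrelationTemplate(np.asarray(mat))
        failures = tuple(
            CrlbFailure(metabolite=f["metabolite"], group=f.get("group"),
                        subject=f.get("subject"), time_point=f.get("time_point"),
                        crlb=float(f.get("crlb", 50.0)))
            for f in d.get("crlb_failures", [])
        )
        return cls(
            panel=panel,
            groups=tuple(d.get("groups", ("control", "stress"))),
            n_subjects_per_group=int(d.get("n_subjects_per_group", DEFAULT_N_SUBJECTS)),
            n_time_points=int(d.get("n_time_points", DEFAULT_N_TIME_POINTS)),
            templates=templates,
            concentration_scale=dict(d.get("concentration_scale", DEFAULT_SCALES)),
            noise_cv=float(d.get("noise_cv", DEFAULT_NOISE_CV)),
            crlb_model=CrlbModel(baseline=d.get("crlb_baseline", DEFAULT_CRLB_BASELINE),
                                 failures=failures),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_cohort_config(seed: int = 0,
                          strength: float = DEFAULT_STRENGTH,
                          disrupted_time_points: Iterable[int] = DEFAULT_DISRUPTED,
                          **kwargs) -> CohortConfig:
    """The default two-group design: clustered control vs Cr-broken stress."""
    panel = kwargs.pop("panel", DEFAULT_PANEL)
    n_tp = kwargs.pop("n_time_points", DEFAULT_N_TIME_POINTS)
    templates: dict[tuple[str, int], CorrelationTemplate] = {}
    for tp, t in control_template(panel, strength, n_tp).items():
        templates[("control", tp)] = t
    for tp, t in stress_template(panel, strength, disrupted_time_points, n_tp).items():
        templates[("stress", tp)] = t
    return CohortConfig(panel=panel, n_time_points=n_tp, templates=templates,
                        seed=seed, **kwargs)


def null_cohort_config(seed: int = 0, strength: float = DEFAULT_STRENGTH,
                       **kwargs) -> CohortConfig:
    """Both groups drawn from the SAME (control) template: a true null for
    group-comparison calibration."""
    panel = kwargs.pop("panel", DEFAULT_PANEL)
    n_tp = kwargs.pop("n_time_points", DEFAULT_N_TIME_POINTS)
    templates: dict[tuple[str, int], CorrelationTemplate] = {}
    for tp, t in control_template(panel, strength, n_tp).items():
        templates[("control", tp)] = t
        templates[("stress", tp)] = t
    return CohortConfig(panel=panel, n_time_points=n_tp, templates=templates,
                        seed=seed, **kwargs)


def _crlb_values(config: CohortConfig, group: str, subjects: list[str],
                 tp: int) -> np.ndarray:
    m = len(config.panel)
    vals = np.empty((len(subjects), m))
    for j, name in enumerate(config.panel):
        vals[:, j] = config.crlb_model.baseline_for(name)
    for f in config.crlb_model.failures:
        if f.group is not None and f.group != group:
            continue
        if f.time_point is not None and f.time_point != tp:
            continue
        if f.metabolite not in config.panel:
            continue
        j = config.panel.index(f.metabolite)
        if f.subject is None:
            vals[:, j] = f.crlb
        elif f.subject in subjects:
            vals[subjects.index(f.subject), j] = f.crlb
    return vals


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a tidy concentration table from the configured cohort design.

    Deterministic given ``config.seed``: each (group, time point) block uses
    its own named random stream.
    """
    m = len(config.panel)
    sigma_log = np.sqrt(np.log1p(config.noise_cv ** 2))
    mu_log = {name: np.log(config.scale_for(name)) - 0.5 * sigma_log ** 2
              for name in config.panel}

    records = []
    for group in config.groups:
        subjects = config.subjects(group)
        for tp in range(1, config.n_time_points + 1):
            tmpl = config.templates.get((group, tp))
            if tmpl is None:
                raise TemplateError(f"no template for (group={group!r}, time_point={tp})")
            if tmpl.target.shape[0] != m:
                raise TemplateError(
                    f"template for (group={group!r}, time_point={tp}) has size "
                    f"{tmpl.target.shape[0]}, panel has {m}"
                )
            pearson = spearman_to_pearson(tmpl.target)
            np.fill_diagonal(pearson, 1.0)
            try:
                pearson = repair_psd(pearson)
            except TemplateError as exc:
                raise TemplateError(
                    f"(group={group!r}, time_point={tp}): {exc}"
                ) from None
            chol = np.linalg.cholesky(pearson + 1e-12 * np.eye(m))
            rng = rng_for(config.seed, "cohort", group, tp)
            z = rng.standard_normal((len(subjects), m)) @ chol.T
            crlb = _crlb_values(config, group, subjects, tp)
            for si, subject in enumerate(subjects):
                for mi, name in enumerate(config.panel):
                    conc = float(np.exp(mu_log[name] + sigma_log * z[si, mi]))
                    records.append((group, subject, tp, name, conc,
                                    float(crlb[si, mi])))
    df = pd.DataFrame.from_records(records, columns=TABLE_COLUMNS)
    return df


def validate_table(table: pd.DataFrame) -> None:
    """Check the tidy-table contract: columns, positivity, key uniqueness."""
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidParameterError(f"table lacks columns: {missing}")
    if len(table) == 0:
        raise InvalidParameterError("table is empty")
    if (table["concentration"] <= 0).any():
        raise InvalidParameterError("concentrations must be strictly positive")
    if (table["crlb"] < 0).any():
        raise InvalidParameterError("CRLB percentages must be >= 0")
    keys = table[["group", "subject", "time_point", "metabolite"]]
    if keys.duplicated().any():
        raise InvalidParameterError("duplicate (group, subject, time_point, metabolite) keys")


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_table(df)
    return df
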