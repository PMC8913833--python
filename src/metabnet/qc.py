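"""Quantification quality control.

A metabolite enters the analysis only if its concentration estimate is
reliable — CRLB strictly below the threshold (default 35%) — for every
subject at every time point.  Subjects whose spectra fail on otherwise
reliable metabolites are excluded first, mirroring the usual order in MRS
studies (bad animals removed, then the metabolite panel trimmed).

Because "a subject failed" and "a metabolite failed" are confounded in a
single CRLB table, metabolite-level failures are identified by a majority
rule: a metabolite with CRLB >= threshold for more than half the subjects
is treated as unquantifiable per se and is not held against individual
subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .errors import InsufficientDataError, InvalidParameterError, QCError
from .synthetic import validate_table


@dataclass(frozen=True)
class QCReport:
    retained_metabolites: tuple[str, ...]
    excluded_metabolites: tuple[dict, ...]   # name, worst time_point, max crlb
    excluded_subjects: tuple[dict, ...]      # group, subject, reason
    crlb_threshold: float
    n_subjects_before: int = 0
    n_subjects_after: int = 0

    def to_dict(self) -> dict:
        return {
            "crlb_threshold": self.crlb_threshold,
            "retained_metabolites": list(self.retained_metabolites),
            "excluded_metabolites": [dict(d) for d in self.excluded_metabolites],
            "excluded_subjects": [dict(d) for d in self.excluded_subjects],
            "n_subjects_before": self.n_subjects_before,
            "n_subjects_after": self.n_subjects_after,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def filter_by_crlb(table: pd.DataFrame, crlb_threshold: float = 35.0
                   ) -> tuple[pd.DataFrame, QCReport]:
    """Apply the CRLB < threshold inclusion rule (strict inequality).

    Order of operations:

    1. metabolites failing for more than half of all subjects are flagged as
       panel-level failures;
    2. a subject is excluded if any remaining metabolite has CRLB >=
       threshold at any time point for that subject;
    3. on the surviving subjects, a metabolite is retained only if CRLB <
       threshold for every (subject, time point) record.

    Returns the filtered table and a report of all removals.
    """
    if table is None or len(table) == 0:
        raise InsufficientDataError("empty concentration table")
    if not crlb_threshold > 0:
        raise InvalidParameterError("crlb_threshold must be > 0")
    validate_table(table)

    df = table.copy()
    df["_subj"] = list(zip(df["group"], df["subject"]))
    n_subjects = df["_subj"].nunique()

    fails = df[df["crlb"] >= crlb_threshold]

    # 1. panel-level metabolite failures (majority rule)
    failing_subj_counts = fails.groupby("metabolite")["_subj"].nunique()
    panel_failures = set(
        failing_subj_counts[failing_subj_counts > n_subjects / 2].index
    )

    # 2. subject exclusion on the remaining (core) metabolites
    subj_fails = fails[~fails["metabolite"].isin(panel_failures)]
    excluded_subjects = []
    for (group, subject), grp in sorted(subj_fails.groupby("_subj"),
                                        key=lambda kv: kv[0]):
        worst = grp.loc[grp["crlb"].idxmax()]
        excluded_subjects.append({
            "group": group,
            "subject": subject,
            "reason": (f"CRLB {worst['crlb']:g}% >= {crlb_threshold:g}% for "
                       f"{worst['metabolite']} at time point {int(worst['time_point'])}"),
        })
    excluded_keys = {(d["group"], d["subject"]) for d in excluded_subjects}
    kept = df[~df["_subj"].isin(excluded_keys)]
    if kept.empty:
        raise QCError("all subjects excluded by CRLB criterion")

    # 3. metabolite retention on the surviving subjects
    excluded_metabolites = []
    retained = []
    for metab, grp in kept.groupby("metabolite", sort=False):
        bad = grp[grp["crlb"] >= crlb_threshold]
        if bad.empty:
            retained.append(metab)
        else:
            worst = bad.loc[bad["crlb"].idxmax()]
            excluded_metabolites.append({
                "metabolite": metab,
                "time_point": int(worst["time_point"]),
                "max_crlb": float(grp["crlb"].max()),
            })
    if not retained:
        raise QCError("all metabolites excluded by CRLB criterion")

    out = kept[kept["metabolite"].isin(retained)].drop(columns="_subj")
    out = out.reset_index(drop=True)
    report = QCReport(
        retained_metabolites=tuple(retained),
        excluded_metabolites=tuple(excluded_metabolites),
        excluded_subjects=tuple(excluded_subjects),
        crlb_threshold=float(crlb_threshold),
        n_subjects_before=n_subjects,
        n_subjects_after=n_subjects - len(excluded_keys),
    )
    return out, report
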