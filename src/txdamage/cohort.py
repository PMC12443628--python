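"""Longitudinal cohort bookkeeping: progression strata, contrasts, power gate.

Disease progression is measured on the UPDRS III motor scale:
ΔUPDRS = score at the last visit (visit 8, 36 months) − score at the
first visit.  Patients with ΔUPDRS > 1 are *severe* progressors, the
rest (including improvers) *mild*.  Group comparisons are screened with
a retrospective two-sample t power computation; groups with Cohen's
d < 0.6 fail the gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: ΔUPDRS III cut separating mild (<= 1) from severe (> 1) progression.
DELTA_UPDRS_CUT = 1

#: Effect sizes below this are excluded as underpowered.
MIN_EFFECT_SIZE = 0.6

HC_GROUPS = ("HC",)
NON_PATIENT_GROUPS = ("HC", "prodromal")


@dataclass
class PowerCheck:
    """Retrospective power of a two-sample t comparison."""

    n1: int
    n2: int
    effect_size: float
    alpha: float
    power: float
    pass_: bool
    rule: str = f"pass iff effect_size >= {MIN_EFFECT_SIZE}"

    def to_dict(self) -> dict:
        return {"n1": self.n1, "n2": self.n2, "effect_size": self.effect_size,
                "alpha": self.alpha, "power": self.power, "pass": self.pass_,
                "rule": self.rule}


@dataclass
class Contrast:
    """One case-vs-HC comparison at a visit, with its sample subset."""

    label: str
    case_group: str
    visit: int
    sample_ids: list[str]


def stratify_progression(samples: pd.DataFrame) -> pd.DataFrame:
    """Label each patient mild or severe from the ΔUPDRS III rule.

    ΔUPDRS = UPDRS III at visit 8 − UPDRS III at visit 1; severe iff
    ΔUPDRS > 1, mild otherwise (boundary Δ = 1 is mild).  Only patient
    groups are labelled (HC and prodromal records are ignored);
    subjects missing either visit are excluded with a logged count.
    """
    pd_samples = samples[~samples["group"].isin(NON_PATIENT_GROUPS)]
    rows = []
    n_incomplete = 0
    for subject_id, grp in pd_samples.groupby("subject_id", sort=True):
        by_visit = grp.set_index("visit")["updrs_iii"]
        if 1 not in by_visit.index or 8 not in by_visit.index:
            n_incomplete += 1
            continue
        v1 = int(by_visit.loc[1]) if np.ndim(by_visit.loc[1]) == 0 else int(by_visit.loc[1].iloc[0])
        v8 = int(by_visit.loc[8]) if np.ndim(by_visit.loc[8]) == 0 else int(by_visit.loc[8].iloc[0])
        delta = v8 - v1
        rows.append(
            {"subject_id": subject_id, "updrs_v1": v1, "updrs_v8": v8,
             "delta_updrs": delta,
             "label": "severe" if delta > DELTA_UPDRS_CUT else "mild"}
        )
    if n_incomplete:
        logger.info("stratify_progression: excluded %d subject(s) missing a visit",
                    n_incomplete)
    return pd.DataFrame(rows, columns=["subject_id", "updrs_v1", "updrs_v8",
                                       "delta_updrs", "label"])


def power_check(
    n1: int, n2: int, effect_size: float, alpha: float = 0.05
) -> PowerCheck:
    """Power of a two-sided two-sample t test at Cohen's d = *effect_size*.

    Uses the noncentral t distribution with
    ncp = d * sqrt(n1 n2 / (n1 + n2)) and df = n1 + n2 − 2.  The pass
    flag applies the exclusion rule d >= 0.6; the computed power is
    reported alongside for transparency.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    df = n1 + n2 - 2
    ncp = effect_size * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    power = float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
    return PowerCheck(n1=n1, n2=n2, effect_size=effect_size, alpha=alpha,
                      power=power, pass_=effect_size >= MIN_EFFECT_SIZE)


def assemble_contrasts(
    samples: pd.DataFrame,
    scheme: str = "subgroups",
    *,
    min_n: int = 3,
    visits: tuple[int, ...] = (1, 8),
) -> tuple[list[Contrast], dict]:
    """Build the case-vs-HC sample subsets for a comparison scheme.

    ``scheme="subgroups"`` compares every patient group against HC at
    each visit; ``scheme="progression"`` compares mild and severe
    progressors (from :func:`stratify_progression`) against HC at each
    visit.  The HC arm at a visit is shared across its case contrasts.
    Contrasts whose case arm falls below *min_n* subjects are skipped
    and recorded in the manifest (mirroring subgroup exclusions at
    follow-up).  Returns ``(contrasts, manifest)``.
    """
    if scheme not in ("subgroups", "progression"):
        raise ValueError(f"unknown scheme {scheme!r}")
    manifest: dict = {"scheme": scheme, "contrasts": [], "skipped": []}
    contrasts: list[Contrast] = []

    if scheme == "progression":
        labels = stratify_progression(samples)
        label_map = dict(zip(labels["subject_id"], labels["label"]))

    for visit in visits:
        at_visit = samples[samples["visit"] == visit]
        hc_ids = at_visit.loc[at_visit["group"].isin(HC_GROUPS), "sample_id"].tolist()
        if scheme == "subgroups":
            case_groups = [g for g in at_visit["group"].unique() if g not in HC_GROUPS]
            case_subsets = {
                g: at_visit.loc[at_visit["group"] == g, "sample_id"].tolist()
                for g in sorted(case_groups)
            }
        else:
            patients = at_visit[~at_visit["group"].isin(NON_PATIENT_GROUPS)]
            case_subsets = {
                lab: patients.loc[
                    patients["subject_id"].map(label_map.get) == lab, "sample_id"
                ].tolist()
                for lab in ("mild", "severe")
            }
        for case, ids in case_subsets.items():
            label = f"{case}_vs_HC_V{visit}"
            if len(ids) < min_n or len(hc_ids) < min_n:
                manifest["skipped"].append(
                    {"contrast": label, "n_case": len(ids), "n_hc": len(hc_ids),
                     "reason": f"fewer than {min_n} samples in an arm"}
                )
                continue
            contrasts.append(
                Contrast(label=label, case_group=case, visit=visit,
                         sample_ids=sorted(ids) + sorted(hc_ids))
            )
            manifest["contrasts"].append(
                {"contrast": label, "n_case": len(ids), "n_hc": len(hc_ids)}
            )
    return contrasts, manifest
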