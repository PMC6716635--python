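"""Reverse-remodeling phenotyping from serial LVEF measurements.

Patients are classified from their change in left-ventricular ejection
fraction (absolute %, LOCF − baseline):

* **Responder (R)** — LVEF increase ≥ 5 absolute % at 3 months *or* ≥ 8 % at
  12 months (each observed timepoint judged against its own threshold,
  disjunctively).
* **Nonresponder (NR)** — everyone else with an analyzable LOCF value.
* **Super-Responder (SR)** — responders whose LOCF increase is ≥ 10 %.
* **Strict NR (SR_NR)** — nonresponders with an increase < 5 % at *every*
  observed timepoint (the control group paired with super-responders).

LOCF (last observation carried forward) uses the 12-month value when present,
otherwise the 3-month value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import ClinicalTable

GROUPS = ("R", "NR", "excluded")


@dataclass(frozen=True)
class ResponseRules:
    """LVEF-change thresholds (absolute %) defining the response groups."""

    r_threshold_m3: float = 5.0
    r_threshold_m12: float = 8.0
    sr_threshold: float = 10.0
    srnr_max: float = 5.0  # strict: every observed change must be < this

    def __post_init__(self) -> None:
        thresholds = (
            self.r_threshold_m3,
            self.r_threshold_m12,
            self.sr_threshold,
            self.srnr_max,
        )
        if any(t < 0 for t in thresholds):
            raise ValueError("response thresholds must be >= 0")
        if self.sr_threshold < self.r_threshold_m3:
            raise ValueError("sr_threshold must be >= r_threshold_m3")


def select_locf(clinical: ClinicalTable) -> dict[str, str | None]:
    """Per-patient LOCF timepoint: m12 if present, else m3, else None."""
    out: dict[str, str | None] = {}
    for patient, row in clinical.data.iterrows():
        if pd.notna(row["lvef_m12"]):
            out[patient] = "m12"
        elif pd.notna(row["lvef_m3"]):
            out[patient] = "m3"
        else:
            out[patient] = None
    return out


def classify_response(
    clinical: ClinicalTable,
    locf_map: dict[str, str | None] | None = None,
    rules: ResponseRules = ResponseRules(),
) -> pd.DataFrame:
    """Classify every patient into R/NR (or excluded).

    Returns a DataFrame indexed by patient_id with columns ``locf_timepoint``,
    ``lvef_change`` (absolute %, LOCF − baseline), ``group``,
    ``super_responder`` (SR ⊆ R) and ``strict_nonresponder``; a ``tertile``
    column is added by :func:`assign_tertiles`.
    """
    if locf_map is None:
        locf_map = select_locf(clinical)
    rows = []
    for patient, row in clinical.data.iterrows():
        tp = locf_map.get(patient)
        if tp is None or pd.isna(row["lvef_baseline"]):
            rows.append((patient, None, np.nan, "excluded", False, False))
            continue
        base = row["lvef_baseline"]
        d3 = row["lvef_m3"] - base if pd.notna(row["lvef_m3"]) else np.nan
        d12 = row["lvef_m12"] - base if pd.notna(row["lvef_m12"]) else np.nan
        d_locf = row[f"lvef_{tp}"] - base
        is_r = bool(
            (np.isfinite(d3) and d3 >= rules.r_threshold_m3)
            or (np.isfinite(d12) and d12 >= rules.r_threshold_m12)
        )
        group = "R" if is_r else "NR"
        is_sr = is_r and d_locf >= rules.sr_threshold
        observed = [d for d in (d3, d12) if np.isfinite(d)]
        is_srnr = (not is_r) and all(d < rules.srnr_max for d in observed)
        rows.append((patient, tp, float(d_locf), group, is_sr, is_srnr))
    df = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "locf_timepoint",
            "lvef_change",
            "group",
            "super_responder",
            "strict_nonresponder",
        ],
    ).set_index("patient_id")
    df["tertile"] = pd.array([pd.NA] * len(df), dtype="Int64")
    return df


def assign_tertiles(assignments: pd.DataFrame) -> pd.DataFrame:
    """Split classified patients into three near-equal LVEF-change tertiles.

    Patients are ranked by ``lvef_change`` ascending (patient_id breaks ties);
    bin sizes are ``ceil``-balanced with the larger bins at the low end, so
    n=47 gives sizes 16/16/15.  Tertile 1 is the smallest change.
    """
    out = assignments.copy()
    classified = out[out["group"].isin(["R", "NR"])]
    n = len(classified)
    if n < 3:
        raise ValueError(f"need >= 3 classified patients for tertiles, got {n}")
    order = (
        classified.reset_index()
        .sort_values(["lvef_change", "patient_id"], kind="mergesort")["patient_id"]
        .tolist()
    )
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    labels = np.repeat([1, 2, 3], sizes)
    out["tertile"] = pd.array([pd.NA] * len(out), dtype="Int64")
    out.loc[order, "tertile"] = labels
    return out


def _anderson_darling_rejects(x: np.ndarray, alpha: float = 0.05) -> bool:
    """True when the Anderson–Darling normality test rejects at `alpha`.

    Applied only when n >= 8; smaller samples are treated as not rejecting
    (the test has essentially no power there).
    """
    if len(x) < 8 or np.ptp(x) == 0:
        return False
    res = stats.anderson(np.asarray(x, dtype=float), dist="norm", method="interpolate")
    return bool(res.pvalue < alpha)


def group_lvef_summary(
    assignments: pd.DataFrame,
    clinical: ClinicalTable,
    groups: tuple[str, str] = ("R", "NR"),
) -> dict:
    """Mean/SD/SEM of baseline, LOCF and change LVEF per group, plus the
    two-group comparison p-value.

    The comparison uses a two-sample t-test when neither group's changes are
    significantly non-normal by the Anderson–Darling test at 0.05; otherwise
    it falls back to the Wilcoxon rank-sum test.
    """
    summaries: dict[str, dict] = {}
    changes: dict[str, np.ndarray] = {}
    for g in groups:
        members = assignments.index[assignments["group"] == g]
        delta = assignments.loc[members, "lvef_change"].dropna().to_numpy(float)
        base = clinical.data.loc[members, "lvef_baseline"].dropna().to_numpy(float)
        locf = base + assignments.loc[members, "lvef_change"].dropna().to_numpy(float)
        s: dict = {"n": len(delta)}
        for name, arr in (("baseline", base), ("locf", locf), ("change", delta)):
            s[f"{name}_mean"] = float(np.mean(arr)) if len(arr) else np.nan
            if len(arr) >= 2:
                s[f"{name}_sd"] = float(np.std(arr, ddof=1))
                s[f"{name}_sem"] = s[f"{name}_sd"] / np.sqrt(len(arr))
        summaries[g] = s
        changes[g] = delta
    a, b = (changes[g] for g in groups)
    if len(a) >= 2 and len(b) >= 2:
        if _anderson_darling_rejects(a) or _anderson_darling_rejects(b):
            p = float(stats.ranksums(a, b).pvalue)
            test = "rank-sum (Anderson-Darling rejected normality)"
        else:
            p = float(stats.ttest_ind(a, b).pvalue)
            test = "t-test"
            if not np.isfinite(p):  # both groups constant and equal
                p = 1.0
        summaries["comparison"] = {"groups": groups, "p_value": p, "test": test}
    return summaries
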