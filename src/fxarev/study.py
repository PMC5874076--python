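"""In vivo study analysis: group summaries, derived effects, tests, correlations.

The preclinical design this analyzes is a four-arm prophylactic bleeding
study: anticoagulant (or vehicle) at time 0, reversal agent (or vehicle)
infused from 20 to 25 min, standardized injury bleeding from 25 to 40
min. Endpoints per animal: anti-FXa activity, PT, aPTT, total/unbound
inhibitor and decoy plasma levels at the four sampling times, plus
terminal blood loss in grams.

Reported derived numbers follow fixed printing precisions (percents to
the integer, grams/folds to 1 decimal, half-up); exact values are always
retained alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._report import DerivedValue, round_half_up
from .reversal import ANDEXANET_MW, EDOXABAN_MW, molar_ratio

__all__ = [
    "GROUPS",
    "TIMEPOINTS",
    "ENDPOINTS",
    "AnimalRecord",
    "GroupSummary",
    "GroupComparison",
    "CorrelationResult",
    "percent_change",
    "fold_change",
    "adjusted_blood_loss",
    "compare_groups",
    "correlate",
    "records_to_frame",
    "frame_to_records",
    "read_animal_csv",
    "write_animal_csv",
    "summarize_groups",
    "analyze_study",
]

#: Treatment arms: control = both vehicles; edox_vehicle = anticoagulant +
#: reversal vehicle; edox_andexanet = anticoagulant + reversal agent;
#: andexanet_only = reversal agent alone.
GROUPS = ("control", "edox_vehicle", "edox_andexanet", "andexanet_only")
#: Sampling times in minutes.
TIMEPOINTS = (0, 20, 25, 40)
#: Per-timepoint endpoints and their units.
ENDPOINTS = (
    ("anti_fxa", "ng/mL"),
    ("pt", "s"),
    ("aptt", "s"),
    ("edoxaban_total", "ng/mL"),
    ("edoxaban_unbound", "ng/mL"),
    ("andexanet", "ug/mL"),
)
_ENDPOINT_NAMES = tuple(name for name, _ in ENDPOINTS)


@dataclass
class AnimalRecord:
    """One animal: arm assignment, timepointed endpoints, terminal blood loss."""

    animal_id: str
    group: str
    blood_loss_g: float
    timepoints: dict[int, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.blood_loss_g < 0:
            raise ValueError("blood_loss_g must be >= 0")
        for tp in self.timepoints:
            if tp not in TIMEPOINTS:
                raise ValueError(f"timepoint {tp} outside the fixed design {TIMEPOINTS}")

    def value(self, endpoint: str, timepoint: int) -> float:
        return self.timepoints[timepoint][endpoint]


@dataclass
class GroupSummary:
    """Per-arm mean ± SD for every endpoint × timepoint, plus blood loss."""

    group: str
    n: int
    means: dict[str, float]  # keyed "<endpoint>_t<tp>" and "blood_loss_g"
    sds: dict[str, float]


class GroupComparison(NamedTuple):
    """Unpaired two-group comparison: pooled-variance t plus rank-sum."""

    t_statistic: float
    p_t: float
    rank_p: float
    degenerate: bool


class CorrelationResult(NamedTuple):
    """Rank correlations of a biomarker with blood loss."""

    spearman_r: float
    p: float
    kendall_tau: float
    kendall_p: float
    undefined: bool


# ---------------------------------------------------------------------------
# Derived arithmetic
# ---------------------------------------------------------------------------


def percent_change(mean_before: float, mean_after: float) -> DerivedValue:
    """Percent decrease from before to after, reported to the nearest integer."""
    if mean_before <= 0:
        raise ValueError("mean_before must be > 0")
    exact = 100.0 * (mean_before - mean_after) / mean_before
    return DerivedValue(round_half_up(exact, 0), exact)


def fold_change(mean_a: float, mean_b: float) -> DerivedValue:
    """Ratio mean_a/mean_b, reported to 1 decimal."""
    if mean_b <= 0:
        raise ValueError("mean_b must be > 0")
    exact = mean_a / mean_b
    return DerivedValue(round_half_up(exact, 1), exact)


def adjusted_blood_loss(group_mean: float, control_mean: float) -> DerivedValue:
    """Group mean blood loss minus the non-anticoagulated control mean (g).

    Reported to 1 decimal; negative values are reported as computed, not
    censored.
    """
    if group_mean < 0 or control_mean < 0:
        raise ValueError("blood loss means must be >= 0")
    exact = group_mean - control_mean
    return DerivedValue(round_half_up(exact, 1), exact)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def compare_groups(values_a: Sequence[float], values_b: Sequence[float]) -> GroupComparison:
    """Two-tailed pooled-variance t-test plus Mann–Whitney rank-sum.

    The nonparametric confirmation uses the rank-sum test because the
    arms are independent (unpaired) by design. Both samples with zero
    variance flag the comparison degenerate.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        same = a[0] == b[0]
        return GroupComparison(0.0 if same else math.inf, 1.0 if same else 0.0, math.nan, True)
    t_res = stats.ttest_ind(a, b, equal_var=True)
    u_res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(float(t_res.statistic), float(t_res.pvalue), float(u_res.pvalue), False)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, observed_r: float) -> float:
    """Exact two-sided permutation p for Spearman's r (tiny n only)."""
    from itertools import permutations

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = 0
    total = 0
    tol = 1e-12
    for perm in permutations(range(len(ry))):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        count += abs(r) >= abs(observed_r) - tol
        total += 1
    return count / total


def correlate(blood_loss: Sequence[float], biomarker: Sequence[float]) -> CorrelationResult:
    """Spearman r (average ranks for ties) and Kendall tau-b confirmation.

    Spearman p uses the large-sample approximation, switching to the
    exact permutation distribution for n ≤ 9. Constant input in either
    variable flags the correlation undefined.
    """
    x = np.asarray(blood_loss, dtype=float)
    y = np.asarray(biomarker, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 4:
        raise ValueError("correlation needs n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(math.nan, math.nan, math.nan, math.nan, True)
    sp = stats.spearmanr(x, y)
    kt = stats.kendalltau(x, y, variant="b")
    p = _exact_spearman_p(x, y, float(sp.statistic)) if x.size <= 9 else float(sp.pvalue)
    return CorrelationResult(
        float(sp.statistic), p, float(kt.statistic), float(kt.pvalue), False
    )


# ---------------------------------------------------------------------------
# I/O — wide animal CSV, one row per animal
# ---------------------------------------------------------------------------


def _wide_columns() -> list[str]:
    cols = ["animal_id", "group", "blood_loss_g"]
    for name in _ENDPOINT_NAMES:
        cols += [f"{name}_t{tp}" for tp in TIMEPOINTS]
    return cols


def records_to_frame(records: Sequence[AnimalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict[str, object] = {
            "animal_id": r.animal_id,
            "group": r.group,
            "blood_loss_g": r.blood_loss_g,
        }
        for tp in TIMEPOINTS:
            for name in _ENDPOINT_NAMES:
                row[f"{name}_t{tp}"] = r.timepoints.get(tp, {}).get(name, math.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=_wide_columns())


def frame_to_records(df: pd.DataFrame) -> list[AnimalRecord]:
    missing = [c for c in _wide_columns() if c not in df.columns]
    if missing:
        raise ValueError(f"animal table missing required columns {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            timepoints = {
                tp: {name: float(row[f"{name}_t{tp}"]) for name in _ENDPOINT_NAMES}
                for tp in TIMEPOINTS
            }
            records.append(
                AnimalRecord(
                    animal_id=str(row["animal_id"]),
                    group=str(row["group"]),
                    blood_loss_g=float(row["blood_loss_g"]),
                    timepoints=timepoints,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"animal table row {i}: {exc}") from exc
    return records


def write_animal_csv(records: Sequence[AnimalRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_animal_csv(path: str | Path) -> list[AnimalRecord]:
    return frame_to_records(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def summarize_groups(records: Sequence[AnimalRecord]) -> dict[str, GroupSummary]:
    """Mean ± SD (ddof=1) per arm for every endpoint; permutation-invariant."""
    df = records_to_frame(records)
    out: dict[str, GroupSummary] = {}
    value_cols = [c for c in df.columns if c not in ("animal_id", "group")]
    for group, sub in df.groupby("group"):
        n = len(sub)
        means = {c: float(sub[c].mean()) for c in value_cols}
        sds = {c: float(sub[c].std(ddof=1)) if n >= 2 else math.nan for c in value_cols}
        out[str(group)] = GroupSummary(group=str(group), n=n, means=means, sds=sds)
    return out


def _comparison_dict(c: GroupComparison) -> dict:
    return {
        "t_statistic": c.t_statistic,
        "p_t": c.p_t,
        "rank_p": c.rank_p,
        "degenerate": c.degenerate,
    }


def analyze_study(records: Sequence[AnimalRecord]) -> dict:
    """Full in vivo analysis: summaries, derived effects, tests, correlations.

    Returns a JSON-serializable report. Derived arithmetic (percent and
    fold changes, control-adjusted blood loss, decoy:inhibitor molar
    ratio at the end of infusion) is computed from group means; group
    comparisons use the pooled t-test with rank-sum confirmation, and
    the biomarker–blood-loss correlations pool the arms present in the
    data excluding the decoy-only arm (which receives no anticoagulant
    and is excluded from the correlation analysis).
    """
    if not records:
        raise ValueError("no animal records supplied")
    summaries = summarize_groups(records)
    for g in ("control", "edox_vehicle", "edox_andexanet"):
        if g not in summaries or summaries[g].n == 0:
            raise ValueError(f"group {g!r} is empty or absent")

    sm = {g: s.means for g, s in summaries.items()}
    rev, veh, ctl = sm["edox_andexanet"], sm["edox_vehicle"], sm["control"]

    anti_fxa_reversal = percent_change(rev["anti_fxa_t20"], rev["anti_fxa_t25"])
    anti_fxa_vehicle = percent_change(veh["anti_fxa_t20"], veh["anti_fxa_t25"])
    unbound_reversal = percent_change(rev["edoxaban_unbound_t20"], rev["edoxaban_unbound_t25"])
    bl_fold = fold_change(veh["blood_loss_g"], ctl["blood_loss_g"])
    adj_rev = adjusted_blood_loss(rev["blood_loss_g"], ctl["blood_loss_g"])
    adj_veh = adjusted_blood_loss(veh["blood_loss_g"], ctl["blood_loss_g"])
    bl_reduction = percent_change(adj_veh.exact, adj_rev.exact)

    andexanet_um = rev["andexanet_t25"] * 1000.0 / ANDEXANET_MW  # μg/mL → μM
    edoxaban_um = rev["edoxaban_total_t25"] / EDOXABAN_MW
    ratio = molar_ratio(andexanet_um, edoxaban_um)

    derived = {
        "anti_fxa_reduction_reversal_pct": anti_fxa_reversal.value,
        "anti_fxa_reduction_vehicle_pct": anti_fxa_vehicle.value,
        "anti_fxa_vehicle_decrease_ng_ml": round_half_up(
            veh["anti_fxa_t20"] - veh["anti_fxa_t25"], 0
        ),
        "unbound_reduction_reversal_pct": unbound_reversal.value,
        "blood_loss_fold_vehicle_vs_control": bl_fold.value,
        "adjusted_blood_loss_reversal_g": adj_rev.value,
        "adjusted_blood_loss_vehicle_g": adj_veh.value,
        "blood_loss_reduction_pct": bl_reduction.value,
        "molar_ratio_decoy_to_inhibitor": ratio.value,
        "exact": {
            "anti_fxa_reduction_reversal_pct": anti_fxa_reversal.exact,
            "anti_fxa_reduction_vehicle_pct": anti_fxa_vehicle.exact,
            "unbound_reduction_reversal_pct": unbound_reversal.exact,
            "blood_loss_fold_vehicle_vs_control": bl_fold.exact,
            "adjusted_blood_loss_reversal_g": adj_rev.exact,
            "adjusted_blood_loss_vehicle_g": adj_veh.exact,
            "blood_loss_reduction_pct": bl_reduction.exact,
            "molar_ratio_decoy_to_inhibitor": ratio.exact,
        },
    }

    df = records_to_frame(records)

    def group_values(group: str, col: str) -> np.ndarray:
        return df.loc[df["group"] == group, col].to_numpy(dtype=float)

    comparisons = {}
    for label, (ga, gb, col) in {
        "blood_loss_vehicle_vs_control": ("edox_vehicle", "control", "blood_loss_g"),
        "blood_loss_reversal_vs_vehicle": ("edox_andexanet", "edox_vehicle", "blood_loss_g"),
        "blood_loss_reversal_vs_control": ("edox_andexanet", "control", "blood_loss_g"),
        "anti_fxa_t25_reversal_vs_vehicle": ("edox_andexanet", "edox_vehicle", "anti_fxa_t25"),
        "unbound_t25_reversal_vs_vehicle": (
            "edox_andexanet",
            "edox_vehicle",
            "edoxaban_unbound_t25",
        ),
    }.items():
        a, b = group_values(ga, col), group_values(gb, col)
        if a.size >= 2 and b.size >= 2:
            comparisons[label] = _comparison_dict(compare_groups(a, b))

    pooled = df[df["group"] != "andexanet_only"]
    correlations = {}
    for label, col in {
        "blood_loss_vs_anti_fxa_t25": "anti_fxa_t25",
        "blood_loss_vs_unbound_t25": "edoxaban_unbound_t25",
    }.items():
        bl = pooled["blood_loss_g"].to_numpy(dtype=float)
        bm = pooled[col].to_numpy(dtype=float)
        if bl.size >= 4:
            c = correlate(bl, bm)
            correlations[label] = {
                "spearman_r": c.spearman_r,
                "p": c.p,
                "kendall_tau": c.kendall_tau,
                "kendall_p": c.kendall_p,
                "undefined": c.undefined,
                "n": int(bl.size),
            }

    return {
        "groups": {
            g: {"n": s.n, "means": s.means, "sds": s.sds} for g, s in summaries.items()
        },
        "derived": derived,
        "comparisons": comparisons,
        "correlations": correlations,
        "units": {name: unit for name, unit in ENDPOINTS} | {"blood_loss": "g"},
    }
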