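"""Relative-expression analysis of validation qPCR data (2^-ddCt).

Each sample contributes a cycle-threshold pair: the target assay and an
internal reference (U6 snRNA for miRNA assays, GAPDH for mRNA). The
within-sample difference dCt = Ct_target - Ct_reference normalizes for
input amount; the between-group difference ddCt = dCt_case - dCt_control
converts to a fold change 2^(-ddCt) under the usual assumption of
near-100% amplification efficiency. Group differences are tested with a
paired t-test for matched tissue pairs or Welch's t-test for independent
groups (e.g. patient sera versus non-cancer controls, where the control
baseline is the mean control dCt).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"


@dataclass
class CtRecord:
    sample_id: str
    group: str  # case | control
    ct_target: float
    ct_reference: float
    pair_id: str | None = None

    def __post_init__(self) -> None:
        for name, ct in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if not np.isfinite(ct) or ct <= 0:
                raise ValueError(f"{name} must be finite and positive, got {ct}")
        if self.group not in (CASE, CONTROL):
            raise ValueError(f"group must be 'case' or 'control', got {self.group!r}")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


@dataclass
class GroupComparison:
    mean_case: float
    se_case: float
    mean_control: float
    se_control: float
    t_stat: float
    p_value: float
    paired: bool


def ddct_fold_change(case: CtRecord, control: CtRecord) -> float:
    """Fold change 2^(-ddCt) of case relative to control."""
    ddct = case.delta_ct - control.delta_ct
    return float(2.0 ** (-ddct))


def relative_expression(records: list[CtRecord]) -> pd.DataFrame:
    """Per-case fold change against the mean control dCt baseline.

    Used for unpaired designs (e.g. serum samples referenced to a pool of
    non-cancer controls): each case's ddCt is its dCt minus the mean
    control dCt.
    """
    controls = [r.delta_ct for r in records if r.group == CONTROL]
    if not controls:
        raise ValueError("no control records to define the baseline")
    baseline = float(np.mean(controls))
    rows = [
        {
            "sample_id": r.sample_id,
            "group": r.group,
            "delta_ct": r.delta_ct,
            "fold_change": float(2.0 ** (-(r.delta_ct - baseline))),
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    return float(values.mean()), float(values.std(ddof=1) / np.sqrt(values.size))


def group_compare(
    values_case: np.ndarray | list[float],
    values_control: np.ndarray | list[float],
    paired: bool = False,
) -> GroupComparison:
    """Group means +- SE with a paired or Welch two-sample t-test."""
    a = np.asarray(values_case, dtype=float)
    b = np.asarray(values_control, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal group sizes")
        diffs = a - b
        if np.allclose(diffs, 0):
            warnings.warn("all paired differences are zero; reporting t=0, p=1")
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(a, b)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    ma, sa = _mean_se(a)
    mb, sb = _mean_se(b)
    return GroupComparison(
        mean_case=ma,
        se_case=sa,
        mean_control=mb,
        se_control=sb,
        t_stat=float(t),
        p_value=float(p),
        paired=paired,
    )


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct table (sample_id, group, pair_id, target, ct_target, ct_reference)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "pair_id": str})
    required = {"sample_id", "group", "target", "ct_target", "ct_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df


def analyze_ct_table(df: pd.DataFrame, paired: bool = True) -> pd.DataFrame:
    """Per-target fold change and group test from a long-format Ct table.

    Replicate rows (same sample, group and target) are averaged before
    computing dCt. For paired analyses samples are matched on pair_id.
    """
    results = []
    df = df.copy()
    df["delta_ct"] = df["ct_target"] - df["ct_reference"]
    group_keys = ["target", "group", "sample_id"] + (["pair_id"] if "pair_id" in df else [])
    collapsed = df.groupby(group_keys, as_index=False)["delta_ct"].mean()
    for target, sub in collapsed.groupby("target"):
        case = sub[sub["group"] == CASE]
        control = sub[sub["group"] == CONTROL]
        if paired:
            merged = case.merge(control, on="pair_id", suffixes=("_case", "_control"))
            a = merged["delta_ct_case"].to_numpy()
            b = merged["delta_ct_control"].to_numpy()
        else:
            a = case["delta_ct"].to_numpy()
            b = control["delta_ct"].to_numpy()
        cmp = group_compare(a, b, paired=paired)
        fold = float(2.0 ** (-(a.mean() - b.mean())))
        results.append(
            {
                "target": target,
                "n_case": a.size,
                "n_control": b.size,
                "mean_dct_case": cmp.mean_case,
                "se_dct_case": cmp.se_case,
                "mean_dct_control": cmp.mean_control,
                "se_dct_control": cmp.se_control,
                "fold_change": fold,
                "t_stat": cmp.t_stat,
                "p_value": cmp.p_value,
            }
        )
    return pd.DataFrame(results)
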