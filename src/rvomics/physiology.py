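"""Derived hemodynamic indices, summary-statistics t-tests and qPCR folds.

Covers the physiological side of the study design: indices derived from
right-heart catheterization and echocardiography (estimated mean
pulmonary artery pressure, pulmonary vascular resistance, free-wall
systolic thickening, TAPSE/RVSP coupling, Fulton index), unpaired
two-group t-tests computed directly from published summary statistics
(mean, SEM, n), and relative qPCR quantification by the 2^-ddCt method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GroupSummary", "derived_indices", "summary_ttest", "ddct"]


@dataclass(frozen=True)
class GroupSummary:
    """Published group summary: mean, standard error of the mean, n."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sem < 0:
            raise ValueError("SEM must be non-negative")


def derived_indices(record: dict[str, float]) -> dict[str, float]:
    """Hemodynamic indices derivable from one animal's measurements.

    Input keys (all optional; an index is computed when its inputs are
    present): rvsp and lvedp (mmHg), co (ml/min), tapse (mm),
    rvfw_systole / rvfw_diastole (mm), rv_mass / lv_septum_mass (g).

    Computes:
      mpap        = 0.6 * RVSP + 2                      (mmHg)
      pvr         = (mPAP - LVEDP) / CO                 (mmHg/ml/min)
      thickening  = (RVFWsys - RVFWdia) / RVFWdia       (fraction)
      coupling    = TAPSE / RVSP                        (mm/mmHg)
      fulton      = RV mass / (LV + septum mass)
    """
    out: dict[str, float] = {}
    if "rvsp" in record:
        out["mpap"] = 0.6 * record["rvsp"] + 2.0
        if "tapse" in record:
            out["coupling"] = record["tapse"] / record["rvsp"]
    if "mpap" in out and "lvedp" in record and "co" in record:
        if record["co"] == 0:
            raise ValueError("cardiac output is zero; PVR undefined")
        out["pvr"] = (out["mpap"] - record["lvedp"]) / record["co"]
    if "rvfw_systole" in record and "rvfw_diastole" in record:
        dia = record["rvfw_diastole"]
        if dia == 0:
            raise ValueError("diastolic free-wall thickness is zero")
        out["thickening"] = (record["rvfw_systole"] - dia) / dia
    if "rv_mass" in record and "lv_septum_mass" in record:
        out["fulton"] = record["rv_mass"] / record["lv_septum_mass"]
    return out


def summary_ttest(
    a: GroupSummary, b: GroupSummary, welch: bool = False
) -> tuple[float, float, float]:
    """Unpaired two-group t-test from summary statistics.

    t = (mean_a - mean_b) / sqrt(sem_a^2 + sem_b^2).  Degrees of
    freedom are pooled (n_a + n_b - 2) by default, or Welch-
    Satterthwaite with ``welch=True``.  Returns (t, df, two-sided p).

    Note the pooled-df variant matches the classic equal-variance test
    exactly only for equal group sizes; with unequal n use Welch.
    """
    if a.sem == 0 and b.sem == 0:
        raise ValueError("both SEMs are zero; t undefined")
    se2 = a.sem**2 + b.sem**2
    t = (a.mean - b.mean) / math.sqrt(se2)
    if welch:
        df = se2**2 / (a.sem**4 / (a.n - 1) + b.sem**4 / (b.n - 1))
    else:
        df = a.n + b.n - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


def ddct(records: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Relative qPCR quantification by the 2^-ddCt method.

    ``records`` needs columns sample, group, ct_target, ct_reference.
    Per sample, dCt = Ct_target - Ct_reference; ddCt subtracts the mean
    dCt of the control group; fold = 2^-ddCt.  By construction the
    geometric mean fold of the control group is 1.
    """
    required = {"sample", "group", "ct_target", "ct_reference"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"qPCR table lacks columns: {sorted(missing)}")
    if records["ct_reference"].isna().any():
        bad = records.loc[records["ct_reference"].isna(), "sample"].tolist()
        raise ValueError(f"missing reference Ct for samples: {bad}")
    if (records["group"] == control_group).sum() == 0:
        raise ValueError(f"control group {control_group!r} not found")
    out = records.copy()
    out["dct"] = out["ct_target"] - out["ct_reference"]
    control_mean = out.loc[out["group"] == control_group, "dct"].mean()
    out["ddct"] = out["dct"] - control_mean
    out["fold"] = np.power(2.0, -out["ddct"])
    return out
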