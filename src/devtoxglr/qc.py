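"""Robust plate-performance metrics from control-well %SOX17+ values.

With ``x`` the median and ``mad`` the median absolute deviation of a control
population's percent-SOX17-positive values,

* signal-to-background  S/B  = xPos / xNeg,
* robust CV             rCV  = 100 * madPos / xPos  (percent),
* robust Z'-factor      rZ'  = 1 - 3 (madPos + madNeg) / |xPos - xNeg|,

where Pos is the differentiated (endoderm or solvent-exposed endoderm)
control and Neg the non-differentiated pluripotent control.  rZ' > 0.5 marks
screening-quality separation.  Inter-plate rCV is the median of the per-plate
values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gating import mad


def signal_to_background(x_pos: float, x_neg: float) -> float:
    if x_neg == 0:
        return float("nan")
    return x_pos / x_neg


def robust_cv(x_pos: float, mad_pos: float) -> float:
    if x_pos == 0:
        return float("nan")
    return 100.0 * mad_pos / x_pos


def robust_zprime(x_pos: float, x_neg: float, mad_pos: float, mad_neg: float) -> float:
    if x_pos == x_neg:
        return float("nan")
    return 1.0 - 3.0 * (mad_pos + mad_neg) / abs(x_pos - x_neg)


@dataclass(frozen=True)
class ControlStats:
    plate: str
    x_pos: float
    x_neg: float
    mad_pos: float
    mad_neg: float
    n_pos: int
    n_neg: int


def control_stats(
    wells: pd.DataFrame,
    pos_role: str = "solvent_control",
    neg_role: str = "pluripotent_control",
    measure: str = "pct_sox17_pos",
    convention: str = "normal",
) -> list[ControlStats]:
    """Per-plate control medians and MADs from a well-level summary table."""
    out = []
    for plate, pw in wells.groupby("plate", sort=True):
        pos = pw.loc[pw["role"] == pos_role, measure].dropna().to_numpy()
        neg = pw.loc[pw["role"] == neg_role, measure].dropna().to_numpy()
        if pos.size < 2 or neg.size < 2:
            raise ValueError(f"plate {plate!r}: need >= 2 wells per control role")
        out.append(
            ControlStats(
                plate=plate,
                x_pos=float(np.median(pos)),
                x_neg=float(np.median(neg)),
                mad_pos=mad(pos, convention),
                mad_neg=mad(neg, convention),
                n_pos=int(pos.size),
                n_neg=int(neg.size),
            )
        )
    return out


def plate_qc(
    wells: pd.DataFrame,
    pos_role: str = "solvent_control",
    neg_role: str = "pluripotent_control",
    measure: str = "pct_sox17_pos",
    convention: str = "normal",
) -> pd.DataFrame:
    """Per-plate S/B, rCV and rZ' plus a pooled ``inter_plate`` row.

    The pooled row carries the median of each per-plate metric (the
    inter-plate rCV convention applied to all three).
    """
    rows = []
    for cs in control_stats(wells, pos_role, neg_role, measure, convention):
        rows.append(
            {
                "plate": cs.plate,
                "sb": signal_to_background(cs.x_pos, cs.x_neg),
                "rcv": robust_cv(cs.x_pos, cs.mad_pos),
                "rzprime": robust_zprime(cs.x_pos, cs.x_neg, cs.mad_pos, cs.mad_neg),
            }
        )
    per_plate = pd.DataFrame(rows)
    pooled = {
        "plate": "inter_plate",
        "sb": float(per_plate["sb"].median()),
        "rcv": float(per_plate["rcv"].median()),
        "rzprime": float(per_plate["rzprime"].median()),
    }
    return pd.concat([per_plate, pd.DataFrame([pooled])], ignore_index=True)
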