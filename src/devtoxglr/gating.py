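"""Per-cell gating: plate-based MAD thresholds and well-level summaries.

A cell is biomarker-positive when its mean channel intensity exceeds the
plate's baseline threshold ``median + multiplier * MAD`` computed from the
appropriate control population: pluripotent-control cells for SOX17 and BRA
(both off before differentiation) and endoderm-control cells for SOX2 (off
after differentiation).  The default multiplier is 5.

The MAD is the scaled median absolute deviation (consistency constant 1.4826,
``mad="normal"``) by default, matching the convention of the downstream
concentration-response pipeline; the raw MAD is selectable (``mad="raw"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .layouts import PlateLayout

CHANNELS = ("sox17", "sox2", "bra")

#: which control role defines the baseline population for each channel
BASELINE_ROLE = {
    "sox17": "pluripotent_control",
    "bra": "pluripotent_control",
    "sox2": "endoderm_control",
}

MAD_SCALE = {"normal": "normal", "raw": 1.0}


def mad(values, convention: str = "normal") -> float:
    """Median absolute deviation under the chosen convention."""
    if convention not in MAD_SCALE:
        raise ValueError(f"unknown MAD convention {convention!r}")
    return float(stats.median_abs_deviation(values, scale=MAD_SCALE[convention]))


def mad_threshold(intensities, multiplier: float = 5.0, convention: str = "normal") -> float:
    """``median + multiplier * MAD`` of a baseline intensity population."""
    x = np.asarray(intensities, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 baseline intensities")
    if not np.all(np.isfinite(x)):
        raise ValueError("baseline intensities must be finite")
    return float(np.median(x)) + multiplier * mad(x, convention)


@dataclass(frozen=True)
class GateThresholds:
    """Per-plate, per-channel gating thresholds.

    ``table`` has columns plate, channel, baseline_role, median, mad,
    multiplier, threshold.
    """

    table: pd.DataFrame
    multiplier: float = 5.0
    convention: str = "normal"

    def threshold(self, plate, channel) -> float:
        t = self.table
        row = t[(t["plate"] == plate) & (t["channel"] == channel)]
        if len(row) != 1:
            raise KeyError(f"no threshold for plate {plate!r} channel {channel!r}")
        return float(row["threshold"].iloc[0])


def compute_plate_thresholds(
    cells: pd.DataFrame,
    layout: PlateLayout | list[PlateLayout],
    multiplier: float = 5.0,
    convention: str = "normal",
) -> GateThresholds:
    """Thresholds for every plate present in ``cells``.

    Baselines pool cells across all technical-replicate control wells of the
    plate; no cross-plate pooling.
    """
    layouts = layout if isinstance(layout, (list, tuple)) else [layout]
    by_id = {lo.plate_id: lo for lo in layouts}
    records = []
    for plate, pcells in cells.groupby("plate", sort=True):
        lo = by_id.get(plate)
        if lo is None:
            raise KeyError(f"no layout for plate {plate!r}")
        for ch in CHANNELS:
            role = BASELINE_ROLE[ch]
            ctrl_wells = lo.role_wells(role)
            if not ctrl_wells:
                raise ValueError(f"plate {plate!r} has no {role} wells")
            baseline = pcells.loc[pcells["well"].isin(ctrl_wells), ch].to_numpy()
            if baseline.size < 2:
                raise ValueError(
                    f"plate {plate!r}: {role} wells contain <2 cells for {ch}"
                )
            med = float(np.median(baseline))
            m = mad(baseline, convention)
            records.append((plate, ch, role, med, m, multiplier, med + multiplier * m))
    table = pd.DataFrame(
        records,
        columns=["plate", "channel", "baseline_role", "median", "mad", "multiplier", "threshold"],
    )
    return GateThresholds(table, multiplier, convention)


def summarize_wells(
    cells: pd.DataFrame,
    thresholds: GateThresholds,
    layout: PlateLayout | list[PlateLayout] | None = None,
) -> pd.DataFrame:
    """Per-well percent responders and cell counts.

    A cell is positive iff intensity > threshold (ties count negative); the
    cell count sums all imaging fields of the well.  Wells with zero cells get
    NaN percentages.  When layouts are supplied, role/chemical_id/conc_uM are
    joined in and wells laid out but empty of cells are emitted with count 0.
    """
    thr = {
        (r.plate, r.channel): r.threshold
        for r in thresholds.table.itertuples(index=False)
    }
    records = []
    for (plate, well), g in cells.groupby(["plate", "well"], sort=True):
        n = len(g)
        rec = {"plate": plate, "well": well, "cell_count": n}
        for ch in CHANNELS:
            key = (plate, ch)
            if key not in thr:
                raise KeyError(f"no threshold for plate {plate!r} channel {ch!r}")
            if n == 0:
                rec[f"pct_{ch}_pos"] = np.nan
            else:
                rec[f"pct_{ch}_pos"] = 100.0 * float((g[ch].to_numpy() > thr[key]).sum()) / n
        records.append(rec)
    wells = pd.DataFrame.from_records(records)

    if layout is not None:
        layouts = layout if isinstance(layout, (list, tuple)) else [layout]
        meta = []
        for lo in layouts:
            m = lo.wells.copy()
            m.insert(0, "plate", lo.plate_id)
            meta.append(m)
        meta = pd.concat(meta, ignore_index=True)
        wells = meta.merge(wells, on=["plate", "well"], how="left")
        wells["cell_count"] = wells["cell_count"].fillna(0).astype(int)
        wells = wells[
            ["plate", "well", "role", "chemical_id", "conc_uM", "cell_count"]
            + [f"pct_{ch}_pos" for ch in CHANNELS]
        ]
    return wells
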