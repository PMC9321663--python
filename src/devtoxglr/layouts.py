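"""384-well plate layouts for the directed-endoderm screen.

A layout maps wells to one of five roles:

* ``pluripotent_control`` — non-differentiated cells in maintenance medium;
  baseline for the SOX17 and BRA gating thresholds.
* ``endoderm_control`` — directed-endoderm differentiated cells; baseline for
  the SOX2 gating threshold and the positive control for QC metrics.
* ``solvent_control`` — endoderm differentiation in 0.2% DMSO; defines the
  normalization baseline (bval) and the noise band (bmad) downstream.
* ``positive_control`` — endoderm differentiation with the TGF-beta receptor
  inhibitor SB431542, which blocks Activin/Nodal signalling and abolishes
  SOX17 induction.
* ``treatment`` — a (chemical, concentration) exposure during differentiation.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

ROLES = (
    "pluripotent_control",
    "endoderm_control",
    "solvent_control",
    "positive_control",
    "treatment",
)
CONTROL_ROLES = ROLES[:4]

PLATE_ROWS = [chr(ord("A") + i) for i in range(16)]
PLATE_COLS = list(range(1, 25))


def well_name(row_idx: int, col_idx: int) -> str:
    return f"{PLATE_ROWS[row_idx]}{col_idx + 1:02d}"


@dataclass
class PlateLayout:
    """Role assignment for (a subset of) a 384-well plate.

    ``wells`` is a DataFrame with columns ``well``, ``role``, ``chemical_id``
    (NA except for treatments) and ``conc_uM`` (NA except for treatments).
    """

    plate_id: str
    wells: pd.DataFrame
    fields_per_well: int = 5

    def __post_init__(self) -> None:
        w = self.wells
        required = {"well", "role", "chemical_id", "conc_uM"}
        missing = required - set(w.columns)
        if missing:
            raise ValueError(f"layout missing columns: {sorted(missing)}")
        if len(w) == 0:
            raise ValueError("empty layout")
        if w["well"].duplicated().any():
            dup = w.loc[w["well"].duplicated(), "well"].iloc[0]
            raise ValueError(f"well {dup!r} assigned more than one role")
        bad = set(w["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        treat = w[w["role"] == "treatment"]
        if treat["chemical_id"].isna().any():
            raise ValueError("treatment wells must carry chemical_id")
        conc = pd.to_numeric(treat["conc_uM"])
        if (conc <= 0).any() or conc.isna().any():
            raise ValueError("treatment concentrations must be strictly positive")
        for role in CONTROL_ROLES:
            n = (w["role"] == role).sum()
            if 0 < n < 2:
                raise ValueError(f"control role {role!r} needs >= 2 wells, got {n}")

    def role_wells(self, role: str) -> list[str]:
        return self.wells.loc[self.wells["role"] == role, "well"].tolist()

    def chemicals(self) -> list[str]:
        t = self.wells.loc[self.wells["role"] == "treatment", "chemical_id"]
        return sorted(t.dropna().unique())

    def to_json(self, path) -> None:
        payload = {
            "plate_id": self.plate_id,
            "fields_per_well": self.fields_per_well,
            "wells": self.wells.where(self.wells.notna(), None).to_dict("records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PlateLayout":
        with open(path) as fh:
            payload = json.load(fh)
        wells = pd.DataFrame(payload["wells"])
        return cls(payload["plate_id"], wells, payload.get("fields_per_well", 5))


def default_concentrations() -> np.ndarray:
    """Eight-point test-chemical series, 1 pM - 200 uM, skewed high.

    Half-log spacing over the top four decades (0.063-200 uM) plus two sparse
    low anchors; the screen concentrated points where chemical activity is
    expected.
    """
    top = 200.0
    upper = top / 10 ** (np.arange(6)[::-1] * 0.5)  # 0.632 ... 200, half-log
    low = np.array([1e-6, 1e-3])  # 1 pM, 1 nM anchors
    return np.concatenate([low, np.round(upper, 4)])


def make_screen_layout(
    plate_id: str,
    chemicals: "list[str]",
    concentrations=None,
    n_replicate_wells: int = 1,
    control_wells_per_role: int = 12,
    fields_per_well: int = 5,
) -> PlateLayout:
    """Lay out a screening plate: control columns plus one well per
    chemical x concentration x replicate, filled row-major.
    """
    if concentrations is None:
        concentrations = default_concentrations()
    concentrations = np.asarray(concentrations, dtype=float)

    records = []
    wells_iter = iter(
        well_name(r, c) for c in range(24) for r in range(16)
    )
    for role in CONTROL_ROLES:
        for _ in range(control_wells_per_role):
            records.append((next(wells_iter), role, None, np.nan))
    for chem, conc, _rep in itertools.product(
        chemicals, concentrations, range(n_replicate_wells)
    ):
        try:
            w = next(wells_iter)
        except StopIteration:
            raise ValueError("layout does not fit on a 384-well plate") from None
        records.append((w, "treatment", chem, float(conc)))

    wells = pd.DataFrame(records, columns=["well", "role", "chemical_id", "conc_uM"])
    return PlateLayout(plate_id, wells, fields_per_well)


def make_control_plate(
    plate_id: str, wells_per_role: int = 96, fields_per_well: int = 5
) -> PlateLayout:
    """A plate of only control wells (layout used for gating calibration)."""
    records = []
    wells_iter = iter(well_name(r, c) for c in range(24) for r in range(16))
    for role in CONTROL_ROLES:
        for _ in range(wells_per_role):
            records.append((next(wells_iter), role, None, np.nan))
    wells = pd.DataFrame(records, columns=["well", "role", "chemical_id", "conc_uM"])
    return PlateLayout(plate_id, wells, fields_per_well)
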