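"""Predictive-performance benchmarking against published chemical tables.

Ships transcriptions of the three published benchmark tables:

* ``table1`` — the eight reference chemicals (four FDA pregnancy category X
  positives, four category A/B/C negatives) with SOX17 IC50 and maximal
  inhibition; the assay called all eight correctly.
* ``table3`` — the 34-chemical overlap with the pluripotent stem cell test
  (hPST): per-assay cytotoxicity and SOX17 potencies plus TP/FP/TN/FN calls.
* ``table4`` — the 40-chemical overlap with the devTOX quickPredict assay:
  viability/cell-count potencies, Teratogen Index vs ACC, and calls.

Potency entries like ``>200`` are right-censored (activity not reached up to
the floor) and ``<2`` left-censored; both are preserved.  Confusion metrics
are computed from the call columns; ``potency_filter`` re-calls actives under
a potency requirement (e.g. the 30 uM AC50 rule) and recomputes metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

CALLS = ("TP", "FP", "TN", "FN")
_ACTIVE = {"TP": True, "FP": True, "TN": False, "FN": False}
_TRUTH = {"TP": "Pos", "FN": "Pos", "TN": "Neg", "FP": "Neg"}

#: 58-chemical training-set outcome counts reported for the assay
TRAINING_SET_COUNTS = {"tp": 30, "fp": 8, "tn": 11, "fn": 9}


def casrn_is_valid(casrn: str) -> bool:
    """CAS registry number checksum (weighted sum of digits mod 10)."""
    parts = str(casrn).split("-")
    if len(parts) != 3 or not all(p.isdigit() for p in parts):
        return False
    digits = parts[0] + parts[1]
    check = int(parts[2])
    total = sum(int(d) * w for w, d in enumerate(reversed(digits), start=1))
    return total % 10 == check


def parse_potency(text) -> tuple[float, str]:
    """Parse a printed potency cell into ``(value_uM, censor)``.

    ``censor`` is ``""`` (observed), ``"gt"`` (``>floor``: not reached below
    the floor), ``"lt"`` (``<ceiling``), or ``"na"`` (no value; NaN).
    """
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return np.nan, "na"
    s = str(text).strip().rstrip("*").strip()
    if s in ("", "NA", "-", "nan"):
        return np.nan, "na"
    if s.startswith(">"):
        return float(s[1:].replace(",", "")), "gt"
    if s.startswith("<"):
        return float(s[1:].replace(",", "")), "lt"
    return float(s.replace(",", "")), ""


def _load(name: str) -> pd.DataFrame:
    with resources.files("devtoxglr.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, dtype=str)


def _parse_potency_columns(df: pd.DataFrame, cols) -> pd.DataFrame:
    df = df.copy()
    for c in cols:
        parsed = df[c].map(parse_potency)
        df[c] = [v for v, _ in parsed]
        df[c + "_censor"] = [f for _, f in parsed]
    return df


def load_table1() -> pd.DataFrame:
    """Reference chemicals; the ``call`` column encodes that the assay called
    all four positives and all four negatives correctly."""
    return _parse_potency_columns(_load("table1.csv"), ["ic50_uM", "pct_max_inhibition"])


def load_table3() -> pd.DataFrame:
    """hPST comparison set (34 chemicals, calls for both assays)."""
    return _parse_potency_columns(
        _load("table3.csv"),
        ["hpst_tc50_uM", "hpst_ic50_uM", "devtox_cc50_uM", "devtox_ac50_uM"],
    )


def load_table4() -> pd.DataFrame:
    """devTOX quickPredict comparison set (40 chemicals, calls for both)."""
    return _parse_potency_columns(
        _load("table4.csv"),
        ["qp_cv_uM", "qp_ti_uM", "devtox_cc_uM", "devtox_acc_uM"],
    )


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0

    def rounded(self, ndigits: int = 1) -> dict:
        return {
            "sensitivity": round(self.sensitivity, ndigits),
            "specificity": round(self.specificity, ndigits),
            "balanced_accuracy": round(self.balanced_accuracy, ndigits),
        }

    def __add__(self, other: "ConfusionMetrics") -> "ConfusionMetrics":
        return ConfusionMetrics(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )

    @classmethod
    def from_counts(cls, counts: dict) -> "ConfusionMetrics":
        return cls(counts["tp"], counts["fp"], counts["tn"], counts["fn"])


def _check_calls(records: pd.DataFrame, call_col: str) -> pd.Series:
    calls = records[call_col]
    if calls.isna().any():
        bad = records.loc[calls.isna(), "chemical"].tolist()
        raise ValueError(f"records missing {call_col!r} call: {bad}")
    unknown = set(calls) - set(CALLS)
    if unknown:
        raise ValueError(f"unknown calls {sorted(unknown)} in {call_col!r}")
    if "dt_class" in records:
        mismatch = records.loc[calls.map(_TRUTH) != records["dt_class"], "chemical"]
        if len(mismatch):
            raise ValueError(
                f"calls inconsistent with truth class: {mismatch.tolist()}"
            )
    return calls


def confusion(records: pd.DataFrame, call_col: str) -> ConfusionMetrics:
    """Tally TP/FP/TN/FN calls from one assay's call column."""
    calls = _check_calls(records, call_col)
    c = calls.value_counts()
    return ConfusionMetrics(
        tp=int(c.get("TP", 0)),
        fp=int(c.get("FP", 0)),
        tn=int(c.get("TN", 0)),
        fn=int(c.get("FN", 0)),
    )


def potency_filter(
    records: pd.DataFrame,
    call_col: str,
    potency_col: str,
    threshold_uM: float,
) -> pd.DataFrame:
    """Re-call actives under a potency requirement (potency <= threshold).

    An active (TP/FP) whose potency is absent, right-censored at or above the
    threshold, or numerically above it becomes inactive (FN/TN); truth classes
    are untouched.  Returns a copy with the call column replaced.
    """
    if threshold_uM < 0:
        raise ValueError("threshold must be non-negative")
    if potency_col not in records.columns:
        raise KeyError(f"unknown potency field {potency_col!r}")
    _check_calls(records, call_col)
    out = records.copy()
    censor_col = potency_col + "_censor"
    for i, row in out.iterrows():
        call = row[call_col]
        if not _ACTIVE[call]:
            continue
        value = row[potency_col]
        censor = row.get(censor_col, "")
        if censor == "na" or (isinstance(value, float) and np.isnan(value)):
            reached = False
        elif censor == "gt":
            reached = False  # absent-with-floor: activity never reached
        elif censor == "lt":
            reached = value <= threshold_uM  # true potency below the ceiling
        else:
            reached = float(value) <= threshold_uM
        if not reached:
            out.at[i, call_col] = "FN" if call == "TP" else "TN"
    return out


def effect_band(pct_max_inhibition: float) -> str:
    """Stratify maximal effect: weak [0,20), moderate [20,80), high [80,100]."""
    p = float(pct_max_inhibition)
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"% max inhibition out of [0, 100]: {p}")
    if p < 20.0:
        return "weak"
    if p < 80.0:
        return "moderate"
    return "high"


def compare_assays(
    records: pd.DataFrame, call_col_a: str, call_col_b: str
) -> tuple[ConfusionMetrics, ConfusionMetrics, pd.DataFrame]:
    """Side-by-side metrics for two assays plus the discordant chemicals."""
    m_a = confusion(records, call_col_a)
    m_b = confusion(records, call_col_b)
    disc = records.loc[
        records[call_col_a] != records[call_col_b],
        ["chemical", "dt_class", call_col_a, call_col_b],
    ].reset_index(drop=True)
    return m_a, m_b, disc
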