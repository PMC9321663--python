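"""qPCR trilineage scorecard: ΔΔCt fold changes and gene-set Z-test scores.

The analysis takes a Ct table (gene x replicate) and a pluripotent reference
panel of per-gene ΔCt values (one per reference cell line):

1. ΔCt(gene, rep) = Ct(gene, rep) - mean Ct of the five housekeeping genes in
   that replicate;
2. ΔΔCt = mean sample ΔCt - reference-panel mean ΔCt; fold change = 2^-ΔΔCt
   (log2 fold change = -ΔΔCt);
3. per gene, a one-sample one-sided t-test of the sample ΔCt replicates
   against the reference mean, alternative "expression increased"
   (ΔCt decreased), gives P_k;
4. per classifier gene set (pluripotency / ectoderm / mesoderm / endoderm),
   the P_k are combined with a correlation-adjusted Stouffer Z:
   Z = sum_k Z_k / sqrt(N + 2 sum_{k<j} r_kj), Z_k = Phi^-1(1 - P_k),
   reported with its upper-tail probability 1 - Phi(Z).  Higher Z means more
   genes in the set significantly up relative to the average pluripotent
   state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_HOUSEKEEPING = ("ACTB-1", "ACTB-2", "CTCF", "EP300", "SMAD1")
GENE_SETS = ("pluripotency", "ectoderm", "mesoderm", "endoderm")

_P_CLIP = 1e-12  # keep Phi^-1 finite


def delta_ct(ct_table: pd.DataFrame, housekeeping=DEFAULT_HOUSEKEEPING) -> pd.DataFrame:
    """Replicate-wise ΔCt relative to the housekeeping-gene mean.

    ``ct_table`` columns: gene, gene_set, replicate, ct.  Returns the same
    shape with a ``delta_ct`` column; housekeeping rows are retained (their
    ΔCt is the deviation from the housekeeping mean).
    """
    hk = ct_table[ct_table["gene"].isin(housekeeping)]
    present = set(hk["gene"])
    missing = set(housekeeping) - present
    if missing:
        raise ValueError(f"missing housekeeping genes: {sorted(missing)}")
    hk_mean = hk.groupby("replicate")["ct"].mean()
    out = ct_table.copy()
    out["delta_ct"] = out["ct"] - out["replicate"].map(hk_mean)
    if out["delta_ct"].isna().any():
        bad = out.loc[out["delta_ct"].isna(), "replicate"].unique()
        raise ValueError(f"replicates without housekeeping coverage: {list(bad)}")
    return out


def fold_change(sample_delta_ct, reference_mean: float) -> tuple[float, float]:
    """(log2 fold change, linear fold change) vs the reference-panel mean.

    ΔΔCt = mean(sample ΔCt) - reference mean; fold change = 2^-ΔΔCt.
    """
    ddct = float(np.mean(np.asarray(sample_delta_ct, dtype=float))) - float(reference_mean)
    return -ddct, 2.0 ** (-ddct)


def gene_pvalue(sample_delta_ct, reference_mean: float) -> float:
    """One-sided, one-sample t-test p-value for increased expression.

    Alternative: sample ΔCt below the reference mean (lower Ct difference =
    higher expression).  Degenerate zero-variance samples collapse to the
    clip values by sign of the mean difference.
    """
    x = np.asarray(sample_delta_ct, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 sample replicates")
    sd = x.std(ddof=1)
    if sd == 0:
        p = _P_CLIP if x.mean() < reference_mean else 1.0 - _P_CLIP
        return p
    t = (x.mean() - float(reference_mean)) / (sd / np.sqrt(x.size))
    p = float(stats.t.cdf(t, df=x.size - 1))
    return float(np.clip(p, _P_CLIP, 1.0 - _P_CLIP))


def combine_zscores(pvalues, correlations=None) -> tuple[float, float]:
    """Correlation-adjusted Stouffer combination of one gene set's p-values.

    Z_k = Phi^-1(1 - P_k); combined Z = sum Z_k / sqrt(N + 2 sum_{k<j} r_kj).
    Returns ``(combined_z, tail_probability)``.  ``correlations`` is an
    N x N matrix of Z-score correlations (independence assumed when omitted).
    """
    p = np.clip(np.asarray(pvalues, dtype=float), _P_CLIP, 1.0 - _P_CLIP)
    n = p.size
    if n < 1:
        raise ValueError("need at least one p-value")
    z = stats.norm.ppf(1.0 - p)
    if correlations is None:
        denom2 = float(n)
    else:
        r = np.asarray(correlations, dtype=float)
        if r.shape != (n, n) or not np.allclose(r, r.T) or np.any(np.abs(r) > 1):
            raise ValueError("correlations must be a symmetric N x N matrix with |r| <= 1")
        denom2 = n + 2.0 * float(np.triu(r, k=1).sum())
    if denom2 <= 0:
        raise ValueError(f"invalid correlation structure: denominator^2 = {denom2}")
    combined = float(z.sum() / np.sqrt(denom2))
    return combined, float(stats.norm.sf(combined))


@dataclass(frozen=True)
class GeneSetScore:
    gene_set: str
    n_genes: int
    combined_z: float
    tail_probability: float


class ScorecardModel:
    """Scorecard analysis of one sample against a pluripotent reference panel.

    Parameters
    ----------
    ct_table : DataFrame
        Columns gene, gene_set, replicate, ct; must include the housekeeping
        genes (gene_set ``"housekeeping"``).
    reference : DataFrame
        Columns gene, line, delta_ct — per-gene reference ΔCt values, one row
        per reference cell line.
    correlations : dict, optional
        Per-gene-set Z correlation matrices (gene order = sorted set genes);
        independence assumed when omitted.
    """

    def __init__(
        self,
        ct_table: pd.DataFrame,
        reference: pd.DataFrame,
        housekeeping=DEFAULT_HOUSEKEEPING,
        correlations: dict | None = None,
    ):
        self.ct_table = ct_table
        self.reference = reference
        self.housekeeping = tuple(housekeeping)
        self.correlations = correlations or {}

    def fit(self) -> "ScorecardResults":
        dct = delta_ct(self.ct_table, self.housekeeping)
        ref_stats = (
            self.reference.groupby("gene")["delta_ct"].agg(["mean", "std", "count"])
        )
        rows = []
        for (gene, gene_set), g in dct.groupby(["gene", "gene_set"], sort=True):
            if gene_set == "housekeeping":
                continue
            if gene not in ref_stats.index:
                raise KeyError(f"gene {gene!r} absent from reference panel")
            if ref_stats.loc[gene, "count"] < 2:
                raise ValueError(f"gene {gene!r}: need >= 2 reference lines")
            ref_mean = float(ref_stats.loc[gene, "mean"])
            x = g["delta_ct"].to_numpy()
            log2fc, fc = fold_change(x, ref_mean)
            p = gene_pvalue(x, ref_mean)
            rows.append(
                {
                    "gene": gene,
                    "gene_set": gene_set,
                    "n_replicates": x.size,
                    "sample_delta_ct": float(x.mean()),
                    "reference_delta_ct": ref_mean,
                    "log2_fold_change": log2fc,
                    "fold_change": fc,
                    "p_value": p,
                    "z": float(stats.norm.ppf(1.0 - p)),
                }
            )
        gene_table = pd.DataFrame(rows)

        scores = []
        for gene_set, g in gene_table.groupby("gene_set", sort=True):
            g = g.sort_values("gene")
            r = self.correlations.get(gene_set)
            z, tail = combine_zscores(g["p_value"].to_numpy(), r)
            scores.append(GeneSetScore(gene_set, len(g), z, tail))
        return ScorecardResults(self, gene_table, scores)


class ScorecardResults:
    def __init__(self, model: ScorecardModel, gene_table: pd.DataFrame, scores):
        self.model = model
        self.gene_table = gene_table
        self.scores = {s.gene_set: s for s in scores}

    def set_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_set": s.gene_set,
                    "n_genes": s.n_genes,
                    "combined_z": s.combined_z,
                    "tail_probability": s.tail_probability,
                }
                for s in self.scores.values()
            ]
        )

    def log2_fold_change(self, gene: str) -> float:
        t = self.gene_table
        return float(t.loc[t["gene"] == gene, "log2_fold_change"].iloc[0])

    def summary(self) -> str:
        lines = ["Scorecard gene-set scores", "-" * 46]
        for s in self.scores.values():
            lines.append(
                f"{s.gene_set:<13s} N={s.n_genes:<3d} Z={s.combined_z:8.3f}"
                f"  tail p={s.tail_probability:.3g}"
            )
        lines.append("")
        top = self.gene_table.reindex(
            self.gene_table["log2_fold_change"].abs().sort_values(ascending=False).index
        ).head(6)
        lines.append("largest fold changes:")
        for r in top.itertuples(index=False):
            lines.append(
                f"  {r.gene:<8s} ({r.gene_set}) log2FC={r.log2_fold_change:+.2f}"
                f"  p={r.p_value:.2g}"
            )
        return "\n".join(lines)
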