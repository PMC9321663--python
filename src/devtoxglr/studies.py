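"""End-to-end simulation studies: the package's own validation experiments.

Each study runs the full pipeline (simulate -> gate -> normalize -> fit ->
call) on seeded synthetic screens at the generator's default settings and
returns the quantities the assay characterization reports: potency-recovery
error, false-hit rate under the null, plate QC metrics, the efficacy cutoff,
and scorecard calibration.  Problem sizes (wells per role, replicates,
numbers of seeds) are arguments with defaults matching a single-chemical
plate; the multi-plate screen study mirrors the 12-plate, 12-technical-
replicate control design of the training screen.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .concresp import ENDPOINTS, SOX17_LOSS, analyze_endpoint, normalize_endpoint
from .gating import compute_plate_thresholds, summarize_wells
from .layouts import make_screen_layout
from .qc import plate_qc
from .scorecard import ScorecardModel, combine_zscores, gene_pvalue
from .simulate import (
    ChemicalEffectSpec,
    SimConfig,
    simulate_ct_panel,
    simulate_screen,
)

__all__ = [
    "single_chemical_screen",
    "recovery_study",
    "null_hit_study",
    "default_screen_qc",
    "scorecard_null_study",
    "endoderm_roundtrip",
]


def single_chemical_screen(
    effect: ChemicalEffectSpec,
    seed: int,
    n_replicate_wells: int = 4,
    control_wells_per_role: int = 12,
    endpoint_id: int = SOX17_LOSS,
):
    """Simulate one plate for one chemical and analyze one endpoint.

    Returns the per-chemical result row (hitc, potencies, winner, coff) from
    :func:`devtoxglr.concresp.analyze_endpoint`.
    """
    layout = make_screen_layout(
        "plate01",
        [effect.chemical_id],
        n_replicate_wells=n_replicate_wells,
        control_wells_per_role=control_wells_per_role,
    )
    cells = simulate_screen([layout], [effect], SimConfig(seed=seed))
    thr = compute_plate_thresholds(cells, layout)
    wells = summarize_wells(cells, thr, layout)
    table, results = analyze_endpoint(wells, endpoint_id, seed=seed)
    return table.iloc[0], results[effect.chemical_id]


def recovery_study(
    n_seeds: int = 50,
    seed: int = 0,
    sox17_top: float = 0.8,
    hill: float = 1.0,
    ga_range: tuple[float, float] = (-1.0, 1.0),
) -> pd.DataFrame:
    """Recover known log10 AC50 values through the full pipeline.

    Each seeded replicate simulates a plate with one SOX17-suppressing
    chemical whose true log10 AC50 is drawn uniformly from ``ga_range``,
    then refits it; returns a DataFrame with true and estimated parameters.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_seeds):
        ga_true = float(rng.uniform(*ga_range))
        effect = ChemicalEffectSpec(
            "chem", sox17_top=sox17_top, sox17_log10_ac50=ga_true, sox17_hill=hill
        )
        row, res = single_chemical_screen(effect, seed=seed + 1000 + i)
        fit = res.winning_fit
        ga_est = fit.params.get("ga", np.nan)
        rows.append(
            {
                "replicate": i,
                "true_ga": ga_true,
                "est_ga": ga_est,
                "abs_error": abs(ga_est - ga_true),
                "hitc": int(row["hitc"]),
                "winner": row["winner"],
            }
        )
    return pd.DataFrame(rows)


def null_hit_study(n_seeds: int = 100, seed: int = 0) -> pd.DataFrame:
    """Hit calls for a chemical with no effect (specificity under the null)."""
    rows = []
    for i in range(n_seeds):
        effect = ChemicalEffectSpec("chem", truth_class="negative")
        row, _ = single_chemical_screen(effect, seed=seed + 5000 + i)
        rows.append({"replicate": i, "hitc": int(row["hitc"]), "winner": row["winner"]})
    return pd.DataFrame(rows)


def default_screen_qc(
    n_plates: int = 12,
    seed: int = 0,
    control_wells_per_role: int = 12,
):
    """QC metrics and efficacy cutoff for a default multi-plate screen.

    Mirrors the training-screen control design (12 plates, 12 technical
    replicates per control).  Returns ``(qc_table, bmad, coff, wells)``.
    """
    effect = ChemicalEffectSpec("chem", truth_class="negative")
    layouts = [
        make_screen_layout(
            f"plate{i + 1:02d}",
            ["chem"],
            n_replicate_wells=1,
            control_wells_per_role=control_wells_per_role,
        )
        for i in range(n_plates)
    ]
    cells = simulate_screen(layouts, [effect], SimConfig(seed=seed))
    thr = compute_plate_thresholds(cells, layouts)
    wells = summarize_wells(cells, thr, layouts)
    qc_table = plate_qc(wells)
    _, bmad, coff = normalize_endpoint(wells, ENDPOINTS[SOX17_LOSS])
    return qc_table, bmad, coff, wells


def scorecard_null_study(
    n_panels: int = 1000,
    seed: int = 0,
    n_genes: int = 5,
    n_replicates: int = 3,
    n_reference_lines: int = 10,
    replicate_sd: float = 0.15,
) -> pd.DataFrame:
    """Combined gene-set tail probabilities with samples drawn at the null.

    Each panel draws per-gene sample replicates from the reference
    distribution (centred on the reference-panel mean with replicate noise)
    and combines the one-sided p-values with the independence Stouffer Z;
    under the null the tail probabilities are uniform on (0, 1).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_panels):
        pvals = []
        for _ in range(n_genes):
            ref_mean = float(rng.normal(10.0, 0.5))
            sample = rng.normal(ref_mean, replicate_sd, n_replicates)
            pvals.append(gene_pvalue(sample, ref_mean))
        z, tail = combine_zscores(pvals)
        rows.append({"panel": i, "combined_z": z, "tail_probability": tail})
    return pd.DataFrame(rows)


def endoderm_roundtrip(seed: int = 0, n_replicates: int = 3):
    """Scorecard analysis of a simulated directed-endoderm panel.

    Returns ``(results, sox17_log2fc, sox17_se)`` where the standard error
    combines sample-replicate and reference-panel uncertainty of the SOX17
    fold-change estimate.
    """
    ct, ref = simulate_ct_panel(
        n_replicates=n_replicates, state="directed_endoderm", config=SimConfig(seed=seed)
    )
    res = ScorecardModel(ct, ref).fit()
    row = res.gene_table.set_index("gene").loc["SOX17"]
    # replicate-wise delta-Ct spread for the s.e. of the fold-change estimate
    from .scorecard import delta_ct as _dct

    d = _dct(ct)
    x = d.loc[d["gene"] == "SOX17", "delta_ct"].to_numpy()
    r = ref.loc[ref["gene"] == "SOX17", "delta_ct"].to_numpy()
    se = float(np.sqrt(x.var(ddof=1) / x.size + r.var(ddof=1) / r.size))
    return res, float(row["log2_fold_change"]), se
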