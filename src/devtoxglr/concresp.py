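"""Concentration-response normalization, curve fitting, and hit calling.

Implements the ToxCast-pipeline-style analysis of well-level screening data:

* responses are normalized to plate solvent controls,
  ``resp = 100 * (rval - bval) / bval`` with ``bval`` the median of the
  plate's DMSO wells, and loss-direction endpoints are sign-inverted so
  that losses read as positive activity;
* the efficacy cutoff is ``coff = 3 * bmad`` where ``bmad`` is the MAD of the
  solvent-control responses pooled across plates for the endpoint;
* each chemical series is fitted by maximum likelihood with three nested
  response models — constant ``f(x) = 0``, Hill
  ``f(x) = tp / (1 + 10^((ga - x) gw))`` and gain-loss
  ``f(x) = tp / [(1 + 10^((ga - x) gw)) (1 + 10^((x - la) lw))]`` with
  ``x = log10(conc uM)`` — under a Student-t (df = 4) error model by default;
  the winner minimizes AIC;
* a series is active (``hitc = 1``) when its maximum per-concentration median
  response reaches the cutoff and the winning model is not the constant;
  potencies are the AC50 (``10^ga``) and the ACC, the lowest concentration at
  which the winning curve crosses the cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .gating import mad

__all__ = [
    "EndpointDef",
    "ENDPOINTS",
    "normalize",
    "baseline_cutoff",
    "hill_curve",
    "gainloss_curve",
    "acc_hill",
    "acc_numeric",
    "CurveFit",
    "ConcentrationResponse",
    "ConcentrationResponseResults",
    "HitResult",
    "call_hit",
    "combined_call",
    "normalize_endpoint",
    "analyze_endpoint",
]


@dataclass(frozen=True)
class EndpointDef:
    """One assay endpoint: which well measure it reads and how to normalize."""

    endpoint_id: int
    name: str
    source_measure: str  # pct_sox17_pos | pct_sox2_pos | pct_bra_pos | cell_count
    direction: str  # "up" | "dn"
    invert: bool
    normalization: str  # "percent_of_solvent" | "raw"


_EP = "CCTE_Deisenroth_DEVTOX_RUES2-GLR_Endo"  # registry endpoint-name stem

#: the six registered assay endpoints (AEIDs 3093-3098)
ENDPOINTS: dict[int, EndpointDef] = {
    e.endpoint_id: e
    for e in (
        EndpointDef(3093, f"{_EP}_Sox17_up", "pct_sox17_pos", "up", False, "percent_of_solvent"),
        EndpointDef(3094, f"{_EP}_Sox17_dn", "pct_sox17_pos", "dn", True, "percent_of_solvent"),
        EndpointDef(3095, f"{_EP}_Sox2_up", "pct_sox2_pos", "up", False, "raw"),
        EndpointDef(3096, f"{_EP}_Bra_up", "pct_bra_pos", "up", False, "raw"),
        EndpointDef(3097, f"{_EP}_CellCount_up", "cell_count", "up", False, "percent_of_solvent"),
        EndpointDef(3098, f"{_EP}_CellCount_dn", "cell_count", "dn", True, "percent_of_solvent"),
    )
}

#: the two endpoints whose joint hit call flags a developmental toxicant
SOX17_LOSS, CELLCOUNT_LOSS = 3094, 3098


def normalize(rval, bval, invert: bool = False):
    """Percent activity relative to the plate solvent-control median.

    ``resp = 100 (rval - bval) / bval``, multiplied by -1 for loss-direction
    endpoints so decreases score as positive activity.
    """
    bval = float(bval)
    if bval <= 0:
        raise ValueError(f"degenerate solvent baseline bval={bval}")
    resp = 100.0 * (np.asarray(rval, dtype=float) - bval) / bval
    return -resp if invert else resp


def baseline_cutoff(solvent_resps, convention: str = "normal") -> tuple[float, float]:
    """(bmad, coff): solvent-response MAD and the 3*bmad efficacy cutoff."""
    x = np.asarray(solvent_resps, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 4:
        raise ValueError(f"need >= 4 solvent-control responses, got {x.size}")
    bmad = mad(x, convention)
    return bmad, 3.0 * bmad


# ---------------------------------------------------------------------------
# response models


def hill_curve(x, tp, ga, gw):
    x = np.asarray(x, dtype=float)
    return tp / (1.0 + 10.0 ** ((ga - x) * gw))


def gainloss_curve(x, tp, ga, gw, la, lw):
    x = np.asarray(x, dtype=float)
    gain = 1.0 / (1.0 + 10.0 ** ((ga - x) * gw))
    loss = 1.0 / (1.0 + 10.0 ** ((x - la) * lw))
    return tp * gain * loss


_MODEL_PARAMS = {
    "constant": (),
    "hill": ("tp", "ga", "gw"),
    "gainloss": ("tp", "ga", "gw", "la", "lw"),
}


def _predict(model: str, x, params: dict):
    if model == "constant":
        return np.zeros_like(np.asarray(x, dtype=float))
    if model == "hill":
        return hill_curve(x, params["tp"], params["ga"], params["gw"])
    if model == "gainloss":
        return gainloss_curve(
            x, params["tp"], params["ga"], params["gw"], params["la"], params["lw"]
        )
    raise ValueError(f"unknown model {model!r}")


@dataclass(frozen=True)
class CurveFit:
    model: str
    params: dict
    sigma: float
    loglik: float
    aic: float
    success: bool = True
    message: str = ""

    @property
    def n_params(self) -> int:
        return len(self.params) + 1  # + error scale

    def predict(self, x):
        return _predict(self.model, x, self.params)


def _loglik(resid, sigma: float, error_model: str) -> float:
    if error_model == "t4":
        return float(np.sum(stats.t.logpdf(resid / sigma, df=4) - math.log(sigma)))
    if error_model == "gaussian":
        return float(np.sum(stats.norm.logpdf(resid, scale=sigma)))
    raise ValueError(f"unknown error model {error_model!r}")


# ---------------------------------------------------------------------------
# potency


def acc_hill(tp: float, ga: float, gw: float, coff: float) -> float | None:
    """Closed-form ACC (uM) for a Hill curve: lowest conc with f = coff."""
    if coff <= 0 or tp <= coff:
        return None
    return 10.0 ** (ga - math.log10(tp / coff - 1.0) / gw)


def acc_numeric(curve, coff: float, x_lo: float, x_hi: float, n_grid: int = 400) -> float | None:
    """Lowest log-conc root of ``curve(x) = coff`` on [x_lo, x_hi], in uM.

    Grid scan for the first upward crossing followed by Brent root polishing;
    independent of the closed form and valid for non-monotone (gain-loss)
    curves.
    """
    xs = np.linspace(x_lo, x_hi, n_grid)
    ys = np.asarray(curve(xs), dtype=float) - coff
    if ys[0] >= 0:  # already above cutoff at the low end
        return 10.0 ** xs[0]
    idx = np.nonzero((ys[:-1] < 0) & (ys[1:] >= 0))[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    root = optimize.brentq(lambda x: float(curve(x)) - coff, xs[i], xs[i + 1])
    return 10.0 ** root


# ---------------------------------------------------------------------------
# hit result


@dataclass(frozen=True)
class HitResult:
    hitc: int
    acc_uM: float | None
    ac50_uM: float | None
    pct_max_inhibition: float
    effect_band: str
    winner: str
    max_med: float
    coff: float
    flags: tuple = ()


def _effect_band(pct: float) -> str:
    p = min(max(float(pct), 0.0), 100.0)
    if p < 20.0:
        return "weak"
    if p < 80.0:
        return "moderate"
    return "high"


def call_hit(log10_conc, resp, fits: dict, winner: str, coff: float) -> HitResult:
    """Hit call and potencies for a fitted series.

    Active iff the maximum per-concentration median response reaches ``coff``
    and the winning model is not the constant.  ACC is the lowest
    concentration where the winning curve crosses the cutoff (closed form for
    Hill, numeric root for gain-loss); AC50 is ``10^ga``.
    """
    x = np.asarray(log10_conc, dtype=float)
    r = np.asarray(resp, dtype=float)
    med = pd.Series(r).groupby(pd.Series(x)).median()
    max_med = float(med.max())
    flags = []

    active = max_med >= coff and winner != "constant"
    acc = ac50 = None
    if active:
        fit = fits[winner]
        p = fit.params
        ac50 = 10.0 ** p["ga"]
        if winner == "hill":
            acc = acc_hill(p["tp"], p["ga"], p["gw"], coff)
        else:
            acc = acc_numeric(fit.predict, coff, x.min() - 3.0, x.max() + 3.0)
        if acc is None:
            flags.append("cutoff_above_top")  # tp <= coff yet medians reached it
        elif acc < 10.0 ** x.min():
            flags.append("extrapolated_acc")
        if abs(max_med - coff) < 0.1 * coff:
            flags.append("borderline_hit")
        if int((med.to_numpy() >= coff).sum()) == 1:
            flags.append("single_point_driver")

    return HitResult(
        hitc=int(active),
        acc_uM=acc,
        ac50_uM=ac50,
        pct_max_inhibition=max_med,
        effect_band=_effect_band(max_med),
        winner=winner,
        max_med=max_med,
        coff=float(coff),
        flags=tuple(flags),
    )


def combined_call(sox17_hit: HitResult, cellcount_hit: HitResult) -> bool:
    """Developmental-toxicity call combining SOX17 loss with cell-count loss.

    Positive when either the SOX17-loss endpoint or the cell-count-loss
    endpoint is active; raises sensitivity to chemicals that kill cells
    without perturbing the surviving SOX17-positive fraction.
    """
    return bool(sox17_hit.hitc or cellcount_hit.hitc)


# ---------------------------------------------------------------------------
# the model / results pair


class ConcentrationResponse:
    """Concentration-response model for one chemical x endpoint series.

    Parameters
    ----------
    conc_uM : array-like
        Test concentrations in uM (replicates repeated).
    resp : array-like
        Normalized responses (% activity), same length.
    coff : float, optional
        Efficacy cutoff; required for a hit call at ``fit()``.
    error_model : {"t4", "gaussian"}
        Residual distribution for maximum likelihood; the heavy-tailed
        Student-t (df = 4) downweights single-well outliers.
    """

    def __init__(self, conc_uM, resp, coff: float | None = None, error_model: str = "t4"):
        conc = np.asarray(conc_uM, dtype=float)
        resp = np.asarray(resp, dtype=float)
        ok = np.isfinite(conc) & np.isfinite(resp)
        conc, resp = conc[ok], resp[ok]
        if conc.size != resp.size or conc.size == 0:
            raise ValueError("conc_uM and resp must be equal-length, non-empty")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.unique(conc).size < 4:
            raise ValueError("need >= 4 distinct concentrations")
        self.log10_conc = np.log10(conc)
        self.resp = resp
        self.coff = coff
        self.error_model = error_model

    @classmethod
    def from_points(cls, points: pd.DataFrame, coff: float | None = None, **kw):
        """Build from a tidy DataFrame with columns ``conc_uM`` and ``resp``."""
        return cls(points["conc_uM"], points["resp"], coff=coff, **kw)

    # -- fitting -----------------------------------------------------------

    def _bounds(self, model: str):
        x, r = self.log10_conc, self.resp
        rmax = max(float(np.max(np.abs(r))), 1.0)
        sig_lo, sig_hi = math.log(1e-3 * rmax), math.log(10.0 * rmax)
        b = {
            "tp": (0.0, 1.2 * rmax),
            "ga": (x.min() - 1.0, x.max() + 1.0),
            "gw": (0.3, 8.0),
            "la": (x.min() - 1.0, x.max() + 2.0),
            "lw": (0.3, 8.0),
        }
        return [b[p] for p in _MODEL_PARAMS[model]] + [(sig_lo, sig_hi)]

    def _starts(self, model: str, n_starts: int, seed: int):
        x, r = self.log10_conc, self.resp
        med = pd.Series(r).groupby(pd.Series(x)).median()
        tp0 = max(float(med.max()), 1e-3)
        half = tp0 / 2.0
        above = med[med >= half]
        ga0 = float(above.index.min()) if len(above) else float(x.mean())
        sig0 = math.log(max(float(mad(r, "normal")), 1e-2))
        base = {
            "constant": [sig0],
            "hill": [tp0, ga0, 1.2, sig0],
            "gainloss": [tp0, ga0, 1.2, min(ga0 + 2.0, x.max() + 1.0), 1.2, sig0],
        }[model]
        starts = [np.array(base, dtype=float)]
        rng = np.random.default_rng(seed)
        bounds = self._bounds(model)
        for _ in range(n_starts - 1):
            jit = np.array(
                [rng.uniform(lo, hi) for lo, hi in bounds[:-1]] + [base[-1]]
            )
            starts.append(jit)
        return starts

    def _fit_one(self, model: str, n_starts: int, seed: int) -> CurveFit:
        x, r = self.log10_conc, self.resp
        names = _MODEL_PARAMS[model]

        def nll(theta):
            params = dict(zip(names, theta[:-1]))
            sigma = math.exp(theta[-1])
            resid = r - _predict(model, x, params)
            return -_loglik(resid, sigma, self.error_model)

        bounds = self._bounds(model)
        best = None
        for theta0 in self._starts(model, n_starts, seed):
            theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])
            res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds)
            if not np.isfinite(res.fun):
                continue
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            return CurveFit(model, {}, np.nan, -np.inf, np.inf, False, "optimizer failed")
        params = dict(zip(names, (float(v) for v in best.x[:-1])))
        sigma = math.exp(float(best.x[-1]))
        ll = -float(best.fun)
        k = len(names) + 1
        return CurveFit(model, params, sigma, ll, 2.0 * k - 2.0 * ll, True, str(best.message))

    def fit(
        self,
        models=("constant", "hill", "gainloss"),
        n_starts: int = 3,
        seed: int = 0,
    ) -> "ConcentrationResponseResults":
        fits = {}
        for m in models:
            f = self._fit_one(m, n_starts, seed)
            if f.success:
                fits[m] = f
        if not fits:
            raise RuntimeError("all response models failed to fit")
        order = {"constant": 0, "hill": 1, "gainloss": 2}
        winner = min(fits.values(), key=lambda f: (f.aic, order[f.model])).model
        hit = None
        if self.coff is not None:
            hit = call_hit(self.log10_conc, self.resp, fits, winner, self.coff)
        return ConcentrationResponseResults(self, fits, winner, hit)


class ConcentrationResponseResults:
    """Fitted curves, AIC model selection, and (optionally) the hit call."""

    def __init__(self, model: ConcentrationResponse, fits: dict, winner: str, hit):
        self.model = model
        self.fits = fits
        self.winner = winner
        self.hit = hit

    @property
    def winning_fit(self) -> CurveFit:
        return self.fits[self.winner]

    def predict(self, conc_uM, model: str | None = None):
        """Winning-curve response at the given concentrations (uM)."""
        fit = self.fits[model or self.winner]
        return fit.predict(np.log10(np.asarray(conc_uM, dtype=float)))

    def aic_table(self) -> pd.DataFrame:
        rows = [
            {
                "model": f.model,
                "n_params": f.n_params,
                "loglik": f.loglik,
                "aic": f.aic,
                "winner": f.model == self.winner,
            }
            for f in self.fits.values()
        ]
        return pd.DataFrame(rows).sort_values("aic", ignore_index=True)

    def summary(self) -> str:
        lines = ["Concentration-response fit", "-" * 42]
        n = self.model.resp.size
        ncon = np.unique(self.model.log10_conc).size
        lines.append(f"points: {n}  concentrations: {ncon}  error model: {self.model.error_model}")
        for f in sorted(self.fits.values(), key=lambda f: f.aic):
            mark = "*" if f.model == self.winner else " "
            pstr = ", ".join(f"{k}={v:.4g}" for k, v in f.params.items())
            lines.append(f"{mark} {f.model:<9s} AIC={f.aic:9.2f}  {pstr}")
        if self.hit is not None:
            h = self.hit
            lines.append(
                f"hitc={h.hitc}  coff={h.coff:.3g}  max_med={h.max_med:.3g}  band={h.effect_band}"
            )
            if h.hitc:
                acc = f"{h.acc_uM:.4g}" if h.acc_uM is not None else "NA"
                lines.append(f"ACC={acc} uM  AC50={h.ac50_uM:.4g} uM  flags={list(h.flags)}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Points, per-model curves and the cutoff band (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, r = self.model.log10_conc, self.model.resp
        ax.scatter(x, r, s=12, color="k", zorder=3)
        xs = np.linspace(x.min() - 0.5, x.max() + 0.5, 200)
        colors = {"constant": "gold", "hill": "darkorange", "gainloss": "steelblue"}
        for m, f in self.fits.items():
            lw = 2.2 if m == self.winner else 1.0
            ax.plot(xs, f.predict(xs), color=colors.get(m, "gray"), lw=lw, label=m)
        if self.model.coff is not None:
            ax.axhspan(-self.model.coff, self.model.coff, color="gray", alpha=0.2)
        ax.set_xlabel("log10 concentration (uM)")
        ax.set_ylabel("response (% activity)")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# screen-level orchestration


def normalize_endpoint(
    wells: pd.DataFrame, endpoint: EndpointDef, convention: str = "normal"
):
    """Normalize one endpoint across a well-level table.

    Returns ``(points, bmad, coff)`` where ``points`` holds the treatment-well
    responses (chemical_id, conc_uM, plate, well, resp) and the cutoff comes
    from the solvent-control responses pooled across plates.  For endpoints
    with ``normalization="raw"`` the response is the raw measure centred at
    the plate solvent median (difference, not percent change).
    """
    measure = endpoint.source_measure
    solvent_resps, frames = [], []
    for plate, pw in wells.groupby("plate", sort=True):
        sol = pw.loc[pw["role"] == "solvent_control", measure].dropna()
        if len(sol) == 0:
            raise ValueError(f"plate {plate!r} has no solvent-control wells")
        bval = float(sol.median())
        sub = pw[pw["role"].isin(["treatment", "solvent_control"])].copy()
        rval = sub[measure].astype(float)
        if endpoint.normalization == "percent_of_solvent":
            sub["resp"] = normalize(rval, bval, endpoint.invert)
        elif endpoint.normalization == "raw":
            resp = rval - bval
            sub["resp"] = -resp if endpoint.invert else resp
        else:
            raise ValueError(f"unknown normalization {endpoint.normalization!r}")
        solvent_resps.extend(sub.loc[sub["role"] == "solvent_control", "resp"])
        frames.append(sub[sub["role"] == "treatment"])
    points = pd.concat(frames, ignore_index=True)[
        ["plate", "well", "chemical_id", "conc_uM", "resp"]
    ]
    bmad, coff = baseline_cutoff(solvent_resps)
    return points, bmad, coff


def analyze_endpoint(
    wells: pd.DataFrame,
    endpoint: EndpointDef | int,
    error_model: str = "t4",
    convention: str = "normal",
    seed: int = 0,
):
    """Fit and hit-call every chemical for one endpoint.

    Returns ``(table, results)``: a per-chemical DataFrame (endpoint_id,
    chemical_id, hitc, acc_uM, ac50_uM, pct_max_inhibition, effect_band,
    winner, coff, flags) and the dict of ConcentrationResponseResults.
    """
    if isinstance(endpoint, int):
        endpoint = ENDPOINTS[endpoint]
    points, bmad, coff = normalize_endpoint(wells, endpoint, convention)
    rows, results = [], {}
    for chem, g in points.groupby("chemical_id", sort=True):
        cr = ConcentrationResponse(
            g["conc_uM"], g["resp"], coff=coff, error_model=error_model
        )
        res = cr.fit(seed=seed)
        results[chem] = res
        h = res.hit
        rows.append(
            {
                "endpoint_id": endpoint.endpoint_id,
                "endpoint": endpoint.name,
                "chemical_id": chem,
                "hitc": h.hitc,
                "acc_uM": h.acc_uM,
                "ac50_uM": h.ac50_uM,
                "pct_max_inhibition": h.pct_max_inhibition,
                "effect_band": h.effect_band,
                "winner": h.winner,
                "bmad": bmad,
                "coff": coff,
                "flags": ";".join(h.flags),
            }
        )
    return pd.DataFrame(rows), results
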