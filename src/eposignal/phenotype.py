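"""Linking signaling integrals to cell-cycle progression and proliferation.

The chain has two regression stages downstream of the kinetic model:

1. signaling -> cell cycle:  log CCI regressed on the 1-h integrated pAKT
   and ppERK responses, where the cell cycle indicator
   ``CCI = fc_cyclinD2 / (fc_cyclinG2 * fc_p27)`` condenses the fold changes
   of one activator and two repressors of G1->S progression into a single
   early readout.
2. (CCI, integrated pS6) -> proliferation:  ordinary least squares for the
   candidate predictor sets {pS6 only, CCI only, pS6 + CCI}; the best model
   is selected by Akaike's information criterion.  Fast-cycling cells are
   expected to be growth-limited (pS6-only), slower-cycling cells
   cycle-limited (CCI-only).

Dose-response curves are summarized with a four-parameter Hill regression
``y = y0 + a*x^b / (c^b + x^b)`` (EC50 = c) and growth curves with an
exponential fit (doubling time = ln 2 / slope of log counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit

from .calibration import perturbation_id
from .network import (
    ModelInstance,
    Perturbation,
    apply_perturbation,
    simulate,
)
from .sensitivity import integrated_response_from_points

__all__ = [
    "CellCycleMeasurement",
    "LinkModel",
    "HillFit",
    "DoublingTimeFit",
    "ProliferationPipeline",
    "cell_cycle_indicator",
    "fit_signaling_to_cci",
    "select_proliferation_model",
    "predict_proliferation",
    "fit_hill",
    "fit_doubling_time",
]


@dataclass(frozen=True)
class CellCycleMeasurement:
    """qPCR fold changes (relative to unstimulated) of the three cell-cycle
    genes, plus condition metadata."""

    fc_ccnd2: float
    fc_ccng2: float
    fc_cdkn1b: float
    context_name: str = ""
    epo_dose: float = float("nan")
    perturbation_id: str = "none"

    def __post_init__(self):
        for v in (self.fc_ccnd2, self.fc_ccng2, self.fc_cdkn1b):
            if not v > 0:
                raise ValueError("fold changes must be > 0")


def cell_cycle_indicator(m: CellCycleMeasurement | tuple) -> float:
    """CCI = fc_cyclinD2 / (fc_cyclinG2 * fc_p27); equals 1 at baseline."""
    if isinstance(m, tuple):
        m = CellCycleMeasurement(*m)
    return m.fc_ccnd2 / (m.fc_ccng2 * m.fc_cdkn1b)


@dataclass
class LinkModel:
    """A fitted linear link (one regression stage)."""

    stage: str  # "signaling_to_cci" | "proliferation"
    predictors: list[str]
    coefficients: dict[str, float]  # includes "intercept"
    r_squared: float
    aic: float
    n_obs: int
    cell_type: str | None = None
    response_scale: str = "linear"  # "log" for log-CCI links
    degenerate: bool = False
    notes: list[str] = field(default_factory=list)

    def predict(self, X: pd.DataFrame | dict) -> np.ndarray:
        X = pd.DataFrame(X)
        eta = np.full(len(X), self.coefficients["intercept"], dtype=float)
        for p in self.predictors:
            eta = eta + self.coefficients[p] * X[p].to_numpy(float)
        return np.exp(eta) if self.response_scale == "log" else eta


def _ols_link(stage, X, y, predictors, cell_type, response_scale):
    design = sm.add_constant(X[predictors], has_constant="add")
    notes = []
    rank = np.linalg.matrix_rank(design.to_numpy())
    degenerate = rank < design.shape[1]
    if degenerate:
        notes.append("rank-deficient design")
    res = sm.OLS(y, design).fit()
    coef = {"intercept": float(res.params.get("const", 0.0))}
    for p in predictors:
        coef[p] = float(res.params.get(p, 0.0))
    return LinkModel(
        stage=stage,
        predictors=list(predictors),
        coefficients=coef,
        r_squared=float(res.rsquared),
        aic=float(res.aic),
        n_obs=int(res.nobs),
        cell_type=cell_type,
        response_scale=response_scale,
        degenerate=degenerate,
        notes=notes,
    )


def fit_signaling_to_cci(
    data: pd.DataFrame,
    per_cell_type: bool = True,
    log_cci: bool = True,
) -> dict[str, LinkModel] | LinkModel:
    """Stage-1 link: regress (log) CCI on integrated pAKT and ppERK.

    ``data`` needs columns ``context, I_pAKT, I_ppERK, cci``.  CCI is a ratio
    statistic and multiplicative by construction, so the default response is
    log(CCI); the raw scale is available via ``log_cci=False``.
    """
    required = {"context", "I_pAKT", "I_ppERK", "cci"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    if (data["cci"] <= 0).any():
        raise ValueError("cci must be > 0")
    scale = "log" if log_cci else "linear"

    def fit_group(sub: pd.DataFrame, name: str | None) -> LinkModel:
        if len(sub) < 3:
            raise ValueError(
                f"need >= 3 conditions per fitted group (got {len(sub)})"
            )
        y = np.log(sub["cci"].to_numpy(float)) if log_cci \
            else sub["cci"].to_numpy(float)
        return _ols_link("signaling_to_cci", sub, y, ["I_pAKT", "I_ppERK"],
                         name, scale)

    if per_cell_type:
        return {name: fit_group(sub, name)
                for name, sub in data.groupby("context", sort=True)}
    return fit_group(data, None)


#: Candidate predictor sets for the proliferation stage.
PROLIFERATION_CANDIDATES = {
    "pS6-only": ["I_pS6"],
    "CCI-only": ["cci"],
    "pS6+CCI": ["I_pS6", "cci"],
}


def select_proliferation_model(
    data: pd.DataFrame,
    cell_type: str | None = None,
    candidates: dict[str, list[str]] | None = None,
    use_aicc: bool = False,
) -> tuple[LinkModel, pd.DataFrame]:
    """Stage-2 link with AIC model selection.

    ``data`` needs columns ``I_pS6, cci, proliferation``.  Returns the
    minimum-AIC :class:`LinkModel` and a delta-AIC table; candidates within
    delta AIC < 2 of the best are flagged as statistically indistinguishable
    and ties are broken toward the model with fewest parameters.
    """
    candidates = PROLIFERATION_CANDIDATES if candidates is None else candidates
    y = data["proliferation"].to_numpy(float)
    fits, rows = {}, []
    for name, preds in candidates.items():
        k = len(preds) + 2  # coefficients + intercept + error variance
        if len(data) <= k - 1:
            rows.append(dict(candidate=name, aic=np.nan, r_squared=np.nan,
                             n_params=k, excluded="fewer observations than "
                             "parameters"))
            continue
        lm = _ols_link("proliferation", data, y, preds, cell_type, "linear")
        if use_aicc:
            n = lm.n_obs
            lm.aic = lm.aic + 2 * k * (k + 1) / max(n - k - 1, 1)
        fits[name] = lm
        rows.append(dict(candidate=name, aic=lm.aic, r_squared=lm.r_squared,
                         n_params=k, excluded=""))
    if not fits:
        raise ValueError("no candidate had enough observations")
    table = pd.DataFrame(rows)
    best_aic = table["aic"].min()
    table["delta_aic"] = table["aic"] - best_aic
    table["indistinguishable"] = table["delta_aic"] < 2.0
    # deterministic tie-break: among delta-AIC ties (< 1e-9), fewest params
    tied = table[np.isclose(table["aic"], best_aic, rtol=0, atol=1e-9)]
    pick = tied.sort_values(["n_params", "candidate"]).iloc[0]["candidate"]
    return fits[pick], table.drop(columns=[]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# End-to-end prediction chain
# ---------------------------------------------------------------------------

@dataclass
class ProliferationPipeline:
    """Calibrated signaling instances plus the two fitted link stages.

    ``instances`` maps cell-type name to a base (unperturbed) model instance
    with observable scales and inhibitor strengths already attached.
    """

    instances: dict[str, ModelInstance]
    stage1: dict[str, LinkModel]
    stage2: dict[str, LinkModel]
    t_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 60.0, 61))

    def integrals(
        self,
        cell_type: str,
        epo_dose: float,
        perturbations: list[Perturbation] = (),
    ) -> dict[str, float]:
        inst = self.instances[cell_type]
        if perturbations:
            inst = apply_perturbation(inst, list(perturbations))
        traj = simulate(inst, epo_dose, self.t_grid)
        out = {}
        for obs in ("pAKT", "ppERK", "pS6"):
            out["I_" + obs] = integrated_response_from_points(
                self.t_grid, traj.observables[obs], 0.0, 60.0)
        return out

    def predict_raw(self, cell_type, epo_dose, perturbations=()):
        if cell_type not in self.stage1 or cell_type not in self.stage2:
            raise ValueError(
                f"link stages not fitted for cell type {cell_type!r}"
            )
        ints = self.integrals(cell_type, epo_dose, perturbations)
        cci = float(self.stage1[cell_type].predict(
            {"I_pAKT": [ints["I_pAKT"]], "I_ppERK": [ints["I_ppERK"]]})[0])
        prolif = float(self.stage2[cell_type].predict(
            {"I_pS6": [ints["I_pS6"]], "cci": [cci]})[0])
        return dict(cci=cci, proliferation=prolif, **ints)


def predict_proliferation(
    pipeline: ProliferationPipeline,
    cell_type: str,
    epo_dose: float,
    perturbations: list[Perturbation] = (),
    reference_dose: float | None = None,
    floor: float | None = None,
) -> float:
    """Scaled proliferation prediction for one condition.

    The chain is simulate -> integrate pAKT/ppERK/pS6 over 1 h -> CCI via the
    stage-1 link -> proliferation via the selected stage-2 link, divided by
    the unperturbed Epo-only prediction (at ``reference_dose``, default the
    same dose) so that the unperturbed condition equals 1.

    A linear link extrapolated to strongly inhibited conditions can fall
    below zero; the optional ``floor`` clips the scaled prediction (off by
    default -- the unclipped behaviour mirrors the elevated-baseline
    mismatch of purely linear phenotype links).
    """
    ref_dose = epo_dose if reference_dose is None else reference_dose
    raw = pipeline.predict_raw(cell_type, epo_dose, perturbations)
    ref = pipeline.predict_raw(cell_type, ref_dose, ())
    if ref["proliferation"] == 0:
        raise ZeroDivisionError("reference proliferation is 0")
    value = raw["proliferation"] / ref["proliferation"]
    if floor is not None:
        value = max(value, floor)
    return value


# ---------------------------------------------------------------------------
# Dose-response and growth-curve summaries
# ---------------------------------------------------------------------------

@dataclass
class HillFit:
    """Four-parameter Hill regression y = y0 + a*x^b / (c^b + x^b)."""

    y0: float
    a: float
    b: float
    c: float  # EC50
    c_stderr: float
    degenerate: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def ec50(self) -> float:
        return self.c

    def predict(self, x):
        x = np.asarray(x, float)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(x > 0, x**self.b / (self.c**self.b + x**self.b), 0.0)
        return self.y0 + self.a * h


def fit_hill(dose: np.ndarray, response: np.ndarray) -> HillFit:
    """Nonlinear least squares for the 4-parameter Hill curve.

    Multi-start over a small deterministic grid of initial EC50 and slope
    guesses; the reported EC50 standard error comes from the fit covariance.
    A flat response is returned as a degenerate fit (a ~ 0, EC50
    unidentifiable) rather than an error.
    """
    x = np.asarray(dose, float)
    y = np.asarray(response, float)
    if len(x) < 5:
        raise ValueError("need at least 5 dose points")
    if np.any(x < 0):
        raise ValueError("doses must be >= 0")

    y_span = float(np.ptp(y))
    y_scale = max(abs(y).max(), 1.0)
    if y_span < 1e-12 * y_scale:
        return HillFit(y0=float(np.mean(y)), a=0.0, b=1.0,
                       c=float(np.median(x[x > 0]) if np.any(x > 0) else 1.0),
                       c_stderr=np.inf, degenerate=True,
                       notes=["flat response; EC50 unidentifiable"])

    def model(x, y0, a, b, c):
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(x > 0, x**b / (c**b + x**b), 0.0)
        return y0 + a * h

    pos = np.sort(np.unique(x[x > 0]))
    c_guesses = [pos[len(pos) // 2]] + list(pos[[0, -1]])
    best = None
    trace = []
    for c0 in c_guesses:
        for b0 in (0.5, 1.0, 2.0):
            p0 = [float(y.min()), y_span, b0, float(c0)]
            try:
                popt, pcov = curve_fit(
                    model, x, y, p0=p0, maxfev=20000,
                    bounds=([-np.inf, -np.inf, 1e-3, 1e-9],
                            [np.inf, np.inf, 50.0, np.inf]))
            except Exception as exc:
                trace.append((p0, str(exc)))
                continue
            rss = float(np.sum((y - model(x, *popt)) ** 2))
            if best is None or rss < best[0]:
                best = (rss, popt, pcov)
    if best is None:
        raise RuntimeError(f"Hill fit did not converge; initials tried: {trace}")
    _, popt, pcov = best
    y0_, a_, b_, c_ = (float(v) for v in popt)
    c_se = float(np.sqrt(pcov[3, 3])) if np.all(np.isfinite(pcov)) else np.inf
    degenerate = abs(a_) < 1e-6 * y_scale
    notes = ["amplitude ~ 0; EC50 unidentifiable"] if degenerate else []
    return HillFit(y0=y0_, a=a_, b=b_, c=c_, c_stderr=c_se,
                   degenerate=degenerate, notes=notes)


@dataclass
class DoublingTimeFit:
    """Exponential growth regression on log counts."""

    doubling_time_h: float  # inf when no growth
    rate_per_h: float
    r_squared: float
    no_growth: bool
    negative_growth: bool


def fit_doubling_time(time_h: np.ndarray, counts: np.ndarray) -> DoublingTimeFit:
    """Doubling time from exponential regression: ln2 / slope of log counts."""
    t = np.asarray(time_h, float)
    c = np.asarray(counts, float)
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    if np.any(c <= 0):
        raise ValueError("counts must be > 0")
    res = sm.OLS(np.log(c), sm.add_constant(t)).fit()
    slope = float(res.params[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = float(res.rsquared)
    if slope <= 0:
        return DoublingTimeFit(
            doubling_time_h=math.inf, rate_per_h=slope, r_squared=r2,
            no_growth=True, negative_growth=slope < 0)
    return DoublingTimeFit(
        doubling_time_h=math.log(2) / slope, rate_per_h=slope, r_squared=r2,
        no_growth=False, negative_growth=False)
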