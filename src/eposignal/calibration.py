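"""Parameter estimation and identifiability analysis.

Fitting minimizes the weighted residual sum of squares (equivalently
-2 log-likelihood up to a constant for Gaussian errors)

    chi^2(theta) = sum_i [(y_i - s_i * yhat_i(theta)) / sigma_i]^2

with measurement standard deviations from the blot error model: 10% relative
error plus 5% absolute error of the highest data point under the condition.
Parameters are estimated on log10 scale with a deterministic derivative-based
local optimizer started from Latin hypercube samples; identifiability is
assessed by the profile likelihood with the pointwise 95% chi-square
threshold (3.84, one degree of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .network import (
    IntegrationError,
    ModelInstance,
    Perturbation,
    SignalingModel,
    apply_cell_context,
    apply_perturbation,
    simulate,
)
from .contexts import CellTypeContext

__all__ = [
    "Observation",
    "ExperimentDataset",
    "FitResult",
    "ProfileResult",
    "Anchor",
    "DEFAULT_ANCHORS",
    "PL_THRESHOLD_95",
    "sigma_error_model",
    "objective",
    "fit_multistart",
    "profile_likelihood",
    "anchor_scalings",
    "ConditionSimulator",
    "parse_perturbation_id",
    "perturbation_id",
]

#: chi-square(df=1) quantile for pointwise 95% profile-likelihood intervals.
PL_THRESHOLD_95 = 3.84

#: Penalty residual used when a simulation fails inside the optimizer.
_FAIL_RESIDUAL = 1e6

DATASET_COLUMNS = ["context", "epo_Uml", "perturbation_id", "time_min",
                   "observable", "value_nM", "sigma_nM"]


def sigma_error_model(y: float, y_max_condition: float) -> float:
    """Measurement standard deviation: 0.10*y + 0.05*max-under-condition.

    ``y_max_condition`` is the highest data point within the condition group
    (same cell type, observable, and perturbation), which sets the absolute
    error floor of a blot.
    """
    y = float(y)
    y_max = float(y_max_condition)
    if y < 0 or y_max < y:
        raise ValueError("need 0 <= y <= y_max_condition")
    if y_max == 0:
        raise ValueError(
            "condition group has no signal (y_max = 0); sigma undefined"
        )
    return 0.10 * y + 0.05 * y_max


@dataclass(frozen=True)
class Observation:
    """A single measured phospho-observable value with its uncertainty."""

    context_name: str
    epo_dose: float
    perturbation_id: str
    time: float
    observable: str
    value: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.time < 0:
            raise ValueError("time must be >= 0 min")


class ExperimentDataset:
    """Tidy table of observations with design metadata.

    Thin wrapper around a DataFrame with the canonical columns
    ``context, epo_Uml, perturbation_id, time_min, observable, value_nM,
    sigma_nM``.  Condition groups (the sigma-normalization unit) are keyed by
    (context, observable, perturbation_id).
    """

    def __init__(self, df: pd.DataFrame, design: dict | None = None):
        missing = [c for c in DATASET_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        if (df["sigma_nM"] <= 0).any():
            raise ValueError("all sigma_nM must be > 0")
        if (df["time_min"] < 0).any():
            raise ValueError("all time_min must be >= 0")
        counts = df.groupby(
            ["context", "epo_Uml", "perturbation_id", "observable"]
        )["time_min"].nunique()
        if (counts < 2).any():
            bad = counts[counts < 2].index[0]
            raise ValueError(f"condition {bad} has fewer than 2 time points")
        self.df = df.reset_index(drop=True)
        self.design = design or {}

    def __len__(self) -> int:
        return len(self.df)

    @property
    def values(self) -> np.ndarray:
        return self.df["value_nM"].to_numpy(float)

    @property
    def sigmas(self) -> np.ndarray:
        return self.df["sigma_nM"].to_numpy(float)

    @property
    def observations(self) -> list[Observation]:
        return [
            Observation(r.context, r.epo_Uml, r.perturbation_id, r.time_min,
                        r.observable, r.value_nM, r.sigma_nM)
            for r in self.df.itertuples()
        ]

    def conditions(self) -> pd.DataFrame:
        """Unique (context, epo_Uml, perturbation_id) combinations."""
        return (self.df[["context", "epo_Uml", "perturbation_id"]]
                .drop_duplicates().reset_index(drop=True))

    @staticmethod
    def assign_sigmas(df: pd.DataFrame) -> pd.DataFrame:
        """Fill ``sigma_nM`` from the error model, per condition group."""
        df = df.copy()
        group_key = ["context", "observable", "perturbation_id"]
        y_max = df.groupby(group_key)["value_nM"].transform(
            lambda v: np.max(np.abs(v))
        )
        if (y_max == 0).any():
            bad = df.loc[y_max == 0, group_key].iloc[0].tolist()
            raise ValueError(f"condition group {bad} has y_max = 0")
        df["sigma_nM"] = 0.10 * np.abs(df["value_nM"]) + 0.05 * y_max
        return df


# ---------------------------------------------------------------------------
# Perturbation-id encoding (shared with the synthetic-data generator)
# ---------------------------------------------------------------------------

def perturbation_id(perturbations: list[Perturbation]) -> str:
    """Canonical string id, e.g. ``"AKTVIII=0.5"`` or ``"oe:PTEN=4"``."""
    if not perturbations:
        return "none"
    toks = []
    for p in sorted(perturbations, key=lambda p: (p.kind, p.agent)):
        prefix = {"inhibitor": "", "overexpression": "oe:",
                  "knockdown": "kd:"}[p.kind]
        toks.append(f"{prefix}{p.agent}={p.dose:g}")
    return "+".join(toks)


def parse_perturbation_id(pid: str) -> list[Perturbation]:
    if pid in ("", "none"):
        return []
    out = []
    for tok in pid.split("+"):
        if tok.startswith("oe:"):
            kind, tok = "overexpression", tok[3:]
        elif tok.startswith("kd:"):
            kind, tok = "knockdown", tok[3:]
        else:
            kind = "inhibitor"
        agent, dose = tok.split("=")
        out.append(Perturbation(kind, agent, float(dose)))
    return out


# ---------------------------------------------------------------------------
# Objective and fitting (generic over a predictor callable)
# ---------------------------------------------------------------------------

def _as_y_sigma(dataset) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(dataset, ExperimentDataset):
        return dataset.values, dataset.sigmas
    y, sigma = dataset
    return np.asarray(y, float), np.asarray(sigma, float)


def _residuals(predict, dataset, theta, scalings=None) -> np.ndarray:
    y, sigma = _as_y_sigma(dataset)
    try:
        with np.errstate(all="ignore"):
            yhat = np.asarray(predict(np.asarray(theta, float)), float)
    except IntegrationError:
        return np.full(y.shape, _FAIL_RESIDUAL)
    if scalings is not None:
        yhat = yhat * np.asarray(scalings, float)
    if yhat.shape != y.shape:
        raise ValueError("predictor output does not align with dataset")
    if not np.all(np.isfinite(yhat)):
        return np.full(y.shape, _FAIL_RESIDUAL)
    return (y - yhat) / sigma


def objective(predict, dataset, theta, scalings=None) -> float:
    """Weighted residual sum of squares for a predictor at ``theta``.

    ``predict`` maps a parameter vector to predictions aligned with the
    dataset rows; ``dataset`` is an :class:`ExperimentDataset` or a
    ``(values, sigmas)`` pair.  Simulation failures return a large penalty
    instead of raising, so the optimizer can move away from bad regions.
    """
    r = _residuals(predict, dataset, theta, scalings)
    return float(np.dot(r, r))


@dataclass
class FitResult:
    """Best parameter vector over all starts, with the per-start trace."""

    parameter_names: list[str]
    theta_hat: np.ndarray
    objective: float
    starts: list[dict] = field(default_factory=list)
    converged_fraction: float = 0.0
    bounds_log10: tuple[float, float] = (-5.0, 3.0)

    @property
    def theta_dict(self) -> dict[str, float]:
        return dict(zip(self.parameter_names, self.theta_hat))


def fit_multistart(
    predict,
    dataset,
    n_starts: int,
    bounds_log10: tuple[float, float] | list[tuple[float, float]] = (-5.0, 3.0),
    seed: int = 0,
    parameter_names: list[str] | None = None,
    n_parameters: int | None = None,
    x0_extra: np.ndarray | None = None,
    scalings=None,
    xtol: float = 1e-10,
    max_nfev: int | None = None,
) -> FitResult:
    """Multi-start trust-region least squares over log10 parameters.

    Starts are Latin hypercube samples over the log10 box (reproducible for a
    given ``seed``); each start is refined with ``scipy.optimize.least_squares``
    (TRF, finite-difference gradients) and the best optimum is kept.
    ``x0_extra`` adds one deterministic extra start (e.g. a known initial
    guess).
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if n_parameters is None:
        if parameter_names is None:
            raise ValueError("need parameter_names or n_parameters")
        n_parameters = len(parameter_names)
    if parameter_names is None:
        parameter_names = [f"p{i}" for i in range(n_parameters)]
    b = np.asarray(bounds_log10, float)
    if b.ndim == 1:
        lo = np.full(n_parameters, b[0])
        hi = np.full(n_parameters, b[1])
    else:
        lo, hi = b[:, 0], b[:, 1]
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ValueError("log10 bounds must be finite")

    # draw a prefix-stable Latin hypercube pool: the first k starts are the
    # same for every n_starts <= pool size, so adding starts can only improve
    # the returned optimum
    pool = max(256, n_starts)
    sampler = qmc.LatinHypercube(d=n_parameters, seed=seed)
    x0s = qmc.scale(sampler.random(pool)[:n_starts], lo, hi)
    if x0_extra is not None:
        x0s = np.vstack([np.clip(np.log10(x0_extra), lo, hi), x0s])

    def res_log(x):
        return _residuals(predict, dataset, 10.0**x, scalings)

    starts, best = [], None
    n_ok = 0
    for i, x0 in enumerate(x0s):
        try:
            sol = least_squares(res_log, x0, bounds=(lo, hi), method="trf",
                                xtol=xtol, ftol=xtol, gtol=xtol,
                                max_nfev=max_nfev)
            fun = float(2 * sol.cost)
            # usable if the optimizer left the failure plateau, even when it
            # stopped on the evaluation budget rather than the tolerances
            usable = fun < _FAIL_RESIDUAL**2
        except Exception as exc:  # pragma: no cover - defensive
            starts.append(dict(start=i, x0=x0.tolist(), objective=np.inf,
                               error=str(exc)))
            continue
        n_ok += usable and bool(sol.success)
        starts.append(dict(start=i, x0=x0.tolist(), objective=fun,
                           x_opt=sol.x.tolist()))
        if usable and (best is None or fun < best[0]):
            best = (fun, sol.x)
    if best is None:
        raise RuntimeError(
            f"all {len(x0s)} starts failed; per-start diagnostics: {starts}"
        )
    fun, x_hat = best
    return FitResult(
        parameter_names=list(parameter_names),
        theta_hat=10.0**x_hat,
        objective=fun,
        starts=starts,
        converged_fraction=n_ok / len(x0s),
        bounds_log10=(float(lo.min()), float(hi.max())),
    )


@dataclass
class ProfileResult:
    """Profile likelihood of one parameter around the optimum."""

    parameter: str
    grid: np.ndarray  # parameter values (linear scale)
    profile: np.ndarray  # profiled objective at each grid value
    minimum: float  # global minimum objective
    threshold: float  # minimum + chi2 quantile
    ci_lower: float  # may be -inf / +inf when open
    ci_upper: float
    flags: list[str] = field(default_factory=list)

    @property
    def lower_open(self) -> bool:
        return not np.isfinite(self.ci_lower)

    @property
    def upper_open(self) -> bool:
        return not np.isfinite(self.ci_upper)

    def contains(self, value: float) -> bool:
        return self.ci_lower <= value <= self.ci_upper


def _crossing(xs, fs, threshold):
    """Linear interpolation of the first threshold crossing along xs."""
    for i in range(1, len(xs)):
        f0, f1 = fs[i - 1], fs[i]
        if (f0 - threshold) * (f1 - threshold) <= 0 and f0 != f1:
            w = (threshold - f0) / (f1 - f0)
            return xs[i - 1] + w * (xs[i] - xs[i - 1])
    return None


def profile_likelihood(
    fit: FitResult,
    predict,
    dataset,
    parameter: str | int,
    span_log10: float = 1.5,
    n_points: int = 9,
    grid: np.ndarray | None = None,
    threshold: float = PL_THRESHOLD_95,
    scalings=None,
    xtol: float = 1e-9,
    max_nfev: int | None = None,
    stop_excess: float | None = 10.0,
) -> ProfileResult:
    """Profile one parameter: re-optimize the others at fixed values.

    The scan proceeds outward from the optimum on a log10 grid, warm-starting
    each re-optimization from the neighbouring solution.  The 95% pointwise
    confidence interval is the set where the profile stays within
    ``threshold`` (3.84) of the minimum; a profile that never crosses the
    threshold before the scan limit is reported as an open (non-identifiable)
    direction.  A branch stops early once the profile exceeds the threshold
    by ``stop_excess`` (the crossing is already bracketed).
    """
    names = fit.parameter_names
    j = names.index(parameter) if isinstance(parameter, str) else parameter
    pname = names[j]
    x_hat = np.log10(fit.theta_hat)
    free = [i for i in range(len(names)) if i != j]

    def profiled(xj, x_start):
        def res(xf):
            x = np.empty(len(names))
            x[free] = xf
            x[j] = xj
            return _residuals(predict, dataset, 10.0**x, scalings)
        if free:
            try:
                sol = least_squares(res, x_start[free], method="trf",
                                    bounds=(np.full(len(free), -8.0),
                                            np.full(len(free), 6.0)),
                                    xtol=xtol, ftol=xtol,
                                    max_nfev=max_nfev)
                x_new = x_start.copy()
                x_new[free] = sol.x
                return float(2 * sol.cost), x_new, True
            except Exception:
                return np.inf, x_start, False
        x = x_start.copy()
        x[j] = xj
        r = res(np.empty(0))
        return float(np.dot(r, r)), x, True

    if grid is not None:
        grid_log = np.log10(np.asarray(grid, float))
    else:
        half = np.linspace(0.0, span_log10, n_points // 2 + 1)[1:]
        grid_log = np.concatenate([x_hat[j] - half[::-1], [x_hat[j]],
                                   x_hat[j] + half])

    order_right = grid_log[grid_log >= x_hat[j]]
    order_left = grid_log[grid_log < x_hat[j]][::-1]
    prof = {}
    flags = []
    for branch in (order_right, order_left):
        x_start = x_hat.copy()
        for xj in branch:
            val, x_start, ok = profiled(xj, x_start)
            prof[xj] = min(val, prof.get(xj, np.inf))
            if not ok:
                flags.append(f"re-optimization failed at {pname}=1e{xj:.3f}")
            if (stop_excess is not None
                    and val > fit.objective + threshold + stop_excess):
                break

    xs = np.array(sorted(prof))
    fs = np.array([prof[x] for x in xs])
    # the profile can never be below the global minimum; clip tiny violations
    fs = np.maximum(fs, fit.objective)
    thr = fit.objective + threshold
    i_hat = int(np.argmin(np.abs(xs - x_hat[j])))
    lo = _crossing(xs[: i_hat + 1][::-1], fs[: i_hat + 1][::-1], thr)
    hi = _crossing(xs[i_hat:], fs[i_hat:], thr)
    ci_lower = 10.0**lo if lo is not None else -np.inf
    ci_upper = 10.0**hi if hi is not None else np.inf
    return ProfileResult(
        parameter=pname,
        grid=10.0**xs,
        profile=fs,
        minimum=fit.objective,
        threshold=thr,
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Signaling-model predictor for dataset fitting
# ---------------------------------------------------------------------------

class ConditionSimulator:
    """Maps a named parameter vector to predictions for a dataset.

    Fit parameters may be global kinetic parameters (plain name), inhibitor
    strengths (``"strength:<agent>:<context>"``), observable scale factors
    (``"scale:<observable>"``), or per-context abundances
    (``"abundance:<protein>:<context>"``, e.g. the basal DUSP level).
    Everything not listed stays at its base value -- the global/cell-type
    parameter split is enforced by construction.
    """

    def __init__(
        self,
        model: SignalingModel,
        contexts: dict[str, CellTypeContext],
        dataset: ExperimentDataset,
        fit_parameters: list[str],
        base_theta: dict[str, float] | None = None,
        inhibitor_strengths: dict[str, dict[str, float]] | None = None,
        observable_scales: dict[str, float] | None = None,
        receptor_scaling: dict[str, tuple[float, float]] | None = None,
        t_extra: tuple[float, ...] = (),
    ):
        self.model = model
        self.contexts = contexts
        self.dataset = dataset
        self.fit_parameters = list(fit_parameters)
        self.base_theta = dict(base_theta or {})
        self.inhibitor_strengths = {k: dict(v) for k, v in
                                    (inhibitor_strengths or {}).items()}
        self.observable_scales = dict(observable_scales or {})
        self.receptor_scaling = dict(receptor_scaling or {})
        self.t_extra = t_extra
        self._conditions = dataset.conditions()
        self._row_index = self._index_rows()

    def _index_rows(self):
        rows = []
        df = self.dataset.df
        for cond in self._conditions.itertuples():
            mask = ((df["context"] == cond.context)
                    & (df["epo_Uml"] == cond.epo_Uml)
                    & (df["perturbation_id"] == cond.perturbation_id))
            sub = df[mask]
            rows.append((cond, sub.index.to_numpy(),
                         sub["time_min"].to_numpy(float),
                         sub["observable"].tolist()))
        return rows

    def _split_theta(self, theta_vec):
        theta = dict(self.base_theta)
        strengths = {k: dict(v) for k, v in self.inhibitor_strengths.items()}
        scales = dict(self.observable_scales)
        abund_over = {}
        for name, val in zip(self.fit_parameters, theta_vec):
            if name.startswith("strength:"):
                _, agent, ctx = name.split(":")
                strengths.setdefault(ctx, {})[agent] = val
            elif name.startswith("scale:"):
                scales[name.split(":", 1)[1]] = val
            elif name.startswith("abundance:"):
                _, prot, ctx = name.split(":")
                abund_over.setdefault(ctx, {})[prot] = val
            else:
                theta[name] = val
        return theta, strengths, scales, abund_over

    def predict(self, theta_vec: np.ndarray) -> np.ndarray:
        theta, strengths, scales, abund_over = self._split_theta(theta_vec)
        out = np.empty(len(self.dataset.df))
        for cond, idx, times, obs in self._row_index:
            ctx = self.contexts[cond.context]
            for prot, val in abund_over.get(cond.context, {}).items():
                ctx = ctx.with_abundance(prot, val)
            inst = apply_cell_context(
                self.model, ctx, theta=theta,
                inhibitor_strengths=strengths.get(cond.context, {}),
                receptor_scaling=self.receptor_scaling.get(cond.context,
                                                           (1.0, 1.0)),
                observable_scales=scales,
            )
            perts = parse_perturbation_id(cond.perturbation_id)
            if perts:
                inst = apply_perturbation(inst, perts)
            t_grid = np.unique(np.concatenate(
                [[0.0], times, np.asarray(self.t_extra, float)]))
            traj = simulate(inst, cond.epo_Uml, t_grid)
            t_pos = {t: k for k, t in enumerate(t_grid)}
            for row, t, ob in zip(idx, times, obs):
                out[row] = traj.observables[ob][t_pos[t]]
        return out

    __call__ = predict


# ---------------------------------------------------------------------------
# Phospho-degree anchoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Anchor:
    """One observable-scale constraint, e.g. "54% of AKT phosphorylated at
    2.5 U/ml Epo and 10 min in mCFU-E cells"."""

    observable: str
    context_name: str
    fraction: float  # phospho degree (0..1] at the anchor point
    protein_total: str  # conserved total that normalizes the degree
    epo_dose: float  # U/ml
    time_min: float | None  # None: use the maximum over the time course


#: The three phospho-degree anchors that convert arbitrary blot units to nM:
#: receptor phosphorylation at most 75% (saturating Epo), 54% pAKT at
#: (mCFU-E, 2.5 U/ml, 10 min), at most 10% double-phosphorylated ERK in
#: mCFU-E.
DEFAULT_ANCHORS = (
    Anchor("pEpoR", "mCFU-E", 0.75, "EpoR", 50.0, None),
    Anchor("pAKT", "mCFU-E", 0.54, "AKT", 2.5, 10.0),
    Anchor("ppERK", "mCFU-E", 0.10, "ERK", 50.0, None),
)


def anchor_scalings(
    instances: dict[str, ModelInstance],
    anchors: tuple[Anchor, ...] = DEFAULT_ANCHORS,
    t_grid: np.ndarray | None = None,
) -> dict[str, float]:
    """Observable scale factors implied by phospho-degree anchors.

    For each anchor the corresponding instance is simulated and the scale is
    chosen so that the scaled observable equals ``fraction * total`` at the
    anchor point (time point, or maximum over the course).  Scaled
    trajectories are then in nM.
    """
    t_grid = np.linspace(0.0, 60.0, 121) if t_grid is None else np.asarray(t_grid)
    scales: dict[str, float] = {}
    for anc in anchors:
        try:
            inst = instances[anc.context_name]
        except KeyError:
            raise ValueError(
                f"anchor for {anc.observable} needs context "
                f"{anc.context_name!r}, not provided"
            ) from None
        if anc.observable not in inst.model.observables:
            raise ValueError(
                f"anchor observable {anc.observable!r} not in model"
            )
        grid = t_grid
        if anc.time_min is not None and anc.time_min not in grid:
            grid = np.unique(np.concatenate([grid, [anc.time_min]]))
        traj = simulate(inst, anc.epo_dose, grid)
        raw = traj.observables[anc.observable]
        if anc.time_min is None:
            ref = float(np.max(raw))
        else:
            ref = float(raw[np.searchsorted(grid, anc.time_min)])
        if ref <= 0:
            raise ValueError(
                f"anchor condition for {anc.observable} produced no signal"
            )
        total = inst.total(anc.protein_total)
        scales[anc.observable] = anc.fraction * total / ref
    return scales
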