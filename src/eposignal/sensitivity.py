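"""Relative sensitivities (response coefficients) of integrated pS6.

The response coefficient of an output X with respect to a parameter p is

    S_p^X = (dX/dp) * (p / X),

a dimensionless log-log slope.  Here X is the pS6 response integrated over
the first hour of Epo stimulation and p ranges over the protein abundances of
one cell-type context, so the matrix of S values quantifies how the signal
flow toward S6 distributes over the network modules in each cell type.
Derivatives are taken by central finite differences on a relative step, with
an optional Richardson half-step check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .contexts import CellTypeContext
from .network import ModelInstance, SignalingModel, apply_cell_context, simulate

__all__ = [
    "MODULE_GROUPS",
    "SensitivityMatrix",
    "integrated_response",
    "integrated_response_from_points",
    "relative_sensitivity",
    "sensitivity_matrix",
]

#: Network-module grouping of the context proteins (rows of the matrix).
MODULE_GROUPS = {
    "receptor": ["EpoR", "SHP1", "Sos"],
    "PI3K/AKT": ["PI3K", "SHIP1", "PTEN", "PDK1", "AKT", "PIP2"],
    "Ras/MEK/ERK": ["Ras", "Raf", "MEK", "ERK", "DUSP"],
    "S6 integration": ["S6", "RSK", "mTOR", "Rictor", "Raptor"],
}

#: Default Epo dose (U/ml) at which sensitivities are evaluated -- the dose
#: used for the inhibitor / phenotype-link experiments.
DEFAULT_EPO_DOSE = 5.0


class SensitivityError(ValueError):
    """Raised when a sensitivity is mathematically undefined (X = 0)."""


def integrated_response(
    trajectory, observable: str, t0: float = 0.0, t1: float = 60.0
) -> float:
    """Area under an observable curve over [t0, t1] in nM*min.

    Model trajectories that carry a dense ODE interpolant are integrated by
    adaptive quadrature on it; otherwise the trapezoidal rule is applied on
    the trajectory grid (exact for piecewise-linear signals).
    """
    if t1 <= t0:
        raise ValueError("need t1 > t0")
    t = np.asarray(trajectory.time, float)
    if t[0] > t0 or t[-1] < t1:
        raise ValueError("trajectory does not cover the integration window")
    if getattr(trajectory, "dense", None) is not None:
        val, _ = quad(lambda x: trajectory.observable_at(observable, x),
                      t0, t1, limit=200)
        return float(val)
    return integrated_response_from_points(t, trajectory.observables[observable],
                                           t0, t1)


def integrated_response_from_points(
    t: np.ndarray, y: np.ndarray, t0: float = 0.0, t1: float = 60.0
) -> float:
    """Trapezoidal AUC of sparse measured points over [t0, t1] (nM*min)."""
    if t1 <= t0:
        raise ValueError("need t1 > t0")
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    mask = (t >= t0) & (t <= t1)
    if mask.sum() < 2:
        raise ValueError("need at least two points inside the window")
    return float(np.trapezoid(y[mask], t[mask]))


def _integrated_ps6(
    model: SignalingModel,
    context: CellTypeContext,
    epo_dose: float,
    observable: str = "pS6",
    t1: float = 60.0,
    n_grid: int = 121,
    instance_options: dict | None = None,
) -> float:
    inst = apply_cell_context(model, context, **(instance_options or {}))
    t = np.linspace(0.0, t1, n_grid)
    traj = simulate(inst, epo_dose, t)
    return integrated_response_from_points(t, traj.observables[observable],
                                           0.0, t1)


def relative_sensitivity(
    model: SignalingModel,
    context: CellTypeContext,
    protein: str,
    epo_dose: float = DEFAULT_EPO_DOSE,
    delta: float = 1e-3,
    observable: str = "pS6",
    richardson_check: bool = False,
    instance_options: dict | None = None,
) -> float:
    """Response coefficient of 1-h-integrated pS6 to one protein abundance.

    Central finite difference with relative step ``delta`` on the abundance.
    A protein the model does not use returns exactly 0; a zero output raises
    :class:`SensitivityError` rather than silently reporting 0.  With
    ``richardson_check`` the step is halved and a >1% disagreement raises.
    """
    p0 = context.concentration(protein)
    if p0 <= 0:
        raise ValueError(f"protein {protein!r} has non-positive abundance")
    X0 = _integrated_ps6(model, context, epo_dose, observable,
                         instance_options=instance_options)
    if X0 == 0:
        raise SensitivityError(
            f"integrated {observable} is 0 in context {context.name!r}; "
            "relative sensitivity undefined"
        )

    def fd(d):
        Xp = _integrated_ps6(model, context.with_abundance(protein, p0 * (1 + d)),
                             epo_dose, observable,
                             instance_options=instance_options)
        Xm = _integrated_ps6(model, context.with_abundance(protein, p0 * (1 - d)),
                             epo_dose, observable,
                             instance_options=instance_options)
        return (Xp - Xm) / (2 * d * X0)

    s = fd(delta)
    if richardson_check:
        s_half = fd(delta / 2)
        denom = max(abs(s), abs(s_half), 1e-12)
        if abs(s - s_half) / denom > 0.01:
            raise SensitivityError(
                f"finite-difference sensitivity for {protein!r} not converged "
                f"(delta={delta:g}: {s:.4g}, delta/2: {s_half:.4g})"
            )
    return float(s)


@dataclass
class SensitivityMatrix:
    """Proteins (grouped by module) x cell-type contexts, entries S_p^X."""

    tidy: pd.DataFrame  # columns: protein, module, context, S, flag

    @property
    def wide(self) -> pd.DataFrame:
        return self.tidy.pivot(index=["module", "protein"], columns="context",
                               values="S")

    def module_magnitude(self, module: str, context: str) -> float:
        """Sum of |S| over the proteins of one module in one context."""
        sub = self.tidy[(self.tidy["module"] == module)
                        & (self.tidy["context"] == context)]
        return float(sub["S"].abs().sum())

    def value(self, protein: str, context: str) -> float:
        sub = self.tidy[(self.tidy["protein"] == protein)
                        & (self.tidy["context"] == context)]
        return float(sub["S"].iloc[0])


def sensitivity_matrix(
    model: SignalingModel,
    contexts: list[CellTypeContext],
    epo_dose: float = DEFAULT_EPO_DOSE,
    delta: float = 1e-3,
    groups: dict[str, list[str]] | None = None,
    instance_options: dict | None = None,
) -> SensitivityMatrix:
    """Full response-coefficient matrix over context proteins x contexts.

    A failed simulation flags the entry (NaN with a note) instead of aborting
    the whole matrix.
    """
    groups = MODULE_GROUPS if groups is None else groups
    rows = []
    for ctx in contexts:
        for module, prots in groups.items():
            for prot in prots:
                try:
                    s = relative_sensitivity(
                        model, ctx, prot, epo_dose=epo_dose, delta=delta,
                        instance_options=instance_options)
                    flag = ""
                except Exception as exc:
                    s, flag = np.nan, str(exc)
                rows.append(dict(protein=prot, module=module,
                                 context=ctx.name, S=s, flag=flag))
    return SensitivityMatrix(tidy=pd.DataFrame(rows))
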