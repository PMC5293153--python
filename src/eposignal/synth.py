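"""Synthetic-data generation from a declared ground truth.

Every input the analysis pipeline consumes -- phospho time courses, qPCR
fold-change triples, and proliferation readouts -- can be generated from a
:class:`GroundTruth` so that calibration, sensitivity analysis and the
phenotype link are testable end to end without any external data.

The generator emulates the experimental design of the study: Epo stimulation
time courses sampled at 0/10/30/60 min, inhibitor pretreatment with AKT VIII
and U0126 at 0/0.05/0.5/5 uM, measurement noise with 10% relative error plus
5% absolute error of the highest data point under each condition, qPCR
measurements of the three cell-cycle genes, and proliferation readouts scaled
to 1 at the Epo-only condition.

The default kinetic truth is the model's reduced fast-simulating
parametrization constrained by the three phospho-degree anchors; the default
link truth makes the small, fast-cycling primary-cell context growth-limited
(proliferation follows integrated pS6) and the large cell-line contexts
cycle-limited (proliferation follows the cell cycle indicator).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import (
    DEFAULT_ANCHORS,
    ExperimentDataset,
    anchor_scalings,
    perturbation_id,
)
from .contexts import CellTypeContext, make_table1_contexts
from .network import (
    ModelInstance,
    Perturbation,
    SignalingModel,
    apply_cell_context,
    apply_perturbation,
    build_signaling_model,
    full_topology,
    simulate,
)
from .sensitivity import integrated_response_from_points

__all__ = [
    "GroundTruth",
    "DesignSpec",
    "default_ground_truth",
    "generate_timecourse_dataset",
    "generate_cci_dataset",
    "generate_proliferation_dataset",
    "fit_links",
    "make_table1_contexts",
]

#: Observables reported by the synthetic time-course blots.
TIMECOURSE_OBSERVABLES = ("pEpoR", "pAKT", "GTPRas", "ppERK", "pS6")


@dataclass(frozen=True)
class DesignSpec:
    """Experimental design: cell types x Epo doses x inhibitor grid x times."""

    cell_types: tuple[str, ...] = ("mCFU-E", "BaF3-EpoR", "32D-EpoR")
    epo_doses: tuple[float, ...] = (5.0,)
    inhibitors: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "AKTVIII": (0.0, 0.05, 0.5, 5.0),
            "U0126": (0.0, 0.05, 0.5, 5.0),
        })
    times_min: tuple[float, ...] = (0.0, 10.0, 30.0, 60.0)

    def __post_init__(self):
        if not (self.cell_types and self.epo_doses and self.times_min):
            raise ValueError("design grids must be non-empty")

    def conditions(self) -> list[tuple[str, float, list[Perturbation]]]:
        """All (cell type, dose, perturbations); the inhibitor-free condition
        appears exactly once per (cell type, dose)."""
        out = []
        for ct in self.cell_types:
            for dose in self.epo_doses:
                out.append((ct, dose, []))
                for agent, dgrid in self.inhibitors.items():
                    for d in dgrid:
                        if d == 0.0:
                            continue
                        out.append((ct, dose,
                                    [Perturbation("inhibitor", agent, d)]))
        return out


@dataclass
class GroundTruth:
    """Declared generating process for all synthetic datasets.

    ``stage1`` maps cell type to positive link coefficients (b_akt, b_erk) of
    log CCI on baseline-subtracted integrated pAKT/ppERK; ``stage2_class``
    assigns each cell type to the growth-limited class (proliferation
    proportional to integrated pS6) or the cycle-limited class (proportional
    to CCI).
    """

    model: SignalingModel
    contexts: dict[str, CellTypeContext]
    theta: dict[str, float]
    inhibitor_strengths: dict[str, dict[str, float]]
    observable_scales: dict[str, float]
    stage1: dict[str, tuple[float, float]]
    stage2_class: dict[str, str]  # "growth-limited" | "cycle-limited"
    noise_relative: float = 0.10
    noise_absolute_frac: float = 0.05  # of the condition maximum
    qpcr_sigma_log: float = 0.15
    prolif_noise_frac: float = 0.05
    seed: int = 0
    _integral_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.noise_relative < 0 or self.noise_absolute_frac < 0:
            raise ValueError("noise fractions must be >= 0")
        for ct, cls in self.stage2_class.items():
            if cls not in ("growth-limited", "cycle-limited"):
                raise ValueError(f"unknown stage-2 class {cls!r} for {ct}")

    # -- simulation helpers -------------------------------------------------

    def instance(self, cell_type: str) -> ModelInstance:
        return apply_cell_context(
            self.model, self.contexts[cell_type], theta=self.theta,
            inhibitor_strengths=self.inhibitor_strengths.get(cell_type, {}),
            observable_scales=self.observable_scales,
        )

    def simulate_condition(self, cell_type, epo_dose, perturbations,
                           t_grid) -> dict[str, np.ndarray]:
        inst = self.instance(cell_type)
        if perturbations:
            inst = apply_perturbation(inst, list(perturbations))
        traj = simulate(inst, epo_dose, np.asarray(t_grid, float))
        return {ob: traj.observables[ob] for ob in traj.observables}

    def integrals(self, cell_type, epo_dose, perturbations=()) -> dict:
        key = (cell_type, epo_dose, perturbation_id(list(perturbations)))
        if key not in self._integral_cache:
            t = np.linspace(0.0, 60.0, 61)
            obs = self.simulate_condition(cell_type, epo_dose,
                                          list(perturbations), t)
            self._integral_cache[key] = {
                "I_" + ob: integrated_response_from_points(t, obs[ob])
                for ob in ("pAKT", "ppERK", "pS6")
            }
        return dict(self._integral_cache[key])

    # -- link truth ---------------------------------------------------------

    def true_cci(self, cell_type, epo_dose, perturbations=()) -> float:
        """CCI implied by the stage-1 truth for one condition."""
        b_akt, b_erk = self.stage1[cell_type]
        ints = self.integrals(cell_type, epo_dose, perturbations)
        base = self.integrals(cell_type, 0.0)
        log_cci = (b_akt * (ints["I_pAKT"] - base["I_pAKT"])
                   + b_erk * (ints["I_ppERK"] - base["I_ppERK"]))
        return float(np.exp(log_cci))

    def true_proliferation_raw(self, cell_type, epo_dose,
                               perturbations=()) -> float:
        if self.stage2_class[cell_type] == "growth-limited":
            return self.integrals(cell_type, epo_dose,
                                  perturbations)["I_pS6"]
        return self.true_cci(cell_type, epo_dose, perturbations)

    def manifest(self) -> dict:
        """Hashable description of the truth (for output manifests)."""
        payload = dict(
            theta=self.theta,
            inhibitor_strengths=self.inhibitor_strengths,
            observable_scales=self.observable_scales,
            stage1=self.stage1,
            stage2_class=self.stage2_class,
            noise=dict(relative=self.noise_relative,
                       absolute_frac=self.noise_absolute_frac,
                       qpcr_sigma_log=self.qpcr_sigma_log,
                       prolif_noise_frac=self.prolif_noise_frac),
            seed=self.seed,
        )
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]
        return dict(truth_hash=digest, **payload)


#: Half-inhibition doses (uM) per cell type; 32D-EpoR is less sensitive to
#: the MEK inhibitor, consistent with its elevated MEK level buffering the
#: drug effect.
DEFAULT_INHIBITOR_STRENGTHS = {
    "mCFU-E": {"AKTVIII": 0.5, "U0126": 0.5, "BID1870": 0.5,
               "rapamycin": 0.05},
    "BaF3-EpoR": {"AKTVIII": 0.5, "U0126": 0.5, "BID1870": 0.5,
                  "rapamycin": 0.05},
    "32D-EpoR": {"AKTVIII": 0.5, "U0126": 2.0, "BID1870": 0.5,
                 "rapamycin": 0.05},
}

#: Epo-only CCI levels the stage-1 truth reproduces (16-fold induction for
#: BaF3-EpoR, 13-fold for CFU-E at a saturating dose) and the AKT share of
#: the log-CCI signal per cell type.
_CCI_TARGETS = {"mCFU-E": (13.0, 0.6), "BaF3-EpoR": (16.0, 0.4),
                "32D-EpoR": (16.0, 0.4)}

_DEFAULT_TRUTH_CACHE: dict[int, GroundTruth] = {}


def default_ground_truth(seed: int = 0, use_cache: bool = True) -> GroundTruth:
    """The calibrated synthetic truth on the measured abundance contexts.

    Observable scales are set from the three phospho-degree anchors; stage-1
    coefficients are calibrated so the Epo-only condition at 5 U/ml
    reproduces the published fold inductions of the cell cycle indicator with
    the declared AKT/ERK share.
    """
    if use_cache and seed in _DEFAULT_TRUTH_CACHE:
        return replace(_DEFAULT_TRUTH_CACHE[seed], seed=seed)
    model = build_signaling_model(full_topology())
    contexts = {c.name: c for c in make_table1_contexts()}
    theta = dict(model.theta_default)
    instances = {
        name: apply_cell_context(model, ctx, theta=theta)
        for name, ctx in contexts.items()
    }
    scales = anchor_scalings(instances, DEFAULT_ANCHORS)
    truth = GroundTruth(
        model=model,
        contexts=contexts,
        theta=theta,
        inhibitor_strengths={k: dict(v) for k, v in
                             DEFAULT_INHIBITOR_STRENGTHS.items()},
        observable_scales=scales,
        stage1={},
        stage2_class={"mCFU-E": "growth-limited",
                      "BaF3-EpoR": "cycle-limited",
                      "32D-EpoR": "cycle-limited"},
        seed=seed,
    )
    # calibrate stage-1 coefficients against the Epo-only integrals
    for ct, (cci_target, akt_share) in _CCI_TARGETS.items():
        ints = truth.integrals(ct, 5.0)
        base = truth.integrals(ct, 0.0)
        d_akt = ints["I_pAKT"] - base["I_pAKT"]
        d_erk = ints["I_ppERK"] - base["I_ppERK"]
        log_target = np.log(cci_target)
        truth.stage1[ct] = (akt_share * log_target / d_akt,
                            (1 - akt_share) * log_target / d_erk)
    if use_cache:
        _DEFAULT_TRUTH_CACHE[seed] = truth
    return truth


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_timecourse_dataset(
    truth: GroundTruth, design: DesignSpec, seed: int | None = None
) -> ExperimentDataset:
    """Noisy phospho time courses over the full design.

    Each condition is simulated, sampled at the design time points, and
    corrupted with Gaussian noise of standard deviation
    ``0.10*y + 0.05*max(condition)``; the per-row sigma is stored alongside.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    times = np.asarray(design.times_min, float)
    rows = []
    for ct, dose, perts in design.conditions():
        pid = perturbation_id(perts)
        try:
            obs = truth.simulate_condition(ct, dose, perts, times)
        except Exception as exc:
            # a failed condition is skipped, not fatal
            rows.append(None)
            print(f"warning: condition ({ct}, {dose}, {pid}) skipped: {exc}")
            continue
        for ob in TIMECOURSE_OBSERVABLES:
            y = np.asarray(obs[ob], float)
            y_max = float(np.max(np.abs(y)))
            if y_max == 0:
                continue
            # stored sigma always follows the canonical error model; the
            # truth's noise fractions control only the injected noise
            sigma = 0.10 * np.abs(y) + 0.05 * y_max
            noise_sd = truth.noise_relative * np.abs(y) \
                + truth.noise_absolute_frac * y_max
            y_obs = y + rng.normal(0.0, 1.0, size=y.shape) * noise_sd
            for t, v, s in zip(times, y_obs, sigma):
                rows.append(dict(context=ct, epo_Uml=dose,
                                 perturbation_id=pid, time_min=t,
                                 observable=ob, value_nM=v, sigma_nM=s))
    df = pd.DataFrame([r for r in rows if r is not None])
    return ExperimentDataset(df, design=dict(
        cell_types=list(design.cell_types),
        epo_doses=list(design.epo_doses),
        inhibitors={k: list(v) for k, v in design.inhibitors.items()},
        times_min=list(design.times_min),
    ))


def _decompose_cci(cci: float) -> tuple[float, float, float]:
    """Split a CCI value into three positive fold changes reproducing it:
    fc_ccnd2 = CCI^(1/2), fc_ccng2 = fc_cdkn1b = CCI^(-1/4) (balanced up and
    down regulation)."""
    return cci**0.5, cci**-0.25, cci**-0.25


def generate_cci_dataset(
    truth: GroundTruth, design: DesignSpec, seed: int | None = None,
    noise: bool = True,
) -> pd.DataFrame:
    """qPCR fold-change triples whose indicator equals the stage-1 truth.

    Per condition the true CCI is decomposed into three fold changes (exact
    pre-noise) and each gene receives independent multiplicative lognormal
    noise.  The unstimulated condition yields the triple (1, 1, 1).
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    rows = []
    for ct, dose, perts in design.conditions():
        cci = truth.true_cci(ct, dose, perts)
        d2, g2, p27 = _decompose_cci(cci)
        fc = np.array([d2, g2, p27])
        if noise and truth.qpcr_sigma_log > 0:
            fc = fc * np.exp(rng.normal(0.0, truth.qpcr_sigma_log, size=3))
        rows.append(dict(context=ct, epo_Uml=dose,
                         perturbation_id=perturbation_id(perts),
                         fc_ccnd2=fc[0], fc_ccng2=fc[1], fc_cdkn1b=fc[2],
                         cci_true=cci))
    return pd.DataFrame(rows)


def generate_proliferation_dataset(
    truth: GroundTruth, design: DesignSpec, assay: str = "coulter",
    seed: int | None = None, noise: bool = True,
) -> pd.DataFrame:
    """Proliferation readouts from the stage-2 truth, scaled so the Epo-only
    condition equals 1 pre-noise; additive Gaussian noise (default SD 5% of
    the maximum)."""
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    rows = []
    ref_dose = max(design.epo_doses)
    for ct, dose, perts in design.conditions():
        raw = truth.true_proliferation_raw(ct, dose, perts)
        ref = truth.true_proliferation_raw(ct, ref_dose, [])
        rows.append(dict(context=ct, epo_Uml=dose,
                         perturbation_id=perturbation_id(perts),
                         assay=assay, proliferation=raw / ref))
    df = pd.DataFrame(rows)
    if noise and truth.prolif_noise_frac > 0:
        scale = truth.prolif_noise_frac * df.groupby("context")[
            "proliferation"].transform("max")
        df["proliferation"] += rng.normal(0.0, 1.0, len(df)) * scale
    return df


def fit_links(
    truth: GroundTruth,
    cci_df: pd.DataFrame,
    prolif_df: pd.DataFrame,
    use_aicc: bool = False,
):
    """Fit both regression stages on generated datasets and assemble the
    prediction pipeline (model-derived integrals + measured CCI and
    proliferation)."""
    from .calibration import parse_perturbation_id
    from .phenotype import (ProliferationPipeline, cell_cycle_indicator,
                            fit_signaling_to_cci, select_proliferation_model)

    rows = []
    for r in cci_df.itertuples():
        ints = truth.integrals(r.context, r.epo_Uml,
                               parse_perturbation_id(r.perturbation_id))
        rows.append(dict(context=r.context, epo_Uml=r.epo_Uml,
                         perturbation_id=r.perturbation_id,
                         cci=cell_cycle_indicator(
                             (r.fc_ccnd2, r.fc_ccng2, r.fc_cdkn1b)),
                         **ints))
    feat = pd.DataFrame(rows)
    stage1 = fit_signaling_to_cci(feat)
    merged = feat.merge(prolif_df,
                        on=["context", "epo_Uml", "perturbation_id"])
    stage2, tables = {}, {}
    for ct, sub in merged.groupby("context"):
        best, table = select_proliferation_model(sub, cell_type=ct,
                                                 use_aicc=use_aicc)
        stage2[ct] = best
        tables[ct] = table
    pipeline = ProliferationPipeline(
        instances={ct: truth.instance(ct) for ct in truth.contexts},
        stage1=stage1, stage2=stage2)
    return pipeline, tables
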