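"""Shared closed-form toy constructions used across test modules."""

import numpy as np
import pandas as pd

from eposignal.contexts import CellTypeContext
from eposignal.phenotype import select_proliferation_model


def power_topology(power: int) -> dict:
    """Steady output proportional to (enzyme abundance)^power; PTEN plays
    the enzyme and the output observable is named pS6 for the sensitivity
    API."""
    rate = "k*" + "*".join(["PTEN_total"] * power)
    return dict(
        name=f"toy_pow{power}",
        species=["Epo", "Y"],
        reactions=[dict(name="syn", reactants={}, products={"Y": 1},
                        kind="regulatory", rate=rate),
                   dict(name="deg", reactants={"Y": 1}, products={},
                        kind="mass_action", rate="kd*Y"),
                   dict(name="ez", reactants={"Epo": 1}, products={},
                        kind="mass_action", rate="kz*Epo")],
        parameters=["k", "kd", "kz"],
        moieties={},
        observables={"pS6": "Y"},
        theta_default={"k": 0.1, "kd": 0.5, "kz": 1.0},
    )


def toy_context() -> CellTypeContext:
    return CellTypeContext(
        name="toy", cytoplasmic_volume_um3=100.0, surface_area_um2=100.0,
        abundances_nM={"PTEN": 10.0, "DUSP": 1.0, "EpoR": 1.0, "Gab1": 5.0})


def selection_replicates(generating: str, n_rep: int = 50,
                         snr: float = 10.0) -> float:
    """Fraction of seeded replicates in which small-sample information-
    criterion selection (AICc, n = 9 conditions) picks the generating
    proliferation structure."""
    rng = np.random.default_rng(2024)
    hits = 0
    for _ in range(n_rep):
        n = 9
        I_ps6 = rng.uniform(1e3, 1e4, n)
        cci = rng.uniform(1, 16, n)
        signal = I_ps6 / I_ps6.std() if generating == "pS6-only" \
            else cci / cci.std()
        y = signal + rng.normal(0, signal.std() / snr, n)
        best, _ = select_proliferation_model(
            pd.DataFrame(dict(I_pS6=I_ps6, cci=cci, proliferation=y)),
            use_aicc=True)
        hits += (best.predictors == (["I_pS6"] if generating == "pS6-only"
                                     else ["cci"]))
    return hits / n_rep
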