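"""Tidy-CSV schemas, structured configs, and output manifests.

Conventions: concentrations in nM, time in minutes, Epo doses in U/ml,
inhibitor doses in uM -- units are encoded in the column names.  All writers
emit locale-independent period-decimal numbers (pandas defaults).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import DATASET_COLUMNS, ExperimentDataset
from .contexts import CellTypeContext
from .network import Trajectory

__all__ = [
    "SchemaError",
    "read_dataset_csv",
    "write_dataset_csv",
    "trajectory_to_tidy",
    "write_sensitivity_csv",
    "context_to_dict",
    "context_from_dict",
    "load_contexts_yaml",
    "save_contexts_yaml",
    "write_manifest",
]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def _validate_rows(df: pd.DataFrame, numeric_cols: list[str]) -> None:
    bad_rows = []
    for col in numeric_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()].tolist()
        bad_rows += [(r, col) for r in bad]
    if bad_rows:
        listing = ", ".join(f"row {r} ({c})" for r, c in bad_rows[:10])
        raise SchemaError(f"malformed numeric values: {listing}")


def read_dataset_csv(path: str | Path) -> ExperimentDataset:
    """Load a phospho-observable dataset; unknown columns pass through."""
    df = pd.read_csv(path)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    _validate_rows(df, ["epo_Uml", "time_min", "value_nM", "sigma_nM"])
    for c in ["epo_Uml", "time_min", "value_nM", "sigma_nM"]:
        df[c] = pd.to_numeric(df[c])
    return ExperimentDataset(df)


def write_dataset_csv(dataset: ExperimentDataset, path: str | Path) -> None:
    dataset.df.to_csv(path, index=False)


def trajectory_to_tidy(traj: Trajectory, species: bool = False) -> pd.DataFrame:
    """Tidy frame: time_min, species (or observable), value_nM, context,
    epo_Uml, perturbation_id."""
    from .calibration import perturbation_id as pid
    source = traj.states if species else traj.observables
    rows = []
    for name, vals in source.items():
        for t, v in zip(traj.time, vals):
            rows.append(dict(time_min=t, species=name, value_nM=v,
                             context=traj.context_name,
                             epo_Uml=traj.epo_dose,
                             perturbation_id=pid(list(traj.perturbations))))
    return pd.DataFrame(rows)


def write_sensitivity_csv(matrix, path_tidy: str | Path,
                          path_wide: str | Path | None = None) -> None:
    matrix.tidy.to_csv(path_tidy, index=False)
    if path_wide is not None:
        matrix.wide.to_csv(path_wide)


# -- contexts as structured config ------------------------------------------

def context_to_dict(ctx: CellTypeContext) -> dict:
    return dict(
        name=ctx.name,
        cytoplasmic_volume_um3=ctx.cytoplasmic_volume_um3,
        surface_area_um2=ctx.surface_area_um2,
        abundances_nM=dict(ctx.abundances_nM),
        ratios_to_reference=dict(ctx.ratios),
        absent=sorted(ctx.absent),
    )


def context_from_dict(d: dict) -> CellTypeContext:
    try:
        return CellTypeContext(
            name=d["name"],
            cytoplasmic_volume_um3=float(d["cytoplasmic_volume_um3"]),
            surface_area_um2=float(d["surface_area_um2"]),
            abundances_nM={k: float(v)
                           for k, v in d.get("abundances_nM", {}).items()},
            ratios={k: float(v)
                    for k, v in d.get("ratios_to_reference", {}).items()},
            absent=frozenset(d.get("absent", [])),
        )
    except KeyError as exc:
        raise SchemaError(f"context config missing key {exc}") from exc


def load_contexts_yaml(path: str | Path) -> dict[str, CellTypeContext]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    ctxs = [context_from_dict(d) for d in data["contexts"]]
    return {c.name: c for c in ctxs}


def save_contexts_yaml(contexts: list[CellTypeContext],
                       path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"contexts": [context_to_dict(c) for c in contexts]},
                       fh, sort_keys=False)


# -- manifests ---------------------------------------------------------------

def write_manifest(out_dir: str | Path, command: str, seed: int | None,
                   config: dict, outputs: list[str]) -> Path:
    """Write ``manifest.json`` recording config hash, seed, and version."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(config, sort_keys=True, default=default)
    manifest = dict(
        command=command,
        seed=seed,
        version=__version__,
        config_sha256=hashlib.sha256(blob.encode()).hexdigest(),
        config=json.loads(blob),
        outputs=sorted(outputs),
    )
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
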