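"""Cell-type protein-abundance contexts and unit conversions.

A :class:`CellTypeContext` carries everything that distinguishes one cell type
from another in the kinetic model: cytoplasmic concentrations of the pathway
components (nM), cell geometry (cytoplasmic volume and surface area), and the
set of proteins that are simply absent.  Kinetic rate constants, by contrast,
are shared across cell types and live with the model, not the context.

Concentrations of the core components for the three murine cell systems
(primary mCFU-E erythroid progenitors and the EpoR-expressing cell lines
BaF3-EpoR and 32D-EpoR) were measured by quantitative immunoblotting against
recombinant calibrator proteins; four components (mTOR, Rictor, Raptor, RSK)
were only quantified relative to mCFU-E and are stored as ratios that get
resolved against declared reference concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.constants import Avogadro

__all__ = [
    "CellTypeContext",
    "copy_number_to_concentration",
    "surface_density",
    "make_table1_contexts",
    "make_hcfue_like_context",
    "RATIO_SCALE_PROTEINS",
    "REFERENCE_CONCENTRATIONS_NM",
    "NOMINAL_CONCENTRATIONS_NM",
]

#: Components quantified only relative to the mCFU-E level.
RATIO_SCALE_PROTEINS = ("mTOR", "Rictor", "Raptor", "RSK")

#: Declared absolute mCFU-E concentrations (nM) used to resolve ratio-scale
#: entries.  These are model reference scales, not measured values.
REFERENCE_CONCENTRATIONS_NM = {
    "mTOR": 150.0,
    "Rictor": 120.0,
    "Raptor": 150.0,
    "RSK": 350.0,
}

#: Nominal concentrations (nM) for components the abundance table does not
#: cover.  SHP1 and Sos are taken identical across cell types; the PIP2 pool is
#: a fixed membrane-lipid reservoir; DUSP is per cell type (the BaF3:mCFU-E
#: basal DUSP ratio 2^5.27 is a model-identified quantity, the 32D ratio is an
#: assumed intermediate).
NOMINAL_CONCENTRATIONS_NM = {
    "SHP1": 100.0,
    "Sos": 100.0,
    "PIP2": 4000.0,
    "DUSP_mCFU-E": 30.0,
    "DUSP_BaF3-EpoR": 30.0 * 2**5.27,
    "DUSP_32D-EpoR": 30.0 * 35.0,
}


def copy_number_to_concentration(n_molecules: float, volume_um3: float) -> float:
    """Convert a per-cell copy number to a cytoplasmic concentration in nM.

    Parameters
    ----------
    n_molecules:
        Number of molecules per cell (>= 0).
    volume_um3:
        Cytoplasmic volume in cubic micrometres (> 0).  1 um^3 = 1e-15 L.
    """
    if n_molecules < 0:
        raise ValueError(f"copy number must be >= 0, got {n_molecules}")
    if volume_um3 <= 0:
        raise ValueError(f"volume must be > 0 um^3, got {volume_um3}")
    molar = n_molecules / (volume_um3 * 1e-15 * Avogadro)
    return molar * 1e9


def surface_density(n_molecules: float, area_um2: float) -> float:
    """Receptor surface density in molecules per um^2, rounded to one decimal."""
    if n_molecules < 0:
        raise ValueError(f"copy number must be >= 0, got {n_molecules}")
    if area_um2 <= 0:
        raise ValueError(f"surface area must be > 0 um^2, got {area_um2}")
    return round(n_molecules / area_um2, 1)


@dataclass(frozen=True)
class CellTypeContext:
    """Named protein-abundance context for one cell type.

    ``abundances`` maps protein name to cytoplasmic concentration in nM;
    ratio-scale entries (see :data:`RATIO_SCALE_PROTEINS`) are stored in
    ``ratios`` as fold relative to the reference cell type and resolved with
    :meth:`resolved_abundances`.  Proteins in ``absent`` are present at exactly
    zero concentration.
    """

    name: str
    cytoplasmic_volume_um3: float
    surface_area_um2: float
    abundances_nM: dict[str, float]
    ratios: dict[str, float] = field(default_factory=dict)
    absent: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.cytoplasmic_volume_um3 <= 0:
            raise ValueError(f"{self.name}: cytoplasmic volume must be > 0")
        if self.surface_area_um2 <= 0:
            raise ValueError(f"{self.name}: surface area must be > 0")
        for prot, conc in self.abundances_nM.items():
            if conc < 0:
                raise ValueError(f"{self.name}: negative abundance for {prot}")
        for prot in self.absent:
            if self.abundances_nM.get(prot, 0.0) != 0.0:
                raise ValueError(
                    f"{self.name}: protein {prot!r} flagged absent but has "
                    f"non-zero abundance"
                )

    def resolved_abundances(
        self, reference: dict[str, float] | None = None
    ) -> dict[str, float]:
        """Abundances in nM with ratio-scale entries resolved to absolute values."""
        reference = REFERENCE_CONCENTRATIONS_NM if reference is None else reference
        out = dict(self.abundances_nM)
        for prot, ratio in self.ratios.items():
            out[prot] = ratio * reference[prot]
        for prot in self.absent:
            out[prot] = 0.0
        return out

    def concentration(self, protein: str) -> float:
        """Resolved concentration (nM) of a single protein."""
        if protein in self.absent:
            return 0.0
        try:
            return self.resolved_abundances()[protein]
        except KeyError:
            raise KeyError(
                f"protein {protein!r} not present in context {self.name!r}"
            ) from None

    def with_abundance(self, protein: str, value_nM: float) -> "CellTypeContext":
        """Copy of this context with one protein set to an absolute value (nM)."""
        if value_nM < 0:
            raise ValueError("abundance must be >= 0 nM")
        abund = dict(self.abundances_nM)
        ratios = dict(self.ratios)
        if protein in ratios:
            ratios[protein] = value_nM / REFERENCE_CONCENTRATIONS_NM[protein]
        else:
            abund[protein] = value_nM
        absent = frozenset(p for p in self.absent if p != protein or value_nM == 0.0)
        return CellTypeContext(
            self.name, self.cytoplasmic_volume_um3, self.surface_area_um2,
            abund, ratios, absent,
        )


def make_table1_contexts() -> list[CellTypeContext]:
    """The three measured cell-type contexts (mCFU-E, BaF3-EpoR, 32D-EpoR).

    Central values only; measurement uncertainties are not propagated into the
    kinetic model.  Gab1/Gab2 abundances are carried for reporting even though
    the receptor module omits Gab adaptors from the fast binding equilibrium.
    """
    nom = NOMINAL_CONCENTRATIONS_NM
    mcfue = CellTypeContext(
        name="mCFU-E",
        cytoplasmic_volume_um3=399.0,
        surface_area_um2=378.5,
        abundances_nM={
            "EpoR": 4.16, "AKT": 407.0, "PI3K": 12.7, "SHIP1": 15.4,
            "PTEN": 10.4, "PDK1": 545.0, "Gab1": 20.8, "Gab2": 0.0,
            "Ras": 3530.0, "Raf": 1340.0, "MEK": 1460.0, "ERK": 1140.0,
            "S6": 5340.0, "SHP1": nom["SHP1"], "Sos": nom["Sos"],
            "PIP2": nom["PIP2"], "DUSP": nom["DUSP_mCFU-E"],
        },
        ratios={"mTOR": 1.0, "Rictor": 1.0, "Raptor": 1.0, "RSK": 1.0},
        absent=frozenset({"Gab2"}),
    )
    baf3 = CellTypeContext(
        name="BaF3-EpoR",
        cytoplasmic_volume_um3=1400.0,
        surface_area_um2=600.3,
        abundances_nM={
            "EpoR": 18.62, "AKT": 510.0, "PI3K": 12.4, "SHIP1": 84.2,
            "PTEN": 107.4, "PDK1": 763.0, "Gab1": 0.0, "Gab2": 30.0,
            "Ras": 9531.0, "Raf": 3886.0, "MEK": 4380.0, "ERK": 2964.0,
            "S6": 2590.0, "SHP1": nom["SHP1"], "Sos": nom["Sos"],
            "PIP2": nom["PIP2"], "DUSP": nom["DUSP_BaF3-EpoR"],
        },
        ratios={"mTOR": 6.18, "Rictor": 4.57, "Raptor": 3.08, "RSK": 7.4},
        absent=frozenset({"Gab1"}),
    )
    d32 = CellTypeContext(
        name="32D-EpoR",
        cytoplasmic_volume_um3=1406.0,
        surface_area_um2=607.0,
        abundances_nM={
            "EpoR": 16.76, "AKT": 607.7, "PI3K": 14.3, "SHIP1": 127.8,
            "PTEN": 96.8, "PDK1": 1554.5, "Gab1": 0.0, "Gab2": 1.1,
            "Ras": 7855.4, "Raf": 7807.3, "MEK": 4743.9, "ERK": 2326.1,
            "S6": 4531.8, "SHP1": nom["SHP1"], "Sos": nom["Sos"],
            "PIP2": nom["PIP2"], "DUSP": nom["DUSP_32D-EpoR"],
        },
        ratios={"mTOR": 1.8, "Rictor": 0.19, "Raptor": 2.3, "RSK": 2.8},
        absent=frozenset({"Gab1"}),
    )
    return [mcfue, baf3, d32]


def make_hcfue_like_context(
    copy_numbers: dict[str, float],
    volume_um3: float,
    surface_area_um2: float,
    name: str = "hCFU-E-like",
    ratios: dict[str, float] | None = None,
) -> CellTypeContext:
    """Build a context for a new cell type from per-cell copy numbers.

    This is the workflow used to transplant the calibrated model to primary
    human erythroid progenitors: proteome-derived copy numbers per cell are
    converted to cytoplasmic concentrations with the measured cell volume.
    Components missing from ``copy_numbers`` fall back to the nominal pools
    (SHP1, Sos, PIP2, DUSP at the mCFU-E level).
    """
    abund = {
        prot: copy_number_to_concentration(n, volume_um3)
        for prot, n in copy_numbers.items()
    }
    nom = NOMINAL_CONCENTRATIONS_NM
    abund.setdefault("SHP1", nom["SHP1"])
    abund.setdefault("Sos", nom["Sos"])
    abund.setdefault("PIP2", nom["PIP2"])
    abund.setdefault("DUSP", nom["DUSP_mCFU-E"])
    absent = frozenset(p for p, v in abund.items() if v == 0.0)
    if ratios is None:
        ratios = {p: 1.0 for p in RATIO_SCALE_PROTEINS}
    return CellTypeContext(
        name=name,
        cytoplasmic_volume_um3=volume_um3,
        surface_area_um2=surface_area_um2,
        abundances_nM=abund,
        ratios=ratios,
        absent=absent,
    )
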