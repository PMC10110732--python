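"""Liquid junction potential via the Henderson (stationary Nernst-Planck)
approximation.

At the interface of two solutions, ions diffuse at different rates set by
their limiting mobilities, producing a steady potential difference. Under
the Henderson assumption of a linear concentration profile across the
junction the stationary Nernst-Planck flux equations integrate to

    V = (RT/F) * [ sum_i (z_i/|z_i|) u_i (c_i^b - c_i^p)
                   / sum_i |z_i| u_i (c_i^b - c_i^p) ]
        * ln( sum_i |z_i| u_i c_i^p / sum_i |z_i| u_i c_i^b ),

with u_i the mobility (taken proportional to lambda_i/|z_i|, lambda_i the
limiting molar ionic conductivity), c^p pipette and c^b bath concentrations.
The sign convention is pipette-relative-to-bath: for a K-gluconate internal
against a NaCl-rich bath the result is positive (~+15 mV), the value by
which uncorrected voltage readings overestimate the true membrane
potential. Identical solutions give exactly 0 and swapping the solutions
flips the sign.

Mobility table: limiting molar ionic conductivities at 25 degC in
S*cm^2/mol, inorganic ions from standard physical-chemistry tabulations
(CRC Handbook); organic anions (gluconate, HEPES, ATP/GTP, EGTA) from the
values commonly used by junction-potential calculators (Barry & Lynch-style
tables). Organic-anion mobilities vary across sources — entries are
user-overridable and that variation dominates the uncertainty (about
+/-1 mV for K-gluconate internals).

Salt speciation is handled by a documented dissociation map (K-gluconate ->
K+ + gluconate-, MgCl2 -> Mg2+ + 2 Cl-, ...). Neutral species (glucose,
sucrose, myo-inositol) are ignored. HEPES is a buffer: at pH 7.3 only the
fraction 1/(1 + 10^(pKa - pH)) (pKa 7.48) is anionic, and that fraction is
assumed titrated with KOH, contributing matching K+. EGTA is counted as the
divalent anion with two K+ counter-ions; Na-GTP is treated as the disodium
salt. Every inclusion/exclusion is visible in the per-species breakdown.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError

log = logging.getLogger(__name__)

R_GAS = 8.31446  # J/(mol K)
FARADAY = 96485.332  # C/mol

HEPES_PKA = 7.48  # at 25 degC
DEFAULT_PH = 7.3


@dataclass(frozen=True)
class IonSpecies:
    name: str
    charge: int
    conductivity: float  # limiting molar ionic conductivity, S*cm^2/mol

    @property
    def mobility(self) -> float:
        return self.conductivity / abs(self.charge)


# limiting molar ionic conductivities at 25 degC, S*cm^2/mol
ION_TABLE: dict[str, IonSpecies] = {
    s.name: s
    for s in [
        IonSpecies("K", +1, 73.48),
        IonSpecies("Na", +1, 50.08),
        IonSpecies("Cl", -1, 76.31),
        IonSpecies("Mg", +2, 106.0),
        IonSpecies("Ca", +2, 118.94),
        IonSpecies("HCO3", -1, 44.5),
        IonSpecies("H2PO4", -1, 33.0),
        IonSpecies("SO4", -2, 160.0),
        IonSpecies("gluconate", -1, 24.3),
        IonSpecies("HEPES-", -1, 22.05),
        IonSpecies("EGTA", -2, 48.0),  # approximate; tiny concentrations
        IonSpecies("ATP", -2, 47.0),  # approximate nucleotide mobility
        IonSpecies("GTP", -2, 47.0),
        IonSpecies("pyruvate", -1, 40.0),
        IonSpecies("ascorbate", -1, 33.0),
    ]
}

NEUTRAL_SPECIES = {"glucose", "sucrose", "myo-inositol", "HEPES0"}


def _hepes_anion_fraction(pH: float) -> float:
    return 1.0 / (1.0 + 10.0 ** (HEPES_PKA - pH))


def _dissociation_map(pH: float) -> dict[str, dict[str, float]]:
    """Moles of each ion released per mole of named compound."""
    f = _hepes_anion_fraction(pH)
    return {
        "KCl": {"K": 1, "Cl": 1},
        "NaCl": {"Na": 1, "Cl": 1},
        "K-gluconate": {"K": 1, "gluconate": 1},
        "MgCl2": {"Mg": 1, "Cl": 2},
        "CaCl2": {"Ca": 1, "Cl": 2},
        "MgSO4": {"Mg": 1, "SO4": 1},
        "NaH2PO4": {"Na": 1, "H2PO4": 1},
        "NaHCO3": {"Na": 1, "HCO3": 1},
        # buffer: anionic fraction at this pH, titrated with KOH
        "HEPES": {"HEPES-": f, "K": f},
        "EGTA": {"EGTA": 1, "K": 2},  # titrated to the divalent anion
        "Mg-ATP": {"Mg": 1, "ATP": 1},
        "Na-GTP": {"Na": 2, "GTP": 1},  # disodium salt
        "Na-Pyruvate": {"Na": 1, "pyruvate": 1},
        "ascorbate": {"Na": 1, "ascorbate": 1},  # sodium ascorbate
        "glucose": {},
        "sucrose": {},
        "myo-inositol": {},
    }


@dataclass
class Solution:
    """Fully speciated ionic solution: ion name -> concentration (mM)."""

    ions: dict[str, float]
    ignored: list = field(default_factory=list)
    table: dict[str, IonSpecies] = field(default_factory=lambda: dict(ION_TABLE))

    @classmethod
    def from_composition(
        cls,
        composition: dict[str, float],
        pH: float = DEFAULT_PH,
        extra_ions: dict[str, IonSpecies] | None = None,
    ) -> "Solution":
        """Build a Solution from salt concentrations via the dissociation map.

        ``composition`` maps compound names (as printed on a recipe, e.g.
        ``{"K-gluconate": 140, "KCl": 10}``) to mM. Unknown compounds raise;
        neutral ones are recorded in ``ignored``.
        """
        dmap = _dissociation_map(pH)
        table = dict(ION_TABLE)
        if extra_ions:
            table.update(extra_ions)
        ions: dict[str, float] = {}
        ignored: list[str] = []
        for name, mM in composition.items():
            if mM < 0:
                raise ParameterError(f"negative concentration for {name}")
            if name in table:  # already an ion
                ions[name] = ions.get(name, 0.0) + mM
                continue
            if name not in dmap:
                raise ParameterError(
                    f"unknown compound {name!r}: not an ion in the mobility table "
                    "and not in the dissociation map"
                )
            stoich = dmap[name]
            if not stoich:
                ignored.append(name)
                log.info("ignoring neutral species %s (%.3g mM)", name, mM)
                continue
            for ion, mult in stoich.items():
                ions[ion] = ions.get(ion, 0.0) + mult * mM
        missing = [i for i in ions if i not in table]
        if missing:
            raise ParameterError(
                f"species missing from the mobility table: {missing}; supply "
                "them via extra_ions"
            )
        return cls(ions=ions, ignored=ignored, table=table)

    def charge_imbalance(self) -> float:
        """Net charge over total ionic charge (0 = electroneutral)."""
        net = sum(self.table[i].charge * c for i, c in self.ions.items())
        tot = sum(abs(self.table[i].charge) * c for i, c in self.ions.items())
        return net / tot if tot else 0.0


@dataclass
class LJPResult:
    potential: float  # mV, pipette minus bath convention
    temperature_C: float
    contributions: dict  # ion -> dict of the Henderson sums' terms


def henderson_ljp(
    pipette: Solution, bath: Solution, temperature_C: float = 25.0
) -> LJPResult:
    """Henderson liquid junction potential, pipette relative to bath (mV)."""
    for label, sol in (("pipette", pipette), ("bath", bath)):
        imb = sol.charge_imbalance()
        if abs(imb) > 0.05:
            log.warning("%s solution charge imbalance %.1f%%", label, 100 * imb)

    table = dict(bath.table)
    table.update(pipette.table)
    names = sorted(set(pipette.ions) | set(bath.ions))
    num = den = s_pip = s_bath = 0.0
    contributions = {}
    for name in names:
        sp = table[name]
        cp = pipette.ions.get(name, 0.0)
        cb = bath.ions.get(name, 0.0)
        u = sp.mobility
        z = sp.charge
        dterm = u * (z / abs(z)) * (cb - cp)
        eterm = u * abs(z) * (cb - cp)
        num += dterm
        den += eterm
        s_pip += u * abs(z) * cp
        s_bath += u * abs(z) * cb
        contributions[name] = {
            "charge": z, "mobility": u, "pipette_mM": cp, "bath_mM": cb,
        }
    if s_pip <= 0 or s_bath <= 0:
        raise ParameterError("both solutions need nonzero ionic content")
    T = temperature_C + 273.15
    if den == 0.0:
        v = 0.0
    else:
        v = (R_GAS * T / FARADAY) * (num / den) * math.log(s_pip / s_bath) * 1000.0
    return LJPResult(potential=v, temperature_C=temperature_C,
                     contributions=contributions)


# the printed recording solutions (mM)
PAPER_INTERNAL = {
    "K-gluconate": 140.0,
    "KCl": 10.0,
    "MgCl2": 1.0,
    "HEPES": 10.0,
    "EGTA": 0.02,
    "Mg-ATP": 3.0,
    "Na-GTP": 0.5,
}

PAPER_ACSF = {
    "KCl": 3.0,
    "NaH2PO4": 1.25,
    "MgSO4": 3.0,
    "NaHCO3": 26.0,
    "NaCl": 124.0,
    "glucose": 10.0,
    "CaCl2": 2.0,  # added to the bath shortly before recording
}


def paper_solutions(pH: float = DEFAULT_PH) -> tuple[Solution, Solution]:
    """The K-gluconate internal and ACSF bath used by the recordings."""
    return (
        Solution.from_composition(PAPER_INTERNAL, pH=pH),
        Solution.from_composition(PAPER_ACSF, pH=pH),
    )
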