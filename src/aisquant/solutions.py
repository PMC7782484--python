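"""Liquid junction potential (LJP) from ionic solution compositions.

Whole-cell potentials recorded with a K-gluconate pipette in bicarbonate
ACSF are offset by the junction potential that forms where the two
solutions meet.  The offset is computed here with the generalized
Henderson equation using limiting ionic mobilities, after decomposing the
salt recipes into free ions (fully dissociated strong salts; fractional
ionization for the HEPES buffer from its pKa; divalent chelator and
nucleotide anions taken from a bundled mobility table).

The sign convention is pipette-minus-bath: a K-gluconate pipette against a
NaCl-rich bath yields a *negative* LJP, and recorded potentials are
corrected by subtracting it (``apply_ljp_correction``).

Mobilities are stored as limiting equivalent conductivities
(S cm^2 eq^-1, 25 C); the Henderson equation only needs relative
mobilities ``u_i = lambda_i / |z_i|`` so the unit system cancels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "IonicSolution", "ljp_henderson", "apply_ljp_correction",
    "ION_TABLE", "SALT_TABLE", "PIPETTE_KGLUCONATE_MM", "ACSF_MM",
    "HEPES_PKA",
]

R_GAS = 8.314462618      # J / (mol K)
FARADAY = 96485.33212    # C / mol
HEPES_PKA = 7.48         # sulfonate/piperazine N-H, 25 C

# ion -> (valence z, limiting equivalent conductivity lambda0, S cm^2/eq)
ION_TABLE = {
    "K": (1, 73.5),
    "Na": (1, 50.1),
    "Li": (1, 38.7),
    "Cs": (1, 77.3),
    "Mg": (2, 53.0),
    "Ca": (2, 59.5),
    "Cl": (-1, 76.3),
    "Br": (-1, 78.1),
    "F": (-1, 55.4),
    "HCO3": (-1, 44.5),
    "H2PO4": (-1, 33.0),
    "SO4": (-2, 80.0),
    "gluconate": (-1, 24.3),
    "acetate": (-1, 40.9),
    "methanesulfonate": (-1, 48.8),
    "HEPES": (-1, 22.0),
    "MES": (-1, 26.8),
    "EGTA": (-2, 24.0),
    "ATP": (-2, 24.0),
    "GTP": (-2, 24.0),
}

# salt name -> {ion: stoichiometry}; neutral species map to {}
SALT_TABLE = {
    "K-gluconate": {"K": 1, "gluconate": 1},
    "KCl": {"K": 1, "Cl": 1},
    "NaCl": {"Na": 1, "Cl": 1},
    "CsCl": {"Cs": 1, "Cl": 1},
    "NaH2PO4": {"Na": 1, "H2PO4": 1},
    "NaHCO3": {"Na": 1, "HCO3": 1},
    "MgCl2": {"Mg": 1, "Cl": 2},
    "CaCl2": {"Ca": 1, "Cl": 2},
    "MgSO4": {"Mg": 1, "SO4": 1},
    "HEPES": "hepes_buffer",          # fractional ionization, see from_recipe
    "EGTA": {"EGTA": 1},
    "Mg-ATP": {"Mg": 1, "ATP": 1},
    "Na2-GTP": {"Na": 2, "GTP": 1},
    "glucose": {},
    "sucrose": {},
}

#: the standard K-gluconate intracellular recipe (mM)
PIPETTE_KGLUCONATE_MM = {
    "K-gluconate": 140.0, "KCl": 3.0, "NaCl": 4.0, "HEPES": 10.0,
    "EGTA": 0.2, "Mg-ATP": 2.0, "Na2-GTP": 0.1,
}

#: standard bicarbonate-buffered artificial cerebrospinal fluid (mM)
ACSF_MM = {
    "NaCl": 125.0, "KCl": 2.5, "NaH2PO4": 1.25, "NaHCO3": 25.0,
    "MgCl2": 1.0, "CaCl2": 2.0, "glucose": 25.0,
}


@dataclass
class IonicSolution:
    """Free-ion composition: ion name -> concentration (mM).

    Valences and mobilities are looked up in :data:`ION_TABLE`.  Build
    from a salt recipe with :meth:`from_recipe`.
    """

    ions_mM: dict
    name: str = ""

    def __post_init__(self):
        for ion, c in self.ions_mM.items():
            if ion not in ION_TABLE:
                raise KeyError(f"no mobility entry for ion '{ion}'")
            if c < 0:
                raise ValueError(f"negative concentration for '{ion}'")
        imbalance = sum(ION_TABLE[i][0] * c for i, c in self.ions_mM.items())
        total = sum(abs(ION_TABLE[i][0]) * c for i, c in self.ions_mM.items())
        if total > 0 and abs(imbalance) > 0.05 * total:
            warnings.warn(
                f"solution '{self.name}' violates electroneutrality by "
                f"{imbalance:+.1f} mEq (>{5}% of total charge)", stacklevel=2)

    @classmethod
    def from_recipe(cls, salts_mM: dict, name: str = "", pH: float = 7.3):
        """Decompose a salt recipe (mM) into free ions.

        HEPES contributes its anionic fraction ``1 / (1 + 10**(pKa - pH))``;
        the neutral zwitterion carries no current and is dropped.  Unknown
        salts raise; neutral species (glucose, sucrose) are skipped.
        """
        ions: dict = {}
        for salt, c in salts_mM.items():
            if salt not in SALT_TABLE:
                raise KeyError(f"unknown salt '{salt}'")
            stoich = SALT_TABLE[salt]
            if stoich == "hepes_buffer":
                frac = 1.0 / (1.0 + 10.0 ** (HEPES_PKA - pH))
                ions["HEPES"] = ions.get("HEPES", 0.0) + frac * c
                continue
            for ion, k in stoich.items():
                ions[ion] = ions.get(ion, 0.0) + k * c
        return cls(ions_mM=ions, name=name)


def _conductance_sums(solution: IonicSolution):
    """Per-ion (z, u, c) with u = lambda0/|z| (relative mobility)."""
    out = []
    for ion, c in solution.ions_mM.items():
        z, lam = ION_TABLE[ion]
        out.append((ion, z, lam / abs(z), c))
    return out


def ljp_henderson(pipette: IonicSolution, bath: IonicSolution,
                  T_K: float = 298.15) -> float:
    """Generalized Henderson junction potential, pipette minus bath (mV).

    V = -(RT/F) * [sum z_i u_i (c_i^bath - c_i^pip)
                   / sum z_i^2 u_i (c_i^bath - c_i^pip)]
               * ln(sum z_i^2 u_i c_i^pip / sum z_i^2 u_i c_i^bath)

    where the leading minus sign expresses the result as the potential of
    the pipette solution relative to the bath.  Identical solutions give
    exactly 0; the function is antisymmetric under exchanging the two
    solutions.
    """
    terms = {}
    for sol, key in ((pipette, "a"), (bath, "b")):
        for ion, z, u, c in _conductance_sums(sol):
            rec = terms.setdefault(ion, {"z": z, "u": u, "a": 0.0, "b": 0.0})
            if rec["z"] != z:
                raise ValueError(f"conflicting valence for ion '{ion}'")
            rec[key] += c
    num = den = ga = gb = 0.0
    for rec in terms.values():
        z, u, ca, cb = rec["z"], rec["u"], rec["a"], rec["b"]
        num += z * u * (cb - ca)
        den += z * z * u * (cb - ca)
        ga += z * z * u * ca
        gb += z * z * u * cb
    if ga <= 0 or gb <= 0:
        raise ValueError("a solution with no charge carriers has no junction")
    if den == 0 or ga == gb:
        if abs(num) < 1e-12 and abs(ga - gb) < 1e-9 * max(ga, gb):
            return 0.0
    if den == 0:
        raise ValueError("degenerate Henderson denominator")
    v_volts = (R_GAS * T_K / FARADAY) * (num / den) * math.log(ga / gb)
    return -1000.0 * v_volts


def apply_ljp_correction(recorded_mV, ljp_mV):
    """Correct recorded potentials post-hoc: ``V_true = V_recorded - LJP``."""
    import numpy as np
    return np.asarray(recorded_mV, float) - ljp_mV
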