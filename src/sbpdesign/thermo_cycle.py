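"""Binding thermodynamic cycle bookkeeping.

ddG_bind = dG*_bind - dG_bind
        = (G_C* - G_P* - G_L) - (G_C - G_P - G_L)
        = G_C* - G_P* - G_C + G_P

where G_C / G_P / G_L are the complex, apo-protein and free-ligand state
energies and starred quantities refer to the mutated system. The free-ligand
energy cancels, so ddG is computable even when G_L is unknown; dG_bind is
not, and asking for it without G_L raises rather than silently assuming 0.

A negative ddG means the mutant binds more favorably than the original.
Important pairing contract: the unstarred (wild-type) energies must be taken
*before* any minimization of the wild-type structure — minimizing the apo
protein first would bias G_P and corrupt the cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "UNKNOWN",
    "ThermodynamicCycle",
    "UnknownLigandEnergyError",
    "delta_g_bind",
    "ddg_bind",
    "is_favorable",
    "cycle_report",
]


class _Unknown:
    """Sentinel for 'energy not measured' (distinct from 0)."""

    def __repr__(self) -> str:
        return "UNKNOWN"


UNKNOWN = _Unknown()


class UnknownLigandEnergyError(ValueError):
    """dG_bind requested without a ligand energy; use ddg_bind instead."""


@dataclass
class ThermodynamicCycle:
    """The five state energies of the mutation/binding double cycle."""

    G_C: float  # wild-type complex
    G_P: float  # wild-type apo protein
    G_C_star: float  # mutant complex
    G_P_star: float  # mutant apo protein
    G_L: float | _Unknown = UNKNOWN  # free ligand (cancels in ddG)

    def __post_init__(self):
        for name in ("G_C", "G_P", "G_C_star", "G_P_star"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if not isinstance(self.G_L, _Unknown) and not math.isfinite(self.G_L):
            raise ValueError(f"G_L must be finite or UNKNOWN, got {self.G_L!r}")

    def swapped(self) -> "ThermodynamicCycle":
        """Exchange starred and unstarred states (negates ddG)."""
        return ThermodynamicCycle(
            G_C=self.G_C_star,
            G_P=self.G_P_star,
            G_C_star=self.G_C,
            G_P_star=self.G_P,
            G_L=self.G_L,
        )


def delta_g_bind(g_c: float, g_p: float, g_l: float) -> float:
    """Binding free energy of one pairing: G_C - (G_P + G_L)."""
    if isinstance(g_l, _Unknown):
        raise UnknownLigandEnergyError(
            "free-ligand energy unknown; dG_bind is undefined but ddg_bind "
            "does not need it"
        )
    for name, v in (("G_C", g_c), ("G_P", g_p), ("G_L", g_l)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite")
    return g_c - (g_p + g_l)


def ddg_bind(cycle: ThermodynamicCycle) -> float:
    """Change in binding free energy upon mutation: G_C* - G_P* - G_C + G_P."""
    return cycle.G_C_star - cycle.G_P_star - cycle.G_C + cycle.G_P


def is_favorable(ddg: float) -> str:
    """'favorable' (ddg < 0), 'neutral' (ddg == 0) or 'unfavorable'."""
    if not math.isfinite(ddg):
        raise ValueError("ddG must be finite")
    if ddg < 0:
        return "favorable"
    if ddg == 0:
        return "neutral"
    return "unfavorable"


def cycle_report(
    energies: dict[str, float],
    *,
    provenance: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Tabulate labelled state energies with provenance.

    ``provenance`` marks each state as "computed" (scored by this package) or
    "supplied" (taken from an external source); unlisted states default to
    "computed". Returns an empty frame for empty input.
    """
    provenance = provenance or {}
    rows = [
        {
            "state": label,
            "energy": value,
            "provenance": provenance.get(label, "computed"),
        }
        for label, value in energies.items()
    ]
    return pd.DataFrame(rows, columns=["state", "energy", "provenance"])
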