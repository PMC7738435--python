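"""Fermentation performance metrics: solid removal, VFA as COD, CH4 yield.

COD conversion factors are derived from full-oxidation stoichiometry rather
than hard-coded: for CxHyOz the theoretical oxygen demand is
(x + y/4 - z/2) mol O2 per mol compound, i.e. 32*(x + y/4 - z/2)/MW g COD
per g compound. Molecular weights use nominal integer atomic masses
(C=12, H=1, O=16), the convention under which acetate's factor is exactly
64/60 = 1.0667 g COD/g.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "PerformanceRecord",
    "COMPOUND_FORMULAS",
    "thod_factor",
    "solid_removal",
    "vfa_as_cod",
    "ch4_yield",
    "vs_fed_from_schedule",
    "read_performance_table",
    "write_performance_table",
]

# C, H, O atom counts for each supported fermentation product.
COMPOUND_FORMULAS: dict[str, tuple[int, int, int]] = {
    "acetic": (2, 4, 2),       # CH3COOH
    "propionic": (3, 6, 2),    # CH3CH2COOH
    "butyric": (4, 8, 2),      # CH3(CH2)2COOH
    "isobutyric": (4, 8, 2),   # (CH3)2CHCOOH
    "ethanol": (2, 6, 1),
    "propanol": (3, 8, 1),
    "isopropanol": (3, 8, 1),
    "butanol": (4, 10, 1),
}

_ATOMIC_MASS = {"C": 12, "H": 1, "O": 16}


def thod_factor(component: str) -> float:
    """Theoretical oxygen demand [g COD per g compound] from stoichiometry."""
    try:
        c, h, o = COMPOUND_FORMULAS[component]
    except KeyError:
        raise ValueError(
            f"unknown component {component!r}; supported: {sorted(COMPOUND_FORMULAS)}"
        ) from None
    mw = c * _ATOMIC_MASS["C"] + h * _ATOMIC_MASS["H"] + o * _ATOMIC_MASS["O"]
    o2_mol = c + h / 4 - o / 2
    return 32 * o2_mol / mw


def solid_removal(vss_in: float, vss_out: float) -> float:
    """Solid removal efficiency (VSSin - VSSout) / VSSin, as a fraction.

    A negative value (effluent solids above feed solids) is reported with a
    warning rather than clipped.
    """
    if vss_in <= 0:
        raise ValueError("vss_in must be positive")
    if vss_out < 0:
        raise ValueError("vss_out must be non-negative")
    eff = (vss_in - vss_out) / vss_in
    if eff < 0:
        warnings.warn(
            f"solid removal is negative ({eff:.3g}): effluent VSS exceeds feed VSS",
            stacklevel=2,
        )
    return eff


def vfa_as_cod(
    components: Mapping[str, float], already_cod: bool = False
) -> tuple[float, dict[str, float]]:
    """Convert per-component VFA/alcohol concentrations [mg/L as the compound]
    to COD equivalents [mg COD/L].

    Returns (total, per-component map). With ``already_cod=True`` the inputs
    are taken as mg COD/L and passed through (factor 1), for tables already
    reported in COD units.
    """
    per: dict[str, float] = {}
    for name, conc in components.items():
        factor = 1.0 if already_cod else thod_factor(name)
        if already_cod and name not in COMPOUND_FORMULAS:
            raise ValueError(
                f"unknown component {name!r}; supported: {sorted(COMPOUND_FORMULAS)}"
            )
        if conc < 0:
            raise ValueError(f"negative concentration for {name!r}")
        per[name] = conc * factor
    return sum(per.values()), per


def ch4_yield(ch4_cumulative_mmol: float, vs_fed_total_g: float) -> float:
    """Methane yield [mmol CH4 per g volatile solids fed]."""
    if vs_fed_total_g <= 0:
        raise ValueError("vs_fed_total_g must be positive")
    if ch4_cumulative_mmol < 0:
        raise ValueError("ch4_cumulative_mmol must be non-negative")
    return ch4_cumulative_mmol / vs_fed_total_g


def vs_fed_from_schedule(event_volume_ml: float, n_events: int, cf_g_per_l: float) -> float:
    """Total volatile solids fed [g] over a feeding schedule:
    sum over events of (event volume [mL] x feed VSS [g/L]) / 1000."""
    if event_volume_ml < 0 or n_events < 0 or cf_g_per_l < 0:
        raise ValueError("schedule quantities must be non-negative")
    return event_volume_ml * n_events * cf_g_per_l / 1000.0


@dataclass(frozen=True)
class PerformanceRecord:
    """One condition/day's measured performance inputs."""

    condition: str
    day: float
    vss_in_g_per_l: float
    vss_out_g_per_l: float
    vfa_components_mg_per_l: dict[str, float] = field(default_factory=dict)
    ch4_cumulative_mmol: float = 0.0
    vs_fed_total_g: float = 0.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.vfa_components_mg_per_l.values()):
            raise ValueError("VFA concentrations must be non-negative")

    def metrics(self, vfa_already_cod: bool = False) -> dict[str, float]:
        """Solid removal, total VFA as mg COD/L, and CH4 yield for this record."""
        total_cod, _ = vfa_as_cod(self.vfa_components_mg_per_l, already_cod=vfa_already_cod)
        out = {
            "solid_removal": solid_removal(self.vss_in_g_per_l, self.vss_out_g_per_l),
            "vfa_total_mg_cod_per_l": total_cod,
        }
        if self.vs_fed_total_g > 0:
            out["ch4_yield_mmol_per_g_vs"] = ch4_yield(
                self.ch4_cumulative_mmol, self.vs_fed_total_g
            )
        return out


_COMPONENT_PREFIX = "vfa_"


def read_performance_table(path: str | Path) -> list[PerformanceRecord]:
    """Read performance inputs from TSV keyed by condition and day.

    Component columns are named ``vfa_<name>`` (mg/L as the compound).
    """
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    records = []
    comp_cols = [c for c in df.columns if c.startswith(_COMPONENT_PREFIX)]
    for _, r in df.iterrows():
        comps = {c[len(_COMPONENT_PREFIX):]: float(r[c]) for c in comp_cols if r[c] != ""}
        records.append(
            PerformanceRecord(
                condition=str(r["condition"]),
                day=float(r["day"]),
                vss_in_g_per_l=float(r["vss_in_g_per_l"]),
                vss_out_g_per_l=float(r["vss_out_g_per_l"]),
                vfa_components_mg_per_l=comps,
                ch4_cumulative_mmol=float(r.get("ch4_cumulative_mmol", 0.0) or 0.0),
                vs_fed_total_g=float(r.get("vs_fed_total_g", 0.0) or 0.0),
            )
        )
    return records


def write_performance_table(
    records: list[PerformanceRecord], path: str | Path, vfa_already_cod: bool = False
) -> None:
    """Write computed metrics as TSV keyed by condition and day."""
    rows = []
    for rec in records:
        row = {"condition": rec.condition, "day": rec.day}
        row.update(rec.metrics(vfa_already_cod=vfa_already_cod))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
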