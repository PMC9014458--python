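"""Boltzmann equilibrium fractions and population-weighted observables.

A conformer M with relative Gibbs free energy dG_M in an ensemble
equilibrated at temperature T has equilibrium fraction

    x_M = exp(-dG_M / RT) / sum_N exp(-dG_N / RT)

with R = 0.0019872 kcal mol^-1 K^-1.  Ensemble observables (vertical
and adiabatic detachment energies here, but any per-conformer scalar)
are x_M-weighted averages.  Report tables display only conformers with
x_M above a population threshold (default 0.01), but fractions and
averages are always computed over the full record set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import HARTREE_TO_KCAL, R_KCAL


class UnitError(ValueError):
    pass


def relative_free_energies(
    absolute_g: Sequence[tuple[str, float]], units: str = "kcal/mol"
) -> list[tuple[str, float]]:
    """Relative Gibbs free energies: subtract the minimum, convert to kcal/mol.

    ``units`` must be ``"kcal/mol"`` or ``"hartree"``.
    """
    if not absolute_g:
        raise ValueError("empty energy collection")
    if units not in ("kcal/mol", "hartree"):
        raise UnitError(f"undeclared/unsupported unit {units!r}")
    labels = [l for l, _ in absolute_g]
    g = np.array([e for _, e in absolute_g], dtype=float)
    if units == "hartree":
        g = g * HARTREE_TO_KCAL
    g = g - g.min()
    return list(zip(labels, g.tolist()))


def equilibrium_fractions(
    delta_g: Sequence[float], temperature: float = 298.15
) -> np.ndarray:
    """Boltzmann populations of conformers from relative free energies.

    Energies are shifted by their minimum before exponentiation
    (overflow safety); the result sums to 1 to machine precision.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    dg = np.asarray(delta_g, dtype=float)
    if dg.size == 0:
        raise ValueError("empty free-energy collection")
    w = np.exp(-(dg - dg.min()) / (R_KCAL * temperature))
    return w / w.sum()


def weighted_observable(
    values: Sequence[float], weights: Sequence[float], renormalize: bool = True
) -> float:
    """Population-weighted average of a per-conformer observable.

    With ``renormalize`` the weights are divided by their sum (useful
    when weighting by a truncated, rounded x_M column that does not sum
    to exactly 1); without it the plain weighted sum is returned.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    s = float(np.dot(w, v))
    return s / total if renormalize else s


def incremental_shifts(series: Sequence[float]) -> list[float]:
    """Consecutive differences series[n] - series[n-1].

    Used for the stepwise increase of detachment energies with the
    number of bound waters.
    """
    s = np.asarray(series, dtype=float)
    if s.size < 2:
        raise ValueError("need at least two entries")
    return np.diff(s).tolist()


@dataclass
class ThermoRecord:
    """One row of a conformer thermochemistry table."""

    label: str
    delta_g: float  # kcal/mol, relative
    x_m: float = float("nan")
    vde: float = float("nan")  # eV
    ade: float = float("nan")  # eV
    displayed: bool = True

    def validate(self) -> None:
        if self.delta_g < 0:
            raise ValueError(f"{self.label}: relative free energy must be >= 0")
        if not (0.0 <= self.x_m <= 1.0 or np.isnan(self.x_m)):
            raise ValueError(f"{self.label}: x_m out of [0, 1]")
        if not (np.isnan(self.ade) or np.isnan(self.vde)) and self.ade > self.vde + 1e-9:
            import warnings

            warnings.warn(f"{self.label}: ADE {self.ade} exceeds VDE {self.vde}")


@dataclass
class ThermoTable:
    """Conformer table with equilibrium fractions and weighted averages."""

    records: list[ThermoRecord]
    temperature: float
    weighted_vde: float
    weighted_ade: float
    population_threshold: float = 0.01

    def fractions(self) -> dict[str, float]:
        return {r.label: r.x_m for r in self.records}

    def displayed_records(self) -> list[ThermoRecord]:
        return [r for r in self.records if r.displayed]

    def to_dataframe(self, displayed_only: bool = True) -> pd.DataFrame:
        recs = self.displayed_records() if displayed_only else self.records
        return pd.DataFrame(
            {
                "name": [r.label for r in recs],
                "dG": [r.delta_g for r in recs],
                "VDE": [r.vde for r in recs],
                "ADE": [r.ade for r in recs],
                "x_M": [r.x_m for r in recs],
            }
        )

    def format_table(self) -> str:
        """Report layout: dG to 1 decimal, energies to 2, x_M to 2."""
        df = self.to_dataframe()
        lines = ["name\tdG\tVDE\tADE\tx_M"]
        for _, r in df.iterrows():
            lines.append(
                f"{r['name']}\t{r['dG']:.1f}\t{r['VDE']:.2f}\t{r['ADE']:.2f}\t{r['x_M']:.2f}"
            )
        lines.append(
            f"weighted average\t\t{self.weighted_vde:.2f}\t{self.weighted_ade:.2f}\t"
        )
        return "\n".join(lines) + "\n"

    def write_tsv(self, path: str | Path) -> None:
        Path(path).write_text(self.format_table(), newline="\n")

    def summary(self) -> dict:
        return {
            "temperature_K": self.temperature,
            "population_threshold": self.population_threshold,
            "weighted_vde_eV": round(self.weighted_vde, 6),
            "weighted_ade_eV": round(self.weighted_ade, 6),
            "n_conformers": len(self.records),
            "n_displayed": len(self.displayed_records()),
        }


def build_thermo_table(
    records: Iterable[dict],
    temperature: float = 298.15,
    population_threshold: float = 0.01,
    units: str = "kcal/mol",
) -> ThermoTable:
    """Assemble a thermochemistry table from raw per-conformer records.

    Each record is a mapping with ``label``, ``delta_g`` (or absolute
    ``g`` in ``units``), and optional ``vde`` / ``ade`` in eV.
    Equilibrium fractions and weighted averages are computed over the
    *full* record set; the population threshold only controls which
    rows are displayed.
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    labels = [r["label"] for r in records]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate conformer labels")

    if all("delta_g" in r for r in records):
        rel = relative_free_energies(
            [(r["label"], float(r["delta_g"])) for r in records], units
        )
    elif all("g" in r for r in records):
        rel = relative_free_energies(
            [(r["label"], float(r["g"])) for r in records], units
        )
    else:
        raise ValueError("records must all carry 'delta_g' or all carry 'g'")
    dg = [e for _, e in rel]
    x = equilibrium_fractions(dg, temperature)
    vde = [float(r.get("vde", np.nan)) for r in records]
    ade = [float(r.get("ade", np.nan)) for r in records]
    w_vde = weighted_observable(vde, x) if not np.any(np.isnan(vde)) else float("nan")
    w_ade = weighted_observable(ade, x) if not np.any(np.isnan(ade)) else float("nan")

    out = []
    for lab, g, xm, v, a in zip(labels, dg, x, vde, ade):
        rec = ThermoRecord(lab, g, float(xm), v, a, displayed=xm >= population_threshold)
        rec.validate()
        out.append(rec)
    return ThermoTable(out, temperature, w_vde, w_ade, population_threshold)


def read_thermo_tsv(path: str | Path) -> list[dict]:
    """Read per-conformer records from TSV/CSV with a header line.

    Recognized columns: label/name, delta_g/dG, g, vde/VDE, ade/ADE,
    x_m/x_M.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else None
    df = pd.read_csv(path, sep=sep, engine="python")
    rename = {}
    for col in df.columns:
        c = col.strip().lower()
        if c in ("label", "name"):
            rename[col] = "label"
        elif c in ("dg", "delta_g", "deltag"):
            rename[col] = "delta_g"
        elif c in ("x_m", "xm"):
            rename[col] = "x_m"
        elif c in ("vde", "ade", "g"):
            rename[col] = c
    df = df.rename(columns=rename)
    return df.to_dict(orient="records")
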