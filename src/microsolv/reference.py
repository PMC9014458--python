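"""Bundled reference data for microsolvated [dGMP - 2H]2- . nH2O.

Published per-conformer thermochemistry of the doubly deprotonated
2'-deoxyguanosine-5'-monophosphate dianion hydrated by n = 1-4 waters
at the CAM-B3LYP/6-31++G(d,p) level: relative Gibbs free energies
(kcal/mol), vertical/adiabatic detachment energies (eV) and printed
equilibrium fractions, together with the experimental NIPES detachment
energies and the BSSE-corrected water binding free energies per
cluster size.

The n = 0 experimental row is the bare-dianion value implied by the
measured first-water shift (VDE 1.80 - 0.50, ADE 1.55 - 0.50 eV).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_PKG = "microsolv.data"


def _read(name: str) -> pd.DataFrame:
    with resources.files(_PKG).joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_conformer_table(n: int) -> pd.DataFrame:
    """Per-conformer table for the n-water cluster (n = 1..4).

    Columns: name, dG (kcal/mol), VDE (eV), ADE (eV), x_M (printed,
    rounded to 2 decimals; the truncated x_M >= 0.01 set).
    """
    if n not in (1, 2, 3, 4):
        raise ValueError("reference tables exist for n = 1..4")
    return _read(f"table_n{n}.tsv")


def load_experimental() -> pd.DataFrame:
    """Experimental VDE/ADE (eV) vs number of waters, n = 0..4."""
    return _read("experimental.tsv")


def load_wbe() -> pd.DataFrame:
    """BSSE-corrected water binding free energies (kcal/mol), n = 1..4."""
    return _read("wbe.tsv")


def load_printed_aggregates() -> pd.DataFrame:
    """Printed weighted-average VDE/ADE (eV) per cluster size."""
    return _read("aggregates.tsv")
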