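"""Packaged fixture tables (transcribed from the published study tables)."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("herbqc.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_bbd_table() -> pd.DataFrame:
    """The 17-run Box-Behnken run table with measured responses and the
    printed overall-desirability (OD) column.

    Columns: run, X1 (first liquid-solid ratio, mL/g), X2 (first extraction
    time, min), X3 (second extraction time, min), CAGC and CAC (marker
    compound contents, mg/g), TSR (total solid ratio, g), OD.
    """
    return _load("table2.csv")


def load_compound_table() -> pd.DataFrame:
    """The 44 decoction constituents: adduct, measured/calculated m/z, ppm,
    molecular formula, name."""
    return _load("table3.csv")


def load_plasma_table() -> pd.DataFrame:
    """The 36 absorbed prototype/metabolite ions found in plasma, same
    columns as the compound table; metabolite names encode the parent and
    biotransformations."""
    return _load("table4.csv")
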