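"""Binding-parameter report tables in the conventional pharmacology layout.

Cells read ``mean ± SEM (K in display units)``: the estimate and its
across-experiment SEM on the log scale, with the antilog shown in nM or µM
for readability.  Rows are ligand/parameter pairs, columns are
construct × ionic-condition, missing cells render as "-" and ligands with
no detectable inhibition as "ND".  Fold-change annotations use the
two-significant-figure convention (e.g. Ki 1.3 → 12 µM is "9-fold").
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import pandas as pd

from .models import fold_change, round_sig

__all__ = [
    "format_k",
    "format_estimate_cell",
    "fold_annotation",
    "build_table",
]

_UNIT_SCALE = {"M": 1.0, "mM": 1e3, "uM": 1e6, "nM": 1e9, "pM": 1e12}

#: Sentinels following the conventional table-footnote vocabulary.
NO_INHIBITION = "ND"   # no inhibition of radioligand binding detected
NOT_MEASURED = "-"     # no binding experiments performed
NOT_CALCULATED = "N/A"


def format_k(K_molar: float, unit: str = "auto", sig: int = 2) -> str:
    """Display a dissociation constant (or cooperativity) in a compact unit."""
    if unit == "auto":
        unit = "nM" if K_molar < 1e-6 else "uM"
    if unit == "":  # dimensionless (cooperativity factor alpha)
        return f"{round_sig(K_molar, sig):g}"
    scale = _UNIT_SCALE[unit]
    return f"{round_sig(K_molar * scale, sig):g}"


def format_estimate_cell(
    mean: float,
    sem: float,
    parameter: str,
    unit: str = "auto",
    footnote: str = "",
) -> str:
    """Render ``mean ± SEM (antilog)`` for a pK or logα estimate.

    pK-type parameters antilog as ``10**-mean`` (a dissociation constant);
    log-type parameters as ``10**mean`` (a cooperativity factor).
    """
    if parameter.startswith("log"):
        value = 10.0 ** mean
        shown = format_k(value, unit="" if unit == "auto" else unit)
    else:
        value = 10.0 ** (-mean)
        shown = format_k(value, unit=unit)
    return f"{mean:.2f} ± {sem:.2f}{footnote} ({shown})"


def fold_annotation(K_ref: float, K_alt: float) -> str:
    """Human-readable fold-loss annotation, e.g. ``"9-fold"``."""
    return f"{fold_change(K_ref, K_alt, rounding='printed'):g}-fold"


def build_table(
    aggregates: pd.DataFrame,
    footnotes: Optional[Dict[Tuple[str, str, str, str], str]] = None,
) -> pd.DataFrame:
    """Pivot tidy aggregate estimates into the report matrix.

    ``aggregates`` must have columns ``ligand, parameter, construct, ion,
    mean, sem`` and optionally ``unit``.  ``footnotes`` maps
    ``(ligand, parameter, construct, ion)`` to a significance-symbol string
    (e.g. ``"*"``).  Missing condition cells render as ``"-"``.
    """
    required = {"ligand", "parameter", "construct", "ion", "mean", "sem"}
    missing = required - set(aggregates.columns)
    if missing:
        raise ValueError(f"aggregates table missing columns: {sorted(missing)}")
    footnotes = footnotes or {}
    rows = []
    row_keys = list(
        dict.fromkeys(zip(aggregates["ligand"], aggregates["parameter"]))
    )
    col_keys = list(dict.fromkeys(zip(aggregates["construct"], aggregates["ion"])))
    for ligand, parameter in row_keys:
        row = {"ligand": ligand, "parameter": parameter}
        for construct, ion in col_keys:
            sel = aggregates[
                (aggregates["ligand"] == ligand)
                & (aggregates["parameter"] == parameter)
                & (aggregates["construct"] == construct)
                & (aggregates["ion"] == ion)
            ]
            col = f"{construct}/{ion}"
            if sel.empty:
                row[col] = NOT_MEASURED
                continue
            rec = sel.iloc[0]
            unit = rec["unit"] if "unit" in sel.columns and pd.notna(rec.get("unit")) else "auto"
            symbol = footnotes.get((ligand, parameter, construct, ion), "")
            row[col] = format_estimate_cell(
                float(rec["mean"]), float(rec["sem"]), parameter, unit=unit,
                footnote=symbol,
            )
        rows.append(row)
    return pd.DataFrame(rows)
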