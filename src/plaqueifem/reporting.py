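"""Summary statistics over tables of fitted Yeoh constants.

A fit table holds one row per cross-section and layer (fibrous intima or
wall) with the fitted constants c1..c3 (kPa) and the achieved NMSE (%).
The packaged fixture ships the constants fitted for ten cross-sections from
five diseased human coronary arteries, and the summaries reproduce the
corresponding published aggregates: mean NMSE, count of cross-sections at
or below 10 %, per-layer constant medians, and uniaxial Cauchy stress
means/maxima at stretch ratios 1.1/1.2/1.3 over the cross-sections whose
optimization error was <= 10 % (cases 5, 7 and 10 excluded).

Medians are descriptive only — the spread across cross-sections is large,
so downstream FE models should use case-specific constants, not these
medians.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .materials import uniaxial_cauchy_stress, yeoh
from .units import round_half_up

__all__ = ["load_fit_table", "packaged_fit_table", "summarize_nmse",
           "median_constants", "stress_summary"]

_COLUMNS = ["artery", "cross_section", "layer", "c1_kPa", "c2_kPa", "c3_kPa",
            "nmse_percent"]


def load_fit_table(path_or_buffer) -> pd.DataFrame:
    table = pd.read_csv(path_or_buffer)
    missing = set(_COLUMNS) - set(table.columns)
    if missing:
        raise ConfigurationError(f"fit table missing columns: {sorted(missing)}")
    dup = table.duplicated(subset=["cross_section", "layer"])
    if dup.any():
        raise ConfigurationError("cross-section ids must be unique per layer")
    return table[_COLUMNS].copy()


def packaged_fit_table() -> pd.DataFrame:
    """The packaged fixture of fitted constants for 10 coronary cross-sections."""
    ref = resources.files("plaqueifem") / "data" / "fitted_yeoh_constants.csv"
    with ref.open() as fh:
        return load_fit_table(fh)


def summarize_nmse(table: pd.DataFrame, threshold_percent: float = 10.0) -> dict:
    """Mean NMSE (%) over cross-sections and the count at/below threshold."""
    if len(table) == 0:
        raise ConfigurationError("empty fit table")
    per_cs = table.groupby("cross_section")["nmse_percent"].first()
    return {"mean_percent": round_half_up(float(per_cs.mean()), 1),
            "count_le_threshold": int((per_cs <= threshold_percent).sum()),
            "n_cross_sections": int(per_cs.size)}


def median_constants(table: pd.DataFrame, layer: str) -> tuple:
    """Per-constant sample medians (kPa) for one layer, full precision.

    Median convention: midpoint of the two central order statistics for even
    counts.  Note that medians of a table printed to 2 decimals can land
    exactly on a rounding tie (e.g. 1.345), so comparisons against published
    medians are meaningful only to within half a printed unit.
    """
    rows = table[table["layer"] == layer]
    if len(rows) == 0:
        raise ConfigurationError(f"no rows for layer '{layer}'")
    return tuple(float(np.median(rows[c])) for c in ("c1_kPa", "c2_kPa", "c3_kPa"))


def stress_summary(table: pd.DataFrame, stretches=(1.1, 1.2, 1.3),
                   exclude_cross_sections=(5, 7, 10)) -> pd.DataFrame:
    """Uniaxial Cauchy stress means and maxima per layer and stretch (kPa).

    Rows whose cross-section id is excluded (by default those with
    optimization error > 10 %) are dropped before aggregation; values are
    rounded half-up to one decimal at this reporting layer only.
    """
    kept = table[~table["cross_section"].isin(exclude_cross_sections)]
    if len(kept) == 0:
        raise ConfigurationError("no rows retained for the stress summary")
    records = []
    for layer, rows in kept.groupby("layer"):
        models = [yeoh(r.c1_kPa, r.c2_kPa, r.c3_kPa) for r in rows.itertuples()]
        for lam in stretches:
            vals = np.array([uniaxial_cauchy_stress(m, lam) for m in models])
            records.append({"layer": layer, "stretch": lam,
                            "n": len(vals),
                            "mean_kPa": round_half_up(float(vals.mean()), 1),
                            "max_kPa": round_half_up(float(vals.max()), 1)})
    return pd.DataFrame.from_records(records)
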