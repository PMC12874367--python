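"""Cross-method comparison of conformer single-point energies.

A set of representative frames per conformational state is evaluated
with several energy methods (force fields under different charge
models, DFT, machine-learned potentials).  Within each method, energies
are referenced to that method's lowest-energy frame across all states
(E_rel), then summarized per (method, state) with Tukey box statistics
and compared against a reference method.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import DataError

__all__ = [
    "read_energy_csv",
    "relative_energies",
    "state_energy_summary",
    "method_agreement",
]

_REQUIRED = ("frame_id", "state", "method", "energy_kcal_mol")


def read_energy_csv(path: str | Path) -> pd.DataFrame:
    """Read an energy table CSV (frame_id, state, method, energy_kcal_mol)."""
    df = pd.read_csv(path)
    return _validate(df)


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    for col in _REQUIRED:
        if col not in table.columns:
            raise DataError(f"energy table missing column {col!r}")
    if table.duplicated(subset=["frame_id", "method"]).any():
        raise DataError("duplicate (frame_id, method) rows in energy table")
    if not np.isfinite(table["energy_kcal_mol"]).all():
        raise DataError("energies must be finite")
    return table


def relative_energies(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``e_rel``: energy minus the per-method global minimum.

    The reference is each method's lowest-energy frame over all states,
    so the most stable conformer sits at exactly 0 for every method and
    per-method constant offsets cancel.
    """
    table = _validate(table).copy()
    table["e_rel"] = table["energy_kcal_mol"] - table.groupby("method")[
        "energy_kcal_mol"
    ].transform("min")
    return table


def _tukey(values: np.ndarray) -> dict[str, object]:
    v = np.sort(np.asarray(values, dtype=float))
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])  # linear interpolation
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    whisk_lo = float(inside.min()) if inside.size else float(med)
    whisk_hi = float(inside.max()) if inside.size else float(med)
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return {
        "n": int(v.size),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_lo": whisk_lo,
        "whisker_hi": whisk_hi,
        "outliers": ";".join(f"{o:.6g}" for o in outliers),
    }


def state_energy_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Tukey box statistics of E_rel per (method, state) cell.

    Whiskers extend to the most extreme data points within 1.5 x IQR of
    the quartiles; points beyond are listed as outliers.  Empty cells
    are simply absent from the output (missing, never zero).
    """
    if "e_rel" not in table.columns:
        table = relative_energies(table)
    rows = []
    for (method, state), grp in table.groupby(["method", "state"], sort=True):
        stats = _tukey(grp["e_rel"].to_numpy())
        rows.append({"method": method, "state": state, **stats})
    return pd.DataFrame(rows)


def method_agreement(
    table: pd.DataFrame, reference_method: str
) -> pd.DataFrame:
    """Per-state agreement of each method with a reference method.

    Reports, per (method, state): the absolute difference of E_rel
    medians from the reference, and the Spearman rank correlation of
    frame E_rel orderings over shared frame ids (NaN when fewer than two
    shared frames).
    """
    if "e_rel" not in table.columns:
        table = relative_energies(table)
    methods = table["method"].unique()
    if reference_method not in methods:
        raise DataError(f"reference method {reference_method!r} not in table")
    ref = table[table["method"] == reference_method]
    rows = []
    for method in sorted(m for m in methods if m != reference_method):
        sub = table[table["method"] == method]
        for state in sorted(table["state"].unique()):
            m_state = sub[sub["state"] == state]
            r_state = ref[ref["state"] == state]
            if m_state.empty or r_state.empty:
                continue
            med_diff = abs(
                m_state["e_rel"].median() - r_state["e_rel"].median()
            )
            merged = m_state.merge(
                r_state, on="frame_id", suffixes=("", "_ref")
            )
            if len(merged) >= 2:
                if (
                    merged["e_rel"].nunique() == 1
                    or merged["e_rel_ref"].nunique() == 1
                ):
                    # constant series: correlation undefined unless equal
                    rho = (
                        1.0
                        if np.allclose(merged["e_rel"], merged["e_rel_ref"])
                        else np.nan
                    )
                else:
                    rho = float(
                        spearmanr(merged["e_rel"], merged["e_rel_ref"])[0]
                    )
            else:
                rho = np.nan
            rows.append(
                {
                    "method": method,
                    "state": state,
                    "median_abs_diff": float(med_diff),
                    "rank_correlation": rho,
                    "n_shared_frames": int(len(merged)),
                }
            )
    return pd.DataFrame(rows)
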