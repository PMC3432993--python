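"""Per-array preprocessing: ratio computation, dye-swap handling, alignment.

Matrix values are stored as-measured; the sample table's dye-orientation
column drives any sign flip. Two dye-swap modes are exposed because the two
analysis stages use different units: pattern extraction keeps both arrays of
an animal×tissue as separate (orientation-corrected) columns, while
classification averages the pair into one column per animal×tissue.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "ratio_to_control",
    "orient_forward",
    "dye_swap_correct",
    "reference_align",
]


def ratio_to_control(treated, control, log_input: bool = False):
    """log2 ratio of treated values to the time-matched control average.

    ``treated`` is a vector or genes × samples array of intensities;
    ``control`` is a per-gene control average (or genes × controls array,
    averaged here). With ``log_input`` both are already log2 intensities and
    the ratio is a subtraction. Nonpositive intensities on the raw scale
    yield NaN (gene flagged missing) rather than an error.
    """
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if c.ndim > 1:
        c = c.mean(axis=1)  # average of time-matched controls, per gene
    if t.ndim > 1 and c.ndim == 1:
        c = c[:, None]  # broadcast per-gene control over treated samples
    if log_input:
        return t - c
    lt = np.where(t > 0, np.log2(np.where(t > 0, t, 1.0)), np.nan)
    lc = np.where(c > 0, np.log2(np.where(c > 0, c, 1.0)), np.nan)
    return lt - lc


def _check_pairs(meta: pd.DataFrame, on_unpaired: str):
    if on_unpaired not in ("error", "keep"):
        raise ValueError("on_unpaired must be 'error' or 'keep'")
    sizes = meta.groupby(["animal_id", "tissue"])["array_id"].count()
    odd = sizes[sizes != 2]
    if len(odd):
        msg = f"animal×tissue units without a dye-swap pair: {list(odd.index)}"
        if on_unpaired == "error":
            raise ValueError(msg)
        warnings.warn(msg)
    dyes = meta.groupby(["animal_id", "tissue"])["dye"].nunique()
    bad = dyes[(sizes == 2) & (dyes != 2)]
    if len(bad):
        raise ValueError(f"paired arrays with identical dye orientation: {list(bad.index)}")


def orient_forward(expr: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Sign-flip swap-orientation arrays so every column reads forward.

    Keeps one column per array (training-set convention: both arrays of a
    rat remain visible as separate profile points).
    """
    meta = metadata.set_index("array_id").loc[expr.columns]
    sign = np.where(meta["dye"].to_numpy() == "swap", -1.0, 1.0)
    return expr * sign[None, :]


def dye_swap_correct(
    expr: pd.DataFrame, metadata: pd.DataFrame, on_unpaired: str = "error"
):
    """Collapse each animal×tissue dye-swap pair to one corrected profile.

    The swap array is flipped to forward orientation and the pair is averaged
    per gene. Returns the corrected genes × (animal×tissue) matrix with
    columns named ``{animal_id}:{tissue}`` plus a per-column metadata table.
    Unpaired units raise by default; ``on_unpaired='keep'`` passes the single
    (orientation-corrected) array through with a warning.
    """
    meta = (
        metadata.set_index("array_id")
        .loc[expr.columns]
        .rename_axis("array_id")
        .reset_index()
    )
    _check_pairs(meta, on_unpaired)
    fwd = orient_forward(expr, metadata)

    unit = meta["animal_id"].astype(str) + ":" + meta["tissue"].astype(str)
    corrected = fwd.T.groupby(unit.to_numpy()).mean().T
    col_meta = (
        meta.assign(unit=unit.to_numpy())
        .drop_duplicates("unit")
        .drop(columns=["array_id", "dye"])
        .set_index("unit")
    )
    # preserve first-appearance order of units
    order = unit.drop_duplicates().tolist()
    corrected = corrected[order]
    col_meta = col_meta.loc[order].reset_index().rename(columns={"unit": "column_id"})
    return corrected, col_meta


def reference_align(expr: pd.DataFrame, enabled: bool = True) -> pd.DataFrame:
    """Median-center each column so its median log-ratio over genes is 0.

    Stands in for a global array-level normalization step: any residual
    per-array additive offset (on the log scale) is removed. Idempotent;
    ``enabled=False`` is an explicit no-op for already-normalized input.
    """
    if not enabled:
        return expr.copy()
    return expr - expr.median(axis=0)
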