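"""Inter-group structure of expression-profile columns.

A profile's columns (arrays or animal×tissue averages) are partitioned into
``m`` inter-groups — experimental cells such as tissue × dose-class — with
``n_i`` replicate columns each. The signal/noise statistics are defined on
this partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: dose (mg/kg) -> dose-class label
SUBTOXIC_DOSE = 150.0
VEHICLE_CLASS, SUBTOXIC_CLASS, TOXIC_CLASS = "vehicle", "subtoxic", "toxic"


def dose_class(dose_mg_kg: float) -> str:
    """Map a dose in mg/kg to its class: 0 → vehicle, 150 → subtoxic, higher → toxic."""
    if dose_mg_kg == 0:
        return VEHICLE_CLASS
    if dose_mg_kg <= SUBTOXIC_DOSE:
        return SUBTOXIC_CLASS
    return TOXIC_CLASS


@dataclass(frozen=True)
class GroupStructure:
    """Partition of profile columns into inter-groups.

    Parameters
    ----------
    indices : np.ndarray of int, shape (n_columns,)
        Inter-group index in ``0..m-1`` for each column.
    names : tuple of str
        One label per inter-group (e.g. ``"blood:toxic"``).
    allow_singletons : bool
        If True, groups of size 1 are allowed; their variance contributes 0
        to the pooled numerator and 0 degrees of freedom to the denominator
        (they still contribute 1/n_i to the reciprocal-size sum).
    """

    indices: np.ndarray
    names: tuple
    allow_singletons: bool = False
    sizes: np.ndarray = field(init=False)

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        m = len(self.names)
        if idx.size == 0:
            raise ValueError("GroupStructure requires at least one column")
        if idx.min() < 0 or idx.max() >= m:
            raise ValueError("group indices out of range for the given names")
        sizes = np.bincount(idx, minlength=m)
        if (sizes == 0).any():
            raise ValueError("every inter-group must have at least one column")
        if not self.allow_singletons and (sizes < 2).any():
            small = [self.names[i] for i in np.where(sizes < 2)[0]]
            raise ValueError(
                f"groups with a single column cannot estimate variance: {small}; "
                "pass allow_singletons=True to zero their contribution"
            )
        object.__setattr__(self, "sizes", sizes)

    @property
    def m(self) -> int:
        return len(self.names)

    @property
    def n_columns(self) -> int:
        return int(self.indices.size)

    @classmethod
    def from_metadata(
        cls,
        metadata: pd.DataFrame,
        by=("tissue", "dose_class"),
        exclude_vehicle: bool = True,
        allow_singletons: bool = False,
    ) -> "GroupStructure":
        """Build the tissue × dose-class partition from a sample table.

        ``metadata`` has one row per profile column, in column order, with the
        fields named in ``by``. Vehicle columns are excluded by default: the
        analyzed unit is the log2 ratio against the time-matched control
        average, so vehicle columns carry no treatment contrast. Use
        :meth:`column_mask` to subset the matrix identically.
        """
        meta = metadata.reset_index(drop=True)
        keep = cls._keep_mask(meta, exclude_vehicle)
        meta = meta[keep]
        keys = meta[list(by)].astype(str).agg(":".join, axis=1)
        names = tuple(sorted(keys.unique()))
        lookup = {k: i for i, k in enumerate(names)}
        idx = keys.map(lookup).to_numpy()
        return cls(indices=idx, names=names, allow_singletons=allow_singletons)

    @staticmethod
    def _keep_mask(metadata: pd.DataFrame, exclude_vehicle: bool) -> np.ndarray:
        if exclude_vehicle and "dose_class" in metadata.columns:
            return (metadata["dose_class"] != VEHICLE_CLASS).to_numpy()
        return np.ones(len(metadata), dtype=bool)

    @classmethod
    def column_mask(cls, metadata: pd.DataFrame, exclude_vehicle: bool = True) -> np.ndarray:
        return cls._keep_mask(metadata.reset_index(drop=True), exclude_vehicle)
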