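"""Tabular container for binding experiments and its CSV dialect.

One row is one well: the three ligand concentrations (molar), the measured
response, condition labels (receptor construct, ionic condition) and the
replicate-experiment index.  The on-disk format is a plain CSV with a fixed
column set; ``is_nonspecific`` is stored as 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Tuple, Union

import numpy as np
import pandas as pd

__all__ = ["COLUMNS", "BindingDataset", "MalformedDatasetError"]

COLUMNS = [
    "experiment_id",
    "construct",
    "ion",
    "conc_radioligand_M",
    "conc_competitor_M",
    "conc_modulator_M",
    "response",
    "response_units",
    "is_nonspecific",
]

_NUMERIC = ["conc_radioligand_M", "conc_competitor_M", "conc_modulator_M", "response"]


class MalformedDatasetError(ValueError):
    """Raised when a dataset file or frame violates the dialect."""


@dataclass
class BindingDataset:
    """A labelled collection of binding records (wells).

    Wraps a :class:`pandas.DataFrame` with the columns in :data:`COLUMNS`.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise MalformedDatasetError(f"missing columns: {missing}")
        df = self.df.loc[:, COLUMNS].reset_index(drop=True).copy()
        for col in _NUMERIC:
            try:
                df[col] = df[col].astype(float)
            except (TypeError, ValueError) as exc:
                bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
                row = int(bad.index[0]) if len(bad) else "?"
                raise MalformedDatasetError(
                    f"column {col!r} is not numeric (first offending row {row})"
                ) from exc
            if not np.all(np.isfinite(df[col])):
                row = int(df.index[~np.isfinite(df[col])][0])
                raise MalformedDatasetError(
                    f"non-finite value in column {col!r} at row {row}"
                )
        if np.any(df[_NUMERIC[:3]].to_numpy() < 0):
            raise MalformedDatasetError("negative concentration in dataset")
        df["is_nonspecific"] = df["is_nonspecific"].astype(int)
        if not df["is_nonspecific"].isin([0, 1]).all():
            raise MalformedDatasetError("is_nonspecific must be 0 or 1")
        self.df = df

    # -- convenience -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def experiment_ids(self) -> list:
        return list(dict.fromkeys(self.df["experiment_id"]))

    def experiments(self) -> Iterator[Tuple[str, "BindingDataset"]]:
        """Yield ``(experiment_id, sub-dataset)`` pairs in file order."""
        for exp_id in self.experiment_ids:
            yield exp_id, BindingDataset(self.df[self.df["experiment_id"] == exp_id])

    def single_experiment(self) -> "BindingDataset":
        ids = self.experiment_ids
        if len(ids) != 1:
            raise ValueError(
                f"expected a single experiment, found {len(ids)}: {ids}; "
                "iterate over .experiments() and fit each"
            )
        return self

    def specific(self) -> pd.DataFrame:
        """Rows measuring specific (non-nonspecific-arm) binding."""
        return self.df[self.df["is_nonspecific"] == 0]

    def vehicle_response(self) -> float:
        """Mean response of vehicle wells (no competitor, no modulator).

        Requires a single experiment; raises if no vehicle record exists.
        """
        self.single_experiment()
        spec = self.specific()
        mask = (spec["conc_competitor_M"] == 0) & (spec["conc_modulator_M"] == 0)
        if not mask.any():
            raise MalformedDatasetError(
                "experiment has no vehicle record (competitor = modulator = 0)"
            )
        return float(spec.loc[mask, "response"].mean())

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: Union[str, Path]) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: Union[str, Path]) -> "BindingDataset":
        path = Path(path)
        try:
            # exact float parsing keeps write->read round trips bit-identical
            df = pd.read_csv(path, float_precision="round_trip")
        except pd.errors.EmptyDataError as exc:
            raise MalformedDatasetError(f"{path} is empty or not a CSV") from exc
        if df.empty:
            raise MalformedDatasetError(f"{path} contains no records")
        return cls(df)

    @classmethod
    def from_records(cls, records: list) -> "BindingDataset":
        return cls(pd.DataFrame.from_records(records, columns=COLUMNS))
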