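"""Retention dataset container and delimited-text I/O.

The unit of all fitting is a table of per-patient thyroid retention
measurements: ``patient_id`` (string), ``time_h`` (hours post administration,
strictly positive) and ``fraction`` (fraction of administered activity in the
gland, in (0, 1.5]; measurement noise may push a value slightly above 1 but
not grossly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

import numpy as np
import pandas as pd

__all__ = ["RetentionDataset", "read_retention_table", "write_retention_table",
           "RetentionDataError"]

REQUIRED_COLUMNS = ("patient_id", "time_h", "fraction")

FRACTION_MAX = 1.5


class RetentionDataError(ValueError):
    """Malformed retention data."""


@dataclass(frozen=True)
class RetentionDataset:
    """Per-patient time/fraction observations.

    Wraps a validated :class:`pandas.DataFrame` with the columns
    ``patient_id``, ``time_h``, ``fraction``.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise RetentionDataError(f"missing required column {col!r}")
        if len(df) == 0:
            raise RetentionDataError("dataset has no records")
        df = df.loc[:, list(REQUIRED_COLUMNS)].reset_index(drop=True)
        df["patient_id"] = df["patient_id"].astype(str)
        df["time_h"] = df["time_h"].astype(float)
        df["fraction"] = df["fraction"].astype(float)
        bad_t = df.index[~(df["time_h"] > 0)].tolist()
        if bad_t:
            raise RetentionDataError(f"non-positive time_h at rows {bad_t}")
        bad_f = df.index[~((df["fraction"] > 0)
                           & (df["fraction"] <= FRACTION_MAX))].tolist()
        if bad_f:
            raise RetentionDataError(
                f"fraction outside (0, {FRACTION_MAX}] at rows {bad_f}")
        dup = df.duplicated(subset=["patient_id", "time_h"])
        if dup.any():
            rows = df.index[dup].tolist()
            pairs = df.loc[dup, ["patient_id", "time_h"]].values.tolist()
            raise RetentionDataError(
                f"duplicate (patient_id, time_h) pairs {pairs} at rows {rows}")
        object.__setattr__(self, "frame", df)

    # ---- basic accessors ----

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    @property
    def n_patients(self) -> int:
        return self.frame["patient_id"].nunique()

    @property
    def patient_ids(self) -> List[str]:
        return list(dict.fromkeys(self.frame["patient_id"]))

    def patient(self, patient_id: str) -> pd.DataFrame:
        sub = self.frame[self.frame["patient_id"] == str(patient_id)]
        if len(sub) == 0:
            raise KeyError(f"unknown patient {patient_id!r}")
        return sub.reset_index(drop=True)

    def by_patient(self) -> Dict[str, pd.DataFrame]:
        return {pid: g.reset_index(drop=True)
                for pid, g in self.frame.groupby("patient_id", sort=False)}

    # ---- padded arrays for vectorized fitting ----

    def padded_arrays(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray, List[str]]:
        """Return (times, fractions, mask, patient_ids) padded to max obs count.

        Arrays have shape (n_patients, m_max); padding entries carry
        time 1.0 / fraction 1.0 and mask False.
        """
        groups = self.by_patient()
        pids = list(groups)
        m = max(len(g) for g in groups.values())
        n = len(pids)
        T = np.ones((n, m))
        Y = np.ones((n, m))
        mask = np.zeros((n, m), dtype=bool)
        for i, pid in enumerate(pids):
            g = groups[pid]
            k = len(g)
            T[i, :k] = g["time_h"].to_numpy()
            Y[i, :k] = g["fraction"].to_numpy()
            mask[i, :k] = True
        return T, Y, mask, pids

    @classmethod
    def from_records(cls, records: Iterable[Tuple[str, float, float]]
                     ) -> "RetentionDataset":
        df = pd.DataFrame(records, columns=list(REQUIRED_COLUMNS))
        return cls(df)


def read_retention_table(path, sep: str | None = None) -> RetentionDataset:
    """Read a delimited retention table (header required, dot decimal).

    The separator is sniffed among comma/tab/semicolon/whitespace when not
    given.  Validation failures raise :class:`RetentionDataError` naming the
    offending rows (0-based data rows, i.e. file line minus two).
    """
    try:
        df = pd.read_csv(path, sep=sep, engine="python")
    except Exception as exc:  # noqa: BLE001 - reported with context
        raise RetentionDataError(f"could not parse {path}: {exc}") from exc
    if len(df.columns) == 1 and df.columns[0] not in REQUIRED_COLUMNS:
        raise RetentionDataError(
            f"{path}: expected columns {REQUIRED_COLUMNS}, got {list(df.columns)}")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise RetentionDataError(f"{path}: missing columns {missing}")
    try:
        return RetentionDataset(df)
    except RetentionDataError as exc:
        raise RetentionDataError(f"{path}: {exc}") from exc


def write_retention_table(dataset: RetentionDataset, path, sep: str = ",") -> None:
    dataset.frame.to_csv(path, sep=sep, index=False)
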