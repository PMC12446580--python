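"""Species occurrence records: presences, pseudo-absences and fold labels."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["OccurrenceSet"]

COLUMNS = ["x", "y", "presence", "fold"]


@dataclass
class OccurrenceSet:
    """A table of occurrence records.

    Each record is a point ``(x, y)`` in metres with a presence flag
    (1 = presence, 0 = pseudo-absence) and an optional cross-validation
    fold id (NaN when unassigned).
    """

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=COLUMNS))

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df[COLUMNS].reset_index(drop=True)
        pres = df["presence"].to_numpy()
        if len(df) and not np.isin(pres, [0, 1]).all():
            raise ValueError("presence flags must be 0 or 1")
        df["presence"] = df["presence"].astype(int) if len(df) else df["presence"]
        self.frame = df

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(cls, x, y, presence, fold=None) -> "OccurrenceSet":
        df = pd.DataFrame({"x": x, "y": y, "presence": presence})
        df["fold"] = np.nan if fold is None else fold
        return cls(df)

    @classmethod
    def read_csv(cls, path: str | Path) -> "OccurrenceSet":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    # -- views ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def x(self) -> np.ndarray:
        return self.frame["x"].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["y"].to_numpy(dtype=float)

    @property
    def presence(self) -> np.ndarray:
        return self.frame["presence"].to_numpy(dtype=int)

    @property
    def fold(self) -> np.ndarray:
        return self.frame["fold"].to_numpy(dtype=float)

    def presences(self) -> "OccurrenceSet":
        return OccurrenceSet(self.frame[self.frame["presence"] == 1])

    def absences(self) -> "OccurrenceSet":
        return OccurrenceSet(self.frame[self.frame["presence"] == 0])

    def with_fold(self, fold: np.ndarray) -> "OccurrenceSet":
        df = self.frame.copy()
        df["fold"] = np.asarray(fold, dtype=float)
        return OccurrenceSet(df)

    def concat(self, other: "OccurrenceSet") -> "OccurrenceSet":
        return OccurrenceSet(pd.concat([self.frame, other.frame], ignore_index=True))
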