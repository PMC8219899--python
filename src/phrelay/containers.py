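"""Shared in-memory containers.

``FeatureTrajectory`` is the universal currency between pipeline stages:
a time-ordered table of named scalar features for a single replica.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class FeatureTrajectory:
    """Frames x features table for one simulation replica.

    Parameters
    ----------
    data:
        One row per frame, one column per named feature.  No missing
        values are allowed and column names must be unique.
    frame_interval_ns:
        Time between consecutive frames in ns (> 0).
    replica_id:
        Identifier of the source replica.
    ensemble:
        Optional ensemble label, e.g. ``"neutral"`` or ``"H294+"``.
    """

    data: pd.DataFrame
    frame_interval_ns: float = 1.0
    replica_id: str = "0"
    ensemble: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(np.asarray(self.data))
            self.data.columns = [str(c) for c in self.data.columns]
        if self.frame_interval_ns <= 0:
            raise ValueError(f"frame_interval_ns must be > 0, got {self.frame_interval_ns}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes}")
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise ValueError(f"missing values in features: {bad}")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ns

    def select(self, names: list[str]) -> "FeatureTrajectory":
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise KeyError(f"features not present: {missing}")
        return FeatureTrajectory(self.data[names].copy(), self.frame_interval_ns,
                                 self.replica_id, self.ensemble)

    def to_csv(self, path: str | Path) -> None:
        """Write as plain CSV: header = feature names, one row per frame."""
        self.data.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path, frame_interval_ns: float = 1.0,
                 replica_id: str | None = None, ensemble: str | None = None
                 ) -> "FeatureTrajectory":
        df = pd.read_csv(path)
        rid = replica_id if replica_id is not None else Path(path).stem
        return cls(df, frame_interval_ns, rid, ensemble)


def stack_values(trajs: list[FeatureTrajectory]) -> np.ndarray:
    """Pool frames of several replicas into one (sum_frames, n_features) array.

    All replicas must share the same feature set (same names, same order).
    """
    if not trajs:
        raise ValueError("no trajectories given")
    names = trajs[0].feature_names
    for t in trajs[1:]:
        if t.feature_names != names:
            raise ValueError(
                f"feature sets differ: {names} vs {t.feature_names} "
                f"(replica {t.replica_id})")
    return np.vstack([t.values for t in trajs])
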