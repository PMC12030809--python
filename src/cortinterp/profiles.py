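"""24 h biomarker concentration profiles and their long-format CSV I/O.

A :class:`Profile` is one subject x condition x specimen concentration time
series over a single 24 h admission.  Time is kept internally in integer
minutes since the 06:00 admission start (0 ... 1440, both endpoints
included); concentrations are in ug/dl.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

WINDOW_MIN = 0
WINDOW_MAX = 1440

REST = "rest"
EXERCISE = "exercise"
CONDITIONS = (REST, EXERCISE)

SERUM = "serum"
SALIVA = "saliva"
SPECIMENS = (SERUM, SALIVA)

CSV_COLUMNS = ["subject_id", "condition", "specimen", "time_min", "value"]


@dataclass(frozen=True)
class Profile:
    """One concentration time series on a stated sampling grid.

    Attributes
    ----------
    subject_id : str
        Opaque subject label.
    condition : str
        ``"rest"`` or ``"exercise"``.
    specimen : str
        ``"serum"`` or ``"saliva"``.
    times : numpy.ndarray
        Sampling times in minutes since admission start, strictly increasing.
    values : numpy.ndarray
        Concentrations in ug/dl, finite and non-negative.
    """

    subject_id: str
    condition: str
    specimen: str
    times: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if self.specimen not in SPECIMENS:
            raise ValueError(
                f"unknown specimen {self.specimen!r}; expected one of {SPECIMENS}"
            )
        if times.ndim != 1 or values.ndim != 1 or times.shape != values.shape:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if len(times) < 2:
            raise ValueError("a profile needs at least 2 samples")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(values)) and np.all(values >= 0)):
            raise ValueError("values must be finite and non-negative")
        if times[0] < WINDOW_MIN or times[-1] > WINDOW_MAX:
            raise ValueError(
                f"times must lie within [{WINDOW_MIN}, {WINDOW_MAX}] minutes"
            )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.condition, self.specimen)

    def with_values(self, values: np.ndarray) -> "Profile":
        return replace(self, values=np.asarray(values, dtype=float))


def profiles_to_frame(profiles: list[Profile]) -> pd.DataFrame:
    """Stack profiles into a long-format table (one row per sample)."""
    rows = []
    for p in profiles:
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": p.subject_id,
                    "condition": p.condition,
                    "specimen": p.specimen,
                    "time_min": p.times.astype(int),
                    "value": p.values,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=CSV_COLUMNS)
    return pd.concat(rows, ignore_index=True)[CSV_COLUMNS]


def frame_to_profiles(frame: pd.DataFrame) -> list[Profile]:
    """Group a long-format table back into :class:`Profile` objects."""
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"long-format table is missing columns {missing}")
    profiles = []
    for (sid, cond, spec), grp in frame.groupby(
        ["subject_id", "condition", "specimen"], sort=True
    ):
        grp = grp.sort_values("time_min")
        profiles.append(
            Profile(
                subject_id=str(sid),
                condition=str(cond),
                specimen=str(spec),
                times=grp["time_min"].to_numpy(dtype=float),
                values=grp["value"].to_numpy(dtype=float),
            )
        )
    return profiles


def write_cohort_csv(profiles: list[Profile], path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


def read_cohort_csv(path) -> list[Profile]:
    return frame_to_profiles(pd.read_csv(path))
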