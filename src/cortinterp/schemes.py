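"""Sampling schemes for the 24 h admission window.

Seven built-in schemes are defined: the equidistant grids Q60 ... Q360
(one sample every 60 ... 360 minutes, endpoints always included) and two
intermittent clinical schedules INT1 and INT2.  Each scheme carries the
maximum polynomial degree that its number of samples supports while
retaining residual degrees of freedom.  Q60 is the serum ground-truth
scheme, Q120 the saliva ground-truth scheme; every other grid is a strict
subset of its specimen's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .profiles import Profile, SALIVA, SERUM


@dataclass(frozen=True)
class SamplingScheme:
    """A named sampling grid (hours since admission start) with a degree cap."""

    name: str
    grid_hours: tuple[int, ...]
    max_degree: int

    def __post_init__(self) -> None:
        hours = tuple(int(h) for h in self.grid_hours)
        object.__setattr__(self, "grid_hours", hours)
        if len(hours) < 2 or hours[0] != 0 or hours[-1] != 24:
            raise ValueError("grid must contain hour 0 and hour 24")
        if any(h < 0 or h > 24 for h in hours):
            raise ValueError("grid hours must lie in 0..24")
        if any(b <= a for a, b in zip(hours, hours[1:])):
            raise ValueError("grid hours must be strictly increasing")
        if not (0 < self.max_degree < len(hours)):
            raise ValueError("max_degree must be positive and below the point count")

    @property
    def grid_minutes(self) -> np.ndarray:
        return np.asarray(self.grid_hours, dtype=float) * 60.0

    @property
    def n_points(self) -> int:
        return len(self.grid_hours)


_BUILTIN_SPECS = {
    "Q60": (tuple(range(25)), 6),
    "Q120": (tuple(range(0, 25, 2)), 6),
    "Q180": (tuple(range(0, 25, 3)), 5),
    "Q240": (tuple(range(0, 25, 4)), 4),
    "Q360": ((0, 6, 12, 18, 24), 3),
    "INT1": ((0, 2, 4, 8, 14, 24), 3),
    "INT2": ((0, 2, 6, 16, 24), 3),
}

BUILTIN_SCHEMES: dict[str, SamplingScheme] = {
    name: SamplingScheme(name, grid, deg) for name, (grid, deg) in _BUILTIN_SPECS.items()
}

#: ground-truth (densest collected) scheme per specimen
GROUND_TRUTH = {SERUM: "Q60", SALIVA: "Q120"}

#: schemes analysed per specimen; the ground truth comes first
SPECIMEN_SCHEMES = {
    SERUM: ("Q60", "Q120", "Q180", "Q240", "Q360", "INT1", "INT2"),
    SALIVA: ("Q120", "Q240", "Q360", "INT1", "INT2"),
}


def build_scheme(name: str) -> SamplingScheme:
    """Return the built-in scheme called ``name``.

    Raises
    ------
    KeyError
        If ``name`` is not one of the seven built-in scheme names.
    """
    try:
        return BUILTIN_SCHEMES[name]
    except KeyError:
        raise KeyError(
            f"unknown scheme {name!r}; valid names: {sorted(BUILTIN_SCHEMES)}"
        ) from None


def downsample(profile: Profile, scheme: SamplingScheme) -> Profile:
    """Restrict ``profile`` to exactly the scheme's sampling times.

    Every scheme time (in minutes) must be present in ``profile.times``;
    values are copied unchanged.  This is what makes a Q120-collected saliva
    profile un-downsampleable to Q180: hour 3 was never sampled.
    """
    grid = scheme.grid_minutes
    present = np.isin(grid, profile.times)
    if not present.all():
        missing = [int(m) for m in grid[~present]]
        raise ValueError(
            f"profile does not contain scheme {scheme.name} times (minutes): {missing}"
        )
    idx = np.searchsorted(profile.times, grid)
    return Profile(
        subject_id=profile.subject_id,
        condition=profile.condition,
        specimen=profile.specimen,
        times=profile.times[idx].copy(),
        values=profile.values[idx].copy(),
    )


def valid_schemes_for(specimen: str) -> list[SamplingScheme]:
    """All schemes analysed for a specimen, ground truth first."""
    try:
        names = SPECIMEN_SCHEMES[specimen]
    except KeyError:
        raise KeyError(
            f"unknown specimen {specimen!r}; expected one of {sorted(SPECIMEN_SCHEMES)}"
        ) from None
    return [BUILTIN_SCHEMES[n] for n in names]


def alternative_schemes_for(specimen: str) -> list[SamplingScheme]:
    """The non-ground-truth schemes for a specimen."""
    return valid_schemes_for(specimen)[1:]


def load_schemes(path) -> dict[str, SamplingScheme]:
    """Load user-defined schemes from a YAML mapping.

    The file maps scheme name to ``{hours: [...], max_degree: n}``.  The
    seven built-in names are immutable and may not be redefined.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    schemes = {}
    for name, entry in raw.items():
        if name in BUILTIN_SCHEMES:
            raise ValueError(f"built-in scheme {name!r} cannot be redefined")
        schemes[name] = SamplingScheme(
            name=name,
            grid_hours=tuple(entry["hours"]),
            max_degree=int(entry["max_degree"]),
        )
    return schemes
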