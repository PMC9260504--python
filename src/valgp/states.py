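"""EQ-5D-5L health states and the Gaussian correlation kernel over them.

The EQ-5D-5L descriptive system codes a health state as five integer levels
(1 = no problems ... 5 = extreme problems) on mobility, self-care, usual
activities, pain/discomfort and anxiety/depression, written as a 5-digit
string: ``"11111"`` is full health, ``"55555"`` the "pits" state.

Utility functions over states are modelled as a Gaussian process whose
correlation between two states decays with their squared level distance,

    c(x, x') = exp{-sum_d b_d (x_d - x'_d)^2},

where b_d is a per-dimension roughness parameter.  The default
b_d = 2.5/(l_d - 1)^2 makes exp(-2.5) ~ 0.082 the correlation between the
best and worst levels of a single dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_DIMENSIONS = 5
N_LEVELS = 5
FULL_HEALTH = "11111"
PITS = "55555"

DIMENSIONS = (
    "mobility",
    "self-care",
    "usual activities",
    "pain/discomfort",
    "anxiety/depression",
)


class InvalidStateError(ValueError):
    """Raised for malformed or out-of-range EQ-5D-5L state codes."""


@dataclass(frozen=True)
class HealthState:
    """An EQ-5D-5L health state: five levels, each in 1..5."""

    levels: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.levels) != N_DIMENSIONS:
            raise InvalidStateError(f"expected {N_DIMENSIONS} levels, got {self.levels!r}")
        for lev in self.levels:
            if not isinstance(lev, (int, np.integer)) or not 1 <= lev <= N_LEVELS:
                raise InvalidStateError(f"level {lev!r} outside 1..{N_LEVELS}")
        object.__setattr__(self, "levels", tuple(int(v) for v in self.levels))

    @property
    def code(self) -> str:
        """The 5-digit string identifier, e.g. ``"11453"``."""
        return "".join(str(v) for v in self.levels)

    @property
    def is_full_health(self) -> bool:
        return self.code == FULL_HEALTH

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code


def parse_state(code: str) -> HealthState:
    """Parse a 5-digit state code into a :class:`HealthState`.

    Round-trips: ``parse_state(s).code == s`` for every valid code.

    Raises
    ------
    InvalidStateError
        If ``code`` is not exactly five characters, contains a non-digit,
        or any digit falls outside 1..5.
    """
    code = str(code)
    if len(code) != N_DIMENSIONS:
        raise InvalidStateError(f"state code must have 5 characters: {code!r}")
    if not code.isdigit():
        raise InvalidStateError(f"state code must be all digits: {code!r}")
    levels = tuple(int(ch) for ch in code)
    if any(not 1 <= lev <= N_LEVELS for lev in levels):
        raise InvalidStateError(f"levels must lie in 1..{N_LEVELS}: {code!r}")
    return HealthState(levels)  # type: ignore[arg-type]


def all_states() -> list[HealthState]:
    """All 3,125 describable EQ-5D-5L states, in lexicographic code order."""
    out = []
    for a in range(1, 6):
        for b in range(1, 6):
            for c in range(1, 6):
                for d in range(1, 6):
                    for e in range(1, 6):
                        out.append(HealthState((a, b, c, d, e)))
    return out


def design_row(state: HealthState) -> np.ndarray:
    """Row h(x) = (1, x1, ..., x5) of the linear prior-mean design matrix."""
    return np.concatenate(([1.0], np.asarray(state.levels, dtype=float)))


def design_matrix(states: list[HealthState]) -> np.ndarray:
    """Stack design rows h(x) for a list of states into an (n, 6) matrix."""
    return np.vstack([design_row(s) for s in states])


def level_matrix(states: list[HealthState]) -> np.ndarray:
    """(n, 5) matrix of raw levels, one row per state."""
    return np.asarray([s.levels for s in states], dtype=float)


@dataclass(frozen=True)
class RoughnessParams:
    """Per-dimension kernel roughness b_d (> 0)."""

    b: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.b) != N_DIMENSIONS:
            raise ValueError(f"expected {N_DIMENSIONS} roughness values")
        if any(not v > 0 for v in self.b):
            raise ValueError("all roughness parameters must be > 0")
        object.__setattr__(self, "b", tuple(float(v) for v in self.b))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.b, dtype=float)


def default_roughness(levels_per_dimension: int = N_LEVELS) -> float:
    """Default roughness 2.5/(l-1)^2 for a dimension with ``l`` levels.

    Chosen so that exp{-(l-1)^2 b} = exp(-2.5) is the correlation between
    utilities of two states differing only between level 1 and level l in
    one dimension.
    """
    if levels_per_dimension < 2:
        raise ValueError("a dimension needs at least 2 levels")
    return 2.5 / (levels_per_dimension - 1) ** 2


def default_roughness_params() -> RoughnessParams:
    """RoughnessParams with b_d = 2.5/(l_d-1)^2 for all five 5-level dimensions."""
    b = default_roughness(N_LEVELS)
    return RoughnessParams((b,) * N_DIMENSIONS)


def kernel_correlation(x: HealthState, x2: HealthState, b: RoughnessParams) -> float:
    """Squared-exponential correlation c(x, x') between two states' utilities."""
    dx = np.asarray(x.levels, dtype=float) - np.asarray(x2.levels, dtype=float)
    return float(np.exp(-np.sum(b.array * dx**2)))


def correlation_matrix(states: list[HealthState], b: RoughnessParams) -> np.ndarray:
    """Kernel correlation matrix A over a list of states.

    Unit diagonal, symmetric and positive semi-definite for any state set
    and positive roughness.  Duplicate states are allowed (they produce
    duplicated rows/columns of ones).
    """
    if len(states) == 0:
        raise ValueError("need at least one state")
    lv = level_matrix(states)
    diff = lv[:, None, :] - lv[None, :, :]
    return np.exp(-np.einsum("ijd,d->ij", diff**2, b.array))
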