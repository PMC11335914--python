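"""Mapping between the factorial design and the model's free parameters.

The go task fully crosses four two-level factors — block type (blockwise vs
trialwise cuing), bias (cue favoring blue vs orange), difficulty (easy vs
hard) and stimulus (majority blue vs orange) — for 16 design cells, and two
accumulators race in every cell, one per response option. Selective-influence
assumptions tie parameters across cells: e.g. thresholds vary with block
type, bias and accumulator identity (they implement cue-induced response
bias), while accumulation rates vary with block type, difficulty and whether
the accumulator matches the stimulus.

A :class:`ParameterMap` records, per parameter type, the factors whose
crossing indexes distinct free parameters, and resolves any (cell, role,
type) triple to a position in the flat parameter vector. Derived
accumulator-level factors are available alongside the design factors:
``response`` (R: which accumulator), ``match`` (M: accumulator matches the
stimulus) and ``congruent`` (accumulator matches the bias cue).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import ndtr, ndtri

from .distributions import GoRunnerParams, StopRunnerParams

__all__ = [
    "DesignCell",
    "AccumulatorRole",
    "MixtureParams",
    "ParameterMap",
    "DESIGN_FACTORS",
    "DERIVED_FACTORS",
    "SELECTIVE_INFLUENCE_ASSIGNMENT",
    "BEESTS_ASSIGNMENT",
    "all_cells",
    "build_map",
    "free_parameter_count",
    "realize",
]

# canonical (alphabetical) level order per factor
DESIGN_FACTORS: dict[str, tuple] = {
    "block_type": ("block", "trial"),
    "bias": ("blue", "orange"),
    "difficulty": ("easy", "hard"),
    "stimulus": ("blue", "orange"),
}
DERIVED_FACTORS: dict[str, tuple] = {
    "response": ("blue", "orange"),
    "match": (False, True),
    "congruent": (False, True),
}
_ALL_FACTORS = {**DESIGN_FACTORS, **DERIVED_FACTORS}

# flat-vector ordering of the standard parameter types
_TYPE_ORDER = ("t0", "B", "v", "mu", "sigma", "tau", "zgf", "ztf")
GO_TYPES = ("t0", "B", "v")
STOP_TYPES = ("mu", "sigma", "tau")
FAILURE_TYPES = ("zgf", "ztf")


@dataclass(frozen=True)
class DesignCell:
    """One cell of the 2x2x2x2 go design."""

    block_type: str
    bias: str
    difficulty: str
    stimulus: str

    def __post_init__(self) -> None:
        for name in DESIGN_FACTORS:
            value = getattr(self, name)
            if value not in DESIGN_FACTORS[name]:
                raise ValueError(
                    f"invalid level {value!r} for factor {name!r}; "
                    f"expected one of {DESIGN_FACTORS[name]}"
                )


@dataclass(frozen=True)
class AccumulatorRole:
    """One of the two racers in a cell, identified by its response option."""

    response: str

    def __post_init__(self) -> None:
        if self.response not in DERIVED_FACTORS["response"]:
            raise ValueError(f"invalid response {self.response!r}")

    def match(self, cell: DesignCell) -> bool:
        return self.response == cell.stimulus

    def congruent(self, cell: DesignCell) -> bool:
        return self.response == cell.bias


@dataclass(frozen=True)
class MixtureParams:
    """Go-failure and trigger-failure probabilities with their probit-scale
    images ``zgf = ndtri(pgf)``, ``ztf = ndtri(ptf)``."""

    pgf: float
    ptf: float

    def __post_init__(self) -> None:
        for name, p in (("pgf", self.pgf), ("ptf", self.ptf)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")

    @property
    def zgf(self) -> float:
        return float(ndtri(self.pgf))

    @property
    def ztf(self) -> float:
        return float(ndtri(self.ptf))

    @classmethod
    def from_probit(cls, zgf: float, ztf: float) -> "MixtureParams":
        return cls(pgf=float(ndtr(zgf)), ptf=float(ndtr(ztf)))


def all_cells() -> list[DesignCell]:
    """The 16 distinct cells of the full crossing, canonically ordered."""
    return [
        DesignCell(bt, b, d, s)
        for bt in DESIGN_FACTORS["block_type"]
        for b in DESIGN_FACTORS["bias"]
        for d in DESIGN_FACTORS["difficulty"]
        for s in DESIGN_FACTORS["stimulus"]
    ]


def _factor_level_index(factor: str, cell: DesignCell, role: AccumulatorRole | None) -> int:
    if factor in DESIGN_FACTORS:
        return DESIGN_FACTORS[factor].index(getattr(cell, factor))
    if role is None:
        raise ValueError(f"factor {factor!r} requires an accumulator role")
    if factor == "response":
        return DERIVED_FACTORS["response"].index(role.response)
    if factor == "match":
        return int(role.match(cell))
    if factor == "congruent":
        return int(role.congruent(cell))
    raise ValueError(f"unknown factor {factor!r}")


# The parametrization used throughout: one shared non-decision time;
# thresholds crossed by block type x bias x accumulator (8); rates by block
# type x difficulty x match (8); stop and failure parameters shared.
SELECTIVE_INFLUENCE_ASSIGNMENT: dict[str, tuple[str, ...]] = {
    "t0": (),
    "B": ("block_type", "bias", "response"),
    "v": ("block_type", "difficulty", "match"),
    "mu": (),
    "sigma": (),
    "tau": (),
    "zgf": (),
    "ztf": (),
}

# Descriptive (ex-Gaussian go runner) parametrization: three go parameters
# per design cell per accumulator, shared stop and failure parameters.
BEESTS_ASSIGNMENT: dict[str, tuple[str, ...]] = {
    "mu_go": ("block_type", "bias", "difficulty", "stimulus", "response"),
    "sigma_go": ("block_type", "bias", "difficulty", "stimulus", "response"),
    "tau_go": ("block_type", "bias", "difficulty", "stimulus", "response"),
    "mu": (),
    "sigma": (),
    "tau": (),
    "zgf": (),
    "ztf": (),
}


@dataclass(frozen=True)
class ParameterMap:
    """Assignment of free parameters to (cell, accumulator, type) triples.

    ``assignment`` maps each parameter type to the tuple of factors whose
    level crossing indexes distinct free parameters; an empty tuple means a
    single parameter shared by all cells and accumulators.
    """

    assignment: Mapping[str, tuple[str, ...]]
    offsets: Mapping[str, int] = field(init=False)
    n_params: int = field(init=False)

    def __post_init__(self) -> None:
        seen: dict[str, tuple[str, ...]] = {}
        for ptype, factors in self.assignment.items():
            factors = tuple(factors)
            if len(set(factors)) != len(factors):
                raise ValueError(f"duplicated factor in assignment for {ptype!r}")
            for f in factors:
                if f not in _ALL_FACTORS:
                    raise ValueError(f"unknown factor {f!r} for parameter {ptype!r}")
            seen[ptype] = factors
        object.__setattr__(self, "assignment", seen)
        # Enumerate the level combinations that actually occur over the
        # full crossing of cells and roles: a derived factor assigned
        # alongside its constituents (e.g. match with stimulus and
        # response) makes part of the naive crossing unreachable, and
        # unreachable combinations must not consume free parameters.
        roles = [AccumulatorRole(r) for r in DERIVED_FACTORS["response"]]
        ranks: dict[str, dict[tuple, int]] = {}
        for ptype, factors in seen.items():
            combos = {
                tuple(_factor_level_index(f, cell, role) for f in factors)
                for cell in all_cells()
                for role in roles
            }
            ranks[ptype] = {c: i for i, c in enumerate(sorted(combos))}
        object.__setattr__(self, "_ranks", ranks)
        ordered = [t for t in _TYPE_ORDER if t in seen]
        ordered += [t for t in seen if t not in _TYPE_ORDER]
        offsets: dict[str, int] = {}
        total = 0
        for ptype in ordered:
            offsets[ptype] = total
            total += len(ranks[ptype])
        object.__setattr__(self, "offsets", offsets)
        object.__setattr__(self, "n_params", total)

    def type_count(self, ptype: str) -> int:
        return len(self._ranks[ptype])

    def index(
        self, ptype: str, cell: DesignCell, role: AccumulatorRole | None = None
    ) -> int:
        """Flat-vector position of the parameter read by (cell, role, type)."""
        factors = self.assignment[ptype]
        combo = tuple(_factor_level_index(f, cell, role) for f in factors)
        return self.offsets[ptype] + self._ranks[ptype][combo]

    def labels(self) -> list[str]:
        """Human-readable names for the flat-vector entries, in order."""
        out: list[str] = []
        ordered = sorted(self.offsets, key=self.offsets.get)  # type: ignore[arg-type]
        for ptype in ordered:
            factors = self.assignment[ptype]
            if not factors:
                out.append(ptype)
                continue
            for combo in sorted(self._ranks[ptype], key=self._ranks[ptype].get):
                suffix = ".".join(
                    str(_ALL_FACTORS[f][lev]) for f, lev in zip(factors, combo)
                )
                out.append(f"{ptype}.{suffix}")
        return out

    def type_slices(self) -> dict[str, slice]:
        """Flat-vector slice covering each parameter type."""
        return {
            t: slice(self.offsets[t], self.offsets[t] + self.type_count(t))
            for t in self.assignment
        }

    # ------------------------------------------------------------------
    # realization
    # ------------------------------------------------------------------
    def _check_vector(self, flat: np.ndarray) -> np.ndarray:
        flat = np.asarray(flat, dtype=float)
        if flat.shape != (self.n_params,):
            raise ValueError(
                f"flat vector length {flat.shape} does not match the "
                f"{self.n_params} free parameters of this map"
            )
        return flat

    def go_params(
        self, flat: np.ndarray, cell: DesignCell, role: AccumulatorRole
    ) -> GoRunnerParams:
        flat = self._check_vector(flat)
        return GoRunnerParams(
            v=flat[self.index("v", cell, role)],
            B=flat[self.index("B", cell, role)],
            A=0.0,
            t0=flat[self.index("t0", cell, role)],
        )

    def stop_params(
        self,
        flat: np.ndarray,
        cell: DesignCell,
        role: AccumulatorRole | None = None,
        lower: float = 0.05,
        upper: float = np.inf,
    ) -> StopRunnerParams:
        flat = self._check_vector(flat)
        return StopRunnerParams(
            mu=flat[self.index("mu", cell, role)],
            sigma=flat[self.index("sigma", cell, role)],
            tau=flat[self.index("tau", cell, role)],
            lower=lower,
            upper=upper,
        )

    def mixture_params(
        self, flat: np.ndarray, cell: DesignCell, role: AccumulatorRole | None = None
    ) -> MixtureParams:
        flat = self._check_vector(flat)
        return MixtureParams.from_probit(
            zgf=flat[self.index("zgf", cell, role)],
            ztf=flat[self.index("ztf", cell, role)],
        )


def build_map(factor_assignment: Mapping[str, Sequence[str]] | None = None) -> ParameterMap:
    """Build a :class:`ParameterMap` from a parameter-type -> factor-list
    assignment; defaults to the selective-influence parametrization
    (:data:`SELECTIVE_INFLUENCE_ASSIGNMENT`)."""
    if factor_assignment is None:
        factor_assignment = SELECTIVE_INFLUENCE_ASSIGNMENT
    return ParameterMap({k: tuple(v) for k, v in factor_assignment.items()})


def free_parameter_count(pmap: ParameterMap) -> int:
    """Total number of distinct free parameters indexed by the map."""
    return pmap.n_params


def realize(
    pmap: ParameterMap,
    flat: np.ndarray,
    cell: DesignCell,
    role: AccumulatorRole,
    stop_lower: float = 0.05,
    stop_upper: float = np.inf,
) -> tuple[GoRunnerParams, StopRunnerParams, MixtureParams]:
    """Resolve the flat vector into parameter objects for one (cell, role)."""
    return (
        pmap.go_params(flat, cell, role),
        pmap.stop_params(flat, cell, role, lower=stop_lower, upper=stop_upper),
        pmap.mixture_params(flat, cell, role),
    )
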