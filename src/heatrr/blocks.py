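"""Block-level and blocktype definitions for the multilevel AV block model.

The atrioventricular (AV) node is modelled as a cascade of up to three
blocking levels.  Each level conducts ``n`` of every ``n + 1`` incoming
signals (a classical ``n+1 : n`` block ratio; ``1:1`` passthrough is
permitted), optionally alternating between several ratios.  A level is
either

* **Type II** (Mobitz): fixed conduction delay, every ``(n+1)``-th signal
  dropped abruptly, or
* **Type I** (Wenckebach): the conduction delay grows linearly across the
  cycle — the ``k``-th conducted signal of a cycle is delayed by
  ``c + (k - 1) * delta`` — and resets after the dropped beat.

A *blocktype* is an ordered stack of level templates, each declaring which
parameters (ratio, phase offset, delay increment) are free and on which
grid they are searched.  Five presets covering the clinically common
configurations are registered in :data:`DEFAULT_REGISTRY`.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Sequence

__all__ = [
    "TYPE_I",
    "TYPE_II",
    "BlockLevel",
    "LevelSpec",
    "Blocktype",
    "BlocktypeRegistry",
    "DEFAULT_REGISTRY",
    "decision_cycle",
    "conducted_fraction",
]

TYPE_I = "I"
TYPE_II = "II"

#: ``(incoming, conducted)`` pair, e.g. ``(4, 3)`` for a 4:3 block.
RatioPair = tuple[int, int]
RatioPattern = tuple[RatioPair, ...]


def _validate_pattern(pattern: Sequence[Sequence[int]]) -> RatioPattern:
    pat = tuple((int(inc), int(con)) for inc, con in pattern)
    return _validate_pattern_cached(pat)


@lru_cache(maxsize=512)
def _validate_pattern_cached(pat: RatioPattern) -> RatioPattern:
    if not pat:
        raise ValueError("ratio pattern must contain at least one pair")
    for inc, con in pat:
        if con < 1 or inc < con or inc > con + 1:
            raise ValueError(
                f"invalid ratio pair {inc}:{con}; need incoming == conducted "
                "or incoming == conducted + 1"
            )
    return pat


def decision_cycle(pattern: Sequence[Sequence[int]]) -> list[tuple[bool, int]]:
    """One full period of per-signal conduction decisions for a ratio pattern.

    Returns a list of ``(conducted, multiplier)`` entries, one per incoming
    signal.  ``multiplier`` is ``k - 1`` for the ``k``-th conducted signal
    within its ``n+1 : n`` pair (the Wenckebach delay-increment count);
    blocked signals carry multiplier 0 by convention.
    """
    pat = _validate_pattern(pattern)
    return _decision_cycle_cached(pat)


@lru_cache(maxsize=512)
def _decision_cycle_cached(pat: RatioPattern) -> list[tuple[bool, int]]:
    cycle: list[tuple[bool, int]] = []
    for inc, con in pat:
        for k in range(1, con + 1):
            cycle.append((True, k - 1))
        if inc == con + 1:
            cycle.append((False, 0))
    return cycle


@lru_cache(maxsize=512)
def _conducted_fraction_cached(pat: RatioPattern) -> Fraction:
    inc = sum(p[0] for p in pat)
    con = sum(p[1] for p in pat)
    return Fraction(con, inc)


def conducted_fraction(pattern: Sequence[Sequence[int]]) -> Fraction:
    """Mean fraction of incoming signals conducted over one pattern period."""
    return _conducted_fraction_cached(_validate_pattern(pattern))


@dataclass(frozen=True)
class BlockLevel:
    """A concrete (fully parameterised) blocking level.

    Parameters
    ----------
    block_type : {"I", "II"}
        Wenckebach (Type I) or Mobitz (Type II) behaviour.
    ratio_pattern : sequence of (incoming, conducted) pairs
        Cycled in order; ``[(2, 1)]`` is a fixed 2:1 block,
        ``[(2, 1), (3, 2)]`` alternates 2:1 and 3:2.
    base_delay_c : float
        Fixed conduction delay in ms (>= 0).
    increment_delta : float
        Per-conducted-beat delay increment in ms (Type I only; forced 0
        for Type II).
    phase_offset_o : int
        Starting position inside the concatenated decision cycle,
        ``0 <= o < cycle length``.
    """

    block_type: str
    ratio_pattern: RatioPattern
    base_delay_c: float = 0.0
    increment_delta: float = 0.0
    phase_offset_o: int = 0

    def __post_init__(self) -> None:
        if self.block_type not in (TYPE_I, TYPE_II):
            raise ValueError(f"unknown block type {self.block_type!r}")
        object.__setattr__(
            self, "ratio_pattern", _validate_pattern(self.ratio_pattern)
        )
        if self.base_delay_c < 0:
            raise ValueError("base_delay_c must be >= 0")
        if self.increment_delta < 0:
            raise ValueError("increment_delta must be >= 0")
        if self.block_type == TYPE_II and self.increment_delta != 0:
            raise ValueError("Type II levels have a fixed delay (delta = 0)")
        cyc = len(self.decision_cycle())
        if not 0 <= self.phase_offset_o < cyc:
            raise ValueError(
                f"phase_offset_o must lie in [0, {cyc}) for this pattern"
            )

    def decision_cycle(self) -> list[tuple[bool, int]]:
        return decision_cycle(self.ratio_pattern)

    def conducted_fraction(self) -> Fraction:
        return conducted_fraction(self.ratio_pattern)


@dataclass(frozen=True)
class LevelSpec:
    """Template for one level of a blocktype preset.

    Declares the discrete choices (ratio options, phase offset) and the
    continuous-on-a-grid parameter (delay increment) the solver may vary.
    """

    block_type: str
    #: selectable ratio patterns; a single entry means the ratio is fixed
    ratio_options: tuple[RatioPattern, ...]
    #: whether the phase offset is searched (else fixed to 0)
    free_offset: bool = True
    #: (lo, hi) bounds in ms for the Type I delay increment grid
    delta_bounds: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.block_type not in (TYPE_I, TYPE_II):
            raise ValueError(f"unknown block type {self.block_type!r}")
        opts = tuple(_validate_pattern(p) for p in self.ratio_options)
        if not opts:
            raise ValueError("need at least one ratio option")
        object.__setattr__(self, "ratio_options", opts)
        lo, hi = self.delta_bounds
        if lo < 0 or hi < lo:
            raise ValueError("invalid delta_bounds")
        if self.block_type == TYPE_II and hi != 0:
            raise ValueError("Type II levels must have delta_bounds (0, 0)")

    def to_dict(self) -> dict:
        return {
            "block_type": self.block_type,
            "ratio_options": [
                [list(pair) for pair in pat] for pat in self.ratio_options
            ],
            "free_offset": self.free_offset,
            "delta_bounds": list(self.delta_bounds),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LevelSpec":
        return cls(
            block_type=d["block_type"],
            ratio_options=tuple(
                tuple(tuple(pair) for pair in pat) for pat in d["ratio_options"]
            ),
            free_offset=bool(d.get("free_offset", True)),
            delta_bounds=tuple(d.get("delta_bounds", (0.0, 0.0))),
        )


@dataclass(frozen=True)
class Blocktype:
    """An ordered stack of 1–3 level templates with a registry id."""

    id: int
    name: str
    levels: tuple[LevelSpec, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.levels) <= 3:
            raise ValueError("a blocktype has between 1 and 3 levels")

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "name": self.name,
            "levels": [lv.to_dict() for lv in self.levels],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Blocktype":
        return cls(
            id=int(d["id"]),
            name=str(d["name"]),
            levels=tuple(LevelSpec.from_dict(lv) for lv in d["levels"]),
        )


class BlocktypeRegistry:
    """Mapping of blocktype id -> preset, serialisable to YAML/JSON."""

    def __init__(self, blocktypes: Sequence[Blocktype]):
        self._by_id: dict[int, Blocktype] = {}
        for bt in blocktypes:
            if bt.id in self._by_id:
                raise ValueError(f"duplicate blocktype id {bt.id}")
            self._by_id[bt.id] = bt

    def __getitem__(self, bt_id: int) -> Blocktype:
        return self._by_id[bt_id]

    def __contains__(self, bt_id: int) -> bool:
        return bt_id in self._by_id

    def __iter__(self):
        return iter(sorted(self._by_id))

    def __len__(self) -> int:
        return len(self._by_id)

    @property
    def ids(self) -> list[int]:
        return sorted(self._by_id)

    def to_dict(self) -> dict:
        return {"blocktypes": [self._by_id[i].to_dict() for i in self.ids]}

    @classmethod
    def from_dict(cls, d: dict) -> "BlocktypeRegistry":
        return cls([Blocktype.from_dict(b) for b in d["blocktypes"]])


def _single_pair_options(n_values: Sequence[int]) -> tuple[RatioPattern, ...]:
    return tuple((((n + 1, n),)) for n in n_values)


def default_registry() -> BlocktypeRegistry:
    """The five registered blocktype presets.

    1. single Type I level, free ratio n+1:n with n in 1..5
    2. single Type II level, free ratio n+1:n with n in 1..5
    3. fixed 2:1 Type II level feeding a free-ratio Type I level
    4. three Type II levels: alternating 2:1/3:2, then twice
       alternating 1:1/2:1
    5. two stacked free-ratio Type I levels (n in 1..3 each)

    The presets are registry entries, not code: overriding the registry
    (e.g. from a YAML config) changes the search space without touching
    the solver.
    """
    delta = (0.0, 100.0)
    return BlocktypeRegistry(
        [
            Blocktype(
                1,
                "single Type I, free ratio",
                (LevelSpec(TYPE_I, _single_pair_options(range(1, 6)),
                           delta_bounds=delta),),
            ),
            Blocktype(
                2,
                "single Type II, free ratio",
                (LevelSpec(TYPE_II, _single_pair_options(range(1, 6))),),
            ),
            Blocktype(
                3,
                "2:1 Type II over free-ratio Type I",
                (
                    LevelSpec(TYPE_II, (((2, 1),),)),
                    LevelSpec(TYPE_I, _single_pair_options(range(1, 6)),
                              delta_bounds=delta),
                ),
            ),
            Blocktype(
                4,
                "alternating 2:1/3:2 over two alternating 1:1/2:1 levels",
                (
                    LevelSpec(TYPE_II, (((2, 1), (3, 2)),)),
                    LevelSpec(TYPE_II, (((1, 1), (2, 1)),)),
                    LevelSpec(TYPE_II, (((1, 1), (2, 1)),)),
                ),
            ),
            Blocktype(
                5,
                "two stacked Type I levels, free ratios",
                (
                    LevelSpec(TYPE_I, _single_pair_options(range(1, 4)),
                              delta_bounds=delta),
                    LevelSpec(TYPE_I, _single_pair_options(range(1, 4)),
                              delta_bounds=delta),
                ),
            ),
        ]
    )


#: Module-level default preset registry (see :func:`default_registry`).
DEFAULT_REGISTRY = default_registry()
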