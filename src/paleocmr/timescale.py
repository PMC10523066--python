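"""Geologic stage table with mass-extinction and recovery flags.

The analysis bins the fossil record into ordered geologic stages (the CMR
"occasions").  Each stage carries two regime flags: ``is_mass_extinction``
marks the terminal stage of one of the canonical Big Five events, and
``is_recovery`` marks the stage immediately following a flagged stage.  The
packaged default table spans the base of the Ordovician (Tremadocian,
485.4 Ma) through the early Pleistocene (Gelasian), 86 stages in all, of
which 5 are flagged mass extinction and 81 are background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "Stage",
    "StageTable",
    "BIG_FIVE_STAGES",
    "load_stage_table",
    "flag_big_five",
    "derive_recovery_flags",
]

#: Conventional stage-level placements of the Big Five mass extinctions:
#: End-Ordovician, Late Devonian, End-Permian, End-Triassic, End-Cretaceous.
#: The Late Devonian event may alternatively be placed at the Famennian;
#: pass a custom name list to :func:`flag_big_five` for sensitivity runs.
BIG_FIVE_STAGES: tuple[str, ...] = (
    "Hirnantian",
    "Frasnian",
    "Changhsingian",
    "Rhaetian",
    "Maastrichtian",
)


@dataclass(frozen=True)
class Stage:
    """One geologic stage: a time bin acting as a CMR occasion.

    ``index`` is the 1-based position in temporal order (oldest = 1).
    Ages are in Ma with ``age_base > age_top``.
    """

    name: str
    index: int
    age_base: float
    age_top: float
    is_mass_extinction: bool = False
    is_recovery: bool = False

    def __post_init__(self) -> None:
        if not self.age_base > self.age_top:
            raise ValueError(
                f"stage {self.name!r}: age_base ({self.age_base}) must exceed "
                f"age_top ({self.age_top})"
            )
        if self.is_mass_extinction and self.is_recovery:
            raise ValueError(
                f"stage {self.name!r} flagged both mass extinction and recovery"
            )


@dataclass(frozen=True)
class StageTable:
    """Ordered collection of :class:`Stage` spanning the analysis window."""

    stages: tuple[Stage, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "stages", tuple(self.stages))
        self._validate()

    def _validate(self) -> None:
        bad: list[str] = []
        for prev, cur in zip(self.stages, self.stages[1:]):
            if cur.index != prev.index + 1:
                bad.append(f"{prev.name} -> {cur.name}: indices not consecutive")
            # contiguity: each stage must start where the previous one ends
            if abs(cur.age_base - prev.age_top) > 1e-6:
                bad.append(
                    f"{prev.name} (top {prev.age_top}) -> {cur.name} "
                    f"(base {cur.age_base}): ages overlap or leave a gap"
                )
        if bad:
            raise ValueError("invalid stage table: " + "; ".join(bad))

    def __len__(self) -> int:
        return len(self.stages)

    def __iter__(self) -> Iterator[Stage]:
        return iter(self.stages)

    def __getitem__(self, i: int) -> Stage:
        return self.stages[i]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.stages]

    @property
    def mass_extinction_names(self) -> list[str]:
        return [s.name for s in self.stages if s.is_mass_extinction]

    def index_of(self, name: str) -> int:
        """1-based temporal index of a stage name; KeyError when absent."""
        for s in self.stages:
            if s.name == name:
                return s.index
        raise KeyError(name)

    def count_background(self) -> int:
        return sum(not s.is_mass_extinction for s in self.stages)

    def count_mass_extinction(self) -> int:
        return sum(s.is_mass_extinction for s in self.stages)

    def subset(self, first_index: int, last_index: int) -> "StageTable":
        """Contiguous sub-window by 1-based stage indices, reindexed from 1."""
        sub = [
            replace(s, index=i + 1)
            for i, s in enumerate(self.stages[first_index - 1 : last_index])
        ]
        return StageTable(tuple(sub))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [s.name for s in self.stages],
                "index": [s.index for s in self.stages],
                "age_base": [s.age_base for s in self.stages],
                "age_top": [s.age_top for s in self.stages],
                "is_mass_extinction": [int(s.is_mass_extinction) for s in self.stages],
                "is_recovery": [int(s.is_recovery) for s in self.stages],
            }
        )


def _default_path() -> Path:
    return Path(str(resources.files("paleocmr").joinpath("data/stages.csv")))


def load_stage_table(path_or_default: str | Path | None = None) -> StageTable:
    """Read a stage table CSV (columns name, age_base, age_top, flags).

    With no argument, returns the packaged 86-stage default with the Big
    Five flagged and recovery stages derived.  Rows are sorted oldest
    first; overlapping or non-contiguous ages raise a validation error
    naming the offending rows.
    """
    path = _default_path() if path_or_default is None else Path(path_or_default)
    df = pd.read_csv(path)
    required = {"name", "age_base", "age_top"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"stage table {path}: missing columns {sorted(missing)}")
    df = df.sort_values("age_base", ascending=False).reset_index(drop=True)
    me = df.get("is_mass_extinction", pd.Series(0, index=df.index)).fillna(0)
    rec = df.get("is_recovery", pd.Series(0, index=df.index)).fillna(0)
    stages = tuple(
        Stage(
            name=str(row["name"]),
            index=i + 1,
            age_base=float(row["age_base"]),
            age_top=float(row["age_top"]),
            is_mass_extinction=bool(int(me.iloc[i])),
            is_recovery=bool(int(rec.iloc[i])),
        )
        for i, row in df.iterrows()
    )
    return StageTable(stages)


def flag_big_five(
    table: StageTable, names: Sequence[str] = BIG_FIVE_STAGES
) -> StageTable:
    """Set mass-extinction flags on exactly the named stages.

    Idempotent: any pre-existing flags are cleared first.  Recovery flags
    are re-derived from the new flag set.  A named stage absent from the
    table raises with the full list of missing names.
    """
    present = set(table.names)
    missing = [n for n in names if n not in present]
    if missing:
        raise ValueError(f"stages not present in table: {missing}")
    wanted = set(names)
    flagged = tuple(
        replace(s, is_mass_extinction=s.name in wanted, is_recovery=False)
        for s in table.stages
    )
    return derive_recovery_flags(StageTable(flagged))


def derive_recovery_flags(table: StageTable) -> StageTable:
    """Flag each stage immediately following a mass-extinction stage.

    Pure function of the mass-extinction flags (re-deriving is idempotent).
    A mass-extinction flag on the final stage has no successor; a warning
    is emitted and no recovery stage is created for it.
    """
    me_flags = [s.is_mass_extinction for s in table.stages]
    if me_flags and me_flags[-1]:
        warnings.warn(
            f"mass-extinction flag on final stage {table.stages[-1].name!r}: "
            "no recovery stage can be created",
            stacklevel=2,
        )
    stages = []
    for i, s in enumerate(table.stages):
        rec = i > 0 and me_flags[i - 1] and not s.is_mass_extinction
        stages.append(replace(s, is_recovery=rec))
    return StageTable(tuple(stages))


def make_toy_table(
    n_stages: int,
    mass_extinction_indices: Iterable[int] = (),
    span: tuple[float, float] = (100.0, 0.0),
) -> StageTable:
    """Equal-duration toy stage table for tests and simulations.

    ``mass_extinction_indices`` are 1-based temporal indices.
    """
    base, top = span
    width = (base - top) / n_stages
    me = set(mass_extinction_indices)
    stages = tuple(
        Stage(
            name=f"S{i + 1}",
            index=i + 1,
            age_base=base - i * width,
            age_top=base - (i + 1) * width,
            is_mass_extinction=(i + 1) in me,
        )
        for i in range(n_stages)
    )
    return derive_recovery_flags(StageTable(stages))
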