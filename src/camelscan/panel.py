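"""Sample panel: individual -> population and sex assignments.

The three analysis cohorts are labelled ``D`` (dromedary-like focal
population), ``B`` (domestic Bactrian-like population) and ``F``
(wild two-humped population); any other labels are accepted but the
pipeline defaults assume these three.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

_VALID_SEXES = {MALE, FEMALE, UNKNOWN}


@dataclass
class PopulationPanel:
    """Maps individual ids to population labels and sexes."""

    population: dict[str, str]
    sex: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ind in self.population:
            self.sex.setdefault(ind, UNKNOWN)
        bad = {s for s in self.sex.values()} - _VALID_SEXES
        if bad:
            raise ValueError(f"invalid sex labels: {sorted(bad)}")

    @property
    def individuals(self) -> list[str]:
        return list(self.population)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.population.values():
            seen.setdefault(p, None)
        return list(seen)

    def members(self, pop: str) -> list[str]:
        out = [ind for ind, p in self.population.items() if p == pop]
        if not out:
            raise KeyError(f"population {pop!r} has no members")
        return out

    def indices(self, samples: Sequence[str], pop: str) -> list[int]:
        """Column indices of ``pop`` members within an ordered sample list."""
        members = set(self.members(pop))
        idx = [i for i, s in enumerate(samples) if s in members]
        if not idx:
            raise KeyError(f"population {pop!r} absent from sample list")
        return idx

    def males(self) -> list[str]:
        return [i for i, s in self.sex.items() if s == MALE]

    def females(self) -> list[str]:
        return [i for i, s in self.sex.items() if s == FEMALE]

    def validate_samples(self, samples: Iterable[str]) -> None:
        missing = [s for s in samples if s not in self.population]
        if missing:
            raise KeyError(f"samples absent from panel: {missing}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PopulationPanel":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"individual", "population"}
        if not required.issubset(df.columns):
            raise ValueError(f"panel TSV needs columns {sorted(required)}")
        sex = {}
        if "sex" in df.columns:
            sex = dict(zip(df["individual"], df["sex"].fillna(UNKNOWN)))
        return cls(dict(zip(df["individual"], df["population"])), sex)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "individual": self.individuals,
                "population": [self.population[i] for i in self.individuals],
                "sex": [self.sex[i] for i in self.individuals],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_mapping(
        cls, pops: Mapping[str, Sequence[str]], sexes: Mapping[str, str] | None = None
    ) -> "PopulationPanel":
        population = {ind: pop for pop, inds in pops.items() for ind in inds}
        return cls(population, dict(sexes or {}))
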