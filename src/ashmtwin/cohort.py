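"""Twin-cohort containers.

A monozygotic (MZ) twin cohort is a set of pairs, each pair carrying two
genetically identical individuals. Pairs are classed by phenotype
concordance: PDC (disease-discordant: exactly one affected cotwin), PCC
(disease-concordant: both affected) and HCC (healthy-concordant: neither
affected). The discordant class drives the transition analysis; the
concordant classes serve as within-design controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = ["PairClass", "Individual", "TwinCohort"]


class PairClass(str, Enum):
    PDC = "PDC"
    PCC = "PCC"
    HCC = "HCC"


_EXPECTED_AFFECTED = {PairClass.PDC: 1, PairClass.PCC: 2, PairClass.HCC: 0}


@dataclass(frozen=True)
class Individual:
    individual_id: str
    pair_id: str
    affected: bool


@dataclass
class TwinCohort:
    """A validated MZ twin cohort.

    Invariants enforced on construction: every pair has exactly two
    members, and the number of affected members matches the pair class
    (PDC: 1, PCC: 2, HCC: 0).
    """

    individuals: list[Individual]
    pair_class: dict[str, PairClass] = field(default_factory=dict)

    def __post_init__(self) -> None:
        by_pair: dict[str, list[Individual]] = {}
        seen: set[str] = set()
        for ind in self.individuals:
            if ind.individual_id in seen:
                raise ValueError(f"duplicate individual id {ind.individual_id!r}")
            seen.add(ind.individual_id)
            by_pair.setdefault(ind.pair_id, []).append(ind)
        for pair_id, members in by_pair.items():
            if len(members) != 2:
                raise ValueError(
                    f"pair {pair_id!r} has {len(members)} members, expected 2"
                )
            cls = self.pair_class.get(pair_id)
            if cls is None:
                raise ValueError(f"pair {pair_id!r} has no concordance class")
            n_aff = sum(m.affected for m in members)
            if n_aff != _EXPECTED_AFFECTED[PairClass(cls)]:
                raise ValueError(
                    f"pair {pair_id!r} of class {cls} has {n_aff} affected members"
                )
        self._by_pair = by_pair

    # -- accessors -------------------------------------------------------

    @property
    def individual_ids(self) -> list[str]:
        return [ind.individual_id for ind in self.individuals]

    @property
    def pair_ids(self) -> list[str]:
        return list(self._by_pair)

    def members(self, pair_id: str) -> tuple[Individual, Individual]:
        a, b = self._by_pair[pair_id]
        return a, b

    def cotwin(self, individual_id: str) -> Individual:
        ind = self.get(individual_id)
        a, b = self._by_pair[ind.pair_id]
        return b if a.individual_id == individual_id else a

    def get(self, individual_id: str) -> Individual:
        for ind in self.individuals:
            if ind.individual_id == individual_id:
                return ind
        raise KeyError(individual_id)

    def pairs_of_class(self, cls: PairClass | str) -> list[str]:
        cls = PairClass(cls)
        return [p for p, c in self.pair_class.items() if PairClass(c) == cls]

    def affected_map(self) -> dict[str, bool]:
        return {ind.individual_id: ind.affected for ind in self.individuals}

    def pair_map(self) -> dict[str, str]:
        return {ind.individual_id: ind.pair_id for ind in self.individuals}

    # -- serialization ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": [i.individual_id for i in self.individuals],
                "pair_id": [i.pair_id for i in self.individuals],
                "affected": [int(i.affected) for i in self.individuals],
                "pair_class": [
                    PairClass(self.pair_class[i.pair_id]).value
                    for i in self.individuals
                ],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TwinCohort":
        inds = [
            Individual(str(r.individual_id), str(r.pair_id), bool(int(r.affected)))
            for r in df.itertuples()
        ]
        pair_class = {
            str(r.pair_id): PairClass(r.pair_class) for r in df.itertuples()
        }
        return cls(inds, pair_class)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TwinCohort":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def build_cohort(
    n_pdc: int, n_pcc: int, n_hcc: int, prefix: str = ""
) -> TwinCohort:
    """Construct a cohort with systematic ids.

    Pair ids are ``PDC1..``, ``PCC1..``, ``HCC1..``; members are suffixed
    ``_a`` / ``_b``. In PDC pairs member ``_a`` is the affected cotwin.
    """
    individuals: list[Individual] = []
    pair_class: dict[str, PairClass] = {}
    plan: Iterable[tuple[PairClass, int]] = [
        (PairClass.PDC, n_pdc),
        (PairClass.PCC, n_pcc),
        (PairClass.HCC, n_hcc),
    ]
    for cls, n in plan:
        for k in range(1, n + 1):
            pid = f"{prefix}{cls.value}{k}"
            pair_class[pid] = cls
            aff = _EXPECTED_AFFECTED[cls]
            individuals.append(Individual(f"{pid}_a", pid, aff >= 1))
            individuals.append(Individual(f"{pid}_b", pid, aff == 2))
    return TwinCohort(individuals, pair_class)
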