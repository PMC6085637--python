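"""Pedigree container with discrete, non-overlapping generations."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Pedigree"]

UNKNOWN = -1


@dataclass
class Pedigree:
    """Parent pointers per individual.

    ``sire[i]`` / ``dam[i]`` are row indices into the same pedigree, or -1 for
    founders. ``generation[i]`` is the discrete generation number (founders =
    0); parents must come from an earlier generation, which is what makes the
    levelwise kinship recursion in :mod:`consgen.inbreeding` valid.
    """

    ids: list[str]
    sire: np.ndarray  # intp, -1 = unknown
    dam: np.ndarray
    sex: np.ndarray  # dtype object, 'M'/'F'
    generation: np.ndarray  # int64

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.intp)
        self.dam = np.asarray(self.dam, dtype=np.intp)
        self.sex = np.asarray(self.sex, dtype=object)
        self.generation = np.asarray(self.generation, dtype=np.int64)
        n = len(self.ids)
        if not (len(self.sire) == len(self.dam) == len(self.sex) == len(self.generation) == n):
            raise ValueError("pedigree columns have unequal lengths")

    @property
    def n(self) -> int:
        return len(self.ids)

    def validate(self) -> None:
        """Parents must exist and belong to a strictly earlier generation."""
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            known = par != UNKNOWN
            if (par[known] < 0).any() or (par[known] >= self.n).any():
                raise ValueError(f"{name} index out of range")
            bad = known & (self.generation[np.clip(par, 0, self.n - 1)] >= self.generation)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"individual {self.ids[i]} has a {name} from its own or a later "
                    "generation (cycle or overlapping generations)"
                )

    @classmethod
    def from_records(cls, records: list[tuple[str, str | None, str | None, str, int]]) -> "Pedigree":
        """Build from (id, sire_id, dam_id, sex, generation) tuples."""
        ids = [r[0] for r in records]
        index = {s: i for i, s in enumerate(ids)}
        if len(index) != len(ids):
            raise ValueError("duplicate individual ids")

        def look(x: str | None) -> int:
            if x is None or x == "" or x == ".":
                return UNKNOWN
            if x not in index:
                raise ValueError(f"unknown parent id {x!r}")
            return index[x]

        ped = cls(
            ids=ids,
            sire=np.array([look(r[1]) for r in records]),
            dam=np.array([look(r[2]) for r in records]),
            sex=np.array([r[3] for r in records], dtype=object),
            generation=np.array([r[4] for r in records]),
        )
        ped.validate()
        return ped

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("id\tsire\tdam\tsex\tgeneration\n")
            for i in range(self.n):
                s = self.ids[self.sire[i]] if self.sire[i] != UNKNOWN else "."
                d = self.ids[self.dam[i]] if self.dam[i] != UNKNOWN else "."
                fh.write(f"{self.ids[i]}\t{s}\t{d}\t{self.sex[i]}\t{int(self.generation[i])}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Pedigree":
        records = []
        with Path(path).open() as fh:
            header = fh.readline()
            if not header.startswith("id\t"):
                raise ValueError(f"{path}: unexpected pedigree header")
            for line in fh:
                pid, s, d, sex, gen = line.rstrip("\n").split("\t")
                records.append((pid, None if s == "." else s, None if d == "." else d, sex, int(gen)))
        return cls.from_records(records)
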