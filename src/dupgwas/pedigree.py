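"""Pedigrees and the additive (numerator) relationship matrix.

The polygenic covariance structure of the animal model is ``A * sigma2_a``,
where ``A`` is the numerator relationship matrix (NRM): twice the kinship
coefficient between every pair of animals, built from the pedigree by the
tabular method.  Unknown parents are encoded by the sentinel ``"0"`` in files
and by ``None`` in memory; founders are assumed non-inbred.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

UNKNOWN = None
_SENTINEL = "0"


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, dangling parent id, ...)."""


@dataclass
class PedigreeRecord:
    animal: str
    sire: str | None = None
    dam: str | None = None
    breed: str | None = None
    herd: str | None = None


@dataclass
class Pedigree:
    """An ordered collection of animal/sire/dam records.

    Animal ids are opaque strings, unique within the pedigree.  Parents may
    be unknown (``None``).  A valid pedigree is acyclic, so a topological
    order (parents before offspring) always exists.
    """

    records: list[PedigreeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.animal for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({a for a in ids if ids.count(a) > 1})
            raise PedigreeError(f"duplicate animal ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def animals(self) -> list[str]:
        return [r.animal for r in self.records]

    def record(self, animal: str) -> PedigreeRecord:
        return self._index()[animal]

    def _index(self) -> dict[str, PedigreeRecord]:
        return {r.animal: r for r in self.records}

    def parents(self, animal: str) -> tuple[str | None, str | None]:
        r = self._index()[animal]
        return r.sire, r.dam

    def founders(self) -> list[str]:
        return [r.animal for r in self.records if r.sire is None and r.dam is None]

    def offspring_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {r.animal: 0 for r in self.records}
        for r in self.records:
            for p in (r.sire, r.dam):
                if p is not None and p in counts:
                    counts[p] += 1
        return counts

    def terminal_animals(self) -> list[str]:
        """Animals that are not recorded as a parent of anyone."""
        counts = self.offspring_counts()
        return [a for a, c in counts.items() if c == 0]

    def topological_order(self) -> list[str]:
        """Animal ids sorted parents-before-offspring; raises on a cycle."""
        idx = self._index()
        order: list[str] = []
        state: dict[str, int] = {}  # 0 in-progress, 1 done

        for root in idx:
            if state.get(root) == 1:
                continue
            stack: list[tuple[str, bool]] = [(root, False)]
            while stack:
                node, processed = stack.pop()
                if processed:
                    state[node] = 1
                    order.append(node)
                    continue
                if state.get(node) == 1:
                    continue
                if state.get(node) == 0:
                    raise PedigreeError(f"cyclic pedigree involving animal {node!r}")
                state[node] = 0
                stack.append((node, True))
                rec = idx.get(node)
                if rec is None:
                    continue
                for p in (rec.sire, rec.dam):
                    if p is not None:
                        if p not in idx:
                            raise PedigreeError(
                                f"parent {p!r} of animal {node!r} has no pedigree record"
                            )
                        if state.get(p) == 0:
                            raise PedigreeError(
                                f"cyclic pedigree involving animals {node!r} and {p!r}"
                            )
                        if state.get(p) != 1:
                            stack.append((p, False))
            # mark any leftover in-progress as done (shouldn't occur)
        return order

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": [r.animal for r in self.records],
                "sire": [r.sire if r.sire is not None else _SENTINEL for r in self.records],
                "dam": [r.dam if r.dam is not None else _SENTINEL for r in self.records],
                "breed": [r.breed for r in self.records],
                "herd": [r.herd for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        recs = []
        for row in df.itertuples(index=False):
            d = row._asdict()
            sire = d.get("sire")
            dam = d.get("dam")
            recs.append(
                PedigreeRecord(
                    animal=str(d["animal"]),
                    sire=None if sire in (None, _SENTINEL, "", np.nan) or pd.isna(sire) else str(sire),
                    dam=None if dam in (None, _SENTINEL, "", np.nan) or pd.isna(dam) else str(dam),
                    breed=None if "breed" not in d or pd.isna(d.get("breed")) else str(d["breed"]),
                    herd=None if "herd" not in d or pd.isna(d.get("herd")) else str(d["herd"]),
                )
            )
        return cls(recs)


def read_pedigree(path: str | Path | io.TextIOBase) -> Pedigree:
    """Read a pedigree text file.

    Whitespace- or comma-separated columns ``animal sire dam [breed [herd]]``;
    ``"0"`` marks an unknown parent; a header line is auto-detected (a first
    line whose second and third fields are not ids occurring elsewhere and
    that contains alphabetic field names like ``sire``).
    """
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
    else:
        text = path.read()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        return Pedigree([])
    sep = "," if "," in lines[0] else None
    rows = [ln.split(sep) for ln in lines]
    header = [f.strip().lower() for f in rows[0]]
    names = ["animal", "sire", "dam", "breed", "herd"]
    if header[:3] == ["animal", "sire", "dam"] or set(header) & {"sire", "dam", "id"}:
        rows = rows[1:]
    recs = []
    for r in rows:
        r = [f.strip() for f in r]
        vals = dict(zip(names, r))
        recs.append(
            PedigreeRecord(
                animal=vals["animal"],
                sire=None if vals.get("sire", _SENTINEL) == _SENTINEL else vals["sire"],
                dam=None if vals.get("dam", _SENTINEL) == _SENTINEL else vals["dam"],
                breed=vals.get("breed"),
                herd=vals.get("herd"),
            )
        )
    return Pedigree(recs)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("animal sire dam breed herd\n")
        for r in ped:
            fh.write(
                f"{r.animal} {r.sire or _SENTINEL} {r.dam or _SENTINEL} "
                f"{r.breed or 'NA'} {r.herd or 'NA'}\n"
            )


def truncate_pedigree(
    ped: Pedigree, depth: int, probands: Sequence[str] | None = None
) -> Pedigree:
    """Truncate ancestry to ``depth`` generations above the probands.

    ``depth`` is counted per individual along ancestral paths: an ancestor
    reachable from a proband only by paths longer than ``depth`` is dropped,
    and animals exactly ``depth`` steps up become founders (parents set
    unknown).  Probands default to the terminal (childless) animals — in a
    phenotyped cohort these are the measured individuals — and are never
    dropped.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    ped.topological_order()  # validates acyclicity / parent ids
    idx = ped._index()
    if probands is None:
        probands = ped.terminal_animals() or ped.animals
    missing = [p for p in probands if p not in idx]
    if missing:
        raise PedigreeError(f"probands not in pedigree: {missing}")

    # BFS upward from the probands, recording the minimum path length.
    dist: dict[str, int] = {p: 0 for p in probands}
    frontier = list(probands)
    while frontier:
        nxt = []
        for a in frontier:
            d = dist[a]
            if d >= depth:
                continue
            for parent in (idx[a].sire, idx[a].dam):
                if parent is not None and dist.get(parent, depth + 1) > d + 1:
                    dist[parent] = d + 1
                    nxt.append(parent)
        frontier = nxt

    keep = set(dist)
    recs = []
    for r in ped:
        if r.animal not in keep:
            continue
        at_limit = dist[r.animal] >= depth
        recs.append(
            PedigreeRecord(
                animal=r.animal,
                sire=None if at_limit or r.sire not in keep else r.sire,
                dam=None if at_limit or r.dam not in keep else r.dam,
                breed=r.breed,
                herd=r.herd,
            )
        )
    return Pedigree(recs)


@dataclass
class RelationshipMatrix:
    """Dense symmetric additive relationship matrix with its animal order."""

    animals: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.animals)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match animal count")

    def loc(self, a: str, b: str) -> float:
        i = self.animals.index(a)
        j = self.animals.index(b)
        return float(self.values[i, j])

    def reorder(self, animals: Iterable[str]) -> "RelationshipMatrix":
        pos = {a: i for i, a in enumerate(self.animals)}
        animals = list(animals)
        idx = np.array([pos[a] for a in animals])
        return RelationshipMatrix(animals, self.values[np.ix_(idx, idx)])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.animals, columns=self.animals).to_csv(
            path, sep="\t", index_label="animal"
        )


def build_nrm(ped: Pedigree, order: Sequence[str] | None = None) -> RelationshipMatrix:
    """Build the numerator relationship matrix by the tabular method.

    With animals sorted parents-before-offspring,

        A_ii = 1 + 0.5 * A(sire_i, dam_i)            (0 if a parent unknown)
        A_ij = 0.5 * (A(j, sire_i) + A(j, dam_i))    for j earlier than i

    Founders are assumed non-inbred.  The returned matrix follows ``order``
    (default: pedigree record order).
    """
    topo = ped.topological_order()
    idx = ped._index()
    pos = {a: i for i, a in enumerate(topo)}
    n = len(topo)
    A = np.zeros((n, n))
    for a in topo:
        i = pos[a]
        rec = idx[a]
        si = pos[rec.sire] if rec.sire is not None else -1
        di = pos[rec.dam] if rec.dam is not None else -1
        row = np.zeros(n)
        if si >= 0:
            row += 0.5 * A[si]
        if di >= 0:
            row += 0.5 * A[di]
        A[i, :] = row
        A[:, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
    result = RelationshipMatrix(topo, A)
    if order is None:
        order = ped.animals
    return result.reorder(order)
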