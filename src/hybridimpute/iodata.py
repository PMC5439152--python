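"""Core containers and file dialects.

All files are plain whitespace-delimited text with the individual id in
column 1 (the AlphaImpute convention).  Genotypes are coded 0/1/2 with 9
for missing; per-gamete alleles are coded 0/1 with 9 for missing; dosages
are real numbers in [0, 2] written with 4 decimals.

A :class:`Pedigree` is held in topological order (every known parent
precedes its offspring) so that downstream sweeps can run parent-first in
a single pass.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

UNKNOWN_PARENT = "0"
MISSING = 9

__all__ = [
    "Pedigree",
    "MarkerMap",
    "PedigreeError",
    "InputError",
    "read_pedigree",
    "read_genotypes",
    "read_phase",
    "read_dosages",
    "read_marker_map",
    "write_outputs",
    "ImputationResult",
]


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, duplicate id)."""


class InputError(ValueError):
    """Malformed input file content."""


@dataclass
class Pedigree:
    """Ordered pedigree records ``(id, sire, dam)`` with "0" = unknown parent.

    Records are stored topologically sorted: parents always precede their
    offspring.  ``index`` maps id -> row position; ``sire_idx``/``dam_idx``
    give the parent row (or -1 for unknown) for vectorised sweeps.
    """

    ids: list[str]
    sires: list[str]
    dams: list[str]
    index: dict[str, int] = field(init=False, repr=False)
    sire_idx: np.ndarray = field(init=False, repr=False)
    dam_idx: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            for i in self.ids:
                if i in seen:
                    raise PedigreeError(f"duplicate individual id {i!r}")
                seen.add(i)
        self.index = {ind: i for i, ind in enumerate(self.ids)}
        self.sire_idx = np.array(
            [self.index.get(s, -1) if s != UNKNOWN_PARENT else -1 for s in self.sires],
            dtype=np.int64,
        )
        self.dam_idx = np.array(
            [self.index.get(d, -1) if d != UNKNOWN_PARENT else -1 for d in self.dams],
            dtype=np.int64,
        )
        order = np.arange(len(self.ids))
        if np.any(self.sire_idx >= order) or np.any(self.dam_idx >= order):
            raise PedigreeError("pedigree records are not in topological order")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, str]]) -> "Pedigree":
        """Build a pedigree from unordered records, topologically sorting them.

        Individuals that only ever appear as parents are appended as founders
        with unknown parents.
        """
        recs = [(str(i), str(s), str(d)) for i, s, d in records]
        ids = [r[0] for r in recs]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise PedigreeError(f"duplicate individual id {i!r}")
                seen.add(i)
        known = set(ids)
        parents_only: list[str] = []
        for _, s, d in recs:
            for p in (s, d):
                if p != UNKNOWN_PARENT and p not in known:
                    known.add(p)
                    parents_only.append(p)
        recs = [(p, UNKNOWN_PARENT, UNKNOWN_PARENT) for p in parents_only] + recs
        graph: dict[str, set[str]] = {}
        for ind, s, d in recs:
            deps = {p for p in (s, d) if p != UNKNOWN_PARENT}
            graph[ind] = deps
        sorter = graphlib.TopologicalSorter(graph)
        try:
            order = list(sorter.static_order())
        except graphlib.CycleError as exc:
            cyc = exc.args[1] if len(exc.args) > 1 else []
            name = cyc[0] if cyc else "?"
            raise PedigreeError(
                f"pedigree contains an ancestry cycle involving {name!r}"
            ) from exc
        by_id = {r[0]: r for r in recs}
        ordered = [by_id[i] for i in order]
        return cls(
            ids=[r[0] for r in ordered],
            sires=[r[1] for r in ordered],
            dams=[r[2] for r in ordered],
        )

    def subset_rows(self, genotype_ids: Sequence[str]) -> np.ndarray:
        """Row index in this pedigree of each id in ``genotype_ids``."""
        return np.array([self.index[g] for g in genotype_ids], dtype=np.int64)

    def founders(self) -> list[str]:
        return [
            i
            for i, s, d in zip(self.ids, self.sires, self.dams)
            if s == UNKNOWN_PARENT and d == UNKNOWN_PARENT
        ]

    def offspring_of(self) -> dict[int, list[int]]:
        """Map parent row -> rows of its offspring (either side)."""
        out: dict[int, list[int]] = {}
        for child in range(self.n):
            for p in (self.sire_idx[child], self.dam_idx[child]):
                if p >= 0:
                    out.setdefault(int(p), []).append(child)
        return out


@dataclass
class MarkerMap:
    """Marker identifiers and genetic positions (cM) for one chromosome."""

    marker_ids: list[str]
    positions_cm: np.ndarray
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.positions_cm = np.asarray(self.positions_cm, dtype=float)
        if np.any(np.diff(self.positions_cm) < 0):
            raise InputError("marker positions must be non-decreasing")

    @property
    def M(self) -> int:
        return len(self.marker_ids)

    @classmethod
    def default(cls, M: int) -> "MarkerMap":
        """Markers at 1 cM intervals when no map is supplied."""
        return cls(
            marker_ids=[f"m{i + 1}" for i in range(M)],
            positions_cm=np.arange(M, dtype=float),
        )


@dataclass
class ImputationResult:
    """Merged output of the hybrid pipeline.

    ``provenance`` holds per-gamete-per-marker flags: 0 = observed,
    1 = heuristic, 2 = hmm.
    """

    ids: list[str]
    genotypes: np.ndarray  # n x M int, {0,1,2,9}
    phase: np.ndarray  # 2n x M int, {0,1,9}
    dosages: np.ndarray  # n x M float in [0,2]
    allele_probs: np.ndarray  # 2n x M float in [0,1]
    provenance: np.ndarray  # 2n x M int8

    PROV_OBSERVED = 0
    PROV_HEURISTIC = 1
    PROV_HMM = 2


def _tokenised_rows(path: Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if toks:
                yield lineno, toks


def read_pedigree(path: str | Path) -> Pedigree:
    """Read ``id sire dam`` rows; returns a topologically ordered pedigree."""
    records = []
    for lineno, toks in _tokenised_rows(Path(path)):
        if len(toks) < 3:
            raise InputError(f"{path}:{lineno}: expected `id sire dam`")
        records.append((toks[0], toks[1], toks[2]))
    return Pedigree.from_records(records)


def _read_code_matrix(
    path: Path, valid: frozenset[int], rows_per_id: int
) -> tuple[list[str], np.ndarray]:
    ids: list[str] = []
    rows: list[np.ndarray] = []
    width = None
    for lineno, toks in _tokenised_rows(path):
        if len(rows) % rows_per_id == 0:
            ids.append(toks[0])
        elif toks[0] != ids[-1]:
            raise InputError(
                f"{path}:{lineno}: expected {rows_per_id} consecutive rows for id {ids[-1]!r}"
            )
        vals = toks[1:]
        if width is None:
            width = len(vals)
        elif len(vals) != width:
            raise InputError(f"{path}:{lineno}: ragged row ({len(vals)} != {width})")
        try:
            arr = np.array([int(v) for v in vals], dtype=np.int8)
        except ValueError as exc:
            raise InputError(f"{path}:{lineno}: non-integer code") from exc
        bad = ~np.isin(arr, list(valid))
        if np.any(bad):
            k = int(np.argmax(bad))
            raise InputError(
                f"{path}:{lineno}: invalid code {arr[k]} at marker {k + 1}"
            )
        rows.append(arr)
    if not rows:
        return [], np.zeros((0, 0), dtype=np.int8)
    return ids, np.vstack(rows)


def read_genotypes(path: str | Path, pedigree: Pedigree) -> np.ndarray:
    """Read ``id g1 .. gM`` rows into a matrix aligned to pedigree order.

    Individuals absent from the file get all-missing rows.
    """
    ids, mat = _read_code_matrix(Path(path), frozenset({0, 1, 2, MISSING}), 1)
    M = mat.shape[1] if mat.size else 0
    out = np.full((pedigree.n, M), MISSING, dtype=np.int8)
    for ind, row in zip(ids, mat):
        if ind not in pedigree.index:
            raise InputError(f"genotyped individual {ind!r} not in pedigree")
        out[pedigree.index[ind]] = row
    return out


def read_phase(path: str | Path, pedigree: Pedigree) -> np.ndarray:
    """Read two ``id a1 .. aM`` rows per individual (paternal then maternal)."""
    ids, mat = _read_code_matrix(Path(path), frozenset({0, 1, MISSING}), 2)
    M = mat.shape[1] if mat.size else 0
    out = np.full((2 * pedigree.n, M), MISSING, dtype=np.int8)
    for j, ind in enumerate(ids):
        if ind not in pedigree.index:
            raise InputError(f"phased individual {ind!r} not in pedigree")
        i = pedigree.index[ind]
        out[2 * i] = mat[2 * j]
        out[2 * i + 1] = mat[2 * j + 1]
    return out


def read_dosages(path: str | Path, pedigree: Pedigree) -> np.ndarray:
    rows: dict[str, np.ndarray] = {}
    width = None
    for lineno, toks in _tokenised_rows(Path(path)):
        vals = np.array([float(v) for v in toks[1:]], dtype=float)
        if width is None:
            width = len(vals)
        elif len(vals) != width:
            raise InputError(f"{path}:{lineno}: ragged row")
        rows[toks[0]] = vals
    out = np.full((pedigree.n, width or 0), np.nan, dtype=float)
    for ind, row in rows.items():
        if ind not in pedigree.index:
            raise InputError(f"individual {ind!r} not in pedigree")
        out[pedigree.index[ind]] = row
    return out


def read_marker_map(path: str | Path) -> MarkerMap:
    """Read ``marker_id chrom position_cM`` rows."""
    mids: list[str] = []
    chroms: set[str] = set()
    pos: list[float] = []
    for lineno, toks in _tokenised_rows(Path(path)):
        if len(toks) < 3:
            raise InputError(f"{path}:{lineno}: expected `marker_id chrom position_cM`")
        mids.append(toks[0])
        chroms.add(toks[1])
        pos.append(float(toks[2]))
    if len(chroms) > 1:
        raise InputError("one chromosome per map file")
    return MarkerMap(mids, np.array(pos), chrom=chroms.pop() if chroms else "1")


def _write_int_rows(path: Path, ids: Iterable[str], mat: np.ndarray) -> None:
    with open(path, "w") as fh:
        for ind, row in zip(ids, mat):
            fh.write(ind + " " + " ".join(str(int(v)) for v in row) + "\n")


def write_outputs(result: ImputationResult, prefix: str | Path) -> dict[str, Path]:
    """Write genotype, phase, dosage and allele-probability files.

    Returns the mapping of file kind to path.  Dosages and probabilities are
    fixed point with 4 decimals; a round-trip read reproduces integer codes
    exactly and real values to 4 decimals.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": prefix.with_name(prefix.name + ".genotypes.txt"),
        "phase": prefix.with_name(prefix.name + ".phase.txt"),
        "dosages": prefix.with_name(prefix.name + ".dosages.txt"),
        "alleleprobs": prefix.with_name(prefix.name + ".alleleprobs.txt"),
    }
    _write_int_rows(paths["genotypes"], result.ids, result.genotypes)
    with open(paths["phase"], "w") as fh:
        for i, ind in enumerate(result.ids):
            for g in (2 * i, 2 * i + 1):
                fh.write(ind + " " + " ".join(str(int(v)) for v in result.phase[g]) + "\n")
    with open(paths["dosages"], "w") as fh:
        for ind, row in zip(result.ids, result.dosages):
            fh.write(ind + " " + " ".join(f"{v:.4f}" for v in row) + "\n")
    with open(paths["alleleprobs"], "w") as fh:
        for i, ind in enumerate(result.ids):
            for g in (2 * i, 2 * i + 1):
                fh.write(
                    ind + " " + " ".join(f"{v:.4f}" for v in result.allele_probs[g]) + "\n"
                )
    return paths
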