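"""Coding species distributions into binary region characters.

Occurrence records ("taxon X is present in area Y") at mixed spatial
scales are expanded down a containment hierarchy to the finest areas
recorded anywhere in the dataset, scored into a taxa × areas presence/
absence matrix, and then simplified by two merge rules:

1. neighbouring regions with *identical* taxon presence/absence columns
   are combined (nearest pair first) until every region carries unique
   information about how taxa group in space;
2. regions occupied by a single taxon (autapomorphic region characters,
   phylogenetically uninformative) are merged into their geographically
   closest neighbour.

Rule 2 can create new duplicates or new autapomorphies, so the pipeline
iterates both rules to a fixpoint; termination is guaranteed because the
region count strictly decreases at each merge.  Every merge is recorded
in an audit log.
"""

from __future__ import annotations

import csv
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np


class RegionCodingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# input containers


@dataclass
class OccurrenceTable:
    """Flat list of (taxon, area) presence assertions."""

    records: list[tuple[str, str]]

    @classmethod
    def from_csv(cls, path) -> "OccurrenceTable":
        records = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].startswith("#") or row[:2] == ["taxon", "area"]:
                    continue
                records.append((row[0].strip(), row[1].strip()))
        return cls(records)

    def taxa(self) -> list[str]:
        seen = dict.fromkeys(t for t, _ in self.records)
        return list(seen)


@dataclass
class AreaHierarchy:
    """Containment forest over areas: parent area → set of child areas.

    An area that appears in no containment relation is its own
    finest-scale area.  Pass ``areas`` to declare the full vocabulary
    explicitly, in which case occurrence records naming anything outside
    it are rejected (catches misspellings).
    """

    containment: dict[str, set[str]]
    areas: Optional[set[str]] = None

    def __post_init__(self):
        parents: dict[str, str] = {}
        for parent, children in self.containment.items():
            for child in children:
                if child in parents:
                    raise RegionCodingError(f"area {child!r} has two parents")
                parents[child] = parent
        # cycle check: walk up from every area
        for area in parents:
            seen = set()
            cur: Optional[str] = area
            while cur is not None:
                if cur in seen:
                    raise RegionCodingError(f"containment cycle through {area!r}")
                seen.add(cur)
                cur = parents.get(cur)
        self._parents = parents

    @classmethod
    def from_csv(cls, path) -> "AreaHierarchy":
        containment: dict[str, set[str]] = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].startswith("#") or row[:2] == ["parent", "child"]:
                    continue
                containment.setdefault(row[0].strip(), set()).add(row[1].strip())
        return cls(containment)

    def known_areas(self) -> set[str]:
        areas = set(self.containment)
        for children in self.containment.values():
            areas |= children
        return areas

    def leaves_under(self, area: str) -> set[str]:
        """Finest-scale (leaf) areas beneath or equal to ``area``."""
        children = self.containment.get(area)
        if not children:
            return {area}
        out: set[str] = set()
        for child in children:
            out |= self.leaves_under(child)
        return out


@dataclass
class RegionGeography:
    """Symmetric inter-region distances with optional explicit adjacency.

    Merged regions inherit the *minimum* distance over their constituents
    (single linkage), which keeps the "closest neighbour" relation well
    defined and order independent throughout the merge cascade.
    """

    distance: dict[frozenset, float]
    adjacency: Optional[set[frozenset]] = None
    adjacency_threshold: Optional[float] = None

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str, float]], *,
                   adjacency_threshold: Optional[float] = None) -> "RegionGeography":
        dist = {}
        for a, b, d in pairs:
            if d < 0:
                raise RegionCodingError("negative distance")
            dist[frozenset((a, b))] = float(d)
        adjacency = None
        if adjacency_threshold is not None:
            adjacency = {k for k, d in dist.items() if d <= adjacency_threshold}
        return cls(dist, adjacency, adjacency_threshold)

    @classmethod
    def from_csv(cls, path, **kw) -> "RegionGeography":
        pairs = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].startswith("#") or row[0] == "region_a":
                    continue
                pairs.append((row[0].strip(), row[1].strip(), float(row[2])))
        return cls.from_pairs(pairs, **kw)

    @classmethod
    def ring(cls, regions: Sequence[str]) -> "RegionGeography":
        """Unit-spaced ring geography (shortest arc distance)."""
        n = len(regions)
        pairs = []
        for i, j in itertools.combinations(range(n), 2):
            d = min(j - i, n - (j - i))
            pairs.append((regions[i], regions[j], float(d)))
        return cls.from_pairs(pairs, adjacency_threshold=1.0)

    def get(self, a: Iterable[str] | str, b: Iterable[str] | str) -> float:
        """Distance between (possibly composite) regions, single linkage.

        Composite regions are passed as iterables of constituent ids.
        """
        aset = {a} if isinstance(a, str) else set(a)
        bset = {b} if isinstance(b, str) else set(b)
        best = None
        for x in aset:
            for y in bset:
                if x == y:
                    return 0.0
                d = self.distance.get(frozenset((x, y)))
                if d is not None and (best is None or d < best):
                    best = d
        if best is None:
            raise RegionCodingError(f"no distance between {sorted(aset)} and {sorted(bset)}")
        return best

    def are_adjacent(self, a, b) -> bool:
        if self.adjacency is None:
            return True  # no adjacency notion: every pair is mergeable
        aset = {a} if isinstance(a, str) else set(a)
        bset = {b} if isinstance(b, str) else set(b)
        return any(frozenset((x, y)) in self.adjacency
                   for x in aset for y in bset if x != y)

    def neighbours_of(self, region: Iterable[str] | str) -> set[str]:
        rset = {region} if isinstance(region, str) else set(region)
        out = set()
        for key in (self.adjacency if self.adjacency is not None else self.distance):
            x, y = tuple(key) if len(key) == 2 else (next(iter(key)),) * 2
            if x in rset and y not in rset:
                out.add(y)
            elif y in rset and x not in rset:
                out.add(x)
        return out


# ---------------------------------------------------------------------------
# the matrix


def _region_id(constituents: Iterable[str]) -> str:
    return "+".join(sorted(constituents))


@dataclass
class RegionMatrix:
    """Taxa × binary region characters with merge provenance.

    ``regions`` are display ids; ``constituents`` maps each region id to
    the set of finest-scale areas it covers.  ``merge_log`` records every
    merge event as a dict with keys ``merged`` (the two region ids
    combined), ``into``, and ``rule``.
    """

    taxa: list[str]
    regions: list[str]
    entries: np.ndarray  # shape (n_taxa, n_regions), dtype int8, values {0,1}
    constituents: dict[str, frozenset] = field(default_factory=dict)
    merge_log: list[dict] = field(default_factory=list)
    untestable: bool = False

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=np.int8)
        if self.entries.shape != (len(self.taxa), len(self.regions)):
            raise RegionCodingError("matrix shape does not match taxa/regions")
        if self.entries.size and not np.isin(self.entries, (0, 1)).all():
            raise RegionCodingError("matrix entries must be 0/1")
        if self.entries.size and (self.entries.sum(axis=1) == 0).any():
            empty = [t for t, row in zip(self.taxa, self.entries) if row.sum() == 0]
            raise RegionCodingError(f"taxa present nowhere: {empty}")
        if not self.constituents:
            self.constituents = {r: frozenset([r]) for r in self.regions}

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def column(self, region: str) -> np.ndarray:
        return self.entries[:, self.regions.index(region)]

    def informative_columns(self) -> np.ndarray:
        """Boolean mask of parsimony-informative characters (≥2 of each state)."""
        ones = self.entries.sum(axis=0)
        zeros = self.n_taxa - ones
        return (ones >= 2) & (zeros >= 2)

    def is_testable(self) -> bool:
        return not self.untestable and bool(self.informative_columns().any())

    def copy(self) -> "RegionMatrix":
        return RegionMatrix(
            list(self.taxa), list(self.regions), self.entries.copy(),
            dict(self.constituents), [dict(e) for e in self.merge_log],
            self.untestable,
        )

    # -- I/O ----------------------------------------------------------------

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["taxon"] + self.regions)
            for taxon, row in zip(self.taxa, self.entries):
                w.writerow([taxon] + [int(x) for x in row])

    @classmethod
    def from_csv(cls, path) -> "RegionMatrix":
        with open(path, newline="") as fh:
            rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
        regions = rows[0][1:]
        taxa = [r[0] for r in rows[1:]]
        entries = np.array([[int(x) for x in r[1:]] for r in rows[1:]], dtype=np.int8)
        return cls(taxa, regions, entries)

    def to_nexus(self, path) -> None:
        """Write as a NEXUS standard-data matrix (symbols 0/1)."""
        def q(name: str) -> str:
            return f"'{name}'" if any(c in name for c in " ()[]{}/\\,;:=*\"`<>") else name
        lines = [
            "#NEXUS", "BEGIN DATA;",
            f"    DIMENSIONS NTAX={self.n_taxa} NCHAR={self.n_regions};",
            '    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;',
            "    MATRIX",
        ]
        for taxon, row in zip(self.taxa, self.entries):
            lines.append(f"    {q(taxon)}  {''.join(str(int(x)) for x in row)}")
        lines += ["    ;", "END;", ""]
        Path(path).write_text("\n".join(lines))

    @classmethod
    def from_nexus(cls, path) -> "RegionMatrix":
        import dendropy

        cm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
        taxa = [t.label for t in cm.taxon_namespace]
        entries = np.array(
            [[int(str(cell)) for cell in cm[t]] for t in cm.taxon_namespace],
            dtype=np.int8,
        )
        regions = [f"r{i+1}" for i in range(entries.shape[1])]
        return cls(taxa, regions, entries)

    def write_merge_log(self, path) -> None:
        with open(path, "w") as fh:
            for event in self.merge_log:
                fh.write(json.dumps(event) + "\n")


# ---------------------------------------------------------------------------
# coding operations


def expand_to_finest(occ: OccurrenceTable, hier: AreaHierarchy) -> dict[str, set[str]]:
    """Expand each taxon's recorded areas to finest-scale (leaf) areas.

    A taxon recorded in a composite area is coded present in every leaf
    area beneath it, matching the finest scale represented anywhere in
    the dataset.
    """
    if hier.areas is not None:
        known = hier.areas | hier.known_areas()
        unknown = sorted({a for _, a in occ.records} - known)
        if unknown:
            raise RegionCodingError(f"areas not in hierarchy: {unknown}")
    sets: dict[str, set[str]] = {}
    for taxon, area in occ.records:
        sets.setdefault(taxon, set()).update(hier.leaves_under(area))
    for taxon, areas in sets.items():
        if not areas:
            raise RegionCodingError(f"taxon {taxon!r} maps to no finest-scale area")
    return sets


def build_region_matrix(sets: dict[str, set[str]]) -> RegionMatrix:
    """Score per-taxon area sets into a presence/absence matrix.

    Columns are the union of areas used by at least one taxon, in sorted
    order; rows follow the insertion order of ``sets``.
    """
    if len(sets) < 2:
        raise RegionCodingError("need at least 2 taxa")
    taxa = list(sets)
    regions = sorted(set().union(*sets.values()))
    entries = np.zeros((len(taxa), len(regions)), dtype=np.int8)
    for i, taxon in enumerate(taxa):
        for area in sets[taxon]:
            entries[i, regions.index(area)] = 1
    return RegionMatrix(taxa, regions, entries)


def _merge_columns(m: RegionMatrix, i: int, j: int, rule: str) -> RegionMatrix:
    """Merge region columns i and j (i < j) by element-wise OR."""
    ra, rb = m.regions[i], m.regions[j]
    merged_constituents = m.constituents[ra] | m.constituents[rb]
    new_id = _region_id(merged_constituents)
    new_col = np.maximum(m.entries[:, i], m.entries[:, j])
    keep = [k for k in range(m.n_regions) if k not in (i, j)]
    regions = [m.regions[k] for k in keep] + [new_id]
    entries = np.column_stack([m.entries[:, keep], new_col]) if keep else new_col[:, None]
    constituents = {r: m.constituents[r] for r in (m.regions[k] for k in keep)}
    constituents[new_id] = merged_constituents
    log = m.merge_log + [{"merged": sorted((ra, rb)), "into": new_id, "rule": rule}]
    # keep columns in stable sorted-id order for order-invariance
    order = sorted(range(len(regions)), key=lambda k: regions[k])
    return RegionMatrix(
        list(m.taxa), [regions[k] for k in order], entries[:, order],
        constituents, log, m.untestable,
    )


def _closest_pair(m: RegionMatrix, geo: RegionGeography,
                  candidates: list[tuple[int, int]]) -> tuple[int, int, float, bool]:
    """Among candidate column pairs, pick the geographically closest.

    Ties break on the lexicographic (smaller id, larger id) pair.  Returns
    (i, j, distance, adjacent).
    """
    best = None
    for i, j in candidates:
        ra, rb = m.regions[i], m.regions[j]
        d = geo.get(m.constituents[ra], m.constituents[rb])
        adj = geo.are_adjacent(m.constituents[ra], m.constituents[rb])
        key = (not adj, d, tuple(sorted((ra, rb))))
        if best is None or key < best[0]:
            best = (key, i, j, d, adj)
    _, i, j, d, adj = best
    return i, j, d, adj


def merge_identical_regions(m: RegionMatrix, geo: RegionGeography) -> RegionMatrix:
    """Combine regions with identical presence/absence columns.

    Adjacent duplicates merge first, closest pair first; once adjacent
    merges are exhausted, remaining duplicate pairs are merged
    closest-first regardless of adjacency (logged with rule
    ``nonadjacent-duplicate``) so that the end condition — all regions
    carry unique taxon presence/absences — always holds.
    """
    m = m.copy()
    while True:
        cols = {tuple(m.entries[:, k]): [] for k in range(m.n_regions)}
        for k in range(m.n_regions):
            cols[tuple(m.entries[:, k])].append(k)
        dupes = [idx for idx in cols.values() if len(idx) > 1]
        if not dupes:
            return m
        candidates = [(i, j) for idx in dupes for i, j in itertools.combinations(idx, 2)]
        i, j, _, adj = _closest_pair(m, geo, candidates)
        rule = "identical-adjacent" if adj else "nonadjacent-duplicate"
        m = _merge_columns(m, min(i, j), max(i, j), rule)


def merge_autapomorphic_regions(m: RegionMatrix, geo: RegionGeography) -> RegionMatrix:
    """Merge single-taxon regions into their geographically closest neighbour.

    A region present for exactly one taxon is an autapomorphic character
    and cannot inform grouping; it is absorbed (element-wise OR) into the
    closest other region.  Identical-column merging is re-applied
    afterwards, and the two rules iterate to a fixpoint.
    """
    m = m.copy()
    while m.n_regions > 1:
        sums = m.entries.sum(axis=0)
        singles = [k for k in range(m.n_regions) if sums[k] == 1]
        if not singles:
            break
        # absorb the lexicographically first autapomorphic region
        k = min(singles, key=lambda x: m.regions[x])
        others = [x for x in range(m.n_regions) if x != k]
        candidates = [(min(k, x), max(k, x)) for x in others]
        i, j, _, _ = _closest_pair(m, geo, candidates)
        m = _merge_columns(m, i, j, "autapomorphic")
        m = merge_identical_regions(m, geo)
    return m


def code_regions(occ: OccurrenceTable, hier: AreaHierarchy, geo: RegionGeography,
                 *, merge_autapomorphies: bool = True) -> RegionMatrix:
    """Full coding pipeline: expand → score → merge to a fixpoint.

    The returned matrix has pairwise-distinct columns and (by default) no
    single-presence columns.  If the result collapses to a single region
    or retains no variable column it is flagged ``untestable`` and
    downstream congruence tests will refuse it.
    """
    sets = expand_to_finest(occ, hier)
    m = build_region_matrix(sets)
    initial = m.n_regions
    m = merge_identical_regions(m, geo)
    if merge_autapomorphies:
        m = merge_autapomorphic_regions(m, geo)
    variable = (m.entries.sum(axis=0) % m.n_taxa != 0).any()
    if m.n_regions <= 1 or not variable:
        m.untestable = True
    m.merge_log.append({
        "summary": {"initial_regions": initial, "final_regions": m.n_regions,
                    "untestable": m.untestable},
    })
    return m
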