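"""Interval handling, alignment extraction, and group construction.

Elements (ChIP-seq peaks) arrive as BED intervals on a reference
genome.  This module filters them against exclusion lists (UTRs, CDSs,
known accelerated regions), extracts their alignments from a MAF
genome alignment or a directory of per-element FASTA files, applies the
informative-site quality filter, builds composite groups (k-of-n
co-binding, pairwise intersection), and removes elements claimed by
more than one group.

All coordinates are 0-based half-open (BED convention); abutting
intervals do not overlap.
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO

from .phylo_engine import _IUPAC, Alignment

UNAMBIGUOUS = set("ACGT")


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def element_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class TFBSGroup:
    """A named group of elements with their extracted alignments."""

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    alignments: dict[str, Alignment] = field(default_factory=dict)
    informative_counts: dict[str, int] = field(default_factory=dict)


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3+ intervals; column 4, when present, is the group label."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric coordinates"
                ) from exc
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = None
            if len(parts) > 4:
                try:
                    score = float(parts[4])
                except ValueError:
                    score = None
            try:
                out.append(GenomicInterval(parts[0], start, end, name, score))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def exclude_regions(intervals, exclusions) -> list[GenomicInterval]:
    """Drop any interval overlapping (>= 1 bp) any exclusion; no trimming."""
    by_chrom = defaultdict(list)
    for e in exclusions:
        by_chrom[e.chrom].append((e.start, e.end))
    for v in by_chrom.values():
        v.sort()
    out = []
    for iv in intervals:
        excl = by_chrom.get(iv.chrom, [])
        if not any(s < iv.end and iv.start < e for s, e in excl):
            out.append(iv)
    return out


class MafSource:
    """Per-element alignment extraction from a MAF genome alignment.

    Blocks are indexed by the reference species' coordinates.  For an
    interval, columns at reference positions in [start, end) are pulled
    from the covering blocks in order; columns where the reference row
    has a gap are dropped (elements are defined in reference
    coordinates), and species absent from a covering block contribute
    missing characters.
    """

    def __init__(self, path, ref_species: str, taxa: list[str]):
        self.ref_species = ref_species
        self.taxa = list(taxa)
        self._blocks = defaultdict(list)  # chrom -> [(start, end, block)]
        with open(path) as fh:
            for block in AlignIO.parse(fh, "maf"):
                ref_rec = None
                for rec in block:
                    sp, _, chrom = rec.id.partition(".")
                    if sp == ref_species:
                        ref_rec = (rec, chrom)
                        break
                if ref_rec is None:
                    continue
                rec, chrom = ref_rec
                start = rec.annotations["start"]
                size = rec.annotations["size"]
                if rec.annotations.get("strand", 1) != 1:
                    raise ValueError(
                        "reference rows must be on the + strand"
                    )
                self._blocks[chrom].append((start, start + size, block))
        for v in self._blocks.values():
            v.sort(key=lambda t: t[0])

    def extract(self, interval: GenomicInterval) -> Alignment:
        blocks = [
            (s, e, b)
            for s, e, b in self._blocks.get(interval.chrom, [])
            if s < interval.end and interval.start < e
        ]
        if not blocks:
            raise ValueError(
                f"no alignment coverage for {interval.element_id}"
            )
        columns = {t: [] for t in self.taxa}
        for bstart, bend, block in blocks:
            rows = {}
            for rec in block:
                sp, _, _ = rec.id.partition(".")
                rows[sp] = str(rec.seq).upper()
            ref_row = rows[self.ref_species]
            pos = bstart
            for col, ch in enumerate(ref_row):
                if ch == "-":
                    continue  # reference-deletion column: skip
                if interval.start <= pos < interval.end:
                    for t in self.taxa:
                        c = rows.get(t, "N" * len(ref_row))[col]
                        columns[t].append(c if c in _IUPAC else "N")
                pos += 1
        seqs = {t: "".join(v) for t, v in columns.items()}
        return Alignment(seqs, element_id=interval.element_id)


class FastaDirSource:
    """Per-element alignments stored as <element_id>.fa multi-FASTA files."""

    def __init__(self, directory):
        self.directory = directory

    def extract(self, interval: GenomicInterval) -> Alignment:
        fname = interval.element_id.replace(":", "_") + ".fa"
        path = os.path.join(self.directory, fname)
        if not os.path.exists(path):
            raise ValueError(f"no alignment file for {interval.element_id}")
        seqs = {}
        with open(path) as fh:
            label = None
            chunks: list[str] = []
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if label is not None:
                        seqs[label] = "".join(chunks)
                    label = line[1:].split()[0]
                    chunks = []
                else:
                    chunks.append(line.upper())
            if label is not None:
                seqs[label] = "".join(chunks)
        return Alignment(seqs, element_id=interval.element_id)


def extract_element_alignment(source, interval: GenomicInterval) -> Alignment:
    """Extract one element's alignment from a MAF or FASTA-directory source."""
    return source.extract(interval)


def count_informative_sites(aln: Alignment, min_species: int = 5) -> int:
    """Columns with unambiguous A/C/G/T in at least ``min_species`` rows."""
    if min_species < 1:
        raise ValueError("min_species must be >= 1")
    if not aln.sequences:
        return 0
    rows = np.array([list(s.upper()) for s in aln.sequences.values()])
    good = np.isin(rows, list(UNAMBIGUOUS)).sum(axis=0)
    return int(np.sum(good >= min_species))


def filter_elements(
    groups: list[TFBSGroup], min_informative: int = 50, min_species: int = 5
) -> list[TFBSGroup]:
    """Drop elements with fewer than ``min_informative`` informative sites."""
    out = []
    for g in groups:
        kept = TFBSGroup(name=g.name)
        for iv in g.intervals:
            aln = g.alignments.get(iv.element_id)
            if aln is None:
                continue
            n_inf = g.informative_counts.get(iv.element_id)
            if n_inf is None:
                n_inf = count_informative_sites(aln, min_species)
            if n_inf >= min_informative:
                kept.intervals.append(iv)
                kept.alignments[iv.element_id] = aln
                kept.informative_counts[iv.element_id] = n_inf
        out.append(kept)
    return out


def _merged(intervals) -> dict[str, list[tuple[int, int]]]:
    """Per-chromosome merged (union) intervals."""
    by_chrom = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append((iv.start, iv.end))
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = [tuple(v) for v in merged]
    return out


def _coverage_runs(per_factor_merged, k: int) -> list[GenomicInterval]:
    """Maximal runs of bases covered by >= k of the factors."""
    chroms = set()
    for m in per_factor_merged:
        chroms.update(m)
    out = []
    for chrom in sorted(chroms):
        events = []
        for m in per_factor_merged:
            for s, e in m.get(chrom, []):
                events.append((s, 1))
                events.append((e, -1))
        events.sort()
        depth, run_start = 0, None
        for pos, delta in events:
            prev = depth
            depth += delta
            if prev < k <= depth:
                run_start = pos
            elif prev >= k > depth and run_start is not None:
                if pos > run_start:
                    out.append(GenomicInterval(chrom, run_start, pos))
                run_start = None
    return out


def define_composite_groups(
    factor_intervals: dict[str, list[GenomicInterval]],
    rule: str,
    factors: list[str],
    k: int | None = None,
    name: str | None = None,
) -> tuple[TFBSGroup, dict[str, list[GenomicInterval]]]:
    """Build a composite group and remove its members from source factors.

    ``rule`` is 'k_of_n' (bases covered by peaks of at least k of the
    listed factors; base-level logic) or 'intersection' (base-level
    intersection of exactly two factors' coverage).  Source factors lose
    any peak overlapping a composite region; the pruned source map is
    returned alongside the composite group.
    """
    unknown = [f for f in factors if f not in factor_intervals]
    if unknown:
        raise ValueError(f"unknown factors: {unknown}")
    merged = [_merged(factor_intervals[f]) for f in factors]
    if rule == "k_of_n":
        if k is None:
            raise ValueError("k_of_n rule needs k")
        regions = _coverage_runs(merged, k)
    elif rule == "intersection":
        if len(factors) != 2:
            raise ValueError("intersection rule takes exactly two factors")
        regions = _coverage_runs(merged, 2)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    composite = TFBSGroup(
        name=name or "+".join(factors), intervals=regions
    )
    pruned = dict(factor_intervals)
    for f in factors:
        pruned[f] = [
            iv
            for iv in factor_intervals[f]
            if not any(iv.overlaps(r) for r in regions)
        ]
    return composite, pruned


def remove_multigroup_overlaps(groups: list[TFBSGroup]) -> list[TFBSGroup]:
    """Remove every element that overlaps an element of a different group.

    Within-group overlaps are untouched.  Both sides of a cross-group
    overlap are removed.
    """
    doomed: set[tuple[str, str]] = set()
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            for iv1 in g1.intervals:
                for iv2 in g2.intervals:
                    if iv1.overlaps(iv2):
                        doomed.add((g1.name, iv1.element_id))
                        doomed.add((g2.name, iv2.element_id))
    out = []
    for g in groups:
        kept = TFBSGroup(name=g.name)
        for iv in g.intervals:
            if (g.name, iv.element_id) in doomed:
                continue
            kept.intervals.append(iv)
            if iv.element_id in g.alignments:
                kept.alignments[iv.element_id] = g.alignments[iv.element_id]
            if iv.element_id in g.informative_counts:
                kept.informative_counts[iv.element_id] = (
                    g.informative_counts[iv.element_id]
                )
        out.append(kept)
    return out


def concatenate_group(group: TFBSGroup) -> Alignment:
    """Concatenate a group's element alignments in member order."""
    alns = [
        group.alignments[iv.element_id]
        for iv in group.intervals
        if iv.element_id in group.alignments
    ]
    if not alns:
        raise ValueError(f"group {group.name!r} has no alignments")
    return Alignment.concatenate(alns, element_id=group.name)
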