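"""Genomic interval primitives: BED I/O, overlap/nearest queries, chain liftover.

Coordinates are 0-based, half-open (BED convention) everywhere, including the
stable region identifier ``"chrom:start-end"``.  Chromosome names are matched
by exact string equality; no "chr" prefix aliasing is applied here (the CLI
offers an optional prefix normalization).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomicRegion",
    "PeakSet",
    "ChainBlock",
    "ChainAlignment",
    "parse_bed",
    "write_bed",
    "read_chain_file",
    "overlap_bp",
    "nearest_region",
    "match_features",
    "liftover_regions",
    "liftover_with_index",
    "pool_peaks",
]

_ID_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


class BedParseError(ValueError):
    """Raised for malformed BED input; carries the 1-based line number."""


@dataclass(frozen=True)
class GenomicRegion:
    """A genomic interval [start, end) on ``chrom`` with an optional peak score."""

    chrom: str
    start: int
    end: int
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got {self.chrom}:{self.start}-{self.end}"
            )
        if self.score is not None and self.score < 0:
            raise ValueError(f"score must be non-negative, got {self.score}")

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def from_id(cls, region_id: str, score: float | None = None) -> "GenomicRegion":
        m = _ID_RE.match(region_id)
        if m is None:
            raise ValueError(f"malformed region id {region_id!r}")
        return cls(m["chrom"], int(m["start"]), int(m["end"]), score)

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


class PeakSet:
    """An ordered, sorted collection of unique genomic regions.

    Regions are sorted by (chrom, start, end); ids are unique.  ``genome_build``
    tags the assembly so that mismatched inputs fail loudly instead of silently
    mismatching coordinates.
    """

    def __init__(
        self,
        regions: Iterable[GenomicRegion],
        genome_build: str = "hg38",
    ) -> None:
        regs = sorted(regions, key=GenomicRegion.sort_key)
        seen: set[str] = set()
        for r in regs:
            if r.id in seen:
                raise ValueError(f"duplicate region id {r.id}")
            seen.add(r.id)
        self.regions: tuple[GenomicRegion, ...] = tuple(regs)
        self.genome_build = genome_build
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[GenomicRegion]:
        return iter(self.regions)

    def __getitem__(self, i: int) -> GenomicRegion:
        return self.regions[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.regions == other.regions and self.genome_build == other.genome_build

    def __repr__(self) -> str:
        return f"PeakSet({len(self)} regions, build={self.genome_build!r})"

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.regions)

    def index_of(self, region_id: str) -> int:
        try:
            return self.ids.index(region_id)
        except ValueError:
            raise KeyError(region_id) from None

    def _chrom_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        # (starts, ends, original indices) per chromosome, in sorted order
        if self._by_chrom is None:
            by: dict[str, list[list[int]]] = {}
            for i, r in enumerate(self.regions):
                by.setdefault(r.chrom, [[], [], []])
                by[r.chrom][0].append(r.start)
                by[r.chrom][1].append(r.end)
                by[r.chrom][2].append(i)
            self._by_chrom = {
                c: (np.asarray(v[0]), np.asarray(v[1]), np.asarray(v[2]))
                for c, v in by.items()
            }
        return self._by_chrom

    def subset(self, indices: Sequence[int]) -> "PeakSet":
        return PeakSet((self.regions[i] for i in indices), self.genome_build)


def pool_peaks(peak_sets: Iterable[PeakSet], genome_build: str | None = None) -> PeakSet:
    """Pool several peak sets into one, keeping the highest score for identical coordinates."""
    best: dict[str, GenomicRegion] = {}
    build = genome_build
    for ps in peak_sets:
        if build is None:
            build = ps.genome_build
        for r in ps:
            prev = best.get(r.id)
            if prev is None:
                best[r.id] = r
            else:
                s_new = -math.inf if r.score is None else r.score
                s_old = -math.inf if prev.score is None else prev.score
                if s_new > s_old:
                    best[r.id] = r
    return PeakSet(best.values(), build or "hg38")


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def parse_bed(source: str | IO[str], genome_build: str = "hg38") -> PeakSet:
    """Parse BED3/BED5 text into a sorted :class:`PeakSet`.

    Column 5, when present, is taken as the peak-calling score.  Comment,
    ``track`` and ``browser`` lines are skipped.  Malformed coordinates raise
    :class:`BedParseError` naming the offending line.
    """
    close = False
    if isinstance(source, str):
        fh: IO[str] = open(source)
        close = True
    else:
        fh = source
    regions: list[GenomicRegion] = []
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"line {lineno}: non-integer coordinates {fields[1]!r}, {fields[2]!r}"
                ) from None
            score = None
            if len(fields) >= 5 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise BedParseError(
                        f"line {lineno}: non-numeric score {fields[4]!r}"
                    ) from None
            try:
                regions.append(GenomicRegion(chrom, start, end, score))
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from None
    finally:
        if close:
            fh.close()
    return PeakSet(regions, genome_build)


def write_bed(peaks: PeakSet, dest: str | IO[str]) -> None:
    """Write a PeakSet as BED (BED5 when any region carries a score)."""
    close = False
    if isinstance(dest, str):
        fh: IO[str] = open(dest, "w")
        close = True
    else:
        fh = dest
    try:
        has_score = any(r.score is not None for r in peaks)
        for r in peaks:
            if has_score:
                score = "." if r.score is None else f"{r.score:g}"
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\t{score}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# Overlap / nearest queries
# ---------------------------------------------------------------------------

def overlap_bp(a: GenomicRegion, b: GenomicRegion) -> int:
    """Base pairs of overlap between two half-open intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def nearest_region(query: GenomicRegion, targets: PeakSet) -> tuple[int, float]:
    """Index and edge-gap distance of the target nearest to ``query``.

    Distance is 0 for overlapping regions and the gap in bp between nearest
    edges otherwise (abutting half-open regions therefore have distance 0
    despite zero overlap).  Targets on other chromosomes are infinitely far.
    Ties are broken toward the lowest target index.
    """
    if len(targets) == 0:
        raise ValueError("targets must be non-empty")
    arrays = targets._chrom_arrays().get(query.chrom)
    if arrays is None:
        return (0, math.inf)
    starts, ends, idx = arrays
    # gap = max(starts, q.start) - min(ends, q.end), clipped at 0 (overlap -> 0)
    gap = np.maximum(np.maximum(starts, query.start) - np.minimum(ends, query.end), 0)
    j = int(np.argmin(gap))  # argmin returns first minimum -> leftmost by sort order
    return (int(idx[j]), float(gap[j]))


def match_features(
    bulk_peaks: PeakSet, ref_peaks: PeakSet
) -> dict[int, int | None]:
    """Map each bulk peak index to its nearest overlapping reference peak index.

    A bulk peak maps to its nearest reference peak iff they share at least one
    bp; otherwise it maps to ``None``.  Several bulk peaks may map to the same
    reference peak.
    """
    if bulk_peaks.genome_build != ref_peaks.genome_build:
        raise ValueError(
            f"genome build mismatch: bulk={bulk_peaks.genome_build!r} vs "
            f"reference={ref_peaks.genome_build!r}; lift the bulk peaks over first"
        )
    mapping: dict[int, int | None] = {}
    ref_arrays = ref_peaks._chrom_arrays()
    for i, r in enumerate(bulk_peaks):
        arrays = ref_arrays.get(r.chrom)
        if arrays is None:
            mapping[i] = None
            continue
        starts, ends, idx = arrays
        ov = np.minimum(ends, r.end) - np.maximum(starts, r.start)
        hit = np.nonzero(ov > 0)[0]
        mapping[i] = int(idx[hit[0]]) if hit.size else None
    return mapping


# ---------------------------------------------------------------------------
# Chain liftover
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainBlock:
    """One aligned block: ``size`` aligned bases, then gaps on each genome."""

    size: int
    source_gap: int = 0
    target_gap: int = 0

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("block size must be > 0")
        if self.source_gap < 0 or self.target_gap < 0:
            raise ValueError("gaps must be non-negative")


@dataclass
class ChainAlignment:
    """A UCSC chain: block-wise alignment from a source to a target assembly.

    ``source_*`` fields correspond to the chain's ``t`` (from) genome and
    ``target_*`` fields to its ``q`` (to) genome.  When ``target_strand`` is
    ``"-"``, target block coordinates live in reverse-complement space and are
    flipped against ``target_size`` during mapping.
    """

    score: float
    source_chrom: str
    source_size: int
    source_strand: str
    source_start: int
    source_end: int
    target_chrom: str
    target_size: int
    target_strand: str
    target_start: int
    target_end: int
    blocks: list[ChainBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        span_s = sum(b.size + b.source_gap for b in self.blocks)
        span_t = sum(b.size + b.target_gap for b in self.blocks)
        if self.source_start + span_s > self.source_size:
            raise ValueError("chain source span exceeds source chromosome size")
        if self.target_start + span_t > self.target_size:
            raise ValueError("chain target span exceeds target chromosome size")

    def map_position(self, pos: int) -> tuple[int, int] | None:
        """Map a 0-based source position to (block index, forward target position).

        Returns None when the position falls outside every aligned block.
        """
        s = self.source_start
        t = self.target_start
        for bi, b in enumerate(self.blocks):
            if s <= pos < s + b.size:
                off = pos - s
                t_pos = t + off
                if self.target_strand == "-":
                    t_pos = self.target_size - 1 - t_pos
                return (bi, t_pos)
            s += b.size + b.source_gap
            t += b.size + b.target_gap
        return None


def read_chain_file(source: str | IO[str]) -> list[ChainAlignment]:
    """Read a UCSC chain file into a list of :class:`ChainAlignment`."""
    close = False
    if isinstance(source, str):
        fh: IO[str] = open(source)
        close = True
    else:
        fh = source
    chains: list[ChainAlignment] = []
    try:
        header: list[str] | None = None
        blocks: list[ChainBlock] = []

        def flush() -> None:
            nonlocal header, blocks
            if header is None:
                return
            chains.append(
                ChainAlignment(
                    score=float(header[1]),
                    source_chrom=header[2],
                    source_size=int(header[3]),
                    source_strand=header[4],
                    source_start=int(header[5]),
                    source_end=int(header[6]),
                    target_chrom=header[7],
                    target_size=int(header[8]),
                    target_strand=header[9],
                    target_start=int(header[10]),
                    target_end=int(header[11]),
                    blocks=blocks,
                )
            )
            header, blocks = None, []

        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] == "chain":
                flush()
                if len(parts) < 12:
                    raise ValueError(f"malformed chain header: {line!r}")
                header = parts
            else:
                if header is None:
                    raise ValueError("chain block line before any chain header")
                if len(parts) == 1:
                    blocks.append(ChainBlock(int(parts[0])))
                elif len(parts) == 3:
                    blocks.append(ChainBlock(int(parts[0]), int(parts[1]), int(parts[2])))
                else:
                    raise ValueError(f"malformed chain block line: {line!r}")
        flush()
    finally:
        if close:
            fh.close()
    return chains


def _lift_one(
    r: GenomicRegion, by_chrom: dict[str, list[ChainAlignment]]
) -> GenomicRegion | str:
    """Lift one region; returns the lifted region or a drop reason string."""
    cands = by_chrom.get(r.chrom)
    if not cands:
        return "no_chain"
    overlapping = [c for c in cands if c.source_start < r.end and c.source_end > r.start]
    if not overlapping:
        return "no_chain"
    best = max(overlapping, key=lambda c: c.score)
    m_start = best.map_position(r.start)
    m_last = best.map_position(r.end - 1)
    if m_start is None or m_last is None or m_start[0] != m_last[0]:
        return "unmapped"
    a, b = m_start[1], m_last[1]
    new_start, new_end = (a, b + 1) if a <= b else (b, a + 1)
    return GenomicRegion(best.target_chrom, new_start, new_end, r.score)


def _chains_by_source(chains: list[ChainAlignment]) -> dict[str, list[ChainAlignment]]:
    by_chrom: dict[str, list[ChainAlignment]] = {}
    for ch in chains:
        by_chrom.setdefault(ch.source_chrom, []).append(ch)
    return by_chrom


def liftover_regions(
    peaks: PeakSet,
    chains: list[ChainAlignment],
    target_build: str = "lifted",
) -> tuple[PeakSet, list[tuple[str, str]]]:
    """Lift regions between assemblies using single-best-chain semantics.

    A region lifts iff its start and end-1 positions both fall inside the same
    aligned block of the single highest-scoring chain overlapping it (so region
    length is always preserved).  On reverse-strand chains the mapped interval
    is flipped against the target chromosome size and re-normalized so
    start < end.  Regions spanning a gap or split across chains are dropped
    with reason ``"unmapped"``; regions on chromosomes without any chain are
    dropped with reason ``"no_chain"``.
    """
    by_chrom = _chains_by_source(chains)
    lifted: list[GenomicRegion] = []
    dropped: list[tuple[str, str]] = []
    for r in peaks:
        out = _lift_one(r, by_chrom)
        if isinstance(out, str):
            dropped.append((r.id, out))
        else:
            lifted.append(out)
    return PeakSet(lifted, target_build), dropped


def liftover_with_index(
    peaks: PeakSet,
    chains: list[ChainAlignment],
    target_build: str = "lifted",
) -> tuple[PeakSet, list[int], list[tuple[str, str]]]:
    """Like :func:`liftover_regions` but also returns, for each region of the
    (sorted) lifted PeakSet, the index of its source region in ``peaks``."""
    by_chrom = _chains_by_source(chains)
    pairs: list[tuple[GenomicRegion, int]] = []
    dropped: list[tuple[str, str]] = []
    for i, r in enumerate(peaks):
        out = _lift_one(r, by_chrom)
        if isinstance(out, str):
            dropped.append((r.id, out))
        else:
            pairs.append((out, i))
    pairs.sort(key=lambda x: x[0].sort_key())
    lifted = PeakSet((p for p, _ in pairs), target_build)
    return lifted, [i for _, i in pairs], dropped
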