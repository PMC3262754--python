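"""Simplified short-read mapper for small amplicon panels.

Placement is ungapped and scored by the sum of reported qualities at
mismatching bases, with candidate positions proposed by exact seed matches
from either read end on both strands.  A read is accepted at the unique
placement minimising that sum, provided the sum does not exceed ``e_max``
(default 100); ties at distinct positions leave the read unmapped.  A
paired-end constraint marks pairs proper when mates map to the same contig
on opposite strands within a maximal outer distance (default 500).

For reads that fail ungapped placement, a gapped fallback considers a
single insertion or deletion of 1..``g_max`` bases at any read offset with
at least ``anchor_min`` exactly matching bases on each side of the gap.
Reads whose true gap exceeds ``g_max`` therefore stay unmapped — with
32 bp reads this is exactly how a 20 bp deletion defeats the mapper, a
failure mode the downstream caller has to surface rather than hide.

The full mapping-quality model of production aligners is deliberately not
reproduced; MAPQ is a coarse 0/60 (ambiguous-or-unmapped vs accepted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .panel import ReferencePanel, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "MapperConfig",
    "Read",
    "AlignedRead",
    "SeedIndex",
    "map_read_ungapped",
    "map_read_gapped",
    "map_read",
    "pair_reads",
    "map_paired_reads",
    "read_fastq_pairs",
    "write_alignments",
    "read_alignments",
]


@dataclass(frozen=True)
class MapperConfig:
    """Mapping parameters.

    e_max: maximum sum of mismatching base qualities for acceptance.
    outer_max: maximum outer distance of a proper read pair.
    g_max: maximum gap length tried in gapped fallback mode.
    anchor_min: exact-match bases required on each side of a gap.
    seed_len: exact seed length used to propose candidate placements.
    """

    e_max: int = 100
    outer_max: int = 500
    g_max: int = 10
    anchor_min: int = 8
    seed_len: int = 12

    def __post_init__(self) -> None:
        for name in ("e_max", "outer_max", "g_max", "anchor_min", "seed_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"MapperConfig.{name} must be positive")


@dataclass
class Read:
    """An unaligned read as sequenced (5'->3')."""

    name: str
    seq: str
    quals: np.ndarray  # reported Phred qualities, one per base

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int64)
        if len(self.quals) != len(self.seq):
            raise ValueError(f"read {self.name}: seq/qual length mismatch")


@dataclass
class AlignedRead:
    """A read placement (or an unmapped read).

    ``seq``/``quals`` are stored in reference orientation; machine cycles
    are recovered from the strand (cycle of stored index i is ``i+1`` on
    the forward strand and ``L-i`` on the reverse strand).  ``quals`` holds
    the working (possibly recalibrated) qualities, ``orig_quals`` the
    reported ones.
    """

    name: str
    seq: str
    quals: np.ndarray
    mapped: bool = False
    contig: str = "*"
    pos: int = -1  # leftmost reference position, 0-based
    is_reverse: bool = False
    cigar: tuple[tuple[str, int], ...] = ()  # ops over 'M', 'I', 'D'
    score: int = 0  # mismatch-quality-sum of the accepted placement
    orig_quals: np.ndarray | None = None
    is_read1: bool = True
    proper_pair: bool = False
    mate: "AlignedRead | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int64)
        if self.orig_quals is None:
            self.orig_quals = self.quals.copy()

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def end(self) -> int:
        """One past the last reference position covered."""
        return self.pos + self.ref_span

    def cycle(self, i: int) -> int:
        return i + 1 if not self.is_reverse else len(self.seq) - i

    def aligned_pairs(self) -> Iterator[tuple[int, int]]:
        """Yield (stored read index, reference position) for matched bases."""
        i, r = 0, self.pos
        for op, n in self.cigar:
            if op == "M":
                for j in range(n):
                    yield i + j, r + j
                i += n
                r += n
            elif op == "I":
                i += n
            elif op == "D":
                r += n

    def gaps(self) -> list[tuple[str, int, int, int]]:
        """Gap descriptors as (op, read offset, ref position, length).

        The read offset is the stored index of the first base after the
        gap; for deletions the ref position is the first deleted base.
        """
        out = []
        i, r = 0, self.pos
        for op, n in self.cigar:
            if op == "M":
                i += n
                r += n
            elif op == "I":
                out.append(("I", i, r, n))
                i += n
            elif op == "D":
                out.append(("D", i, r, n))
                r += n
        return out

    def gap_adjacent_mask(self, pad: int = 1) -> np.ndarray:
        """Boolean mask of stored bases within ``pad`` bp of a gap."""
        mask = np.zeros(len(self.seq), dtype=bool)
        for op, i, _r, n in self.gaps():
            lo = max(0, i - pad)
            hi = min(len(self.seq), (i + n if op == "I" else i) + pad)
            mask[lo:hi] = True
        return mask


class SeedIndex:
    """Exact k-mer index over the panel contigs."""

    def __init__(self, panel: ReferencePanel, seed_len: int):
        self.seed_len = seed_len
        self.panel = panel
        self.ref_bytes = {
            name: np.frombuffer(c.sequence.encode(), dtype=np.uint8)
            for name, c in panel.contigs.items()
        }
        self._index: dict[str, list[tuple[str, int]]] = {}
        for name, c in panel.contigs.items():
            s = c.sequence
            for i in range(len(s) - seed_len + 1):
                self._index.setdefault(s[i : i + seed_len], []).append((name, i))

    def hits(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


def _oriented(read: Read, strand_rev: bool) -> tuple[str, np.ndarray]:
    if strand_rev:
        return revcomp(read.seq), read.quals[::-1]
    return read.seq, read.quals


def _candidate_starts(
    index: SeedIndex, oriented_seq: str, deltas: Sequence[int]
) -> set[tuple[str, int]]:
    k = index.seed_len
    L = len(oriented_seq)
    cands: set[tuple[str, int]] = set()
    for offset in (0, L - k):
        for contig, hit in index.hits(oriented_seq[offset : offset + k]):
            base = hit - offset
            for d in deltas:
                cands.add((contig, base + d))
    return cands


def _unmapped(read: Read, is_read1: bool = True) -> AlignedRead:
    return AlignedRead(
        name=read.name,
        seq=read.seq,
        quals=read.quals.copy(),
        mapped=False,
        is_read1=is_read1,
    )


def map_read_ungapped(
    read: Read, index: SeedIndex, config: MapperConfig
) -> AlignedRead:
    """Best ungapped placement by mismatch-quality-sum, or unmapped.

    Candidates come from exact seed hits at either read end on both
    strands.  The read is unmapped if the best sum exceeds ``e_max`` or if
    the best score is achieved at more than one distinct position.
    """
    L = len(read.seq)
    if L < config.seed_len:
        return _unmapped(read)
    placements: dict[tuple[str, int, bool], int] = {}
    for strand_rev in (False, True):
        seq, quals = _oriented(read, strand_rev)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for contig, start in _candidate_starts(index, seq, (0,)):
            ref = index.ref_bytes[contig]
            if start < 0 or start + L > len(ref):
                continue
            mism = ref[start : start + L] != arr
            score = int(quals[mism].sum())
            placements[(contig, start, strand_rev)] = score
    if not placements:
        return _unmapped(read)
    best = min(placements.values())
    if best > config.e_max:
        return _unmapped(read)
    winners = [k for k, v in placements.items() if v == best]
    if len(winners) > 1:
        return _unmapped(read)  # ambiguous placement is discarded
    contig, start, strand_rev = winners[0]
    seq, quals = _oriented(read, strand_rev)
    return AlignedRead(
        name=read.name,
        seq=seq,
        quals=quals.copy(),
        mapped=True,
        contig=contig,
        pos=start,
        is_reverse=strand_rev,
        cigar=(("M", L),),
        score=best,
    )


def _score_gapped_at(
    arr: np.ndarray,
    quals: np.ndarray,
    ref: np.ndarray,
    start: int,
    config: MapperConfig,
) -> list[tuple[int, int, str, int]]:
    """All admissible single-gap placements at a fixed start.

    Returns tuples (score, gap offset o, op, gap length); the gap sits
    after read offset ``o``.  Anchors of ``anchor_min`` exact matches are
    required on both sides of the gap.
    """
    L = len(arr)
    a = config.anchor_min
    if start < 0 or start + L > len(ref):
        return []
    results: list[tuple[int, int, str, int]] = []
    # mismatch-qual and mismatch-count prefix sums for the unshifted frame
    m0 = ref[start : start + L] != arr
    pq0 = np.concatenate(([0], np.cumsum(quals * m0)))
    pc0 = np.concatenate(([0], np.cumsum(m0)))
    o_grid = np.arange(a, L - a + 1)
    for d in range(1, config.g_max + 1):
        # deletion of d reference bases after read offset o
        if start + L + d <= len(ref):
            md = ref[start + d : start + L + d] != arr
            pqd = np.concatenate(([0], np.cumsum(quals * md)))
            pcd = np.concatenate(([0], np.cumsum(md)))
            scores = pq0[o_grid] + (pqd[L] - pqd[o_grid])
            ok_left = (pc0[o_grid] - pc0[o_grid - a]) == 0
            ok_right = (pcd[o_grid + a] - pcd[o_grid]) == 0
            for o, sc in zip(o_grid[ok_left & ok_right], scores[ok_left & ok_right]):
                results.append((int(sc), int(o), "D", d))
        # insertion of d read bases after read offset o
        g = d
        if start + L - g <= len(ref) and L - g >= a + 1:
            mg = np.ones(L, dtype=bool)
            mg[g:] = ref[start : start + L - g] != arr[g:]
            pqg = np.concatenate(([0], np.cumsum(quals * mg)))
            pcg = np.concatenate(([0], np.cumsum(mg)))
            o_ins = o_grid[o_grid + g + a <= L]
            if o_ins.size:
                scores = pq0[o_ins] + (pqg[L] - pqg[o_ins + g])
                ok_left = (pc0[o_ins] - pc0[o_ins - a]) == 0
                ok_right = (pcg[o_ins + g + a] - pcg[o_ins + g]) == 0
                keep = ok_left & ok_right
                for o, sc in zip(o_ins[keep], scores[keep]):
                    results.append((int(sc), int(o), "I", g))
    return results


def map_read_gapped(
    read: Read, index: SeedIndex, config: MapperConfig
) -> AlignedRead:
    """Best single-gap placement, or unmapped.

    The search is exhaustive over gap offsets and lengths 1..``g_max`` at
    every seed-proposed start; among equal-scoring placements at the same
    position the leftmost gap offset wins (downstream left-alignment
    normalises indels anyway), while ties across distinct positions leave
    the read unmapped.
    """
    L = len(read.seq)
    if L < config.seed_len:
        return _unmapped(read)
    deltas = range(-config.g_max, config.g_max + 1)
    by_key: dict[tuple[str, int, bool], tuple[int, int, str, int]] = {}
    for strand_rev in (False, True):
        seq, quals = _oriented(read, strand_rev)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for contig, start in _candidate_starts(index, seq, deltas):
            ref = index.ref_bytes[contig]
            placements = _score_gapped_at(arr, quals, ref, start, config)
            if not placements:
                continue
            best = min(placements)  # (score, o, op, len): leftmost gap wins ties
            key = (contig, start, strand_rev)
            if key not in by_key or best < by_key[key]:
                by_key[key] = best
    if not by_key:
        return _unmapped(read)
    best_score = min(v[0] for v in by_key.values())
    if best_score > config.e_max:
        return _unmapped(read)
    winners = [(k, v) for k, v in by_key.items() if v[0] == best_score]
    if len(winners) > 1:
        return _unmapped(read)
    (contig, start, strand_rev), (score, o, op, glen) = winners[0]
    seq, quals = _oriented(read, strand_rev)
    if op == "D":
        cigar = (("M", o), ("D", glen), ("M", L - o))
    else:
        cigar = (("M", o), ("I", glen), ("M", L - o - glen))
    return AlignedRead(
        name=read.name,
        seq=seq,
        quals=quals.copy(),
        mapped=True,
        contig=contig,
        pos=start,
        is_reverse=strand_rev,
        cigar=cigar,
        score=score,
    )


def map_read(
    read: Read, index: SeedIndex, config: MapperConfig, gapped: bool = True
) -> AlignedRead:
    """Ungapped placement with single-gap fallback."""
    aln = map_read_ungapped(read, index, config)
    if not aln.mapped and gapped:
        aln = map_read_gapped(read, index, config)
    return aln


def pair_reads(
    aln1: AlignedRead, aln2: AlignedRead, config: MapperConfig
) -> bool:
    """Link two mates and flag the pair proper or not.

    A pair is proper iff both mates map to the same contig on opposite
    strands with outer distance (rightmost end minus leftmost start) not
    exceeding ``outer_max``.  Improper pairs keep their individual
    placements.
    """
    aln1.mate, aln2.mate = aln2, aln1
    aln1.is_read1, aln2.is_read1 = True, False
    proper = (
        aln1.mapped
        and aln2.mapped
        and aln1.contig == aln2.contig
        and aln1.is_reverse != aln2.is_reverse
        and max(aln1.end, aln2.end) - min(aln1.pos, aln2.pos) <= config.outer_max
    )
    aln1.proper_pair = aln2.proper_pair = proper
    return proper


def map_paired_reads(
    pairs: Iterable[tuple[Read, Read]],
    panel: ReferencePanel,
    config: MapperConfig | None = None,
    gapped: bool = True,
) -> list[AlignedRead]:
    """Map read pairs against the panel; returns a flat alignment list."""
    config = config or MapperConfig()
    index = SeedIndex(panel, config.seed_len)
    out: list[AlignedRead] = []
    n_mapped = n_proper = n_total = 0
    for r1, r2 in pairs:
        a1 = map_read(r1, index, config, gapped=gapped)
        a2 = map_read(r2, index, config, gapped=gapped)
        n_proper += pair_reads(a1, a2, config)
        n_mapped += a1.mapped + a2.mapped
        n_total += 2
        out.extend((a1, a2))
    logger.info(
        "mapped %d/%d reads (%d proper pairs)", n_mapped, n_total, n_proper
    )
    return out


# ---------------------------------------------------------------------------
# FASTQ / SAM I/O
# ---------------------------------------------------------------------------

def read_fastq_pairs(
    path1: str | Path, path2: str | Path
) -> Iterator[tuple[Read, Read]]:
    """Iterate paired reads from two Sanger-encoded FASTQ files."""
    with pysam.FastxFile(str(path1)) as fq1, pysam.FastxFile(str(path2)) as fq2:
        for rec1, rec2 in zip(fq1, fq2):
            yield (
                Read(rec1.name, rec1.sequence.upper(),
                     np.array(rec1.get_quality_array(), dtype=np.int64)),
                Read(rec2.name, rec2.sequence.upper(),
                     np.array(rec2.get_quality_array(), dtype=np.int64)),
            )


_CIGAR_OP = {"M": 0, "I": 1, "D": 2}
_OP_CIGAR = {0: "M", 1: "I", 2: "D"}


def write_alignments(
    alignments: Sequence[AlignedRead],
    panel: ReferencePanel,
    path: str | Path,
) -> None:
    """Write alignments as SAM (reported qualities kept in the OQ tag)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": name, "LN": len(c)} for name, c in panel.contigs.items()
        ],
        "PG": [{"ID": "poolcall", "PN": "poolcall"}],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
        tids = {name: i for i, name in enumerate(panel.contigs)}
        for aln in alignments:
            seg = pysam.AlignedSegment(sam.header)
            seg.query_name = aln.name
            seg.query_sequence = aln.seq
            seg.query_qualities = [min(93, int(q)) for q in aln.quals]
            flag = 0x1
            flag |= 0x40 if aln.is_read1 else 0x80
            if aln.mapped:
                seg.reference_id = tids[aln.contig]
                seg.reference_start = aln.pos
                seg.cigartuples = [(_CIGAR_OP[op], n) for op, n in aln.cigar]
                seg.mapping_quality = 60
                if aln.is_reverse:
                    flag |= 0x10
                if aln.proper_pair:
                    flag |= 0x2
            else:
                flag |= 0x4
                seg.mapping_quality = 0
            mate = aln.mate
            if mate is not None:
                if mate.mapped:
                    seg.next_reference_id = tids[mate.contig]
                    seg.next_reference_start = mate.pos
                    if mate.is_reverse:
                        flag |= 0x20
                else:
                    flag |= 0x8
            seg.flag = flag
            seg.set_tag("OQ", pysam.qualities_to_qualitystring(
                [min(93, int(q)) for q in aln.orig_quals]))
            seg.set_tag("ZS", int(aln.score))
            sam.write(seg)


def read_alignments(path: str | Path) -> list[AlignedRead]:
    """Read a SAM file produced by :func:`write_alignments`."""
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for seg in sam:
            quals = np.array(seg.query_qualities, dtype=np.int64)
            if seg.has_tag("OQ"):
                orig = np.array(
                    pysam.qualitystring_to_array(seg.get_tag("OQ")),
                    dtype=np.int64,
                )
            else:
                orig = quals.copy()
            cigar = tuple(
                (_OP_CIGAR[op], n) for op, n in (seg.cigartuples or ())
            )
            out.append(
                AlignedRead(
                    name=seg.query_name,
                    seq=seg.query_sequence,
                    quals=quals,
                    mapped=not seg.is_unmapped,
                    contig=seg.reference_name if not seg.is_unmapped else "*",
                    pos=seg.reference_start if not seg.is_unmapped else -1,
                    is_reverse=seg.is_reverse,
                    cigar=cigar,
                    score=seg.get_tag("ZS") if seg.has_tag("ZS") else 0,
                    orig_quals=orig,
                    is_read1=not seg.is_read2,
                    proper_pair=seg.is_proper_pair,
                )
            )
    return out
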