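"""Empirical base-quality recalibration and Q20 masking.

Reported base qualities from short-read sequencers are often miscalibrated
in systematic ways.  Following the empirical-recalibration approach used
for pooled resequencing, aligned bases are binned by (reported quality,
machine cycle, preceding nucleotide), the mismatch rate of each bin against
the reference is measured at positions *not* present in the known-sites
database, and each bin is assigned the quality matching its empirical error
rate.  Bases whose recalibrated quality falls below 20 are subsequently
masked out of all downstream pileups.

Smoothing uses add-one on mismatches and add-two on observations so that
zero-mismatch bins receive a finite quality; bins with fewer than
``min_obs`` observations keep their reported quality.  Recalibrated
qualities are capped at 40 to avoid unbounded confidence from finite data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .mapper import AlignedRead
    from .panel import KnownSiteDB, ReferencePanel

logger = logging.getLogger(__name__)

__all__ = [
    "phred_error_prob",
    "quality_from_error",
    "RecalTable",
    "tabulate_empirical",
    "recalibrate",
    "q20_mask",
]

START_CONTEXT = "^"  # distinguished symbol for cycle-1 bases
Q_CAP = 40
Q20 = 20

_COMP = str.maketrans("ACGTN", "TGCAN")


def phred_error_prob(q) -> float | np.ndarray:
    """Error probability for a Phred quality: ``10**(-q/10)``.

    Q20 corresponds to a 1% error rate.  Negative qualities are a domain
    error.
    """
    arr = np.asarray(q)
    if np.any(arr < 0):
        raise ValueError(f"negative Phred quality: {q}")
    out = np.power(10.0, -arr / 10.0)
    return float(out) if np.isscalar(q) or arr.ndim == 0 else out


def quality_from_error(p: float) -> int:
    """Integer Phred quality matching an error probability (capped)."""
    if p <= 0:
        return Q_CAP
    return min(Q_CAP, max(0, round(-10.0 * math.log10(p))))


BinKey = tuple[int, int, str]  # (reported Q, machine cycle 1-based, preceding base)


@dataclass
class RecalTable:
    """Empirical error counts and recalibrated quality per covariate bin."""

    min_obs: int = 100
    counts: dict[BinKey, list[int]] = field(default_factory=dict)  # [obs, mis]

    def observe(self, key: BinKey, mismatch: bool) -> None:
        cell = self.counts.setdefault(key, [0, 0])
        cell[0] += 1
        cell[1] += mismatch

    def empirical_error(self, key: BinKey) -> float | None:
        cell = self.counts.get(key)
        if cell is None:
            return None
        obs, mis = cell
        return (mis + 1) / (obs + 2)

    def recal_q(self, key: BinKey) -> int:
        """Recalibrated quality for a bin.

        Bins with at least ``min_obs`` observations get the quality of
        their smoothed empirical error rate; sparse or absent bins fall
        back to the reported quality (the first element of the key).
        """
        cell = self.counts.get(key)
        if cell is None or cell[0] < self.min_obs:
            return min(Q_CAP, key[0])
        obs, mis = cell
        return quality_from_error((mis + 1) / (obs + 2))

    # -- serialization ------------------------------------------------------

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("reported_q\tcycle\tprev_base\tobserved\tmismatches\trecal_q\n")
            for key in sorted(self.counts):
                obs, mis = self.counts[key]
                fh.write(
                    f"{key[0]}\t{key[1]}\t{key[2]}\t{obs}\t{mis}\t{self.recal_q(key)}\n"
                )

    @classmethod
    def read_tsv(cls, path: str | Path, min_obs: int = 100) -> "RecalTable":
        table = cls(min_obs=min_obs)
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("reported_q"):
                raise ValueError(f"not a recalibration table: {path}")
            for line in fh:
                q, cyc, prev, obs, mis = line.split("\t")[:5]
                table.counts[(int(q), int(cyc), prev)] = [int(obs), int(mis)]
        return table


def _iter_observations(read: "AlignedRead", ref_seq: str):
    """Yield (key, ref_pos0, stored_index, mismatch) for recalibration.

    Bases within 1 bp of an indel in the same read are excluded, as are
    positions where the reference is N.  The preceding-base context is the
    previous *called* base in sequencing order (a distinguished start
    symbol at cycle 1); for reads mapped to the reverse strand the stored,
    reference-oriented sequence is read backwards and complemented.
    """
    L = len(read.seq)
    excluded = read.gap_adjacent_mask(pad=1)
    for i, rpos in read.aligned_pairs():
        if excluded[i]:
            continue
        ref_base = ref_seq[rpos]
        if ref_base == "N":
            continue
        base = read.seq[i]
        if base == "N":
            continue
        cycle = i + 1 if not read.is_reverse else L - i
        if cycle == 1:
            prev = START_CONTEXT
        elif not read.is_reverse:
            prev = read.seq[i - 1]
        else:
            prev = read.seq[i + 1].translate(_COMP)
        key = (int(read.orig_quals[i]), cycle, prev)
        yield key, rpos, i, base != ref_base


def tabulate_empirical(
    alignments: Iterable["AlignedRead"],
    panel: "ReferencePanel",
    known_sites: "KnownSiteDB | None" = None,
    min_obs: int = 100,
) -> RecalTable:
    """Build a recalibration table from aligned reads.

    Every aligned base at a position absent from the known-sites database
    contributes to its bin; a base contributes a mismatch iff it differs
    from the reference.  Known-variant positions are excluded so genuine
    polymorphism is not mistaken for error.
    """
    if known_sites is None:
        known_sites = panel.known_sites
    table = RecalTable(min_obs=min_obs)
    seqs = {name: c.sequence for name, c in panel.contigs.items()}
    for read in alignments:
        if not read.mapped:
            continue
        ref_seq = seqs[read.contig]
        contig = read.contig
        known = known_sites.contains_position
        for key, rpos, _i, mism in _iter_observations(read, ref_seq):
            if known(contig, rpos + 1):
                continue
            table.observe(key, mism)
    if not table.counts:
        logger.warning("recalibration table is empty (no usable aligned bases)")
    return table


def recalibrate(
    alignments: Iterable["AlignedRead"], table: RecalTable
) -> list["AlignedRead"]:
    """Replace every base quality with its bin's recalibrated quality.

    Original qualities are retained on the read (``orig_quals``).  Bases in
    absent bins keep their reported quality.  Reads are modified in place
    and returned as a list.
    """
    out = []
    missing = 0
    for read in alignments:
        if read.mapped:
            L = len(read.seq)
            new_q = read.quals.copy()
            for i in range(L):
                cycle = i + 1 if not read.is_reverse else L - i
                if cycle == 1:
                    prev = START_CONTEXT
                elif not read.is_reverse:
                    prev = read.seq[i - 1]
                else:
                    prev = read.seq[i + 1].translate(_COMP)
                key = (int(read.orig_quals[i]), cycle, prev)
                if key not in table.counts:
                    missing += 1
                new_q[i] = table.recal_q(key)
            read.quals = new_q
        out.append(read)
    if missing:
        logger.debug("%d bases fell back to reported quality (absent bin)", missing)
    if not out:
        logger.warning("recalibrate called on an empty alignment set")
    return out


def q20_mask(recal_q: int, threshold: int = Q20) -> bool:
    """Keep flag for a base: True iff recalibrated quality >= threshold.

    The rule is strict below-20 dropping, so Q20 itself is kept.
    """
    return recal_q >= threshold
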