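"""Reference panel: contigs, target regions, gene models and known sites.

The panel is the coordinate source of truth for every downstream stage.
Internally all coordinates are 0-based, half-open.  File interfaces keep
their native conventions: BED is 0-based half-open, VCF and HGVS-style
``c.`` positions are 1-based.  Minus-strand CDS coordinates count along the
reverse complement from the annotated start codon, following HGVS usage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "PanelError",
    "Contig",
    "TargetRegion",
    "GeneModel",
    "KnownSiteDB",
    "ReferencePanel",
    "load_reference",
    "load_targets",
    "load_known_sites",
    "load_gene_models",
    "merge_intervals",
    "merged_footprint",
    "cds_to_genomic",
    "genomic_to_cds",
    "revcomp",
]

_VALID_SEQ = re.compile(r"^[ACGTN]+$")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class PanelError(ValueError):
    """Raised for malformed or inconsistent panel inputs."""


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Contig:
    """A reference sequence.  ``sequence`` is upper-case over {A,C,G,T,N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise PanelError("contig name must be non-empty")
        if not self.sequence:
            raise PanelError(f"contig {self.name!r} has empty sequence")
        if not _VALID_SEQ.match(self.sequence):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise PanelError(
                f"contig {self.name!r} contains invalid characters {bad}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TargetRegion:
    """A targeted interval (0-based half-open), e.g. one coding exon."""

    contig: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise PanelError(
                f"target {self.label!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A coding gene: ordered CDS intervals on one contig.

    ``cds_intervals`` are 0-based half-open genomic intervals listed in
    transcription order (ascending genomic coordinate on '+', descending
    on '-').  Total CDS length must be a multiple of 3.
    """

    name: str
    contig: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise PanelError(f"gene {self.name}: strand must be '+' or '-'")
        ivals = tuple((int(s), int(e)) for s, e in self.cds_intervals)
        object.__setattr__(self, "cds_intervals", ivals)
        if not ivals:
            raise PanelError(f"gene {self.name}: no CDS intervals")
        for s, e in ivals:
            if not (0 <= s < e):
                raise PanelError(f"gene {self.name}: bad interval ({s},{e})")
        genomic = sorted(ivals)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise PanelError(f"gene {self.name}: overlapping CDS intervals")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if ivals != tuple(expected):
            raise PanelError(
                f"gene {self.name}: intervals not in transcription order"
            )
        if self.cds_length % 3 != 0:
            raise PanelError(
                f"gene {self.name}: CDS length {self.cds_length} "
                "not a multiple of 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    def cds_sequence(self, panel: "ReferencePanel") -> str:
        """Spliced CDS in reading direction (reverse-complemented on '-')."""
        seq = panel.contigs[self.contig].sequence
        parts = []
        for s, e in self.cds_intervals:
            chunk = seq[s:e]
            parts.append(chunk if self.strand == "+" else revcomp(chunk))
        return "".join(parts)


class KnownSiteDB:
    """Set of previously observed variants (a dbSNP stand-in).

    Supports membership queries by position and by exact allele.  Positions
    are 1-based, VCF-style.
    """

    def __init__(self, records: Iterable[tuple[str, int, str, str, str]] = ()):
        self._by_allele: dict[tuple[str, int, str, str], str] = {}
        self._by_pos: set[tuple[str, int]] = set()
        for contig, pos, ref, alt, site_id in records:
            self.add(contig, pos, ref, alt, site_id)

    def add(self, contig: str, pos: int, ref: str, alt: str, site_id: str) -> None:
        if pos < 1:
            raise PanelError(f"known site position must be >= 1, got {pos}")
        self._by_allele[(contig, int(pos), ref.upper(), alt.upper())] = site_id
        self._by_pos.add((contig, int(pos)))

    def __len__(self) -> int:
        return len(self._by_allele)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, KnownSiteDB)
            and self._by_allele == other._by_allele
        )

    def contains_position(self, contig: str, pos: int) -> bool:
        return (contig, pos) in self._by_pos

    def contains_allele(self, contig: str, pos: int, ref: str, alt: str) -> bool:
        return (contig, pos, ref.upper(), alt.upper()) in self._by_allele

    def id_of(self, contig: str, pos: int, ref: str, alt: str) -> str | None:
        return self._by_allele.get((contig, pos, ref.upper(), alt.upper()))

    def records(self) -> list[tuple[str, int, str, str, str]]:
        return sorted(
            (c, p, r, a, i) for (c, p, r, a), i in self._by_allele.items()
        )


@dataclass
class ReferencePanel:
    """Bundle of contigs, targets, gene models and known sites."""

    contigs: dict[str, Contig]
    targets: list[TargetRegion] = field(default_factory=list)
    genes: dict[str, GeneModel] = field(default_factory=dict)
    known_sites: KnownSiteDB = field(default_factory=KnownSiteDB)

    def fetch(self, contig: str, start: int, end: int) -> str:
        return self.contigs[contig].sequence[start:end]

    def base(self, contig: str, pos0: int) -> str:
        return self.contigs[contig].sequence[pos0]

    def validate(self) -> None:
        """Cross-validate coordinates of targets, genes and known sites."""
        for t in self.targets:
            if t.contig not in self.contigs:
                raise PanelError(f"target {t.label!r}: unknown contig {t.contig}")
            if t.end > len(self.contigs[t.contig]):
                raise PanelError(
                    f"target {t.label!r} extends past contig "
                    f"{t.contig} (length {len(self.contigs[t.contig])})"
                )
        for g in self.genes.values():
            if g.contig not in self.contigs:
                raise PanelError(f"gene {g.name}: unknown contig {g.contig}")
            clen = len(self.contigs[g.contig])
            for s, e in g.cds_intervals:
                if e > clen:
                    raise PanelError(f"gene {g.name}: CDS outside contig")
        for contig, pos, ref, alt, _ in self.known_sites.records():
            if contig not in self.contigs:
                raise PanelError(f"known site on unknown contig {contig}")
            if pos > len(self.contigs[contig]):
                raise PanelError(
                    f"known site {contig}:{pos} outside contig bounds"
                )


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------

def load_reference(path: str | Path) -> list[Contig]:
    """Load a FASTA file into a list of contigs.

    Sequences are upper-cased; N is allowed.  Duplicate record names and
    invalid sequence characters are rejected with the offending line number.
    """
    contigs: list[Contig] = []
    names: set[str] = set()
    name: str | None = None
    parts: list[str] = []
    header_line = 0

    def flush(line_no: int) -> None:
        nonlocal name, parts
        if name is None:
            return
        seq = "".join(parts)
        if not seq:
            raise PanelError(f"FASTA record {name!r} (line {header_line}) is empty")
        contigs.append(Contig(name, seq))
        name, parts = None, []

    line_no = 0
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise PanelError(f"FASTA parse error at line {line_no}: empty header")
                if name in names:
                    raise PanelError(
                        f"duplicate contig name {name!r} at line {line_no}"
                    )
                names.add(name)
                header_line = line_no
            else:
                if name is None:
                    raise PanelError(
                        f"FASTA parse error at line {line_no}: "
                        "sequence before first header"
                    )
                seq = line.upper()
                if not _VALID_SEQ.match(seq):
                    raise PanelError(
                        f"FASTA parse error at line {line_no}: "
                        "invalid sequence characters"
                    )
                parts.append(seq)
        flush(line_no)
    if not contigs:
        raise PanelError(f"no FASTA records found in {path}")
    return contigs


def load_targets(path: str | Path, panel: ReferencePanel) -> list[TargetRegion]:
    """Load BED3+ target regions and validate them against contig bounds."""
    targets: list[TargetRegion] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise PanelError(f"BED parse error at line {line_no}: <3 columns")
            contig = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise PanelError(
                    f"BED parse error at line {line_no}: non-numeric coordinate"
                ) from exc
            label = fields[3] if len(fields) > 3 else f"{contig}:{start}-{end}"
            if contig not in panel.contigs:
                raise PanelError(f"BED line {line_no}: unknown contig {contig!r}")
            if not (0 <= start < end <= len(panel.contigs[contig])):
                raise PanelError(
                    f"BED line {line_no}: interval [{start},{end}) outside "
                    f"contig {contig} (length {len(panel.contigs[contig])})"
                )
            targets.append(TargetRegion(contig, start, end, label))
    return targets


def _parse_vcf_sites(lines: Iterable[str]) -> list[tuple[str, int, str, str, str]]:
    records = []
    for line_no, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            fields = line.split()
        if len(fields) < 5:
            raise PanelError(f"VCF parse error at line {line_no}: <5 columns")
        contig, pos_s, site_id, ref, alts = fields[:5]
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise PanelError(
                f"parse error at line {line_no}: non-numeric position {pos_s!r}"
            ) from exc
        for alt in alts.split(","):
            records.append((contig, pos, ref.upper(), alt.upper(), site_id))
    return records


def load_known_sites(path: str | Path) -> KnownSiteDB:
    """Load known variant sites from a VCF or a 5-column TSV.

    The TSV layout is ``contig  pos(1-based)  id  ref  alt`` which matches
    the first five VCF columns, so both encodings of the same sites produce
    identical databases.
    """
    with open(path) as fh:
        return KnownSiteDB(_parse_vcf_sites(fh))


def load_gene_models(path: str | Path) -> dict[str, GeneModel]:
    """Load a gene-model table.

    Tab-separated columns: name, contig, strand, CDS intervals as
    ``start-end;start-end`` (0-based half-open, transcription order).
    """
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise PanelError(
                    f"gene table parse error at line {line_no}: <4 columns"
                )
            name, contig, strand, ivals_s = fields[:4]
            ivals = []
            for chunk in ivals_s.split(";"):
                s, e = chunk.split("-")
                ivals.append((int(s), int(e)))
            if name in genes:
                raise PanelError(f"duplicate gene name {name!r} at line {line_no}")
            genes[name] = GeneModel(name, contig, strand, tuple(ivals))
    return genes


def load_panel(
    fasta: str | Path,
    bed: str | Path | None = None,
    known_sites: str | Path | None = None,
    gene_models: str | Path | None = None,
) -> ReferencePanel:
    """Convenience loader assembling a validated :class:`ReferencePanel`."""
    contigs = {c.name: c for c in load_reference(fasta)}
    panel = ReferencePanel(contigs=contigs)
    if bed is not None:
        panel.targets = load_targets(bed, panel)
    if known_sites is not None:
        panel.known_sites = load_known_sites(known_sites)
    if gene_models is not None:
        panel.genes = load_gene_models(gene_models)
    panel.validate()
    return panel


# ---------------------------------------------------------------------------
# Interval utilities
# ---------------------------------------------------------------------------

def merge_intervals(
    intervals: Iterable[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Union of half-open intervals, returned sorted and non-overlapping."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def merged_footprint(
    targets: Sequence[TargetRegion],
) -> dict[str, list[tuple[int, int]]]:
    """Per-contig merged target intervals (the coverage footprint)."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for t in targets:
        by_contig.setdefault(t.contig, []).append((t.start, t.end))
    return {c: merge_intervals(iv) for c, iv in sorted(by_contig.items())}


def footprint_length(targets: Sequence[TargetRegion]) -> int:
    return sum(
        e - s for ivals in merged_footprint(targets).values() for s, e in ivals
    )


# ---------------------------------------------------------------------------
# CDS <-> genomic coordinate conversion
# ---------------------------------------------------------------------------

def cds_to_genomic(gene: GeneModel, c_pos: int) -> tuple[str, int]:
    """Map a 1-based CDS coordinate to (contig, 1-based genomic position).

    On '-' strand genes the CDS counts along the reverse complement, so c.1
    is the genomic end of the first (most downstream in genome coordinates)
    interval.
    """
    if not (1 <= c_pos <= gene.cds_length):
        raise PanelError(
            f"c.{c_pos} out of range for gene {gene.name} "
            f"(CDS length {gene.cds_length})"
        )
    offset = c_pos - 1
    for s, e in gene.cds_intervals:
        ln = e - s
        if offset < ln:
            if gene.strand == "+":
                return gene.contig, s + offset + 1
            return gene.contig, e - offset
        offset -= ln
    raise AssertionError("unreachable")


def genomic_to_cds(gene: GeneModel, pos1: int) -> int:
    """Inverse of :func:`cds_to_genomic`; raises if outside the CDS."""
    pos0 = pos1 - 1
    cum = 0
    for s, e in gene.cds_intervals:
        if s <= pos0 < e:
            if gene.strand == "+":
                return cum + (pos0 - s) + 1
            return cum + (e - 1 - pos0) + 1
        cum += e - s
    raise PanelError(f"position {gene.contig}:{pos1} not in CDS of {gene.name}")
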