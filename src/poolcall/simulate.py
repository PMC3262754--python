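"""Synthetic pooled amplicon sequencing with planted variants.

Emulates a non-barcoded pooled resequencing experiment: N diploid samples
are PCR-amplified over a target panel, pooled at equal amplicon
representation, and sequenced as short paired-end reads (32 bp by
default).  Each fragment draws its haplotype uniformly from the 2N pooled
chromosomes, so a planted heterozygous singleton appears at allele
fraction 1/(2N) among overlapping reads.  Reads from an indel-bearing
chromosome carry the alternate haplotype sequence literally; whether they
survive mapping is the mapper's problem, which is how a 20 bp deletion in
32 bp reads becomes a false negative rather than being hard-coded as one.

Sequencing errors are substitutions with a true rate structured by machine
cycle and preceding nucleotide (overall ~1% at Q20-grade bases by
default).  Reported qualities are drawn per (cycle, preceding base) bin
and may be deliberately miscalibrated — the default profile over-reports
quality late in the read — giving the empirical recalibrator something
real to correct.  PCR duplicates, chimeras and indel sequencing errors are
not modelled.

The module also provides direct pileup-column simulation (the same
allele-sampling model collapsed onto a single position) for power and
specificity studies at scales where generating every read would be
wasteful, plus builders for a ready-made two-pool study scenario.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .caller import PileupColumn, PileupEntry, left_align_indel
from .panel import (
    Contig,
    GeneModel,
    KnownSiteDB,
    PanelError,
    ReferencePanel,
    TargetRegion,
    cds_to_genomic,
    revcomp,
)
from .recal import quality_from_error

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "ErrorProfile",
    "VariantSpec",
    "TruthVariant",
    "SimRead",
    "plant_genotypes",
    "generate_reads",
    "write_fastq",
    "write_truth",
    "simulate_pileup_column",
    "variant_free_candidate_columns",
    "build_example_panel",
    "write_panel_files",
    "example_variant_specs",
    "example_sim_config",
]

BASES = "ACGT"
_PREV_ORDER = "ACGT^"  # '^' = start-of-read context


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for one pool.

    n_samples: diploid samples pooled without barcodes.
    read_length: paired-end read length in bp.
    insert_mean / insert_sd: fragment (outer) length distribution.
    depth: target mean per-base raw read depth per amplicon (the pool is
        sequenced deep; completeness is later judged against 20 x N).
    flank: primer-flank bases added to each target to form its amplicon.
    strand_bias_indel: if set, probability that the read covering an
        indel junction is sequenced on the forward strand (models the
        strand-asymmetric support of larger indels); None leaves the
        natural ~50/50.
    uncovered_labels: target labels excluded from the library (amplicons
        that failed), e.g. an exon the assay never covered.
    """

    n_samples: int = 8
    read_length: int = 32
    insert_mean: float = 150.0
    insert_sd: float = 15.0
    depth: float = 1000.0
    flank: int = 200  # > insert length: keeps target bases double-stranded
    strand_bias_indel: float | None = None
    uncovered_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.read_length < 16:
            raise ValueError("read_length must be >= 16")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")

    @property
    def n_chromosomes(self) -> int:
        return 2 * self.n_samples


class ErrorProfile:
    """True substitution error rates and reported qualities per bin.

    Bins follow the axes the recalibrator measures: machine cycle and
    preceding (template) nucleotide, with a distinguished start-of-read
    context.  ``rates`` and ``reported`` are (max_cycle, 5) arrays over
    the context order A, C, G, T, start.
    """

    def __init__(self, rates: np.ndarray, reported: np.ndarray):
        rates = np.asarray(rates, dtype=np.float64)
        reported = np.asarray(reported, dtype=np.int64)
        if rates.shape != reported.shape or rates.ndim != 2 or rates.shape[1] != 5:
            raise ValueError("rates/reported must be (max_cycle, 5) arrays")
        if np.any(rates <= 0) or np.any(rates >= 0.75):
            raise ValueError("error rates must lie in (0, 0.75)")
        self.rates = rates
        self.reported = reported

    @property
    def max_cycle(self) -> int:
        return self.rates.shape[0]

    @property
    def mean_rate(self) -> float:
        return float(self.rates[:, :4].mean())

    def rate(self, cycle: int, prev: str) -> float:
        return float(self.rates[cycle - 1, _PREV_ORDER.index(prev)])

    def reported_q(self, cycle: int, prev: str) -> int:
        return int(self.reported[cycle - 1, _PREV_ORDER.index(prev)])

    @classmethod
    def default(cls, read_length: int = 32, miscalibrated: bool = True) -> "ErrorProfile":
        """Cycle-ramped, context-modulated profile (~1% overall).

        The true rate rises linearly along the read from 0.3% to 1.7%
        (mean 1%), modulated by the preceding base.  When
        ``miscalibrated`` (the default study condition) the reported
        quality over-states the truth by 4 in the last quarter of the
        read — the classic overconfident late-cycle pattern that
        empirical recalibration exists to correct.
        """
        cycles = np.arange(read_length, dtype=np.float64)
        ramp = 0.003 + (0.017 - 0.003) * cycles / max(1, read_length - 1)
        context = np.array([0.85, 1.05, 1.25, 0.85, 1.0])
        rates = np.clip(ramp[:, None] * context[None, :], 1e-6, 0.7)
        reported = np.array(
            [[quality_from_error(r) for r in row] for row in rates]
        )
        if miscalibrated:
            late = cycles >= 0.75 * read_length
            reported[late] += 4
        return cls(rates, np.clip(reported, 2, 40))

    @classmethod
    def flat(
        cls,
        rate: float,
        read_length: int = 32,
        reported_q: int | None = None,
    ) -> "ErrorProfile":
        """Uniform error rate; optionally a fixed (miscalibrated) reported Q."""
        rates = np.full((read_length, 5), rate)
        q = reported_q if reported_q is not None else quality_from_error(rate)
        return cls(rates, np.full((read_length, 5), q, dtype=np.int64))

    def _prev_index(self, seq_arr: np.ndarray) -> np.ndarray:
        idx = np.empty(len(seq_arr), dtype=np.int64)
        idx[0] = 4
        lut = np.zeros(256, dtype=np.int64)
        for i, b in enumerate(BASES):
            lut[ord(b)] = i
        idx[1:] = lut[seq_arr[:-1]]
        return idx

    def vectors(self, seq: str) -> tuple[np.ndarray, np.ndarray]:
        """(true error rate, reported quality) per base of a template read."""
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        prev = self._prev_index(arr)
        cyc = np.minimum(np.arange(len(arr)), self.max_cycle - 1)
        return self.rates[cyc, prev], self.reported[cyc, prev]


# ---------------------------------------------------------------------------
# Truth planting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSpec:
    """Requested planted variant (VCF-style pos/ref/alt, 1-based anchor).

    ``allele_count`` with ``zygosity`` distributes copies over random
    samples ('het': k samples with one copy; 'hom': k/2 samples with two);
    ``carriers`` may instead give explicit {sample index: copies}.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    allele_count: int = 1
    zygosity: str = "het"
    carriers: tuple[tuple[int, int], ...] | None = None
    label: str = ""

    @property
    def vtype(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "SNV"
        return "DEL" if len(self.ref) > len(self.alt) else "INS"


@dataclass
class TruthVariant:
    """A planted variant with its per-sample copy numbers (ground truth)."""

    contig: str
    pos: int  # 1-based, VCF anchor convention for indels
    ref: str
    alt: str
    vtype: str
    copies: np.ndarray  # per-sample copy number in {0, 1, 2}
    carrier_haplotypes: frozenset[int] = frozenset()
    label: str = ""

    @property
    def k(self) -> int:
        return int(self.copies.sum())


def plant_genotypes(
    panel: ReferencePanel,
    specs: Sequence[VariantSpec],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[TruthVariant]:
    """Assign planted variants to pooled chromosomes.

    Deterministic given the RNG state.  Carrier identities are recorded in
    the truth only; the caller never sees them.  Two variants at the same
    position are rejected (tri-allelic sites are not modelled), as are
    allele counts exceeding 2N.
    """
    n = config.n_samples
    seen: set[tuple[str, int]] = set()
    truth: list[TruthVariant] = []
    for spec in specs:
        key = (spec.contig, spec.pos)
        if key in seen:
            raise PanelError(f"two variants at the same position {key}")
        seen.add(key)
        ref_here = panel.fetch(spec.contig, spec.pos - 1, spec.pos - 1 + len(spec.ref))
        if ref_here != spec.ref:
            raise PanelError(
                f"variant ref {spec.ref!r} does not match reference "
                f"{ref_here!r} at {spec.contig}:{spec.pos}"
            )
        copies = np.zeros(n, dtype=np.int64)
        if spec.carriers is not None:
            for sample, c in spec.carriers:
                copies[sample] = c
        elif spec.zygosity == "het":
            if spec.allele_count > n:
                raise PanelError(
                    f"cannot place {spec.allele_count} het carriers in {n} samples"
                )
            for s in rng.choice(n, size=spec.allele_count, replace=False):
                copies[s] = 1
        elif spec.zygosity == "hom":
            if spec.allele_count % 2 or spec.allele_count // 2 > n:
                raise PanelError(
                    f"homozygous allele count {spec.allele_count} not placeable"
                )
            for s in rng.choice(n, size=spec.allele_count // 2, replace=False):
                copies[s] = 2
        else:
            raise PanelError(f"unknown zygosity {spec.zygosity!r}")
        k = int(copies.sum())
        if not (1 <= k <= 2 * n):
            raise PanelError(f"allele count {k} outside 1..{2 * n}")
        haps = set()
        for s in np.nonzero(copies)[0]:
            if copies[s] == 2:
                haps.update((2 * int(s), 2 * int(s) + 1))
            else:
                haps.add(2 * int(s) + int(rng.integers(2)))
        truth.append(
            TruthVariant(
                contig=spec.contig,
                pos=spec.pos,
                ref=spec.ref,
                alt=spec.alt,
                vtype=spec.vtype,
                copies=copies,
                carrier_haplotypes=frozenset(haps),
                label=spec.label,
            )
        )
    return truth


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------

@dataclass
class SimRead:
    """A simulated read plus its (truth-only) provenance."""

    name: str
    seq: str
    quals: np.ndarray
    contig: str = ""
    true_start: int = -1  # start in haplotype coordinates of the amplicon's contig
    is_reverse: bool = False
    hap: int = -1  # pooled chromosome index 0..2N-1
    sample: int = -1
    n_errors: int = 0


def _apply_variants(
    seq: str, a_start: int, variants: Sequence[TruthVariant]
) -> tuple[str, list[int]]:
    """Apply variants (sorted, non-overlapping) to an amplicon substring.

    Returns the mutated sequence and the haplotype-coordinate junction
    positions of any indels (index of the first base after the anchor).
    """
    pieces: list[str] = []
    junctions: list[int] = []
    cur = 0
    out_len = 0
    for v in sorted(variants, key=lambda v: v.pos):
        rel = v.pos - 1 - a_start
        if rel < cur:
            raise PanelError(f"overlapping variants in amplicon at {v.contig}:{v.pos}")
        if v.vtype == "SNV":
            pieces.append(seq[cur:rel] + v.alt)
            out_len += rel - cur + 1
            cur = rel + 1
        elif v.vtype == "DEL":
            pieces.append(seq[cur : rel + 1])
            out_len += rel + 1 - cur
            junctions.append(out_len)
            cur = rel + len(v.ref)
        else:  # INS / DUP
            inserted = v.alt[1:]
            pieces.append(seq[cur : rel + 1] + inserted)
            junctions.append(out_len + rel + 1 - cur + len(inserted) // 2)
            out_len += rel + 1 - cur + len(inserted)
            cur = rel + 1
    pieces.append(seq[cur:])
    return "".join(pieces), junctions


def _sequence_read(
    template: str,
    profile: ErrorProfile,
    rng: np.random.Generator,
) -> tuple[str, np.ndarray, int]:
    """Call bases from a template with cycle/context errors and quals."""
    rates, reported = profile.vectors(template)
    hits = np.nonzero(rng.random(len(template)) < rates)[0]
    if hits.size == 0:
        return template, reported, 0
    arr = list(template)
    for i in hits:
        others = [b for b in BASES if b != template[i]]
        arr[i] = others[int(rng.integers(3))]
    return "".join(arr), reported, int(hits.size)


def generate_reads(
    panel: ReferencePanel,
    truth: Sequence[TruthVariant],
    profile: ErrorProfile,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[tuple[SimRead, SimRead]]:
    """Generate pooled paired-end reads over all amplicons.

    Each target (minus any ``uncovered_labels``) becomes one amplicon
    extended by the primer flank.  Amplicons receive Poisson fragment
    counts around a common per-base depth (equal representation); each
    fragment draws one of the 2N pooled chromosomes, a length from the
    insert distribution, and yields one forward-strand and one
    reverse-strand read from its two ends.
    """
    L = config.read_length
    pairs: list[tuple[SimRead, SimRead]] = []
    counter = 0
    for target in panel.targets:
        if target.label in config.uncovered_labels:
            logger.info("amplicon %s excluded from the library", target.label)
            continue
        contig = panel.contigs[target.contig]
        a_start = max(0, target.start - config.flank)
        a_end = min(len(contig), target.end + config.flank)
        amp_seq = contig.sequence[a_start:a_end]
        if len(amp_seq) < L:
            raise PanelError(
                f"amplicon {target.label!r} shorter than the read length"
            )
        overlapping = [
            v
            for v in truth
            if v.contig == target.contig
            and a_start < v.pos - 1 + len(v.ref) and v.pos - 1 >= a_start
            and v.pos - 1 + len(v.ref) <= a_end
        ]
        # per-haplotype amplicon sequences (cached by carried-variant subset)
        hap_cache: dict[frozenset[int], tuple[str, list[int]]] = {}
        hap_key: list[frozenset[int]] = []
        for hap in range(config.n_chromosomes):
            carried = frozenset(
                i for i, v in enumerate(overlapping) if hap in v.carrier_haplotypes
            )
            hap_key.append(carried)
            if carried not in hap_cache:
                hap_cache[carried] = _apply_variants(
                    amp_seq, a_start, [overlapping[i] for i in sorted(carried)]
                )
        n_frags = int(rng.poisson(config.depth * len(amp_seq) / (2.0 * L)))
        for _ in range(n_frags):
            hap = int(rng.integers(config.n_chromosomes))
            hseq, junctions = hap_cache[hap_key[hap]]
            hlen = len(hseq)
            flen = int(np.clip(round(rng.normal(config.insert_mean, config.insert_sd)), L, hlen))
            start = int(rng.integers(0, hlen - flen + 1))
            if junctions and config.strand_bias_indel is not None:
                start = _bias_orientation(
                    start, flen, L, hlen, junctions, config.strand_bias_indel, rng
                )
            w1 = hseq[start : start + L]
            w2 = revcomp(hseq[start + flen - L : start + flen])
            s1, q1, e1 = _sequence_read(w1, profile, rng)
            s2, q2, e2 = _sequence_read(w2, profile, rng)
            name = f"frag{counter:07d}"
            counter += 1
            pairs.append(
                (
                    SimRead(name, s1, q1, target.contig, a_start + start,
                            False, hap, hap // 2, e1),
                    SimRead(name, s2, q2, target.contig,
                            a_start + start + flen - L, True, hap, hap // 2, e2),
                )
            )
    logger.info("simulated %d read pairs over %d amplicons",
                len(pairs), len(panel.targets))
    return pairs


def _bias_orientation(
    start: int,
    flen: int,
    L: int,
    hlen: int,
    junctions: list[int],
    bias: float,
    rng: np.random.Generator,
) -> int:
    """Mirror a fragment so the indel-covering read sits on the wanted strand.

    The forward-strand read covers the first ``L`` bases of the fragment,
    the reverse-strand read the last ``L``.  When exactly one of the two
    windows covers a junction, the fragment is reflected about the
    junction as needed so the covering read is forward with probability
    ``bias``.
    """
    for j in junctions:
        in_w1 = start + 1 <= j <= start + L - 1
        in_w2 = start + flen - L + 1 <= j <= start + flen - 1
        if in_w1 == in_w2:
            continue
        want_fwd = rng.random() < bias
        if (want_fwd and in_w2) or (not want_fwd and in_w1):
            mirrored = 2 * j - start - flen
            return int(np.clip(mirrored, 0, hlen - flen))
        return start
    return start


def write_fastq(
    pairs: Sequence[tuple[SimRead, SimRead]],
    path1: str | Path,
    path2: str | Path,
) -> None:
    """Write mates to two FASTQ files (Sanger Phred+33 qualities)."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r1, r2 in pairs:
            for fh, r in ((f1, r1), (f2, r2)):
                qual = "".join(chr(33 + min(93, int(q))) for q in r.quals)
                fh.write(f"@{r.name}\n{r.seq}\n+\n{qual}\n")


def write_truth(
    truth: Sequence[TruthVariant],
    panel: ReferencePanel,
    path: str | Path,
) -> None:
    """Write planted variants as a left-aligned VCF with AC and VT INFO."""
    rows = []
    for v in truth:
        pos, ref, alt = left_align_indel(panel, v.contig, v.pos, v.ref, v.alt)
        rows.append((v.contig, pos, ref, alt, v.k, v.vtype))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=poolcall-simulate\n")
        for name, contig in panel.contigs.items():
            fh.write(f"##contig=<ID={name},length={len(contig)}>\n")
        fh.write('##INFO=<ID=AC,Number=1,Type=Integer,Description="planted allele count">\n')
        fh.write('##INFO=<ID=VT,Number=1,Type=String,Description="variant type">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for contig, pos, ref, alt, k, vtype in sorted(rows):
            fh.write(
                f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tAC={k};VT={vtype}\n"
            )


# ---------------------------------------------------------------------------
# Direct pileup-column simulation
# ---------------------------------------------------------------------------

def simulate_pileup_column(
    rng: np.random.Generator,
    *,
    n_samples: int,
    allele_count: int,
    depth_fwd: int,
    depth_rev: int,
    error_rate: float = 0.01,
    ref: str = "A",
    alt: str = "C",
    contig: str = "sim",
    pos: int = 0,
) -> PileupColumn:
    """One SNV pileup column under the pooled sampling model.

    Every entry draws the variant chromosome with probability
    ``allele_count / 2N`` and is then miscalled to a uniform other base
    with probability ``error_rate``; qualities are the Phred equivalent of
    the true error rate (a perfectly recalibrated column).
    """
    f = allele_count / (2 * n_samples)
    q = quality_from_error(error_rate)
    entries: list[PileupEntry] = []
    others = {b: [x for x in BASES if x != b] for b in BASES}
    for strand, depth in (("+", depth_fwd), ("-", depth_rev)):
        true_alt = rng.random(depth) < f
        err = rng.random(depth) < error_rate
        pick = rng.integers(0, 3, size=depth)
        for i in range(depth):
            base = alt if true_alt[i] else ref
            if err[i]:
                base = others[base][pick[i]]
            entries.append(
                PileupEntry(base, q, strand, f"sim{strand}{i}", 1)
            )
    return PileupColumn(contig, pos, ref, entries)


def variant_free_candidate_columns(
    rng: np.random.Generator,
    n_positions: int,
    depth: int,
    error_rate: float = 0.01,
    ref: str = "A",
    min_alt_support: int = 4,
) -> list[PileupColumn]:
    """Columns from a variant-free panel that could possibly be called.

    Simulates per-position substitution-error counts for ``n_positions``
    targeted bases at fixed depth and materialises full columns only where
    at least ``min_alt_support`` errors landed.  At uniform Q20-grade
    evidence, fewer than four supporting bases cannot push the pooled LLR
    over the calling threshold at these depths, so discarding quieter
    positions does not change the resulting call set — it only skips
    columns whose LLR is guaranteed negative.
    """
    n_err = rng.binomial(depth, error_rate, size=n_positions)
    q = quality_from_error(error_rate)
    out = []
    for idx in np.nonzero(n_err >= min_alt_support)[0]:
        k = int(n_err[idx])
        entries = []
        alts = rng.integers(0, 3, size=k)
        strands = rng.random(depth) < 0.5
        others = [b for b in BASES if b != ref]
        for i in range(depth):
            base = others[alts[i]] if i < k else ref
            entries.append(
                PileupEntry(base, q, "+" if strands[i] else "-", f"r{i}", 1)
            )
        out.append(PileupColumn("sim", int(idx), ref, entries))
    return out


# ---------------------------------------------------------------------------
# Ready-made two-pool study scenario
# ---------------------------------------------------------------------------

_PANEL_SEED = 1159  # fixed: the example panel is a deterministic artifact

_STOPS = {"TAA", "TAG", "TGA"}


def _random_cds(n_codons: int, rng: np.random.Generator) -> list[str]:
    codons = []
    while len(codons) < n_codons:
        c = "".join(BASES[i] for i in rng.integers(0, 4, size=3))
        if c not in _STOPS:
            codons.append(c)
    return codons


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def build_example_panel() -> ReferencePanel:
    """Deterministic four-gene toy panel mirroring the study design.

    Contains a SOX2-like gene whose CDS carries a five-codon GGC
    (glycine) run at codons 19-23 and a CCCC homopolymer at c.536-539
    (the two repeat contexts in which indel calls shift under
    left-alignment), an OTX2-like minus-strand gene with Gln at codon
    105, a FOXE3-like gene with Cys at codon 240, and a PAX2-like
    two-exon target of which one exon can be dropped from the library.
    """
    rng = np.random.default_rng(_PANEL_SEED)
    flank = 120

    def assemble(cds: str, minus: bool = False) -> tuple[str, int]:
        left = _random_seq(flank, rng)
        right = _random_seq(flank, rng)
        body = revcomp(cds) if minus else cds
        return left + body + right, flank

    # SOX2-like: 200 codons
    codons = _random_cds(200, rng)
    codons[17] = "AAT"                      # Asn18: bounds the glycine run
    for i in range(18, 23):
        codons[i] = "GGC"                   # Gly19..Gly23 (c.55-69)
    codons[23] = "AAT"                      # Asn24
    codons[178] = "ACC"                     # -> c.535 'A', c.536-537 'CC'
    codons[179] = "CCG"                     # -> c.538-539 'CC', c.540 'G'
    sox_cds = "".join(codons)
    sox_seq, sox_off = assemble(sox_cds)

    # OTX2-like on the minus strand: 150 codons, Gln105
    codons = _random_cds(150, rng)
    codons[104] = "CAG"                     # c.313-315, c.313 'C'
    otx_cds = "".join(codons)
    otx_seq, otx_off = assemble(otx_cds, minus=True)

    # FOXE3-like: 250 codons, Cys240
    codons = _random_cds(250, rng)
    codons[239] = "TGC"                     # c.718-720, c.720 'C'
    fox_cds = "".join(codons)
    fox_seq, fox_off = assemble(fox_cds)

    # PAX2-like: two 150 bp "exons" separated by 200 bp
    pax_seq = _random_seq(150 + 200 + 150 + 2 * flank, rng)

    contigs = {
        "SOX2L": Contig("SOX2L", sox_seq),
        "OTX2L": Contig("OTX2L", otx_seq),
        "FOXE3L": Contig("FOXE3L", fox_seq),
        "PAX2L": Contig("PAX2L", pax_seq),
    }
    genes = {
        "SOX2L": GeneModel("SOX2L", "SOX2L", "+",
                           ((sox_off, sox_off + len(sox_cds)),)),
        "OTX2L": GeneModel("OTX2L", "OTX2L", "-",
                           ((otx_off, otx_off + len(otx_cds)),)),
        "FOXE3L": GeneModel("FOXE3L", "FOXE3L", "+",
                            ((fox_off, fox_off + len(fox_cds)),)),
    }
    targets = [
        TargetRegion("SOX2L", sox_off, sox_off + len(sox_cds), "SOX2L_ex1"),
        TargetRegion("OTX2L", otx_off, otx_off + len(otx_cds), "OTX2L_ex1"),
        TargetRegion("FOXE3L", fox_off, fox_off + len(fox_cds), "FOXE3L_ex1"),
        TargetRegion("PAX2L", flank, flank + 150, "PAX2L_ex5"),
        TargetRegion("PAX2L", flank + 350, flank + 500, "PAX2L_ex6"),
    ]
    panel = ReferencePanel(contigs=contigs, targets=targets, genes=genes)

    # known sites: common SNPs, some planted in the pools, some not
    known = KnownSiteDB()
    for i, (gene_name, c_pos) in enumerate(
        [("FOXE3L", 150), ("SOX2L", 300), ("OTX2L", 90),
         ("FOXE3L", 420), ("SOX2L", 450)]
    ):
        gene = genes[gene_name]
        contig, gpos = cds_to_genomic(gene, c_pos)
        ref = panel.base(contig, gpos - 1)
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
        known.add(contig, gpos, ref, alt, f"rs{9000 + i}")
    panel.known_sites = known
    panel.validate()
    return panel


def _genomic_snv(
    panel: ReferencePanel, gene: GeneModel, c_pos: int, c_ref: str, c_alt: str
) -> tuple[str, int, str, str]:
    contig, gpos = cds_to_genomic(gene, c_pos)
    if gene.strand == "-":
        c_ref, c_alt = revcomp(c_ref), revcomp(c_alt)
    assert panel.base(contig, gpos - 1) == c_ref
    return contig, gpos, c_ref, c_alt


def example_variant_specs(
    panel: ReferencePanel, pool: str
) -> list[VariantSpec]:
    """Planted variant roster for the two emulated pools.

    Pool 'POOL1' (N=8): a 1 bp CDS deletion at the right end of the CCCC
    homopolymer, a nonsense C>T singleton in the minus-strand gene, and a
    known common SNP at higher allele count.  Pool 'POOL2' (N=7): a
    homozygous nonsense C>A in one sample, a 3 bp (GGC) duplication after
    the glycine run, a 20 bp CDS deletion, and a known SNP.
    """
    genes = panel.genes
    specs: list[VariantSpec] = []
    if pool == "POOL1":
        sox = genes["SOX2L"]
        contig, g539 = cds_to_genomic(sox, 539)
        anchor = panel.base(contig, g539 - 2)
        specs.append(VariantSpec(contig, g539 - 1, anchor + "C", anchor,
                                 1, "het", label="SOX2L:c.539del"))
        specs.append(VariantSpec(*_genomic_snv(panel, genes["OTX2L"], 313, "C", "T"),
                                 1, "het", label="OTX2L:c.313C>T"))
        fox = genes["FOXE3L"]
        contig, gpos = cds_to_genomic(fox, 150)
        ref = panel.base(contig, gpos - 1)
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
        specs.append(VariantSpec(contig, gpos, ref, alt, 4, "het",
                                 label="FOXE3L:c.150 known SNP"))
    elif pool == "POOL2":
        specs.append(VariantSpec(*_genomic_snv(panel, genes["FOXE3L"], 720, "C", "A"),
                                 2, "hom", label="FOXE3L:c.720C>A hom"))
        sox = genes["SOX2L"]
        contig, g66 = cds_to_genomic(sox, 66)
        anchor = panel.base(contig, g66 - 1)
        # GGC duplication within the glycine run (anchored mid-run; the
        # 20 bp deletion occupies the run's right anchor position)
        specs.append(VariantSpec(contig, g66, anchor, anchor + "GGC",
                                 1, "het", label="SOX2L:c.64_66dupGGC"))
        contig, g69 = cds_to_genomic(sox, 69)
        deleted = panel.fetch(contig, g69 - 1, g69 + 20)
        specs.append(VariantSpec(contig, g69, deleted, deleted[0],
                                 1, "het", label="SOX2L:c.70del20"))
        contig, gpos = cds_to_genomic(sox, 300)
        ref = panel.base(contig, gpos - 1)
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
        specs.append(VariantSpec(contig, gpos, ref, alt, 3, "het",
                                 label="SOX2L:c.300 known SNP"))
    else:
        raise ValueError(f"unknown pool {pool!r}")
    return specs


def example_sim_config(pool: str, depth: float = 800.0) -> SimConfig:
    """Study-design configuration for one of the two emulated pools."""
    if pool == "POOL1":
        return SimConfig(n_samples=8, depth=depth,
                         uncovered_labels=("PAX2L_ex6",))
    if pool == "POOL2":
        return SimConfig(n_samples=7, depth=depth,
                         strand_bias_indel=1.0,
                         uncovered_labels=("PAX2L_ex6",))
    raise ValueError(f"unknown pool {pool!r}")


def write_panel_files(panel: ReferencePanel, outdir: str | Path) -> dict[str, Path]:
    """Write a panel to FASTA/BED/TSV files (for the CLI entry points)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "panel.fa",
        "bed": outdir / "targets.bed",
        "genes": outdir / "genes.tsv",
        "known_sites": outdir / "known_sites.tsv",
    }
    with open(paths["fasta"], "w") as fh:
        for name, contig in panel.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(contig), 60):
                fh.write(contig.sequence[i : i + 60] + "\n")
    with open(paths["bed"], "w") as fh:
        for t in panel.targets:
            fh.write(f"{t.contig}\t{t.start}\t{t.end}\t{t.label}\n")
    with open(paths["genes"], "w") as fh:
        for g in panel.genes.values():
            ivals = ";".join(f"{s}-{e}" for s, e in g.cds_intervals)
            fh.write(f"{g.name}\t{g.contig}\t{g.strand}\t{ivals}\n")
    with open(paths["known_sites"], "w") as fh:
        for contig, pos, ref, alt, site_id in panel.known_sites.records():
            fh.write(f"{contig}\t{pos}\t{site_id}\t{ref}\t{alt}\n")
    return paths
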