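"""Likelihood-ratio variant calling in non-barcoded pools.

At each targeted position the caller compares the likelihood that a
variant allele is present in the pool at frequency ``f = k/(2N)`` for some
integer carrier allele count ``k`` (k = 1..2N; a heterozygote contributes
one chromosome, a homozygote two) against the null likelihood that every
non-reference base is a sequencing error.  With per-base error
probabilities ``e_i`` from recalibrated qualities, the emission model is

    p(b | a) = 1 - e_i          if b == a
             = e_i / 3          otherwise,

so  L0 = prod_i p(b_i | ref)  and  L1(k) = prod_i [(1-f) p(b_i | ref)
+ f p(b_i | alt)].  The statistic is LLR = log10(max_k L1(k) / L0); a
candidate is emitted where LLR strictly exceeds the threshold (default 3,
i.e. a likelihood ratio of ~1000).  The carrier allele count is then
estimated by an EM iteration on the mixture weight, with the integer
``k_hat`` taken as the argmax of L1 over the k grid (ties toward smaller
k).  Sample-level zygosity is not identifiable without barcodes, so the
caller reports allele counts, not genotypes.

High-confidence calls additionally require (1) statistically balanced
variant support between forward and reverse strands (two-sided Fisher
exact test), (2) per-strand LLR above the threshold on *both* strands, and
(3) no adjacent candidate within a 1 bp window.  Because criterion (2)
systematically rejects indels whose supporting reads are concentrated on
one strand, a relaxed re-check pass reports indel candidates whose LLR
exceeds the threshold on *either* strand alone.

Indels are represented VCF-style with an anchor base and normalised to
their leftmost equivalent position, so a deletion planted at the right end
of a homopolymer run is reported at the start of the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .panel import ReferencePanel, TargetRegion, merged_footprint
from .recal import phred_error_prob, q20_mask

logger = logging.getLogger(__name__)

__all__ = [
    "CallerConfig",
    "PileupEntry",
    "PileupColumn",
    "CandidateVariant",
    "VariantCallSet",
    "build_pileup",
    "column_likelihoods",
    "call_candidate",
    "em_allele_count",
    "strand_balance_test",
    "per_strand_llr",
    "adjacency_filter",
    "indel_recheck",
    "left_align_indel",
    "call_variants",
    "write_vcf",
    "write_candidates_tsv",
]

MIN_ERROR = 1e-10  # floor on per-base error probability (Q cap is 40 anyway)

TIER_HIGH = "high_confidence"
TIER_CANDIDATE = "candidate"
TIER_RECHECK = "indel_recheck"

FILTER_STRAND_BIAS = "strand_bias"
FILTER_STRAND_LLR = "one_strand_llr"
FILTER_ADJACENT = "adjacent_variant"


@dataclass(frozen=True)
class CallerConfig:
    """Pooled-calling parameters.

    n_samples: diploid samples in the pool (pool holds 2N chromosomes).
    llr_threshold: log10 likelihood-ratio needed to call (strict '>').
    strand_p_threshold: Fisher-test p below which strand balance fails.
    both_strand_rule: 'threshold' requires per-strand LLR > llr_threshold
        on both strands for high confidence; 'positive' merely requires
        both per-strand LLRs > 0.
    """

    n_samples: int = 8
    llr_threshold: float = 3.0
    strand_p_threshold: float = 0.05
    em_tol: float = 1e-8
    em_max_iter: int = 200
    adjacency_window: int = 1
    both_strand_rule: str = "threshold"

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.llr_threshold <= 0:
            raise ValueError("llr_threshold must be positive")
        if self.both_strand_rule not in ("threshold", "positive"):
            raise ValueError("both_strand_rule must be 'threshold' or 'positive'")

    @property
    def n_chromosomes(self) -> int:
        return 2 * self.n_samples

    def per_strand_cut(self) -> float:
        return self.llr_threshold if self.both_strand_rule == "threshold" else 0.0


@dataclass
class PileupEntry:
    """One read's evidence at one reference position.

    ``sym`` is the called base, or ``D<len>`` when this read carries a
    deletion whose first deleted base is this position.  ``ins`` carries an
    insertion (sequence, proxy quality) anchored immediately after this
    position; the proxy quality of gap symbols is the flanking base
    quality of the same read.
    """

    sym: str
    qual: int
    strand: str  # '+' or '-'
    read_id: str
    cycle: int
    ins: tuple[str, int] | None = None


@dataclass
class PileupColumn:
    """All Q20-passing evidence at one targeted reference position."""

    contig: str
    pos: int  # 0-based
    ref: str
    entries: list[PileupEntry] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.entries)

    def alt_symbols(self) -> list[str]:
        """Distinct alternate symbols with at least one supporting entry."""
        syms: set[str] = set()
        for e in self.entries:
            if e.sym != self.ref:
                syms.add(e.sym)
            if e.ins is not None:
                syms.add("I" + e.ins[0])
        return sorted(syms)

    def support(self, alt: str) -> int:
        return sum(1 for s in self._effective_syms(alt) if s == alt)

    def _effective_syms(self, alt: str) -> list[str]:
        """Per-entry symbols in the context of a specific alt allele.

        For insertion alleles a read that carries the insertion supports
        the alt; any read spanning the junction without it supports the
        reference, represented by its called base.
        """
        if alt.startswith("I"):
            return [
                "I" + e.ins[0] if e.ins is not None else e.sym
                for e in self.entries
            ]
        return [e.sym for e in self.entries]

    def evidence_arrays(
        self, alt: str
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(p_ref, p_alt, is_forward) arrays for the emission model."""
        syms = self._effective_syms(alt)
        quals = np.array(
            [
                e.ins[1] if (alt.startswith("I") and e.ins is not None) else e.qual
                for e in self.entries
            ],
            dtype=np.float64,
        )
        err = np.maximum(phred_error_prob(quals), MIN_ERROR)
        sym_arr = np.array(syms)
        p_ref = np.where(sym_arr == self.ref, 1.0 - err, err / 3.0)
        p_alt = np.where(sym_arr == alt, 1.0 - err, err / 3.0)
        fwd = np.array([e.strand == "+" for e in self.entries])
        return p_ref, p_alt, fwd


# ---------------------------------------------------------------------------
# Pileup construction
# ---------------------------------------------------------------------------

def build_pileup(
    alignments: Iterable,
    targets: Sequence[TargetRegion],
    panel: ReferencePanel,
    mask_threshold: int = 20,
) -> list[PileupColumn]:
    """Assemble per-position evidence columns over the target footprint.

    Only bases passing the Q20 mask (recalibrated quality >= 20) enter a
    column; reference-N positions are skipped.  Deletion evidence is
    attributed to the first deleted base; insertion evidence is attached to
    the anchor base immediately left of the junction.  Each read
    contributes at most one entry per column.
    """
    footprint = merged_footprint(targets)
    in_target: dict[str, set[int]] = {
        c: set(p for s, e in ivals for p in range(s, e))
        for c, ivals in footprint.items()
    }
    columns: dict[tuple[str, int], PileupColumn] = {}

    def col(contig: str, pos: int) -> PileupColumn | None:
        if pos not in in_target.get(contig, ()):  # outside targets
            return None
        key = (contig, pos)
        c = columns.get(key)
        if c is None:
            ref = panel.base(contig, pos)
            if ref == "N":
                return None
            c = columns[key] = PileupColumn(contig, pos, ref)
        return c

    for read in alignments:
        if not read.mapped:
            continue
        strand = "-" if read.is_reverse else "+"
        pending_entry: dict[int, PileupEntry] = {}
        for i, r in read.aligned_pairs():
            q = int(read.quals[i])
            if not q20_mask(q, mask_threshold):
                continue
            base = read.seq[i]
            if base == "N":
                continue
            pending_entry[r] = PileupEntry(
                sym=base,
                qual=q,
                strand=strand,
                read_id=read.name,
                cycle=read.cycle(i),
            )
        # gap evidence, left-normalised so equivalent placements within a
        # repeat pool at one canonical column
        if panel is not None:
            seq = panel.contigs[read.contig].sequence
            for op, i, r, n in read.gaps():
                flank_i = i - 1 if i > 0 else 0
                q = int(read.quals[flank_i])
                if not q20_mask(q, mask_threshold):
                    continue
                cycle = read.cycle(flank_i)
                if op == "D":
                    if r < 1:
                        continue
                    pos1, _ref, _alt = left_align_indel(
                        panel, read.contig, r, seq[r - 1 : r + n], seq[r - 1]
                    )
                    entry = PileupEntry(
                        sym=f"D{n}", qual=q, strand=strand,
                        read_id=read.name, cycle=cycle,
                    )
                    pending_entry[pos1] = entry  # first deleted base, 0-based
                else:  # insertion anchored left of ref position r
                    if r < 1:
                        continue
                    ins_seq = read.seq[i : i + n]
                    pos1, _ref, alt = left_align_indel(
                        panel, read.contig, r, seq[r - 1], seq[r - 1] + ins_seq
                    )
                    canon_seq = alt[1:]
                    anchor0 = pos1 - 1
                    entry = pending_entry.get(anchor0)
                    if entry is not None:
                        entry.ins = (canon_seq, q)
                    else:
                        # read does not cover the canonical anchor; carry the
                        # insertion on a base-less entry (contributes only to
                        # insertion-allele scoring)
                        pending_entry[anchor0] = PileupEntry(
                            sym="I" + canon_seq, qual=q, strand=strand,
                            read_id=read.name, cycle=cycle,
                            ins=(canon_seq, q),
                        )
        for pos, entry in pending_entry.items():
            c = col(read.contig, pos)
            if c is not None:
                c.entries.append(entry)
    return [columns[k] for k in sorted(columns)]


# ---------------------------------------------------------------------------
# Likelihoods, EM, filters
# ---------------------------------------------------------------------------

def column_likelihoods(
    column: PileupColumn,
    alt: str,
    config: CallerConfig,
    mask: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """(log10 L0, log10 L1(k) for k = 1..2N) for one column and alt.

    ``mask`` optionally restricts the evidence to a subset of entries
    (used for the per-strand statistics).  Computation is in log space.
    """
    p_ref, p_alt, _ = column.evidence_arrays(alt)
    if mask is not None:
        p_ref, p_alt = p_ref[mask], p_alt[mask]
    if p_ref.size == 0:
        return -np.inf, np.full(config.n_chromosomes, -np.inf)
    log_l0 = float(np.log10(p_ref).sum())
    k = np.arange(1, config.n_chromosomes + 1)
    f = k[:, None] / config.n_chromosomes
    mix = (1.0 - f) * p_ref[None, :] + f * p_alt[None, :]
    log_l1 = np.log10(mix).sum(axis=1)
    return log_l0, log_l1


def _llr(log_l0: float, log_l1: np.ndarray) -> float:
    if not np.isfinite(log_l0):
        return -np.inf
    return float(log_l1.max() - log_l0)


def em_allele_count(
    column: PileupColumn, alt: str, config: CallerConfig
) -> tuple[float, int]:
    """EM estimate of the pooled allele fraction and integer allele count.

    The E-step computes per-entry responsibilities for the alt component,
    the M-step sets f to their mean; f starts at max(1/2N, observed alt
    fraction).  The integer ``k_hat`` is the argmax over the k grid of
    L1(k/2N), ties resolved toward smaller k.
    """
    p_ref, p_alt, _ = column.evidence_arrays(alt)
    n = p_ref.size
    if n == 0:
        return 0.0, 0
    obs_frac = column.support(alt) / n
    f = max(1.0 / config.n_chromosomes, obs_frac)
    converged = False
    for _ in range(config.em_max_iter):
        w = f * p_alt / (f * p_alt + (1.0 - f) * p_ref)
        f_new = float(w.mean())
        if abs(f_new - f) < config.em_tol:
            f = f_new
            converged = True
            break
        f = f_new
    if not converged:
        logger.debug(
            "EM did not converge at %s:%d alt %s", column.contig, column.pos, alt
        )
    _, log_l1 = column_likelihoods(column, alt, config)
    k_hat = int(np.argmax(log_l1)) + 1  # argmax returns the smallest tied k
    return f, k_hat


def strand_balance_test(column: PileupColumn, alt: str) -> float:
    """Two-sided Fisher exact p for strand balance of alt support.

    Table: [[alt fwd, ref fwd], [alt rev, ref rev]].  A strand with zero
    depth makes the test untestable and returns p = 1.
    """
    syms = column._effective_syms(alt)
    fwd = [e.strand == "+" for e in column.entries]
    alt_f = sum(1 for s, fw in zip(syms, fwd) if s == alt and fw)
    alt_r = sum(1 for s, fw in zip(syms, fwd) if s == alt and not fw)
    ref_f = sum(1 for s, fw in zip(syms, fwd) if s == column.ref and fw)
    ref_r = sum(1 for s, fw in zip(syms, fwd) if s == column.ref and not fw)
    if alt_f + ref_f == 0 or alt_r + ref_r == 0:
        logger.debug(
            "strand test untestable at %s:%d (empty strand)",
            column.contig,
            column.pos,
        )
        return 1.0
    _, p = stats.fisher_exact([[alt_f, ref_f], [alt_r, ref_r]])
    return float(p)


def per_strand_llr(
    column: PileupColumn, alt: str, config: CallerConfig
) -> tuple[float, float]:
    """LLR computed from forward-strand and reverse-strand reads alone.

    An empty strand yields -inf for that strand, which can never satisfy
    the both-strand rule.
    """
    _, _, fwd = column.evidence_arrays(alt)
    l0f, l1f = column_likelihoods(column, alt, config, mask=fwd)
    l0r, l1r = column_likelihoods(column, alt, config, mask=~fwd)
    return _llr(l0f, l1f), _llr(l0r, l1r)


@dataclass
class CandidateVariant:
    """A scored pooled variant call."""

    contig: str
    pos: int  # 0-based column position
    ref_base: str
    alt_sym: str  # base, D<len> or I<seq>
    llr_total: float
    llr_fwd: float = -np.inf
    llr_rev: float = -np.inf
    f_hat: float = 0.0
    k_hat: int = 0
    strand_p: float = 1.0
    n_alt: int = 0
    depth: int = 0
    filters: dict[str, bool] = field(default_factory=dict)  # name -> passed
    tier: str = TIER_CANDIDATE
    # normalised VCF representation (1-based, anchor-base style for indels)
    vcf_pos: int = 0
    vcf_ref: str = ""
    vcf_alt: str = ""
    column: "PileupColumn | None" = field(default=None, repr=False)

    @property
    def is_indel(self) -> bool:
        return self.alt_sym.startswith(("D", "I"))

    @property
    def passed_all(self) -> bool:
        return all(self.filters.values())

    def allele_key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.vcf_pos, self.vcf_ref, self.vcf_alt)


@dataclass
class VariantCallSet:
    """All scored candidates plus the filtered tiers."""

    candidates: list[CandidateVariant] = field(default_factory=list)
    high_confidence: list[CandidateVariant] = field(default_factory=list)
    indel_recheck: list[CandidateVariant] = field(default_factory=list)
    scored: list[CandidateVariant] = field(default_factory=list)


def left_align_indel(
    panel: ReferencePanel, contig: str, pos: int, ref: str, alt: str
) -> tuple[int, str, str]:
    """Normalise an indel to its leftmost equivalent representation.

    ``pos`` is 1-based with the usual VCF anchor-base convention.  The
    representation is shifted left while the implied alternate haplotype
    is unchanged (identical trailing bases are rotated off using the
    reference); the operation is idempotent.  SNVs are returned untouched.
    """
    if len(ref) == len(alt) == 1:
        return pos, ref, alt
    seq = panel.contigs[contig].sequence
    ref_l, alt_l = ref, alt
    # trim shared trailing bases first (keeping at least one base each)
    while len(ref_l) > 1 and len(alt_l) > 1 and ref_l[-1] == alt_l[-1]:
        ref_l, alt_l = ref_l[:-1], alt_l[:-1]
    while ref_l[-1] == alt_l[-1] and pos > 1:
        prev = seq[pos - 2]
        ref_l = prev + ref_l[:-1]
        alt_l = prev + alt_l[:-1]
        pos -= 1
    return pos, ref_l, alt_l


def _vcf_repr(
    panel: ReferencePanel, contig: str, pos: int, ref: str, alt_sym: str
) -> tuple[int, str, str]:
    """VCF-style (1-based pos, ref, alt) for a column-level alt symbol."""
    seq = panel.contigs[contig].sequence
    if alt_sym.startswith("D"):
        d = int(alt_sym[1:])
        anchor = pos - 1
        if anchor < 0:  # deletion at contig start: right-anchor instead
            return 1, seq[: d + 1], seq[d]
        vcf = (anchor + 1, seq[anchor : anchor + d + 1], seq[anchor])
    elif alt_sym.startswith("I"):
        vcf = (pos + 1, seq[pos], seq[pos] + alt_sym[1:])
    else:
        return pos + 1, ref, alt_sym
    return left_align_indel(panel, contig, *vcf)


def call_candidate(
    column: PileupColumn,
    config: CallerConfig,
    panel: ReferencePanel | None = None,
) -> tuple[CandidateVariant | None, list[CandidateVariant]]:
    """Score every supported alt at a column; emit the best as candidate.

    Returns (candidate or None, all scored alleles).  A candidate is
    emitted iff its total LLR strictly exceeds the threshold; when several
    alts exceed it the one with the largest LLR is reported (ties toward
    the lexicographically smaller symbol).
    """
    scored: list[CandidateVariant] = []
    for alt in column.alt_symbols():
        log_l0, log_l1 = column_likelihoods(column, alt, config)
        llr_f, llr_r = per_strand_llr(column, alt, config)
        cand = CandidateVariant(
            contig=column.contig,
            pos=column.pos,
            ref_base=column.ref,
            alt_sym=alt,
            llr_total=_llr(log_l0, log_l1),
            llr_fwd=llr_f,
            llr_rev=llr_r,
            n_alt=column.support(alt),
            depth=column.depth,
            column=column,
        )
        if panel is not None:
            cand.vcf_pos, cand.vcf_ref, cand.vcf_alt = _vcf_repr(
                panel, column.contig, column.pos, column.ref, alt
            )
        else:
            cand.vcf_pos = column.pos + 1
            cand.vcf_ref, cand.vcf_alt = column.ref, alt
        scored.append(cand)
    above = [c for c in scored if c.llr_total > config.llr_threshold]
    if not above:
        return None, scored
    best = max(above, key=lambda c: (c.llr_total, [-ord(ch) for ch in c.alt_sym]))
    tied = [c for c in above if c.llr_total == best.llr_total]
    if len(tied) > 1:
        logger.debug(
            "LLR tie at %s:%d; reporting %s",
            column.contig,
            column.pos,
            best.alt_sym,
        )
    best.f_hat, best.k_hat = em_allele_count(column, best.alt_sym, config)
    best.strand_p = strand_balance_test(column, best.alt_sym)
    return best, scored


def adjacency_filter(
    candidates: Sequence[CandidateVariant], config: CallerConfig
) -> None:
    """Flag candidates with another candidate within the adjacency window.

    Both members of an adjacent pair fail, mirroring the rule that true
    variants should not cluster at neighbouring bases.
    """
    by_contig: dict[str, list[CandidateVariant]] = {}
    for c in candidates:
        by_contig.setdefault(c.contig, []).append(c)
    for group in by_contig.values():
        group.sort(key=lambda c: c.pos)
        for i, c in enumerate(group):
            ok = True
            for j in (i - 1, i + 1):
                if 0 <= j < len(group):
                    if abs(group[j].pos - c.pos) <= config.adjacency_window:
                        ok = False
            c.filters[FILTER_ADJACENT] = ok


def indel_recheck(
    scored: Sequence[CandidateVariant], config: CallerConfig
) -> list[CandidateVariant]:
    """Relaxed either-strand pass over all scored indel alleles.

    Emits indel candidates whose LLR exceeds the threshold on the forward
    or the reverse strand alone, regardless of the both-strand rule.  SNVs
    are never re-checked.
    """
    out = []
    for c in scored:
        if not c.is_indel:
            continue
        if max(c.llr_fwd, c.llr_rev) > config.llr_threshold:
            c.tier = TIER_RECHECK if c.tier != TIER_HIGH else c.tier
            out.append(c)
    return out


def call_variants(
    columns: Iterable[PileupColumn],
    config: CallerConfig,
    panel: ReferencePanel | None = None,
) -> VariantCallSet:
    """Run calling, filtering and the indel re-check over a pileup."""
    callset = VariantCallSet()
    cut = config.per_strand_cut()
    for column in columns:
        cand, scored = call_candidate(column, config, panel)
        callset.scored.extend(scored)
        if cand is not None:
            callset.candidates.append(cand)
    adjacency_filter(callset.candidates, config)
    for c in callset.candidates:
        c.filters[FILTER_STRAND_BIAS] = c.strand_p > config.strand_p_threshold
        c.filters[FILTER_STRAND_LLR] = c.llr_fwd > cut and c.llr_rev > cut
        c.filters.setdefault(FILTER_ADJACENT, True)
        if c.passed_all:
            c.tier = TIER_HIGH
            callset.high_confidence.append(c)
    callset.indel_recheck = indel_recheck(callset.scored, config)
    for c in callset.indel_recheck:
        if c.k_hat == 0 and c.column is not None:
            c.f_hat, c.k_hat = em_allele_count(c.column, c.alt_sym, config)
            c.strand_p = strand_balance_test(c.column, c.alt_sym)
    logger.info(
        "called %d candidates (%d high-confidence, %d indel re-check)",
        len(callset.candidates),
        len(callset.high_confidence),
        len(callset.indel_recheck),
    )
    return callset


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def _filter_field(c: CandidateVariant) -> str:
    if c.tier == TIER_HIGH:
        return "PASS"
    if c.tier == TIER_RECHECK and not c.filters:
        return "one_strand_indel"
    failed = [name for name, ok in c.filters.items() if not ok]
    if c.tier == TIER_RECHECK and FILTER_STRAND_LLR in failed:
        return "one_strand_indel"
    return ";".join(failed) if failed else "PASS"


def write_vcf(
    callset: VariantCallSet,
    panel: ReferencePanel,
    config: CallerConfig,
    path: str | Path,
) -> None:
    """Write candidate and re-check calls as VCF v4.2."""
    recheck_keys = {id(c) for c in callset.indel_recheck}
    rows = {id(c): c for c in callset.candidates}
    for c in callset.indel_recheck:
        rows.setdefault(id(c), c)
    ordered = sorted(rows.values(), key=lambda c: (c.contig, c.vcf_pos, c.vcf_alt))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=poolcall\n")
        for name, contig in panel.contigs.items():
            fh.write(f"##contig=<ID={name},length={len(contig)}>\n")
        fh.write('##INFO=<ID=LLR,Number=1,Type=Float,Description="log10 likelihood ratio, both strands">\n')
        fh.write('##INFO=<ID=LLRF,Number=1,Type=Float,Description="log10 likelihood ratio, forward strand">\n')
        fh.write('##INFO=<ID=LLRR,Number=1,Type=Float,Description="log10 likelihood ratio, reverse strand">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="EM pooled allele fraction">\n')
        fh.write('##INFO=<ID=AC,Number=1,Type=Integer,Description="estimated variant allele count in the pool">\n')
        fh.write('##INFO=<ID=SP,Number=1,Type=Float,Description="strand balance Fisher exact p">\n')
        fh.write('##INFO=<ID=TIER,Number=1,Type=String,Description="call tier">\n')
        fh.write('##FILTER=<ID=strand_bias,Description="strand balance test failed">\n')
        fh.write('##FILTER=<ID=one_strand_llr,Description="per-strand LLR rule failed">\n')
        fh.write('##FILTER=<ID=adjacent_variant,Description="adjacent to another candidate">\n')
        fh.write('##FILTER=<ID=one_strand_indel,Description="indel accepted on one strand only (re-check tier)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in ordered:
            tier = c.tier if id(c) not in recheck_keys or c.tier == TIER_HIGH else TIER_RECHECK
            info = (
                f"LLR={c.llr_total:.4f};LLRF={_fmt(c.llr_fwd)};"
                f"LLRR={_fmt(c.llr_rev)};AF={c.f_hat:.6f};AC={c.k_hat};"
                f"SP={c.strand_p:.4g};TIER={tier}"
            )
            fh.write(
                f"{c.contig}\t{c.vcf_pos}\t.\t{c.vcf_ref}\t{c.vcf_alt}\t"
                f"{c.llr_total:.2f}\t{_filter_field(c)}\t{info}\n"
            )


def _fmt(x: float) -> str:
    return f"{x:.4f}" if np.isfinite(x) else "-inf"


def write_candidates_tsv(callset: VariantCallSet, path: str | Path) -> None:
    """TSV of every scored allele (diagnostic companion to the VCF)."""
    with open(path, "w") as fh:
        fh.write(
            "contig\tpos\tref\talt\tllr_total\tllr_fwd\tllr_rev\t"
            "f_hat\tk_hat\tstrand_p\tn_alt\tdepth\ttier\n"
        )
        for c in sorted(callset.scored, key=lambda c: (c.contig, c.pos, c.alt_sym)):
            fh.write(
                f"{c.contig}\t{c.pos + 1}\t{c.ref_base}\t{c.alt_sym}\t"
                f"{c.llr_total:.4f}\t{_fmt(c.llr_fwd)}\t{_fmt(c.llr_rev)}\t"
                f"{c.f_hat:.6f}\t{c.k_hat}\t{c.strand_p:.4g}\t"
                f"{c.n_alt}\t{c.depth}\t{c.tier}\n"
            )
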