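"""Coverage completeness, call triage and coding-effect annotation.

Experimental completeness is judged per targeted base against a pooled
depth threshold of 20 x N (e.g. > 160X for a pool of 8 diploid samples,
> 140X for 7): a base counts as covered only when its Q20 depth strictly
exceeds the threshold, and targets with no coverage at all are listed by
label so a dropped amplicon is visible rather than silently absent.

Triage separates finalized calls into known polymorphisms (exact-allele
match against the known-sites database — a novel alternate allele at a
known position is still novel) and novel calls that need orthogonal
verification, the latter ordered by descending likelihood ratio.  Known
calls are accepted without verification, mirroring the screening policy
that database membership is sufficient evidence; the report flags this
assumption.

Effect annotation works on the toy gene models of the panel: codon
comparison for SNVs (synonymous / missense / nonsense / stop-loss with
downstream extension), frame bookkeeping for indels (frameshift with the
new-stop offset, in-frame otherwise), and HGVS-style c./p. strings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .caller import CandidateVariant, PileupColumn
from .panel import (
    GeneModel,
    KnownSiteDB,
    ReferencePanel,
    TargetRegion,
    genomic_to_cds,
    merged_footprint,
    revcomp,
)

logger = logging.getLogger(__name__)

__all__ = [
    "coverage_threshold",
    "CoverageReport",
    "coverage_report",
    "TriageRecord",
    "triage_calls",
    "EffectAnnotation",
    "annotate_effect",
]

_CODON = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON[_stop] = "*"

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "X",
}


def translate(cds: str) -> str:
    """Translate a DNA string codon-by-codon; '*' marks stops."""
    return "".join(
        _CODON.get(cds[i : i + 3], "X") for i in range(0, len(cds) - 2, 3)
    )


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def coverage_threshold(n_samples: int) -> int:
    """Pooled depth threshold for completeness: 20 x N.

    20X per diploid sample is required to see both chromosomes reliably,
    so a pool of 8 needs > 160X and a pool of 7 needs > 140X.
    """
    if n_samples < 1:
        raise ValueError("pool size must be >= 1")
    return 20 * n_samples


@dataclass
class CoverageReport:
    """Per-target and global completeness against the 20 x N rule."""

    n_samples: int
    threshold: int
    completeness: float  # fraction of targeted bases with depth > threshold
    per_target: list[dict] = field(default_factory=list)
    uncovered: list[str] = field(default_factory=list)  # labels with zero depth

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_samples": self.n_samples,
                    "threshold": self.threshold,
                    "completeness": self.completeness,
                    "per_target": self.per_target,
                    "uncovered": self.uncovered,
                    "policy_note": (
                        "known-database calls are accepted without "
                        "verification; completeness uses strict > threshold"
                    ),
                },
                fh,
                indent=2,
            )
            fh.write("\n")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("label\tcontig\tstart\tend\tfraction_above\tmean_depth\tcovered\n")
            for row in self.per_target:
                fh.write(
                    f"{row['label']}\t{row['contig']}\t{row['start']}\t"
                    f"{row['end']}\t{row['fraction_above']:.4f}\t"
                    f"{row['mean_depth']:.1f}\t{row['covered']}\n"
                )


def coverage_report(
    columns: Iterable[PileupColumn],
    targets: Sequence[TargetRegion],
    n_samples: int,
) -> CoverageReport:
    """Assess completeness of Q20 coverage over the target footprint.

    Depth at a base is the number of Q20-passing pileup entries;
    positions with no column have depth zero.  Completeness is the
    fraction of targeted bases whose depth strictly exceeds 20 x N.
    """
    if not targets:
        raise ValueError("coverage report needs at least one target")
    thr = coverage_threshold(n_samples)
    depth: dict[tuple[str, int], int] = {}
    for col in columns:
        depth[(col.contig, col.pos)] = col.depth
    per_target = []
    uncovered = []
    total = above = 0
    for t in targets:
        depths = np.array(
            [depth.get((t.contig, p), 0) for p in range(t.start, t.end)]
        )
        frac = float((depths > thr).mean())
        covered = bool(depths.sum() > 0)
        per_target.append(
            {
                "label": t.label,
                "contig": t.contig,
                "start": t.start,
                "end": t.end,
                "fraction_above": frac,
                "mean_depth": float(depths.mean()),
                "covered": covered,
            }
        )
        if not covered:
            uncovered.append(t.label)
    # global completeness over the merged footprint (bases counted once)
    for contig, ivals in merged_footprint(targets).items():
        for s, e in ivals:
            for p in range(s, e):
                total += 1
                above += depth.get((contig, p), 0) > thr
    return CoverageReport(
        n_samples=n_samples,
        threshold=thr,
        completeness=above / total if total else 0.0,
        per_target=per_target,
        uncovered=uncovered,
    )


# ---------------------------------------------------------------------------
# Triage
# ---------------------------------------------------------------------------

KNOWN_SNP = "known_SNP"
NOVEL = "novel_needs_verification"


@dataclass
class TriageRecord:
    """Disposition of one finalized call."""

    candidate: CandidateVariant
    disposition: str
    site_id: str | None = None


def triage_calls(
    candidates: Sequence[CandidateVariant], known_sites: KnownSiteDB
) -> list[TriageRecord]:
    """Split calls into known polymorphisms and a verification list.

    Matching is allele-exact on the normalized (contig, pos, ref, alt);
    novel calls are ordered by descending total LLR so the strongest
    candidates head the verification queue.
    """
    records = []
    for c in candidates:
        site_id = known_sites.id_of(c.contig, c.vcf_pos, c.vcf_ref, c.vcf_alt)
        records.append(
            TriageRecord(
                candidate=c,
                disposition=KNOWN_SNP if site_id is not None else NOVEL,
                site_id=site_id,
            )
        )
    known = [r for r in records if r.disposition == KNOWN_SNP]
    novel = sorted(
        (r for r in records if r.disposition == NOVEL),
        key=lambda r: -r.candidate.llr_total,
    )
    return known + novel


def write_triage_tsv(records: Sequence[TriageRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpos\tref\talt\tllr\tdisposition\tsite_id\n")
        for r in records:
            c = r.candidate
            fh.write(
                f"{c.contig}\t{c.vcf_pos}\t{c.vcf_ref}\t{c.vcf_alt}\t"
                f"{c.llr_total:.3f}\t{r.disposition}\t{r.site_id or '.'}\n"
            )


# ---------------------------------------------------------------------------
# Coding-effect annotation
# ---------------------------------------------------------------------------

EFFECTS = (
    "synonymous",
    "missense",
    "nonsense",
    "frameshift",
    "inframe_indel",
    "stoploss_extension",
    "noncoding",
    "complex",
)


@dataclass(frozen=True)
class EffectAnnotation:
    gene: str
    effect: str
    c_notation: str
    p_notation: str


def _gene_strand_alleles(gene: GeneModel, ref: str, alt: str) -> tuple[str, str]:
    if gene.strand == "+":
        return ref, alt
    return revcomp(ref), revcomp(alt)


def _downstream_cds_frame(
    panel: ReferencePanel, gene: GeneModel
) -> str:
    """Genomic sequence continuing past the CDS end in reading direction."""
    last = gene.cds_intervals[-1]
    contig = panel.contigs[gene.contig].sequence
    if gene.strand == "+":
        return contig[last[1]:]
    return revcomp(contig[: last[0]])


def _new_stop_offset(extended: str) -> int | None:
    """1-based codon index of the first stop in an in-frame DNA string."""
    for i in range(0, len(extended) - 2, 3):
        if _CODON.get(extended[i : i + 3], "X") == "*":
            return i // 3 + 1
    return None


def annotate_effect(
    candidate: CandidateVariant | tuple[str, int, str, str],
    gene: GeneModel,
    panel: ReferencePanel,
) -> EffectAnnotation:
    """Classify the coding consequence of a call on a toy gene model.

    Accepts a scored candidate or a plain (contig, pos, ref, alt) tuple
    (1-based, VCF anchor convention).  SNVs are classified by codon
    comparison; a substitution that destroys the stop codon is reported
    as a stop-loss with the distance to the next in-frame downstream
    stop.  Indels are frameshift when length % 3 != 0 (with the fs*n
    new-stop offset) and in-frame otherwise.  Variants outside the CDS
    are noncoding; variants straddling a CDS boundary are complex.
    """
    if isinstance(candidate, tuple):
        contig, pos, ref, alt = candidate
    else:
        contig, pos, ref, alt = (
            candidate.contig,
            candidate.vcf_pos,
            candidate.vcf_ref,
            candidate.vcf_alt,
        )
    if contig != gene.contig:
        return EffectAnnotation(gene.name, "noncoding", "", "")
    span0 = (pos - 1, pos - 1 + len(ref))
    in_cds = [
        any(s <= p < e for s, e in gene.cds_intervals)
        for p in range(*span0)
    ]
    if not any(in_cds):
        return EffectAnnotation(gene.name, "noncoding", "", "")
    if not all(in_cds):
        logger.warning(
            "variant %s:%d spans a CDS boundary of %s", contig, pos, gene.name
        )
        return EffectAnnotation(gene.name, "complex", "", "")

    cds = gene.cds_sequence(panel)
    gref, galt = _gene_strand_alleles(gene, ref, alt)

    if len(ref) == len(alt) == 1:  # SNV
        c_pos = genomic_to_cds(gene, pos)
        assert cds[c_pos - 1] == gref
        codon_i = (c_pos - 1) // 3
        offset = (c_pos - 1) % 3
        codon = cds[codon_i * 3 : codon_i * 3 + 3]
        new_codon = codon[:offset] + galt + codon[offset + 1 :]
        aa_ref, aa_alt = _CODON[codon], _CODON[new_codon]
        c_not = f"c.{c_pos}{gref}>{galt}"
        aa_pos = codon_i + 1
        if aa_ref == aa_alt:
            return EffectAnnotation(
                gene.name, "synonymous", c_not, f"p.{_AA3[aa_ref]}{aa_pos}=",
            )
        if aa_alt == "*":
            return EffectAnnotation(
                gene.name, "nonsense", c_not, f"p.{_AA3[aa_ref]}{aa_pos}X"
            )
        if aa_ref == "*":
            downstream = _downstream_cds_frame(panel, gene)
            mutated_tail = new_codon + downstream
            stop_at = _new_stop_offset(mutated_tail[3:])
            ext = f"*{stop_at}" if stop_at is not None else "*?"
            return EffectAnnotation(
                gene.name,
                "stoploss_extension",
                c_not,
                f"p.X{aa_pos}{_AA3[aa_alt]}extX{ext}",
            )
        return EffectAnnotation(
            gene.name, "missense", c_not, f"p.{_AA3[aa_ref]}{aa_pos}{_AA3[aa_alt]}"
        )

    # indel: VCF anchor base + inserted/deleted bases
    indel_len = abs(len(ref) - len(alt))
    is_del = len(ref) > len(alt)
    if is_del:
        # deleted genomic bases are pos+1 .. pos+len(ref)-1 (1-based)
        if gene.strand == "+":
            start_c = genomic_to_cds(gene, pos + 1)
        else:
            start_c = genomic_to_cds(gene, pos + len(ref) - 1)
        end_c = start_c + indel_len - 1
        c_not = f"c.{start_c}del" if indel_len == 1 else f"c.{start_c}_{end_c}del"
        mutant = cds[: start_c - 1] + cds[end_c:]
        first_new_idx = start_c - 1  # 0-based CDS index of first affected base
    else:
        # insertion between genomic pos and pos+1
        ins_seq = galt[1:] if gene.strand == "+" else galt[:-1]
        if gene.strand == "+":
            ins_after_c = genomic_to_cds(gene, pos)
        else:
            ins_after_c = genomic_to_cds(gene, pos) - 1
        preceding = cds[max(0, ins_after_c - indel_len) : ins_after_c]
        if preceding == ins_seq and ins_after_c >= indel_len:
            c_not = f"c.{ins_after_c - indel_len + 1}_{ins_after_c}dup{ins_seq}"
        else:
            c_not = f"c.{ins_after_c}_{ins_after_c + 1}ins{ins_seq}"
        mutant = cds[:ins_after_c] + ins_seq + cds[ins_after_c:]
        first_new_idx = ins_after_c

    aa_pos = first_new_idx // 3 + 1
    if indel_len % 3 != 0:
        extended = mutant + _downstream_cds_frame(panel, gene)
        frame_start = (aa_pos - 1) * 3
        tail_prot = translate(extended[frame_start:])
        stop_i = tail_prot.find("*")
        wt_aa = _AA3[_CODON[cds[(aa_pos - 1) * 3 : (aa_pos - 1) * 3 + 3]]]
        new_aa = _AA3.get(tail_prot[0], "X") if tail_prot else "X"
        fs = f"fs*{stop_i + 1}" if stop_i >= 0 else "fs*?"
        return EffectAnnotation(
            gene.name, "frameshift", c_not, f"p.{wt_aa}{aa_pos}{new_aa}{fs}"
        )
    kind = "del" if is_del else "dup" if "dup" in c_not else "ins"
    return EffectAnnotation(
        gene.name, "inframe_indel", c_not, f"p.{aa_pos}{kind}{indel_len // 3}aa"
    )
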