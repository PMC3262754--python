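"""Coverage completeness, triage partition and effect annotation."""

import numpy as np
import pytest

from poolcall.caller import CandidateVariant, PileupColumn, PileupEntry
from poolcall.panel import (
    Contig,
    GeneModel,
    KnownSiteDB,
    ReferencePanel,
    TargetRegion,
    cds_to_genomic,
    revcomp,
)
from poolcall.report import (
    KNOWN_SNP,
    NOVEL,
    annotate_effect,
    coverage_report,
    coverage_threshold,
    translate,
    triage_calls,
)

from conftest import make_panel, random_seq


class TestCoverageThreshold:
    @pytest.mark.parametrize("n,thr", [(8, 160), (7, 140), (1, 20)])
    def test_twenty_x_per_sample(self, n, thr):
        assert coverage_threshold(n) == thr

    def test_linear_in_pool_size(self):
        assert all(
            coverage_threshold(n) == n * coverage_threshold(1)
            for n in range(1, 12)
        )

    def test_invalid_pool_size(self):
        with pytest.raises(ValueError):
            coverage_threshold(0)


def columns_at_depth(contig, positions, depth, ref="A"):
    cols = []
    for p in positions:
        entries = [
            PileupEntry(ref, 25, "+" if i % 2 else "-", f"r{p}_{i}", 1)
            for i in range(depth)
        ]
        cols.append(PileupColumn(contig, p, ref, entries))
    return cols


class TestCoverageReport:
    def test_uniform_depth_200_complete(self):
        targets = [TargetRegion("c", 0, 50, "t1")]
        cols = columns_at_depth("c", range(50), 200)
        rep = coverage_report(cols, targets, 8)
        assert rep.completeness == 1.0
        assert rep.uncovered == []

    def test_depth_exactly_at_threshold_is_not_covered(self):
        """Strictly-greater rule: 160X with N=8 counts as below."""
        targets = [TargetRegion("c", 0, 20, "t1")]
        cols = columns_at_depth("c", range(20), 160)
        rep = coverage_report(cols, targets, 8)
        assert rep.completeness == 0.0

    def test_zero_read_target_listed_uncovered(self):
        targets = [TargetRegion("c", 0, 20, "t1"), TargetRegion("c", 50, 70, "t2")]
        cols = columns_at_depth("c", range(20), 200)
        rep = coverage_report(cols, targets, 8)
        assert rep.uncovered == ["t2"]
        assert 0 < rep.completeness < 1

    def test_monotone_in_depth(self):
        targets = [TargetRegion("c", 0, 30, "t1")]
        vals = [
            coverage_report(columns_at_depth("c", range(30), d), targets, 8
                            ).completeness
            for d in (100, 161, 300)
        ]
        assert vals == sorted(vals)

    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError):
            coverage_report([], [], 8)


def cand(contig, pos, ref, alt, llr=10.0):
    c = CandidateVariant(contig, pos - 1, ref, alt, llr_total=llr)
    c.vcf_pos, c.vcf_ref, c.vcf_alt = pos, ref, alt
    return c


class TestTriage:
    db = KnownSiteDB([("c", 100, "A", "G", "rs1"), ("c", 200, "C", "T", "rs2")])

    def test_exact_match_is_known(self):
        recs = triage_calls([cand("c", 100, "A", "G")], self.db)
        assert recs[0].disposition == KNOWN_SNP
        assert recs[0].site_id == "rs1"

    def test_different_alt_at_known_position_is_novel(self):
        recs = triage_calls([cand("c", 100, "A", "T")], self.db)
        assert recs[0].disposition == NOVEL

    def test_thirteen_calls_eight_known_five_novel(self):
        known = [cand("c", 100, "A", "G", llr=5 + i) for i in range(4)]
        known += [cand("c", 200, "C", "T", llr=9 + i) for i in range(4)]
        novel = [cand("c", 300 + 10 * i, "G", "A", llr=3 + i) for i in range(5)]
        recs = triage_calls(known + novel, self.db)
        assert len(recs) == 13
        assert sum(r.disposition == KNOWN_SNP for r in recs) == 8
        verification = [r for r in recs if r.disposition == NOVEL]
        assert len(verification) == 5
        llrs = [r.candidate.llr_total for r in verification]
        assert llrs == sorted(llrs, reverse=True)

    def test_partition_is_exhaustive_and_disjoint(self):
        calls = [cand("c", 100, "A", "G"), cand("c", 101, "A", "C")]
        recs = triage_calls(calls, self.db)
        assert len(recs) == len(calls)
        assert {id(r.candidate) for r in recs} == {id(c) for c in calls}


def toy_gene(cds, flank=30, strand="+", rng=None, downstream=None):
    rng = rng or np.random.default_rng(0)
    left = random_seq(flank, rng)
    right = downstream if downstream is not None else random_seq(flank, rng)
    body = cds if strand == "+" else revcomp(cds)
    seq = left + body + right
    panel = ReferencePanel(contigs={"g": Contig("g", seq)})
    if strand == "+":
        ivals = ((flank, flank + len(cds)),)
    else:
        ivals = ((flank, flank + len(cds)),)
    gene = GeneModel("G1", "g", strand, ivals)
    return panel, gene


class TestAnnotateEffect:
    def test_nonsense(self):
        panel, gene = toy_gene("ATGCAGTAA")
        # c.4 C>T: CAG -> TAG
        contig, gpos = cds_to_genomic(gene, 4)
        ann = annotate_effect((contig, gpos, "C", "T"), gene, panel)
        assert ann.effect == "nonsense"
        assert ann.c_notation == "c.4C>T"
        assert ann.p_notation == "p.Gln2X"

    def test_synonymous(self):
        panel, gene = toy_gene("ATGCAGTAA")
        contig, gpos = cds_to_genomic(gene, 6)  # CAG -> CAA
        ann = annotate_effect((contig, gpos, "G", "A"), gene, panel)
        assert ann.effect == "synonymous"

    def test_missense(self):
        panel, gene = toy_gene("ATGCAGTAA")
        contig, gpos = cds_to_genomic(gene, 4)  # CAG -> AAG (Gln -> Lys)
        ann = annotate_effect((contig, gpos, "C", "A"), gene, panel)
        assert ann.effect == "missense"
        assert ann.p_notation == "p.Gln2Lys"

    def test_stoploss_extension_15_codons(self):
        # stop TAA destroyed; next in-frame stop 15 codons downstream
        downstream = "GGC" * 14 + "TGA" + "ACGT"
        panel, gene = toy_gene("ATGCAGTAA", downstream=downstream)
        contig, gpos = cds_to_genomic(gene, 8)  # TAA -> TTA (Leu)
        ann = annotate_effect((contig, gpos, "A", "T"), gene, panel)
        assert ann.effect == "stoploss_extension"
        assert "ext" in ann.p_notation
        assert ann.p_notation == "p.X3LeuextX*15"

    def test_frameshift_deletion_reports_new_stop(self):
        # deleting c.4 shifts frame; engineered TAA soon after
        panel, gene = toy_gene("ATGCCAGGGTAA", downstream="TAAGGG" * 5)
        contig, gpos = cds_to_genomic(gene, 3)
        ref2 = panel.fetch("g", gpos - 1, gpos + 1)
        ann = annotate_effect((contig, gpos, ref2, ref2[0]), gene, panel)
        assert ann.effect == "frameshift"
        assert "fs*" in ann.p_notation

    def test_inframe_duplication(self):
        panel, gene = toy_gene("ATGGGCGGCTAA")
        # duplicate the GGC at c.7-9 (anchor c.9)
        contig, gpos = cds_to_genomic(gene, 9)
        anchor = panel.base("g", gpos - 1)
        ann = annotate_effect((contig, gpos, anchor, anchor + "GGC"), gene, panel)
        assert ann.effect == "inframe_indel"
        assert "dup" in ann.c_notation

    def test_noncoding_outside_cds(self):
        panel, gene = toy_gene("ATGCAGTAA")
        ann = annotate_effect(("g", 5, panel.base("g", 4), "A"), gene, panel)
        assert ann.effect == "noncoding"

    def test_minus_strand_nonsense(self):
        panel, gene = toy_gene("ATGCAGTAA", strand="-")
        contig, gpos = cds_to_genomic(gene, 4)
        # genomic alleles are the reverse complement of the CDS alleles
        ann = annotate_effect((contig, gpos, "G", "A"), gene, panel)
        assert ann.effect == "nonsense"
        assert ann.c_notation == "c.4C>T"


def brute_force_effect(cds, downstream, mutant_cds, indel_len):
    """Independent classifier: translate and diff full proteins."""
    def protein(dna):
        prot = translate(dna)
        stop = prot.find("*")
        return prot[: stop + 1] if stop >= 0 else prot

    wt = protein(cds + downstream)
    mut = protein(mutant_cds + downstream)
    if indel_len:
        return "frameshift" if indel_len % 3 else "inframe_indel"
    if mut == wt:
        return "synonymous"
    if len(mut) < len(wt) and mut[:-1] == wt[: len(mut) - 1]:
        return "nonsense"
    if len(mut) > len(wt) and wt[:-1] == mut[: len(wt) - 1]:
        return "stoploss_extension"
    return "missense"


def test_annotation_agrees_with_brute_force_translation():
    """Effect classes match an independent whole-protein diff on 1000
    random SNVs and indels over random toy genes (both strands)."""
    rng = np.random.default_rng(99)
    stops = {"TAA", "TAG", "TGA"}
    checked = 0
    while checked < 1000:
        n_codons = int(rng.integers(4, 15))
        codons = []
        while len(codons) < n_codons:
            c = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3))
            if c not in stops:
                codons.append(c)
        cds = "".join(codons) + ["TAA", "TAG", "TGA"][int(rng.integers(3))]
        strand = "+" if rng.random() < 0.5 else "-"
        panel, gene = toy_gene(cds, strand=strand, rng=rng)
        downstream_gene = (
            panel.contigs["g"].sequence[gene.cds_intervals[-1][1] :]
            if strand == "+"
            else revcomp(panel.contigs["g"].sequence[: gene.cds_intervals[0][0]])
        )
        kind = rng.random()
        if kind < 0.5:  # SNV
            c_pos = int(rng.integers(1, len(cds) + 1))
            contig, gpos = cds_to_genomic(gene, c_pos)
            gref = panel.base("g", gpos - 1)
            galt = "ACGT"[int(rng.integers(4))]
            if galt == gref:
                continue
            cref = cds[c_pos - 1]
            calt = galt if strand == "+" else revcomp(galt)
            mutant = cds[: c_pos - 1] + calt + cds[c_pos:]
            indel_len = 0
            var = (contig, gpos, gref, galt)
        elif kind < 0.75:  # deletion (keep inside CDS, after base 1)
            dlen = int(rng.integers(1, 5))
            if len(cds) - dlen < 2:
                continue
            c_start = int(rng.integers(2, len(cds) - dlen + 1))
            if strand == "-" and c_start + dlen > len(cds):
                continue
            mutant = cds[: c_start - 1] + cds[c_start - 1 + dlen :]
            if strand == "+":
                contig, gpos = cds_to_genomic(gene, c_start - 1)
            else:
                contig, gpos = cds_to_genomic(gene, c_start + dlen)
            ref_seq = panel.fetch("g", gpos - 1, gpos + dlen)
            var = (contig, gpos, ref_seq, ref_seq[0])
            indel_len = dlen
        else:  # insertion
            ilen = int(rng.integers(1, 5))
            ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=ilen))
            c_after = int(rng.integers(1, len(cds)))
            mutant = cds[:c_after] + ins + cds[c_after:]
            if strand == "+":
                contig, gpos = cds_to_genomic(gene, c_after)
                g_ins = ins
            else:
                contig, gpos = cds_to_genomic(gene, c_after + 1)
                g_ins = revcomp(ins)
            anchor = panel.base("g", gpos - 1)
            var = (contig, gpos, anchor, anchor + g_ins)
            indel_len = ilen
        expected = brute_force_effect(cds, downstream_gene, mutant, indel_len)
        ann = annotate_effect(var, gene, panel)
        assert ann.effect == expected, (var, strand, cds, ann)
        checked += 1
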