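"""End-to-end pooled-resequencing pipeline.

Runs simulate -> map -> recalibrate -> mask -> pileup -> call ->
coverage/triage from a single configuration and seed, writing every
intermediate artifact (FASTQ, truth VCF, SAM, recalibration table, calls
VCF, coverage report, verification list) plus a machine-readable manifest
that compares the calls against the planted truth.  Variants the pipeline
misses are classified by *why* they were missed:

``unmapped-indel``
    no gap evidence reached the pileup near the planted site (reads
    carrying the allele could not be placed — the fate of deletions
    longer than the mapper's gap limit);
``filtered-strand``
    a matching candidate exceeded the LLR threshold but failed the
    strand-based high-confidence rules;
``below-LLR``
    evidence was present but the likelihood ratio never cleared the
    threshold.

Randomness derives from one seed, forked into named substreams per stage,
so an identical seed reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import caller as _caller
from . import mapper as _mapper
from . import recal as _recal
from . import report as _report
from . import simulate as _sim
from .panel import ReferencePanel, load_panel

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "compare_truth", "example_run_config"]

REASON_UNMAPPED_INDEL = "unmapped-indel"
REASON_FILTERED_STRAND = "filtered-strand"
REASON_BELOW_LLR = "below-LLR"


@dataclass
class RunConfig:
    """Everything one pipeline run needs, seed included."""

    seed: int
    panel: ReferencePanel
    sim: _sim.SimConfig
    variant_specs: list[_sim.VariantSpec] = field(default_factory=list)
    profile: _sim.ErrorProfile | None = None
    mapper: _mapper.MapperConfig = field(default_factory=_mapper.MapperConfig)
    caller: _caller.CallerConfig | None = None
    min_obs: int = 100

    def __post_init__(self) -> None:
        if self.profile is None:
            self.profile = _sim.ErrorProfile.default(self.sim.read_length)
        if self.caller is None:
            self.caller = _caller.CallerConfig(n_samples=self.sim.n_samples)
        elif self.caller.n_samples != self.sim.n_samples:
            raise ValueError("caller and simulator disagree on pool size")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        """Load a flat key-value run configuration.

        Keys: seed, pool size and simulator fields under ``sim``, panel
        file paths under ``panel`` (fasta/bed/genes/known_sites), variant
        specs under ``variants`` as VCF-style dicts, mapper/caller
        overrides under their own sections.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        panel = load_panel(
            raw["panel"]["fasta"],
            raw["panel"].get("bed"),
            raw["panel"].get("known_sites"),
            raw["panel"].get("genes"),
        )
        sim = _sim.SimConfig(**{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in raw.get("sim", {}).items()
        })
        specs = [
            _sim.VariantSpec(
                contig=v["contig"], pos=v["pos"], ref=v["ref"], alt=v["alt"],
                allele_count=v.get("allele_count", 1),
                zygosity=v.get("zygosity", "het"),
                label=v.get("label", ""),
            )
            for v in raw.get("variants", [])
        ]
        return cls(
            seed=seed if seed is not None else raw.get("seed", 0),
            panel=panel,
            sim=sim,
            variant_specs=specs,
            mapper=_mapper.MapperConfig(**raw.get("mapper", {})),
            caller=_caller.CallerConfig(
                n_samples=sim.n_samples, **raw.get("caller", {})
            ),
            min_obs=raw.get("min_obs", 100),
        )


def example_run_config(pool: str, seed: int, depth: float = 800.0) -> RunConfig:
    """Ready-made run mirroring one of the two emulated pools."""
    panel = _sim.build_example_panel()
    return RunConfig(
        seed=seed,
        panel=panel,
        sim=_sim.example_sim_config(pool, depth=depth),
        variant_specs=_sim.example_variant_specs(panel, pool),
    )


def _norm_truth(
    panel: ReferencePanel, truth: Sequence[_sim.TruthVariant]
) -> list[tuple[tuple[str, int, str, str], _sim.TruthVariant]]:
    out = []
    for v in truth:
        key = (v.contig, *_caller.left_align_indel(panel, v.contig, v.pos, v.ref, v.alt))
        out.append((key, v))
    return out


def compare_truth(
    panel: ReferencePanel,
    truth: Sequence[_sim.TruthVariant],
    callset: _caller.VariantCallSet,
) -> list[dict]:
    """Allele-exact truth-vs-called comparison after left-alignment.

    Returns one record per planted variant with its detection tier or a
    miss reason, plus the number of false-positive high-confidence calls.
    """
    high = {c.allele_key(): c for c in callset.high_confidence}
    cands = {c.allele_key(): c for c in callset.candidates}
    recheck = {c.allele_key(): c for c in callset.indel_recheck}
    scored = {}
    for c in callset.scored:
        scored.setdefault(c.allele_key(), c)
    records = []
    for key, v in _norm_truth(panel, truth):
        rec = {
            "label": v.label or f"{key[0]}:{key[1]}{key[2]}>{key[3]}",
            "contig": key[0],
            "pos": key[1],
            "ref": key[2],
            "alt": key[3],
            "planted_k": v.k,
            "vtype": v.vtype,
        }
        if key in high:
            c = high[key]
            rec.update(status="detected", tier=_caller.TIER_HIGH,
                       llr=c.llr_total, k_hat=c.k_hat)
        elif key in recheck:
            c = recheck[key]
            rec.update(status="detected", tier=_caller.TIER_RECHECK,
                       llr=c.llr_total, k_hat=c.k_hat)
        elif key in cands:
            c = cands[key]
            rec.update(status="missed", tier=_caller.TIER_CANDIDATE,
                       llr=c.llr_total, reason=REASON_FILTERED_STRAND)
        else:
            if v.vtype in ("DEL", "INS") and not _indel_evidence_near(
                callset, key[0], key[1], v.vtype
            ):
                reason = REASON_UNMAPPED_INDEL
            else:
                reason = REASON_BELOW_LLR
            c = scored.get(key)
            rec.update(
                status="missed",
                tier=None,
                llr=c.llr_total if c else None,
                reason=reason,
            )
        records.append(rec)
    truth_keys = {key for key, _ in _norm_truth(panel, truth)}
    for key, c in high.items():
        if key not in truth_keys:
            records.append(
                {
                    "label": f"FP:{key[0]}:{key[1]}{key[2]}>{key[3]}",
                    "contig": key[0],
                    "pos": key[1],
                    "ref": key[2],
                    "alt": key[3],
                    "status": "false_positive",
                    "tier": _caller.TIER_HIGH,
                    "llr": c.llr_total,
                }
            )
    return records


def _indel_evidence_near(
    callset: _caller.VariantCallSet,
    contig: str,
    pos: int,
    vtype: str,
    window: int = 30,
) -> bool:
    """Any scored gap allele of the same kind near the planted site?"""
    prefix = "D" if vtype == "DEL" else "I"
    for c in callset.scored:
        if (
            c.alt_sym.startswith(prefix)
            and c.contig == contig
            and abs(c.vcf_pos - pos) <= window
        ):
            return True
    return False


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage and write the results manifest.

    Stage outputs are pure functions of (inputs, config, seed); rerunning
    with the same seed reproduces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = config.panel
    streams = np.random.SeedSequence(config.seed).spawn(2)
    rng_geno = np.random.default_rng(streams[0])
    rng_reads = np.random.default_rng(streams[1])

    logger.info("stage 1/6: simulate (seed %d)", config.seed)
    truth = _sim.plant_genotypes(panel, config.variant_specs, config.sim, rng_geno)
    pairs = _sim.generate_reads(panel, truth, config.profile, config.sim, rng_reads)
    _sim.write_fastq(pairs, outdir / "reads_1.fastq", outdir / "reads_2.fastq")
    _sim.write_truth(truth, panel, outdir / "truth.vcf")

    logger.info("stage 2/6: map %d read pairs", len(pairs))
    alignments = _mapper.map_paired_reads(pairs, panel, config.mapper)
    n_mapped = sum(a.mapped for a in alignments)

    logger.info("stage 3/6: recalibrate")
    table = _recal.tabulate_empirical(
        alignments, panel, panel.known_sites, min_obs=config.min_obs
    )
    table.write_tsv(outdir / "recal_table.tsv")
    alignments = _recal.recalibrate(alignments, table)
    _mapper.write_alignments(alignments, panel, outdir / "alignments.sam")

    logger.info("stage 4/6: pileup + call")
    columns = _caller.build_pileup(alignments, panel.targets, panel)
    callset = _caller.call_variants(columns, config.caller, panel)
    _caller.write_vcf(callset, panel, config.caller, outdir / "calls.vcf")
    _caller.write_candidates_tsv(callset, outdir / "candidates.tsv")

    logger.info("stage 5/6: coverage + triage")
    coverage = _report.coverage_report(columns, panel.targets, config.sim.n_samples)
    coverage.to_tsv(outdir / "coverage.tsv")
    coverage.to_json(outdir / "coverage.json")
    triage = _report.triage_calls(callset.high_confidence, panel.known_sites)
    _report.write_triage_tsv(triage, outdir / "verification_list.tsv")

    logger.info("stage 6/6: manifest")
    truth_eval = compare_truth(panel, truth, callset)
    manifest = {
        "seed": config.seed,
        "n_samples": config.sim.n_samples,
        "depth": config.sim.depth,
        "read_length": config.sim.read_length,
        "n_read_pairs": len(pairs),
        "n_reads_mapped": int(n_mapped),
        "n_recal_bins": len(table.counts),
        "n_pileup_columns": len(columns),
        "n_candidates": len(callset.candidates),
        "n_high_confidence": len(callset.high_confidence),
        "n_indel_recheck": len(callset.indel_recheck),
        "coverage_completeness": coverage.completeness,
        "coverage_threshold": coverage.threshold,
        "uncovered_targets": coverage.uncovered,
        "n_known_calls": sum(
            1 for r in triage if r.disposition == _report.KNOWN_SNP
        ),
        "n_novel_calls": sum(1 for r in triage if r.disposition == _report.NOVEL),
        "truth_eval": truth_eval,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
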