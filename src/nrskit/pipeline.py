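"""End-to-end orchestration: simulate -> extract -> anchor -> merge ->
genotype -> stats, with serialized plain-text intermediates, a stage
MANIFEST and deterministic outputs under a fixed seed."""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as nio
from . import popstats
from .anchoring import PlacedNrs, UnplacedNrs, anchor, filter_unplaced
from .extraction import (contamination_filter, depth_filter,
                         extract_unaligned, satellite_filter)
from .genotyping import GenotypeMatrix, genotype_sample, mendelian_error_rate
from .merging import (build_catalogue, cluster_placed, merge_unplaced,
                      select_representatives)
from .reference import ReferenceGenome
from .simulate import (SimConfig, TruthSet, build_reference,
                       emit_assembly, simulate_population)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "extract_anchor", "merge", "genotype", "stats")


@dataclass
class PipelineResult:
    outdir: Path
    reference: ReferenceGenome
    truth: TruthSet
    catalogue: object
    genotypes: GenotypeMatrix
    placed_calls: dict[str, list[PlacedNrs]]
    stats: dict


def _mark_done(outdir: Path, stage: str) -> None:
    with open(outdir / "MANIFEST", "a") as handle:
        handle.write(f"{stage}\tcompleted\n")
    logger.info("stage %s completed", stage)


def run_pipeline(config: SimConfig, outdir: str | Path) -> PipelineResult:
    """Run the full desk-scale pipeline on a simulated panel.

    Each stage writes its intermediate as plain text before the next one
    starts; identical config (and seed) reproduces identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "MANIFEST").write_text("")

    # --- simulate -------------------------------------------------------
    ref = build_reference(config)
    truth = simulate_population(ref, config)
    nio.write_reference(ref, outdir / "reference")
    nio.write_tsv(outdir / "panel.tsv", truth.panel_frame())
    with open(outdir / "config.json", "w") as handle:
        json.dump(dataclasses.asdict(config), handle, indent=1, default=str)
    _mark_done(outdir, "simulate")

    # --- extract + anchor per sample -----------------------------------
    placed_calls: dict[str, list[PlacedNrs]] = {}
    unplaced_calls: list[UnplacedNrs] = []
    span_by_sample: dict[str, dict] = {}
    n_segments = 0
    for info in truth.samples:
        assembly = emit_assembly(ref, truth, config, info.sample)
        segments, alignments = extract_unaligned(
            assembly.contigs, ref, sample=info.sample,
            return_alignments=True)
        spans: dict[str, list[tuple[int, int]]] = {}
        for alns in alignments.values():
            for aln in alns:
                spans.setdefault(aln.target_id, []).append(
                    (aln.target_start, aln.target_end))
        span_by_sample[info.sample] = spans
        segments = depth_filter(segments, assembly.mean_depth,
                                assembly.depth_track)
        segments = satellite_filter(segments)
        segments = contamination_filter(segments, reference=ref)
        surviving = [s for s in segments if s.passed]
        n_segments += len(surviving)
        calls = [anchor(seg, assembly.contigs, ref) for seg in surviving]
        placed_calls[info.sample] = [c for c in calls
                                     if isinstance(c, PlacedNrs)]
        unplaced_calls.extend(c for c in calls
                              if isinstance(c, UnplacedNrs))
        logger.info("sample %s: %d segments, %d placed",
                    info.sample, len(surviving),
                    len(placed_calls[info.sample]))
    rows = [{"sample": s, "chrom": c.chrom, "position": c.position,
             "length": len(c.sequence), "end_gap": c.end_gap}
            for s, calls in placed_calls.items() for c in calls]
    nio.write_tsv(outdir / "placed_calls.tsv", pd.DataFrame(rows))
    _mark_done(outdir, "extract_anchor")

    # --- merge ----------------------------------------------------------
    all_placed = [c for calls in placed_calls.values() for c in calls]
    clusters = select_representatives(cluster_placed(all_placed))
    retained_unplaced, _ = filter_unplaced(unplaced_calls, ref)
    unplaced_records = merge_unplaced(retained_unplaced)
    catalogue = build_catalogue(
        clusters, unplaced_records,
        provenance={"n_samples": len(truth.samples),
                    "n_raw_segments": n_segments, "seed": config.seed})
    nio.catalogue_to_vcf(catalogue, ref, outdir / "catalogue.vcf")
    nio.unplaced_to_fasta(catalogue, outdir / "unplaced.fa")
    _mark_done(outdir, "merge")

    # --- genotype -------------------------------------------------------
    columns: dict[str, dict[str, int]] = {}
    support: dict[tuple[str, str], tuple[int, int]] = {}
    for info in truth.samples:
        assembly = emit_assembly(ref, truth, config, info.sample)
        genotypes, ev = genotype_sample(
            assembly.contigs, catalogue, ref, sample=info.sample,
            sample_calls=placed_calls[info.sample],
            span_intervals=span_by_sample[info.sample])
        columns[info.sample] = genotypes
        for locus, counts in ev.items():
            support[(locus, info.sample)] = counts
    loci = [r.gnrs_id for r in catalogue.placed_records]
    matrix = GenotypeMatrix(
        dosage=pd.DataFrame(columns, index=loci, dtype="int8"),
        support=support)
    nio.catalogue_to_vcf(catalogue, ref, outdir / "genotypes.vcf",
                         genotypes=matrix)
    _mark_done(outdir, "genotype")

    # --- stats ----------------------------------------------------------
    panel = truth.panel_frame()
    af_records = popstats.compute_af(matrix, panel)
    af_by_id = {r.gnrs_id: r for r in af_records}
    updated = []
    for rec in catalogue.records:
        af_rec = af_by_id.get(rec.gnrs_id)
        if af_rec is not None and af_rec.af is not None:
            updated.append(dataclasses.replace(
                rec, af=af_rec.af, category=af_rec.category))
        else:
            updated.append(rec)
    catalogue.records = updated
    summary = popstats.catalogue_summary(catalogue)
    nio.write_tsv(outdir / "catalogue_summary.tsv", summary)
    af_frame = pd.DataFrame([{
        "locus": r.gnrs_id, "allele_count": r.allele_count,
        "allele_number": r.allele_number, "af": r.af,
        "category": r.category} for r in af_records])
    nio.write_tsv(outdir / "allele_frequencies.tsv", af_frame)
    stats = {"summary": summary, "af_records": af_records}
    if truth.trio_pedigree:
        rate, per_trio = mendelian_error_rate(matrix, truth.trio_pedigree)
        nio.write_tsv(outdir / "mendelian.tsv", per_trio)
        stats["mendelian_rate"] = rate
    _mark_done(outdir, "stats")

    return PipelineResult(outdir=outdir, reference=ref, truth=truth,
                          catalogue=catalogue, genotypes=matrix,
                          placed_calls=placed_calls, stats=stats)
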