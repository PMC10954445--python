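"""Presence/absence genotyping of catalogue records per sample, plus the
genotype-quality validations (Mendelian error, exact HWE test,
concordance against truth).

Graph genotyping is replaced by dual-allele breakpoint evidence
counting: per placed record, contig alignments spanning the insertion
point either carry a matching inserted segment (insertion allele) or
cross the point contiguously (reference allele).  A true graph genotyper
can be swapped in behind :func:`genotype_sample`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import seqcore
from .anchoring import PlacedNrs, anchor
from .extraction import extract_unaligned
from .merging import NrsCatalogue
from .reference import ReferenceGenome
from .seqcore.msa import _ALIGNER as _PAIR_ALIGNER

MISSING = -1                 # dosage codes: -1 ./., 0, 1, 2
DEFAULT_MIN_SUPPORT = 2
ALT_HOM_FRACTION = 0.8       # alt evidence fraction calling 1/1
MATCH_IDENTITY = 0.90
MATCH_COVERAGE = 0.80
POSITION_SLACK = 100         # call-to-record breakpoint tolerance (bp)

GT_STRINGS = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
GT_CODES = {v: k for k, v in GT_STRINGS.items()}


@dataclass
class GenotypeMatrix:
    """Loci x samples diploid genotypes with optional evidence counts."""

    dosage: pd.DataFrame           # int8; -1 encodes ./.
    support: dict[tuple[str, str], tuple[int, int]] = field(
        default_factory=dict)      # (locus, sample) -> (alt, ref) evidence

    @property
    def loci(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def samples(self) -> list[str]:
        return list(self.dosage.columns)

    def genotype(self, locus: str, sample: str) -> str:
        return GT_STRINGS[int(self.dosage.at[locus, sample])]

    @classmethod
    def from_strings(cls, table: Mapping[str, Mapping[str, str]]
                     ) -> "GenotypeMatrix":
        frame = pd.DataFrame(table).T
        return cls(dosage=frame.map(lambda g: GT_CODES[g]).astype("int8"))


def _sequences_equivalent(a: str, b: str) -> bool:
    if a == b:
        return True
    if min(len(a), len(b)) / max(len(a), len(b)) < MATCH_COVERAGE:
        return False
    aln = _PAIR_ALIGNER.align(a, b)[0]
    identity = aln.counts().identities / aln.length
    return identity >= MATCH_IDENTITY


def genotype_sample(contigs: Mapping[str, str],
                    catalogue: NrsCatalogue,
                    reference: ReferenceGenome,
                    min_support: int = DEFAULT_MIN_SUPPORT,
                    alt_hom_fraction: float = ALT_HOM_FRACTION,
                    sample: str = "sample",
                    sample_calls: Sequence[PlacedNrs] | None = None,
                    span_intervals: Mapping[str, list[tuple[int, int]]]
                    | None = None,
                    ) -> tuple[dict[str, int],
                               dict[str, tuple[int, int]]]:
    """Genotype one sample's contigs against the placed catalogue records.

    Returns (locus -> dosage code, locus -> (alt, ref) evidence).  Pass
    ``sample_calls`` / ``span_intervals`` to reuse already-computed
    anchored calls and per-chromosome contig alignment intervals.
    """
    for record in catalogue.placed_records:
        if record.chrom not in reference.sequences:
            raise ValueError(f"record chromosome {record.chrom!r} absent "
                             "from reference")
    need_alignments = span_intervals is None
    if sample_calls is None or need_alignments:
        segments, alignments = extract_unaligned(
            contigs, reference, sample=sample, return_alignments=True)
        if sample_calls is None:
            sample_calls = [
                call for call in (anchor(seg, contigs, reference)
                                  for seg in segments)
                if isinstance(call, PlacedNrs)
            ]
        if need_alignments:
            span_intervals = {}
            for alns in alignments.values():
                for aln in alns:
                    span_intervals.setdefault(aln.target_id, []).append(
                        (aln.target_start, aln.target_end))

    genotypes: dict[str, int] = {}
    support: dict[str, tuple[int, int]] = {}
    for record in catalogue.placed_records:
        pos = record.position
        alt = sum(
            1 for call in sample_calls
            if call.chrom == record.chrom
            and abs(call.position - pos) <= POSITION_SLACK
            and _sequences_equivalent(call.sequence, record.sequence))
        # reference-allele evidence: alignments crossing well beyond the
        # point on both sides; an insertion-carrying contig's alignment
        # splits AT the breakpoint, so it never counts here
        ref_n = sum(
            1 for s, e in span_intervals.get(record.chrom, [])
            if s + 20 < pos < e - 20)
        support[record.gnrs_id] = (alt, ref_n)
        total = alt + ref_n
        if total < min_support:
            genotypes[record.gnrs_id] = MISSING
        elif alt == 0:
            genotypes[record.gnrs_id] = 0
        elif alt / total >= alt_hom_fraction:
            genotypes[record.gnrs_id] = 2
        else:
            genotypes[record.gnrs_id] = 1
    return genotypes, support


def genotype_panel(assemblies: Iterable, catalogue: NrsCatalogue,
                   reference: ReferenceGenome,
                   min_support: int = DEFAULT_MIN_SUPPORT,
                   calls_by_sample: Mapping[str, Sequence[PlacedNrs]]
                   | None = None,
                   span_by_sample: Mapping[str, Mapping] | None = None,
                   ) -> GenotypeMatrix:
    """Genotype every sample assembly; assemblies yield objects with
    ``sample`` and ``contigs`` attributes."""
    columns: dict[str, dict[str, int]] = {}
    support: dict[tuple[str, str], tuple[int, int]] = {}
    for assembly in assemblies:
        calls = (calls_by_sample or {}).get(assembly.sample)
        genotypes, ev = genotype_sample(
            assembly.contigs, catalogue, reference,
            min_support=min_support, sample=assembly.sample,
            sample_calls=calls,
            span_intervals=(span_by_sample or {}).get(assembly.sample))
        columns[assembly.sample] = genotypes
        for locus, counts in ev.items():
            support[(locus, assembly.sample)] = counts
    loci = [r.gnrs_id for r in catalogue.placed_records]
    frame = pd.DataFrame(columns, index=loci, dtype="int8")
    return GenotypeMatrix(dosage=frame, support=support)


# ---------------------------------------------------------------- trios

_TRANSMISSIBLE = {0: {0}, 1: {0, 1}, 2: {1}}


def _trio_consistent(child: int, father: int, mother: int) -> bool:
    return any(child == fa + mo
               for fa in _TRANSMISSIBLE[father]
               for mo in _TRANSMISSIBLE[mother])


def mendelian_error_rate(genotypes: GenotypeMatrix,
                         trios: Mapping[str, tuple[str, str]],
                         ) -> tuple[float, pd.DataFrame]:
    """Fraction of evaluated (locus, trio) pairs with a child genotype
    impossible under biallelic transmission; missing genotypes anywhere
    in the trio exclude the pair."""
    rows = []
    total_errors = total_evaluated = 0
    for child, (father, mother) in trios.items():
        errors = evaluated = 0
        for locus in genotypes.loci:
            g = genotypes.dosage.loc[locus]
            c, f, m = int(g[child]), int(g[father]), int(g[mother])
            if MISSING in (c, f, m):
                continue
            evaluated += 1
            if not _trio_consistent(c, f, m):
                errors += 1
        rows.append({"child": child, "evaluated": evaluated,
                     "errors": errors,
                     "rate": errors / evaluated if evaluated else math.nan})
        total_errors += errors
        total_evaluated += evaluated
    rate = total_errors / total_evaluated if total_evaluated else math.nan
    return rate, pd.DataFrame(rows)


# ------------------------------------------------------------------ HWE

def hwe_exact_test(hom_ref: int, het: int, hom_alt: int) -> float:
    """Exact conditional test of the heterozygote count given allele
    counts (two-sided: sum of configurations no more probable than the
    observed one).  Log-space enumeration over all het counts of the
    correct parity."""
    for v in (hom_ref, het, hom_alt):
        if v < 0:
            raise ValueError("negative genotype count")
    n = hom_ref + het + hom_alt
    if n == 0:
        return 1.0
    rare = min(2 * hom_ref + het, 2 * hom_alt + het)
    if rare == 0:
        return 1.0

    def log_weight(h: int) -> float:
        # homozygote class counts implied by h hets at fixed allele counts
        n_rare_hom = (rare - h) // 2
        n_common_hom = n - h - n_rare_hom
        return (math.lgamma(n + 1)
                - math.lgamma(n_rare_hom + 1) - math.lgamma(h + 1)
                - math.lgamma(n_common_hom + 1) + h * math.log(2.0))

    hets = [h for h in range(rare % 2, rare + 1, 2)]
    logs = np.array([log_weight(h) for h in hets])
    logs -= logs.max()
    probs = np.exp(logs)
    probs /= probs.sum()
    observed = probs[hets.index(het)]
    return float(probs[probs <= observed * (1 + 1e-12)].sum())


def hwe_pass(hom_ref: int, het: int, hom_alt: int,
             threshold: float = 1e-4) -> bool:
    return hwe_exact_test(hom_ref, het, hom_alt) >= threshold


def genotype_counts(genotypes: GenotypeMatrix, locus: str,
                    samples: Sequence[str] | None = None
                    ) -> tuple[int, int, int]:
    row = genotypes.dosage.loc[locus]
    if samples is not None:
        row = row[list(samples)]
    values = row.to_numpy()
    return (int((values == 0).sum()), int((values == 1).sum()),
            int((values == 2).sum()))


# ---------------------------------------------------------- concordance

def genotype_concordance(genotypes: GenotypeMatrix,
                         truth_dosage: pd.DataFrame,
                         ) -> tuple[float, float, pd.DataFrame]:
    """Allele-presence sensitivity and precision against a truth dosage
    matrix (same loci x samples; entries 0/1/2)."""
    common_loci = [l for l in genotypes.loci if l in truth_dosage.index]
    called = genotypes.dosage.loc[common_loci]
    truth = truth_dosage.loc[common_loci, called.columns]
    called_np = called.to_numpy()
    truth_np = truth.to_numpy()
    non_missing = called_np != MISSING
    true_carrier = truth_np > 0
    called_carrier = (called_np > 0) & non_missing
    tp = int((true_carrier & called_carrier).sum())
    eligible = int((true_carrier & non_missing).sum())
    positives = int(called_carrier.sum())
    sensitivity = tp / eligible if eligible else math.nan
    precision = tp / positives if positives else math.nan
    per_class = pd.DataFrame({
        "n_loci": [len(common_loci)],
        "true_carriers": [eligible],
        "called_carriers": [positives],
        "true_positives": [tp],
    })
    return sensitivity, precision, per_class
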