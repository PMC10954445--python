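"""Stage 3: merge per-sample calls into the nonredundant population
catalogue and compare catalogues against external sequence sets."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import seqcore
from .anchoring import PlacedNrs, UnplacedNrs
from .seqcore import GenomeIndex, choose_representative
from .seqcore.msa import _ALIGNER as _REP_ALIGNER

CLUSTER_DISTANCE = 250          # max pairwise insertion-point distance
MATCH_MIN_LENGTH = 200
MATCH_MIN_IDENTITY = 0.90
CONTAINMENT_COVERAGE = 0.80
MULTIALLELIC_IDENTITY = 0.90


@dataclass
class NrsCluster:
    members: list[PlacedNrs]
    median_position: int = 0
    representative: str = ""
    representative_sample: str = ""
    tie_break: str = ""

    @property
    def chrom(self) -> str:
        return self.members[0].chrom

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(sorted({m.sample for m in self.members}))

    @property
    def multi_allelic(self) -> bool:
        unique = sorted({m.sequence for m in self.members})
        if len(unique) <= 1:
            return False
        for i, a in enumerate(unique):
            for b in unique[i + 1:]:
                aln = _REP_ALIGNER.align(a, b)[0]
                if aln.counts().identities / aln.length < \
                        MULTIALLELIC_IDENTITY:
                    return True
        return False


@dataclass(frozen=True)
class CatalogueRecord:
    gnrs_id: str
    placed: bool
    chrom: str | None
    position: int | None
    sequence: str
    samples: tuple[str, ...]
    multi_allelic: bool = False
    af: float | None = None
    category: str | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class NrsCatalogue:
    records: list[CatalogueRecord]
    provenance: dict = field(default_factory=dict)

    @property
    def placed_records(self) -> list[CatalogueRecord]:
        return [r for r in self.records if r.placed]

    @property
    def unplaced_records(self) -> list[CatalogueRecord]:
        return [r for r in self.records if not r.placed]

    def __len__(self) -> int:
        return len(self.records)


def _greedy_split(positions: Sequence[int]) -> list[list[int]]:
    """Split sorted member indices so every block spans <= 250 bp.

    Left-to-right greedy on sorted positions gives the minimum number of
    blocks for this 1-D span constraint.
    """
    order = sorted(range(len(positions)), key=lambda i: positions[i])
    blocks: list[list[int]] = []
    block_start = None
    for i in order:
        if block_start is None or \
                positions[i] - block_start > CLUSTER_DISTANCE:
            blocks.append([i])
            block_start = positions[i]
        else:
            blocks[-1].append(i)
    return blocks


def cluster_placed(calls: Sequence[PlacedNrs]) -> list[NrsCluster]:
    """Single-linkage clustering at 250 bp, then greedy splitting so all
    pairwise insertion-point distances stay within 250 bp; at most one
    member per sample per cluster (closest to the cluster median)."""
    clusters: list[NrsCluster] = []
    by_chrom: dict[str, list[PlacedNrs]] = {}
    for call in calls:
        by_chrom.setdefault(call.chrom, []).append(call)
    for chrom in sorted(by_chrom):
        chrom_calls = sorted(by_chrom[chrom],
                             key=lambda c: (c.position, c.sample))
        linked: list[list[PlacedNrs]] = []
        for call in chrom_calls:
            if linked and call.position - linked[-1][-1].position \
                    <= CLUSTER_DISTANCE:
                linked[-1].append(call)
            else:
                linked.append([call])
        for group in linked:
            positions = [c.position for c in group]
            for block in _greedy_split(positions):
                members = [group[i] for i in block]
                median = int(np.floor(np.median([m.position
                                                 for m in members])))
                deduped: dict[str, PlacedNrs] = {}
                for m in sorted(members,
                                key=lambda c: (abs(c.position - median),
                                               c.position)):
                    deduped.setdefault(m.sample, m)
                clusters.append(NrsCluster(
                    members=sorted(deduped.values(),
                                   key=lambda c: (c.sample, c.position)),
                    median_position=median))
    return clusters


def select_representatives(clusters: Sequence[NrsCluster]) -> list[NrsCluster]:
    """Fill each cluster's representative via sum-of-pairs scoring."""
    for cluster in clusters:
        choice = choose_representative([m.sequence for m in cluster.members])
        cluster.representative = choice.sequence
        cluster.representative_sample = cluster.members[choice.index].sample
        cluster.tie_break = choice.tie_break
    return list(clusters)


def match_components(sequences: Sequence[str]) -> list[list[int]]:
    """Connected components of the all-vs-all match graph
    (alignment length >= 200 bp and identity >= 0.90)."""
    n = len(sequences)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            if _sequences_match(sequences[i], sequences[j]):
                parent[find(j)] = find(i)
    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(find(i), []).append(i)
    return [sorted(v) for v in sorted(components.values())]


def _alignments_between(a: str, b: str):
    if min(len(a), len(b)) < MATCH_MIN_LENGTH // 4:
        return []
    return seqcore.align_pair(a, b, mode="local")


def _sequences_match(a: str, b: str) -> bool:
    for aln in _alignments_between(a, b):
        if (aln.aligned_length >= MATCH_MIN_LENGTH
                and aln.identity >= MATCH_MIN_IDENTITY):
            return True
    return False


def _covers(shorter: str, longer: str) -> bool:
    """True if some qualifying alignment covers >= 80% of the shorter."""
    for aln in _alignments_between(shorter, longer):
        if (aln.identity >= MATCH_MIN_IDENTITY
                and aln.query_coverage >= CONTAINMENT_COVERAGE):
            return True
    return False


def merge_unplaced(calls: Sequence[UnplacedNrs]
                   ) -> list[tuple[str, tuple[str, ...]]]:
    """Deduplicate unplaced calls; returns (sequence, supporting samples).

    Within each match-graph component the shorter sequence of any
    >=80%-coverage pair is absorbed into the longer one; components whose
    calls span a single individual are dropped.
    """
    components = match_components([c.sequence for c in calls])
    records: list[tuple[str, tuple[str, ...]]] = []
    for comp in components:
        samples = {calls[i].sample for i in comp}
        if len(samples) <= 1:
            continue
        # absorb contained sequences, shortest first
        alive = sorted(comp, key=lambda i: (len(calls[i].sequence), i))
        absorbed_into: dict[int, int] = {}
        support: dict[int, set[str]] = {i: {calls[i].sample} for i in comp}
        for pos, i in enumerate(alive):
            for j in reversed(alive[pos + 1:]):   # longest candidates first
                if j in absorbed_into or i in absorbed_into:
                    continue
                if _covers(calls[i].sequence, calls[j].sequence):
                    absorbed_into[i] = j
                    support[j] |= support[i]
                    break
        for i in alive:
            if i in absorbed_into:
                continue
            records.append((calls[i].sequence,
                            tuple(sorted(support[i]))))
    return records


def build_catalogue(placed_clusters: Sequence[NrsCluster],
                    unplaced_records: Sequence[tuple[str, tuple[str, ...]]],
                    provenance: dict | None = None) -> NrsCatalogue:
    """Assemble the catalogue: placed records in coordinate order first,
    then unplaced records; GNRS ids assigned in that stable order."""
    records: list[CatalogueRecord] = []
    ordered = sorted(placed_clusters,
                     key=lambda c: (c.chrom, c.median_position,
                                    c.representative))
    counter = 0
    for cluster in ordered:
        counter += 1
        records.append(CatalogueRecord(
            gnrs_id=f"GNRS_{counter:05d}", placed=True,
            chrom=cluster.chrom, position=cluster.median_position,
            sequence=cluster.representative or cluster.members[0].sequence,
            samples=cluster.samples,
            multi_allelic=cluster.multi_allelic))
    for sequence, samples in unplaced_records:
        counter += 1
        records.append(CatalogueRecord(
            gnrs_id=f"GNRS_{counter:05d}", placed=False, chrom=None,
            position=None, sequence=sequence, samples=tuple(samples)))
    return NrsCatalogue(records=records, provenance=provenance or {})


def compare_catalogues(catalogue: NrsCatalogue,
                       external: Mapping[str, str],
                       ) -> dict:
    """Overlap report against an external sequence set.

    A record is recovered iff some external sequence aligns to it with
    length >= min(200 bp, record length), identity >= 0.90 and coverage
    >= 0.80 of the record.
    """
    index = GenomeIndex(dict(external)) if external else None
    recovered: list[str] = []
    recovered_bp = 0
    for record in catalogue.records:
        if index is None:
            break
        hit = False
        min_len = min(MATCH_MIN_LENGTH, len(record.sequence))
        for aln in seqcore.align_pair(record.sequence, index, mode="local"):
            if (aln.aligned_length >= min_len
                    and aln.identity >= MATCH_MIN_IDENTITY
                    and aln.query_coverage >= CONTAINMENT_COVERAGE):
                hit = True
                break
        if hit:
            recovered.append(record.gnrs_id)
            recovered_bp += record.length
    return {
        "recovered_ids": recovered,
        "n_recovered": len(recovered),
        "n_total": len(catalogue.records),
        "recovered_bp": recovered_bp,
        "total_bp": sum(r.length for r in catalogue.records),
    }
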