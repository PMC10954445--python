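"""Seed-and-extend pairwise alignment.

Seeding uses exact k-mer anchors (numpy), chaining is a banded sparse DP,
and the short inter-anchor gaps plus chain ends are polished with
Bio.Align.PairwiseAligner under an affine gap scheme.  The engine targets
desk-scale genomes (megabases); it is not a chromosome-scale aligner.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from Bio import Align as _bioalign

from ._encode import VALID_CHARS, encode, kmer_codes, revcomp

DEFAULT_K = 15
DEFAULT_MAX_OCC = 64
DEFAULT_BAND = 64
MAX_JOIN_GAP = 40          # larger query/target gaps split the chain
MAX_END_EXTENSION = 2000   # longest unseeded tail we try to polish
MIN_EXT_IDENTITY = 0.75    # end extensions below this identity are clipped

MATCH_SCORE = 2.0
MISMATCH_SCORE = -1.0
GAP_OPEN = -2.0
GAP_EXTEND = -0.5


@dataclass(frozen=True)
class Alignment:
    """One pairwise alignment between a query and a target interval.

    Coordinates are 0-based half-open in the forward orientation of each
    sequence.  ``identity`` counts matches over all alignment columns
    (gap columns included); ``query_coverage`` is aligned query bases over
    query length.
    """

    query_id: str
    query_start: int
    query_end: int
    target_id: str
    target_start: int
    target_end: int
    strand: str
    aligned_length: int
    matches: int
    identity: float
    query_coverage: float
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity out of range: {self.identity}")
        if not 0.0 <= self.query_coverage <= 1.0 + 1e-9:
            raise ValueError(f"coverage out of range: {self.query_coverage}")


def _gap_aligner(mode: str) -> _bioalign.PairwiseAligner:
    aligner = _bioalign.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN + GAP_EXTEND
    aligner.extend_gap_score = GAP_EXTEND
    if mode == "ends_free_target":
        # free end-overhangs of the second (window) sequence
        try:
            aligner.end_insertion_score = 0.0
        except AttributeError:  # older Biopython naming
            aligner.target_end_gap_score = 0.0
    return aligner


_GLOBAL_ALIGNER = _gap_aligner("global")
_EXTEND_ALIGNER = _gap_aligner("ends_free_target")


def _polish(a: str, b: str, aligner: _bioalign.PairwiseAligner):
    """Align two short strings; return (score, matches, columns, b_used).

    ``b_used`` is the number of target bases consumed inside the aligned
    region (relevant for the ends-free aligner).
    """
    if not a and not b:
        return 0.0, 0, 0, 0
    if not a or not b:
        n = max(len(a), len(b))
        return GAP_OPEN + GAP_EXTEND * (n - 1), 0, n, len(b)
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    t_start = int(aln.aligned[1][0][0]) if len(aln.aligned[1]) else 0
    t_end = int(aln.aligned[1][-1][1]) if len(aln.aligned[1]) else 0
    columns = int(aln.length)
    if aligner is _EXTEND_ALIGNER:
        # drop the free end-gap columns from the column count
        columns -= t_start + (len(b) - t_end)
        b_used = t_end - t_start
    else:
        b_used = len(b)
    return float(aln.score), int(counts.identities), columns, b_used


class GenomeIndex:
    """Sorted k-mer index over one or more target sequences."""

    def __init__(self, sequences: Mapping[str, str] | str, k: int = DEFAULT_K,
                 max_occ: int = DEFAULT_MAX_OCC):
        if isinstance(sequences, str):
            sequences = {"target": sequences}
        self.k = k
        self.max_occ = max_occ
        self.names: list[str] = list(sequences)
        self.lengths = {name: len(sequences[name]) for name in self.names}
        spacer = "N" * k
        parts, offsets, pos = [], [], 0
        for name in self.names:
            offsets.append(pos)
            parts.append(sequences[name])
            pos += len(sequences[name]) + k
            parts.append(spacer)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.concat = "".join(parts)
        codes = encode(self.concat)
        kmers, positions = kmer_codes(codes, k)
        order = np.argsort(kmers, kind="stable")
        self._kmers = kmers[order]
        self._positions = positions[order]

    def sequence(self, name: str) -> str:
        i = self.names.index(name)
        start = int(self.offsets[i])
        return self.concat[start:start + self.lengths[name]]

    def chrom_of(self, global_pos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.offsets, global_pos, side="right") - 1

    def lookup(self, query_kmers: np.ndarray, query_pos: np.ndarray):
        """Return (query_pos, global_target_pos) match arrays."""
        left = np.searchsorted(self._kmers, query_kmers, side="left")
        right = np.searchsorted(self._kmers, query_kmers, side="right")
        counts = right - left
        keep = (counts > 0) & (counts <= self.max_occ)
        left, counts, qpos = left[keep], counts[keep], query_pos[keep]
        total = int(counts.sum())
        if total == 0:
            return (np.empty(0, dtype=np.int64),) * 2
        out_q = np.repeat(qpos, counts)
        starts = np.repeat(left, counts)
        within = np.arange(total) - np.repeat(
            np.cumsum(counts) - counts, counts)
        out_t = self._positions[starts + within]
        return out_q, out_t


def _merge_runs(qpos: np.ndarray, tpos: np.ndarray, k: int):
    """Collapse consecutive k-mer hits on one diagonal into exact anchors.

    Returns arrays (qs, ts, length) of maximal exact-match runs.
    """
    if qpos.size == 0:
        return (np.empty(0, dtype=np.int64),) * 3
    diag = tpos - qpos
    order = np.lexsort((qpos, diag))
    qpos, tpos, diag = qpos[order], tpos[order], diag[order]
    new_run = np.ones(qpos.size, dtype=bool)
    new_run[1:] = (np.diff(diag) != 0) | (np.diff(qpos) != 1)
    starts = np.flatnonzero(new_run)
    ends = np.append(starts[1:], qpos.size) - 1
    qs = qpos[starts]
    ts = tpos[starts]
    length = qpos[ends] - qs + k
    return qs, ts, length


def _chain(qs, ts, ln, chrom, band: int, max_join: int, lookback: int = 64):
    """Sparse chaining DP; returns list of chains as index lists."""
    n = qs.size
    order = np.lexsort((ts, qs))
    qs, ts, ln, chrom = qs[order], ts[order], ln[order], chrom[order]
    score = ln.astype(np.float64).copy()
    parent = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        lo = max(0, i - lookback)
        for j in range(i - 1, lo - 1, -1):
            if chrom[j] != chrom[i]:
                continue
            qgap = qs[i] - (qs[j] + ln[j])
            tgap = ts[i] - (ts[j] + ln[j])
            if qgap > max_join or tgap > max_join:
                continue
            overlap = max(-qgap, -tgap, 0)
            if overlap >= min(ln[i], ln[j]):
                continue
            if abs(qgap - tgap) > band:
                continue
            cost = 0.01 * max(qgap, tgap, 0) + 0.5 * abs(qgap - tgap) + overlap
            if score[j] + ln[i] - cost > score[i]:
                score[i] = score[j] + ln[i] - cost
                parent[i] = j
    used = np.zeros(n, dtype=bool)
    chains = []
    for i in np.argsort(-score, kind="stable"):
        if used[i]:
            continue
        chain = []
        j = int(i)
        while j >= 0 and not used[j]:
            chain.append(j)
            used[j] = True
            j = int(parent[j])
        chains.append([
            (int(qs[m]), int(ts[m]), int(ln[m]), int(chrom[m]))
            for m in reversed(chain)
        ])
    return chains


def _chain_to_alignment(chain, query: str, index: GenomeIndex, strand: str,
                        query_id: str, mode: str) -> Alignment | None:
    chrom_idx = chain[0][3]
    chrom = index.names[chrom_idx]
    chrom_off = int(index.offsets[chrom_idx])
    chrom_len = index.lengths[chrom]
    qlen = len(query)

    # trim anchor overlaps, accumulate matches / columns / score
    anchors = []
    prev_qe = prev_te = -1
    for q0, t0, ln, _ in chain:
        if anchors:
            trim = max(prev_qe - q0, prev_te - t0, 0)
            q0 += trim
            t0 += trim
            ln -= trim
            if ln <= 0:
                continue
        anchors.append((q0, t0, ln))
        prev_qe, prev_te = q0 + ln, t0 + ln
    if not anchors:
        return None

    matches = columns = 0
    score = 0.0
    for idx, (q0, t0, ln) in enumerate(anchors):
        matches += ln
        columns += ln
        score += MATCH_SCORE * ln
        if idx:
            pq, pt, pl = anchors[idx - 1]
            gap_q = query[pq + pl:q0]
            gap_t = index.concat[pt + pl:t0]
            s, m, c, _ = _polish(gap_q, gap_t, _GLOBAL_ALIGNER)
            score += s
            matches += m
            columns += c

    q_start, t_start = anchors[0][0], anchors[0][1]
    q_end = anchors[-1][0] + anchors[-1][2]
    t_end = anchors[-1][1] + anchors[-1][2]

    if mode == "glocal":
        # left tail: query[0:q_start] vs preceding target window
        head = query[:q_start]
        if 0 < len(head) <= MAX_END_EXTENSION:
            wlen = len(head) + DEFAULT_BAND
            w_start = max(chrom_off, t_start - wlen)
            window = index.concat[w_start:t_start]
            s, m, c, b_used = _polish(head, window, _EXTEND_ALIGNER)
            if s > 0 and c > 0 and m / c >= MIN_EXT_IDENTITY:
                score += s
                matches += m
                columns += c
                q_start = 0
                t_start -= b_used
        tail = query[q_end:]
        if 0 < len(tail) <= MAX_END_EXTENSION:
            wlen = len(tail) + DEFAULT_BAND
            w_end = min(chrom_off + chrom_len, t_end + wlen)
            window = index.concat[t_end:w_end]
            s, m, c, b_used = _polish(tail, window, _EXTEND_ALIGNER)
            if s > 0 and c > 0 and m / c >= MIN_EXT_IDENTITY:
                score += s
                matches += m
                columns += c
                q_end = qlen
                t_end += b_used

    if columns == 0:
        return None
    rel_ts, rel_te = t_start - chrom_off, t_end - chrom_off
    if strand == "-":
        q_start, q_end = qlen - q_end, qlen - q_start
    return Alignment(
        query_id=query_id,
        query_start=int(q_start),
        query_end=int(q_end),
        target_id=chrom,
        target_start=int(rel_ts),
        target_end=int(rel_te),
        strand=strand,
        aligned_length=int(columns),
        matches=int(matches),
        identity=matches / columns,
        query_coverage=(q_end - q_start) / qlen,
        score=float(score),
    )


def align_pair(query: str,
               target: str | Mapping[str, str] | GenomeIndex,
               mode: str = "glocal",
               query_id: str = "query",
               min_chain_bases: int = 30,
               k: int = DEFAULT_K,
               band: int = DEFAULT_BAND,
               max_join: int = MAX_JOIN_GAP) -> list[Alignment]:
    """Align ``query`` against a target sequence or indexed genome.

    Returns alignments ordered by (score desc, target id, target start).
    ``glocal`` additionally polishes the unseeded query ends back toward
    full query coverage; ``local`` reports the chained region only.
    """
    if mode not in ("local", "glocal"):
        raise ValueError(f"unknown mode: {mode}")
    if not query:
        raise ValueError("empty query sequence")
    bad = set(query) - VALID_CHARS
    if bad:
        raise ValueError(f"invalid characters in query: {sorted(bad)!r}")
    index = target if isinstance(target, GenomeIndex) else GenomeIndex(target, k=k)
    k = index.k

    results: list[Alignment] = []
    for strand, q in (("+", query), ("-", revcomp(query))):
        if strand == "-" and results:
            # skip the reverse pass when forward chains already explain
            # nearly the whole query
            covered = np.zeros(len(query), dtype=bool)
            for a in results:
                covered[a.query_start:a.query_end] = True
            if covered.mean() > 0.95:
                break
        codes = encode(q)
        kmers, qpos = kmer_codes(codes, k)
        if kmers.size == 0:
            continue
        mq, mt = index.lookup(kmers, qpos)
        qs, ts, ln = _merge_runs(mq, mt, k)
        if qs.size == 0:
            continue
        if qs.size > 5000:  # keep the longest anchors in repeat blowups
            keep = np.argsort(-ln, kind="stable")[:5000]
            qs, ts, ln = qs[keep], ts[keep], ln[keep]
        chrom = index.chrom_of(ts)
        for chain in _chain(qs, ts, ln, chrom, band, max_join):
            if sum(c[2] for c in chain) < min_chain_bases:
                continue
            aln = _chain_to_alignment(chain, q, index, strand, query_id, mode)
            if aln is not None:
                results.append(aln)
    results.sort(key=lambda a: (-a.score, a.target_id, a.target_start))
    return results
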