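"""Representative selection for clusters of similar sequences.

Scoring follows the merging stage's scheme: match +2, mismatch -1, gap
-0.5 (the open penalty doubles as the extension penalty since no separate
extension is specified).  A sequence's score is its sum of optimal
pairwise global alignment scores against every other cluster member
(sum-of-pairs), which makes the selection exactly equal to brute-force
pairwise scoring.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from Bio import Align as _bioalign

REP_MATCH = 2.0
REP_MISMATCH = -1.0
REP_GAP = -0.5


def _rep_aligner() -> _bioalign.PairwiseAligner:
    aligner = _bioalign.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = REP_MATCH
    aligner.mismatch_score = REP_MISMATCH
    aligner.open_gap_score = REP_GAP
    aligner.extend_gap_score = REP_GAP
    return aligner


_ALIGNER = _rep_aligner()


def pairwise_score(a: str, b: str) -> float:
    """Optimal global alignment score under the +2/-1/-0.5 scheme."""
    if not a or not b:
        return REP_GAP * max(len(a), len(b))
    return float(_ALIGNER.score(a, b))


@dataclass(frozen=True)
class RepresentativeChoice:
    sequence: str
    index: int                  # position in the input list
    scores: tuple[float, ...]   # per input sequence, input order
    tie_break: str              # "score" | "length" | "lexicographic" | "order"


def choose_representative(sequences: list[str]) -> RepresentativeChoice:
    """Pick the member with the highest sum of pairwise alignment scores.

    Ties broken by longer length, then lexicographically smaller sequence,
    then input order; the applied rule is recorded.
    """
    if not sequences:
        raise ValueError("choose_representative requires >=1 sequence")
    if len(sequences) == 1:
        return RepresentativeChoice(sequences[0], 0, (0.0,), "score")

    # identical members are common; score unique sequences once
    counts = Counter(sequences)
    unique = list(counts)
    pair: dict[tuple[str, str], float] = {}
    for i, u in enumerate(unique):
        for v in unique[i:]:
            pair[(u, v)] = pair[(v, u)] = pairwise_score(u, v)
    unique_score = {
        u: sum(counts[v] * pair[(u, v)] for v in unique) - pair[(u, u)]
        for u in unique
    }
    scores = tuple(unique_score[s] for s in sequences)

    best = max(scores)
    tied = [i for i, s in enumerate(scores) if s == best]
    rule = "score"
    if len(tied) > 1:
        max_len = max(len(sequences[i]) for i in tied)
        tied = [i for i in tied if len(sequences[i]) == max_len]
        rule = "length"
    if len(tied) > 1:
        min_seq = min(sequences[i] for i in tied)
        tied = [i for i in tied if sequences[i] == min_seq]
        rule = "lexicographic"
    if len(tied) > 1:
        rule = "order"
    idx = tied[0]
    return RepresentativeChoice(sequences[idx], idx, scores, rule)
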