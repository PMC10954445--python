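"""Tandem-repeat, satellite and low-complexity annotation."""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._encode import encode

STR_MAX_MOTIF = 6          # 1-6 bp motifs; >=7 bp are VNTRs
MIN_ARRAY_LENGTH = 5
MIN_COPIES = 3.0


@dataclass(frozen=True)
class RepeatAnnotation:
    start: int
    end: int
    cls: str               # STR | VNTR | satellite | low_complexity
    motif: str
    copy_number: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _least_rotation(s: str) -> str:
    doubled = s + s
    return min(doubled[i:i + len(s)] for i in range(len(s)))


def _smallest_period(s: str) -> int:
    # KMP failure function
    n = len(s)
    fail = [0] * n
    k = 0
    for i in range(1, n):
        while k and s[i] != s[k]:
            k = fail[k - 1]
        if s[i] == s[k]:
            k += 1
        fail[i] = k
    p = n - fail[-1]
    return p if n % p == 0 else n


def scan_tandem_repeats(seq: str, max_period: int = 100,
                        min_copies: float = MIN_COPIES,
                        min_length: int = MIN_ARRAY_LENGTH
                        ) -> list[RepeatAnnotation]:
    """Detect maximal exact tandem arrays by per-period self-match runs.

    For each candidate period p, positions where ``seq[i] == seq[i+p]``
    form runs; a run of length L spans a tandem array of length L+p with
    L/p + 1 copies.  Consecutive units inside an exact run are identical,
    which trivially satisfies the >=80% unit-identity requirement.  The
    motif is reported as the lexicographically least rotation of the
    smallest primitive period.
    """
    n = len(seq)
    if n < 2:
        return []
    codes = encode(seq)
    pmax = min(max_period, n - 1)
    periods = np.arange(1, pmax + 1)
    # one (period x position) self-match matrix; padding with sentinel 5
    # keeps runs from crossing period rows after flattening
    padded = np.concatenate((codes, np.full(pmax, 5, dtype=codes.dtype)))
    idx = np.arange(n - 1)
    shifted = padded[periods[:, None] + idx[None, :]]
    eq = (shifted == codes[:n - 1][None, :]) & (codes[:n - 1][None, :] != 4)
    eq = np.concatenate(
        (eq, np.zeros((pmax, 1), dtype=bool)), axis=1).ravel()
    flat = np.concatenate(([False], eq, [False]))
    edges = np.flatnonzero(np.diff(flat.astype(np.int8)))
    width = n  # row width after the column padding
    pairs = edges.reshape(-1, 2)
    p_arr = pairs[:, 0] // width + 1
    start_arr = pairs[:, 0] % width
    len_arr = pairs[:, 1] - pairs[:, 0] + p_arr
    keep = (len_arr >= min_length) & \
           (len_arr >= np.ceil(min_copies * p_arr))
    candidates = sorted(
        (int(p), int(s), int(s + l))
        for p, s, l in zip(p_arr[keep], start_arr[keep], len_arr[keep]))

    covered = np.zeros(n, dtype=bool)
    out: list[RepeatAnnotation] = []
    for p, start, end in candidates:
        span = covered[start:end]
        if span.sum() >= 0.5 * (end - start):
            continue
        covered[start:end] = True
        motif = seq[start:start + p]
        prim = _smallest_period(motif)
        motif = _least_rotation(motif[:prim])
        cls = "STR" if len(motif) <= STR_MAX_MOTIF else "VNTR"
        out.append(RepeatAnnotation(
            start=start, end=end, cls=cls, motif=motif,
            copy_number=(end - start) / len(motif)))
    out.sort(key=lambda a: (a.start, a.end))
    return out


def scan_low_complexity(seq: str, window: int = 50,
                        entropy_max: float = 1.2) -> list[RepeatAnnotation]:
    """Flag windows whose mononucleotide Shannon entropy is below a bound."""
    n = len(seq)
    if n < window:
        return []
    codes = encode(seq)
    onehot = np.zeros((5, n), dtype=np.float64)
    onehot[codes, np.arange(n)] = 1.0
    kernel = np.ones(window)
    counts = np.stack([np.convolve(onehot[b], kernel, "valid")
                       for b in range(4)])
    freqs = counts / window
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.nansum(np.where(freqs > 0, freqs * np.log2(freqs), 0.0),
                         axis=0)
    flagged = ent < entropy_max
    out = []
    padded = np.concatenate(([False], flagged, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for s, e in edges.reshape(-1, 2):
        out.append(RepeatAnnotation(start=int(s), end=int(e) + window - 1,
                                    cls="low_complexity", motif="",
                                    copy_number=1.0))
    return out


@lru_cache(maxsize=64)
def _monomer_kmers(monomer: str, k: int) -> np.ndarray:
    """Sorted unique k-mers of the doubled monomer, both strands."""
    from ._encode import kmer_codes, revcomp

    lib: set[int] = set()
    for strand_seq in (monomer + monomer, revcomp(monomer + monomer)):
        lk, _ = kmer_codes(encode(strand_seq), k)
        lib.update(lk.tolist())
    arr = np.fromiter(lib, dtype=np.int64) if lib \
        else np.empty(0, dtype=np.int64)
    arr.sort()
    return arr


def match_satellites(seq: str, satellite_library: Mapping[str, str],
                     k: int = 13) -> list[RepeatAnnotation]:
    """Annotate satellite arrays by monomer k-mer matching with chaining.

    Library k-mers are taken from the doubled monomer (both strands) so
    junction-spanning words of a tandem array are matched; hit intervals
    are merged when separated by less than one monomer length.
    """
    out: list[RepeatAnnotation] = []
    n = len(seq)
    if n < k:
        return out
    codes = encode(seq)
    from ._encode import kmer_codes
    kmers, positions = kmer_codes(codes, k)
    if kmers.size == 0:
        return out
    order = np.argsort(kmers, kind="stable")
    skmers, spos = kmers[order], positions[order]
    for name, monomer in satellite_library.items():
        lib_arr = _monomer_kmers(monomer, k)
        if lib_arr.size == 0:
            continue
        idx = np.searchsorted(lib_arr, skmers)
        idx[idx == lib_arr.size] = 0
        hit = lib_arr[idx] == skmers
        hit_pos = np.sort(spos[hit])
        if hit_pos.size == 0:
            continue
        merge_gap = len(monomer)
        starts = [int(hit_pos[0])]
        ends = [int(hit_pos[0]) + k]
        for p in hit_pos[1:]:
            if p <= ends[-1] + merge_gap:
                ends[-1] = max(ends[-1], int(p) + k)
            else:
                starts.append(int(p))
                ends.append(int(p) + k)
        for s, e in zip(starts, ends):
            if e - s < k * 2:
                continue
            out.append(RepeatAnnotation(
                start=s, end=min(e, n), cls="satellite", motif=name,
                copy_number=(e - s) / len(monomer)))
    out.sort(key=lambda a: (a.start, a.end))
    return out


def interval_union_length(intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    prev_end = -1
    for s, e in sorted(intervals):
        s = max(s, prev_end)
        if e > s:
            total += e - s
            prev_end = e
        else:
            prev_end = max(prev_end, e)
    return total


def mask_and_fraction(seq: str, annotations: Sequence[RepeatAnnotation],
                      classes: Iterable[str]) -> tuple[str, float]:
    """Mask selected-class intervals with N; fraction is their union length
    over the sequence length."""
    classes = set(classes)
    picked = [(max(a.start, 0), min(a.end, len(seq)))
              for a in annotations if a.cls in classes]
    if not picked or not seq:
        return seq, 0.0
    masked = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    for s, e in picked:
        masked[s:e] = ord("N")
    fraction = interval_union_length(picked) / len(seq)
    return masked.tobytes().decode("ascii"), fraction
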