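"""Stage 1: raw insertion-segment extraction and the depth / satellite /
contamination filters.

Each filter sets only its own flag from the segment's intrinsic data, so
the three filter operations commute.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from . import seqcore
from .reference import ReferenceGenome
from .seqcore import GenomeIndex
from .seqcore.taxon import CompositionProfile

logger = logging.getLogger(__name__)

DEFAULT_MIN_CONTIG = 1000
DEFAULT_MIN_SEGMENT = 50
DEPTH_HIGH_FACTOR = 3.0
DEPTH_LOW_FACTOR = 1.0 / 3.0
SATELLITE_MASK_MAX = 0.80
_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class RawSegment:
    """A contig interval with no reference alignment coverage."""
    sample: str
    contig: str
    start: int
    end: int
    sequence: str
    depth: float | None = None
    filter_flags: frozenset[str] = frozenset()

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def segment_id(self) -> str:
        return f"{self.sample}:{self.contig}:{self.start}-{self.end}"

    def with_flag(self, flag: str, on: bool) -> "RawSegment":
        flags = set(self.filter_flags)
        if on:
            flags.add(flag)
        else:
            flags.discard(flag)
        return replace(self, filter_flags=frozenset(flags))

    @property
    def passed(self) -> bool:
        return not self.filter_flags


def _uncovered_runs(length: int, covered: Sequence[tuple[int, int]],
                    min_segment: int) -> list[tuple[int, int]]:
    mask = np.zeros(length, dtype=bool)
    for s, e in covered:
        mask[max(s, 0):min(e, length)] = True
    out = []
    padded = np.concatenate(([True], mask, [True]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for s, e in edges.reshape(-1, 2):
        if e - s >= min_segment:
            out.append((int(s), int(e)))
    return out


def extract_unaligned(contigs: Mapping[str, str],
                      reference: ReferenceGenome | GenomeIndex,
                      sample: str = "sample",
                      min_contig: int = DEFAULT_MIN_CONTIG,
                      min_segment: int = DEFAULT_MIN_SEGMENT,
                      return_alignments: bool = False,
                      ):
    """Emit contig intervals not covered by any reference alignment.

    Contigs shorter than ``min_contig`` are skipped outright; both fully
    unaligned contigs and internal unaligned fragments of length >=
    ``min_segment`` are reported.  With ``return_alignments`` the per
    contig reference alignments are returned alongside the segments.
    """
    index = (reference.index if isinstance(reference, ReferenceGenome)
             else reference)
    segments: list[RawSegment] = []
    alignments_by_contig: dict[str, list] = {}
    for name in sorted(contigs):
        seq = contigs[name]
        bad = set(seq.upper()) - _VALID
        if bad:
            raise ValueError(
                f"contig {name!r} contains non-ACGTN characters: "
                f"{sorted(bad)!r}")
        if len(seq) < min_contig:
            continue
        alignments = seqcore.align_pair(seq, index, mode="glocal",
                                        query_id=name)
        if return_alignments:
            alignments_by_contig[name] = alignments
        covered = [(a.query_start, a.query_end) for a in alignments]
        for s, e in _uncovered_runs(len(seq), covered, min_segment):
            segments.append(RawSegment(
                sample=sample, contig=name, start=s, end=e,
                sequence=seq[s:e]))
    if return_alignments:
        return segments, alignments_by_contig
    return segments


def segment_depths(segments: Sequence[RawSegment],
                   depth_track: Sequence[tuple[str, int, int, float]],
                   ) -> list[float | None]:
    """Mean per-base depth over each segment's contig interval."""
    by_contig: dict[str, list[tuple[int, int, float]]] = {}
    for contig, s, e, d in depth_track:
        by_contig.setdefault(contig, []).append((s, e, d))
    out: list[float | None] = []
    for seg in segments:
        rows = by_contig.get(seg.contig)
        if not rows:
            out.append(None)
            continue
        weight = value = 0.0
        for s, e, d in rows:
            lo, hi = max(s, seg.start), min(e, seg.end)
            if hi > lo:
                weight += hi - lo
                value += (hi - lo) * d
        out.append(value / weight if weight else None)
    return out


def depth_filter(segments: Sequence[RawSegment], mean_depth: float,
                 depth_track: Sequence[tuple[str, int, int, float]] | None,
                 ) -> list[RawSegment]:
    """Flag segments whose depth is > 3x or < 1/3 of the sample mean."""
    if mean_depth <= 0:
        raise ValueError("mean depth must be positive")
    if depth_track is None:
        warnings.warn("no depth track supplied; depth filter passes "
                      "all segments through", stacklevel=2)
        return list(segments)
    out = []
    for seg, depth in zip(segments, segment_depths(segments, depth_track)):
        if depth is None:
            out.append(replace(seg, depth=None))
            continue
        flagged = (depth > DEPTH_HIGH_FACTOR * mean_depth
                   or depth < DEPTH_LOW_FACTOR * mean_depth)
        out.append(replace(seg, depth=depth).with_flag("depth", flagged))
    return out


def satellite_filter(segments: Sequence[RawSegment],
                     satellite_library: Mapping[str, str] | None = None,
                     ) -> list[RawSegment]:
    """Flag segments whose satellite-masked fraction is >= 0.80."""
    if satellite_library is None:
        satellite_library = seqcore.load_bundled_satellites()
    out = []
    for seg in segments:
        annotations = seqcore.match_satellites(seg.sequence,
                                               satellite_library)
        _, fraction = seqcore.mask_and_fraction(seg.sequence, annotations,
                                                {"satellite"})
        out.append(seg.with_flag("satellite",
                                 fraction >= SATELLITE_MASK_MAX))
    return out


def contamination_filter(segments: Sequence[RawSegment],
                         host_profile: CompositionProfile | None = None,
                         foreign_profiles: Sequence[CompositionProfile]
                         | None = None,
                         reference: ReferenceGenome | GenomeIndex
                         | None = None,
                         satellite_library: Mapping[str, str] | None = None,
                         ) -> list[RawSegment]:
    """Two-tier contaminant flagging.

    The primary composition classifier sees the repeat-masked segment; a
    primary non-chordate call is re-queried against the host reference
    (>=90% identity alignment rescues the segment).  Only segments that
    both tiers call non-chordate are flagged; unclassified stays kept.
    """
    if host_profile is None or foreign_profiles is None:
        bundled_host, bundled_foreign = seqcore.load_bundled_profiles()
        host_profile = host_profile or bundled_host
        foreign_profiles = foreign_profiles or bundled_foreign
    if satellite_library is None:
        satellite_library = seqcore.load_bundled_satellites()
    index = None
    if reference is not None:
        index = (reference.index if isinstance(reference, ReferenceGenome)
                 else reference)
    from .seqcore.taxon import PROFILE_WINDOW

    out = []
    for seg in segments:
        if seg.length < PROFILE_WINDOW:
            # unclassifiable either way; keep without classification work
            out.append(seg.with_flag("contaminant", False))
            continue
        annotations = (seqcore.scan_tandem_repeats(seg.sequence)
                       + seqcore.scan_low_complexity(seg.sequence)
                       + seqcore.match_satellites(seg.sequence,
                                                  satellite_library))
        masked, _ = seqcore.mask_and_fraction(
            seg.sequence, annotations,
            {"STR", "VNTR", "satellite", "low_complexity"})
        primary = seqcore.classify_taxon(masked, host_profile,
                                         foreign_profiles, source="primary")
        flagged = False
        if primary.value == "non_chordate":
            rescued = False
            if index is not None:
                for aln in seqcore.align_pair(seg.sequence, index,
                                              mode="local"):
                    if aln.identity >= 0.90:
                        rescued = True
                        break
            if not rescued:
                secondary = seqcore.classify_taxon(
                    seg.sequence, host_profile, foreign_profiles,
                    source="secondary")
                flagged = secondary.value == "non_chordate"
        out.append(seg.with_flag("contaminant", flagged))
    return out
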