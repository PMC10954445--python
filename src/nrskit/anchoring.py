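"""Stage 2: anchor surviving segments to the reference, filter the
unplaced ones, and provide the insertion-density analyses."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _scipy_stats

from . import seqcore
from .extraction import RawSegment
from .reference import ReferenceGenome
from .seqcore import Alignment, GenomeIndex

DEFAULT_FLANK = 1000
MIN_FLANK_ALIGNED = 500     # flank alignment must exceed this many columns
MAX_END_GAP = 20            # reference inner endpoints must be closer
GENOME_HIT_IDENTITY = 0.90
GENOME_HIT_COVERAGE = 0.80
REPEAT_MASK_MAX = 0.80


@dataclass(frozen=True)
class PlacedNrs:
    sample: str
    sequence: str
    chrom: str
    position: int           # 0-based between-base insertion point
    upstream: Alignment
    downstream: Alignment
    end_gap: int

    def __post_init__(self) -> None:
        if self.end_gap >= MAX_END_GAP:
            raise ValueError("placed call violates the end-gap bound")


@dataclass(frozen=True)
class UnplacedNrs:
    sample: str
    sequence: str
    reason: str             # flank_missing | flank_short | gap_too_large
    filter_flags: frozenset[str] = frozenset()

    def with_flag(self, flag: str) -> "UnplacedNrs":
        return replace(self,
                       filter_flags=frozenset(self.filter_flags | {flag}))


def _best_flank(flank_seq: str, index: GenomeIndex) -> Alignment | None:
    if not flank_seq:
        return None
    alignments = seqcore.align_pair(flank_seq, index, mode="glocal")
    if not alignments:
        return None
    # highest score; ties -> smallest reference coordinate
    return min(alignments, key=lambda a: (-a.score, a.target_id,
                                          a.target_start))


def anchor(segment: RawSegment, contigs: Mapping[str, str],
           reference: ReferenceGenome | GenomeIndex,
           flank: int = DEFAULT_FLANK) -> PlacedNrs | UnplacedNrs:
    """Place a segment via its two contig flanks.

    Placed iff both best flank alignments exceed 500 aligned columns,
    land on one chromosome and strand, and their reference inner
    endpoints are < 20 bp apart; the insertion point is the floor
    midpoint of the endpoints.
    """
    index = (reference.index if isinstance(reference, ReferenceGenome)
             else reference)
    contig_seq = contigs[segment.contig]
    up_seq = contig_seq[max(segment.start - flank, 0):segment.start]
    down_seq = contig_seq[segment.end:segment.end + flank]
    if not up_seq or not down_seq:
        return UnplacedNrs(segment.sample, segment.sequence, "flank_missing")
    up = _best_flank(up_seq, index)
    down = _best_flank(down_seq, index)
    if up is None or down is None:
        return UnplacedNrs(segment.sample, segment.sequence, "flank_missing")
    if (up.aligned_length <= MIN_FLANK_ALIGNED
            or down.aligned_length <= MIN_FLANK_ALIGNED):
        return UnplacedNrs(segment.sample, segment.sequence, "flank_short")
    if up.target_id != down.target_id or up.strand != down.strand:
        return UnplacedNrs(segment.sample, segment.sequence, "gap_too_large")
    if up.strand == "+":
        inner_up, inner_down = up.target_end, down.target_start
    else:
        inner_up, inner_down = up.target_start, down.target_end
    gap = abs(inner_down - inner_up)
    if gap >= MAX_END_GAP:
        return UnplacedNrs(segment.sample, segment.sequence, "gap_too_large")
    position = (inner_up + inner_down) // 2
    return PlacedNrs(sample=segment.sample, sequence=segment.sequence,
                     chrom=up.target_id, position=int(position),
                     upstream=up, downstream=down, end_gap=int(gap))


def filter_unplaced(unplaced: Sequence[UnplacedNrs],
                    reference: ReferenceGenome | GenomeIndex,
                    satellite_library: Mapping[str, str] | None = None,
                    ) -> tuple[list[UnplacedNrs], list[UnplacedNrs]]:
    """Apply the unplaced-sequence filters; returns (retained, audit).

    The audit list holds every input call with its final flags.  Drops:
    whole-sequence reference hit (identity >= 0.90 and coverage >= 0.80),
    tandem-repeat masked fraction > 0.80, combined satellite + simple
    repeat + low-complexity masked fraction > 0.80, and sequences whose
    cross-sample match component spans a single individual.
    """
    from .merging import match_components  # cross-sample match criteria

    if satellite_library is None:
        satellite_library = seqcore.load_bundled_satellites()
    index = (reference.index if isinstance(reference, ReferenceGenome)
             else reference)
    audited: list[UnplacedNrs] = []
    for call in unplaced:
        flags = call
        for aln in seqcore.align_pair(call.sequence, index, mode="glocal"):
            if (aln.identity >= GENOME_HIT_IDENTITY
                    and aln.query_coverage >= GENOME_HIT_COVERAGE):
                flags = flags.with_flag("genome_hit")
                break
        tandem = seqcore.scan_tandem_repeats(call.sequence)
        _, trf_fraction = seqcore.mask_and_fraction(
            call.sequence, tandem, {"STR", "VNTR"})
        if trf_fraction > REPEAT_MASK_MAX:
            flags = flags.with_flag("trf80")
        combined = (tandem
                    + seqcore.scan_low_complexity(call.sequence)
                    + seqcore.match_satellites(call.sequence,
                                               satellite_library))
        _, combined_fraction = seqcore.mask_and_fraction(
            call.sequence, combined,
            {"STR", "VNTR", "satellite", "low_complexity"})
        if combined_fraction > REPEAT_MASK_MAX:
            flags = flags.with_flag("repeat80")
        audited.append(flags)

    survivor_idx = [i for i, c in enumerate(audited) if not c.filter_flags]
    components = match_components([audited[i].sequence
                                   for i in survivor_idx])
    keep: set[int] = set()
    for comp in components:
        samples = {audited[survivor_idx[j]].sample for j in comp}
        for j in comp:
            gi = survivor_idx[j]
            if len(samples) <= 1:
                audited[gi] = audited[gi].with_flag("singleton")
            else:
                keep.add(gi)
    final = [audited[i] for i in sorted(keep)]
    return final, audited


def hotspot_scan(placed: Sequence[PlacedNrs],
                 reference: ReferenceGenome,
                 bandwidth: float = 200_000.0,
                 trials: int = 1000,
                 seed: int = 0,
                 grid_step: float | None = None,
                 ) -> list[tuple[str, int, int, float]]:
    """Permutation test of insertion-point density.

    Gaussian-kernel density of insertion points per chromosome is
    compared against ``trials`` same-size uniform draws over the
    non-excluded genome; maximal regions above the pointwise 95th null
    percentile are reported with the add-one empirical p-value of their
    peak density against the null per-trial peaks.
    """
    if trials < 100:
        warnings.warn(f"only {trials} trials; p-values are coarse",
                      stacklevel=2)
    if not placed:
        return []
    rng = np.random.default_rng(seed)
    if grid_step is None:
        grid_step = max(bandwidth / 20.0, 1.0)
    hotspots: list[tuple[str, int, int, float]] = []
    for chrom in sorted(reference.sequences):
        points = np.array(sorted(p.position for p in placed
                                 if p.chrom == chrom), dtype=float)
        if points.size < 2:
            continue
        L = len(reference.sequences[chrom])
        allowed = _allowed_positions(reference, chrom, L)
        grid = np.arange(0.0, L + grid_step, grid_step)

        def density(pts: np.ndarray) -> np.ndarray:
            d = (grid[:, None] - pts[None, :]) / bandwidth
            return np.exp(-0.5 * d * d).sum(axis=1)

        observed = density(points)
        null = np.empty((trials, grid.size))
        for t in range(trials):
            draw = rng.choice(allowed, size=points.size, replace=True)
            null[t] = density(draw.astype(float))
        threshold = np.percentile(null, 95.0, axis=0)
        null_peaks = null.max(axis=1)
        above = observed > threshold
        padded = np.concatenate(([False], above, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for s, e in edges.reshape(-1, 2):
            peak = observed[s:e].max()
            p = (1 + int((null_peaks >= peak).sum())) / (trials + 1)
            hotspots.append((chrom, int(grid[s]),
                             int(min(grid[min(e, grid.size - 1)], L)), p))
    return hotspots


def _allowed_positions(reference: ReferenceGenome, chrom: str,
                       L: int) -> np.ndarray:
    mask = np.ones(L, dtype=bool)
    for s, e in reference.excluded_intervals(chrom):
        mask[max(s, 0):min(e, L)] = False
    return np.flatnonzero(mask)


def arm_end_enrichment(placed: Sequence[PlacedNrs],
                       reference: ReferenceGenome,
                       window: int = 5_000_000,
                       ) -> tuple[float, float, list[list[float]], dict]:
    """Fisher test of insertion counts in distal arm-end windows against
    the genome-length-scaled expectation.

    Returns (odds ratio, p, 2x2 table, metadata).  An infinite odds
    ratio (all insertions inside) is reported with an ``or_upper_bounded``
    flag rather than a number.
    """
    if not placed:
        raise ValueError("no placed calls")
    windows: dict[str, list[tuple[int, int]]] = {}
    inside_bp = total_bp = 0
    for chrom, seq in reference.sequences.items():
        L = len(seq)
        w = min(window, L // 2)
        windows[chrom] = [(0, w), (L - w, L)]
        inside_bp += 2 * w
        total_bp += L
    inside = sum(1 for p in placed
                 if any(s <= p.position < e for s, e in windows[p.chrom]))
    outside = len(placed) - inside
    frac = inside_bp / total_bp
    expected_inside = round(len(placed) * frac)
    expected_outside = len(placed) - expected_inside
    table = [[inside, outside], [expected_inside, expected_outside]]
    odds_ratio, p = _scipy_stats.fisher_exact(table)
    meta = {
        "window_bp": window,
        "inside_bp": inside_bp,
        "total_bp": total_bp,
        "contingency": "observed inside/outside vs length-scaled "
                       "expected inside/outside",
        "or_upper_bounded": outside == 0,
    }
    return float(odds_ratio), float(p), table, meta
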