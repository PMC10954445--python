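"""Population-level descriptive statistics of the catalogue: allele
frequencies and categories, population sharing, growth curves, N50,
genic annotation and Fisher enrichment."""
from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .genotyping import MISSING, GenotypeMatrix
from .merging import NrsCatalogue
from .reference import Gene

CATEGORIES = ("singleton", "polymorphic", "major", "shared")


def percent(numerator: int, total: int) -> float:
    """Percentage to one decimal, round-half-even (reporting style)."""
    if total <= 0:
        raise ValueError("total must be positive")
    value = Decimal(numerator) / Decimal(total) * 100
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_EVEN))


def average_length(total_bp: int, count: int) -> int:
    """Mean length rounded to the nearest integer (half away from zero)."""
    if count <= 0:
        raise ValueError("count must be positive")
    value = (Decimal(total_bp) / Decimal(count)).quantize(
        Decimal("1"), rounding="ROUND_HALF_UP")
    return int(value)


@dataclass(frozen=True)
class AfRecord:
    gnrs_id: str
    allele_count: int
    allele_number: int
    af: float | None
    category: str | None
    per_population_af: Mapping[str, float | None]
    all_missing: bool = False


def classify_af(allele_count: int, af: float) -> str:
    """singleton (count=1) / polymorphic (count>=2, AF<0.5) /
    major (0.5<=AF<1) / shared (AF=1)."""
    if allele_count == 1:
        return "singleton"
    if af == 1.0:
        return "shared"
    if af >= 0.5:
        return "major"
    return "polymorphic"


def compute_af(genotypes: GenotypeMatrix, panel: pd.DataFrame
               ) -> list[AfRecord]:
    """Allele frequencies over non-offspring samples; missing genotypes
    drop out of the allele number."""
    offspring = set(panel.loc[panel["trio_role"] == "child", "sample"])
    included = [s for s in genotypes.samples if s not in offspring]
    pop_of = dict(zip(panel["sample"], panel["population"]))
    populations = sorted({pop_of[s] for s in included if s in pop_of})
    records = []
    dosage = genotypes.dosage[included]
    for locus in genotypes.loci:
        row = dosage.loc[locus].to_numpy()
        ok = row != MISSING
        count = int(row[ok].sum())
        number = 2 * int(ok.sum())
        per_pop: dict[str, float | None] = {}
        for pop in populations:
            members = [i for i, s in enumerate(included)
                       if pop_of.get(s) == pop]
            sub = row[members]
            sub_ok = sub != MISSING
            n = 2 * int(sub_ok.sum())
            per_pop[pop] = (int(sub[sub_ok].sum()) / n) if n else None
        if number == 0:
            records.append(AfRecord(locus, 0, 0, None, None, per_pop,
                                    all_missing=True))
            continue
        af = count / number
        category = classify_af(count, af) if count > 0 else None
        records.append(AfRecord(locus, count, number, af, category,
                                per_pop))
    return records


def presence_af(catalogue: NrsCatalogue, panel: pd.DataFrame
                ) -> dict[str, float]:
    """Presence-based AF for unplaced records: carriers / individuals
    among non-offspring samples."""
    offspring = set(panel.loc[panel["trio_role"] == "child", "sample"])
    included = [s for s in panel["sample"] if s not in offspring]
    out = {}
    for record in catalogue.unplaced_records:
        carriers = sum(1 for s in record.samples if s in included)
        out[record.gnrs_id] = carriers / len(included) if included else 0.0
    return out


def population_sharing(records: Sequence[AfRecord],
                       populations: Sequence[str],
                       ) -> tuple[dict[str, str], dict[str, float]]:
    """Label records common (allele observed in every population with
    data) / specific (exactly one) / intermediate; plus summary
    percentages of the catalogue."""
    labels: dict[str, str] = {}
    n_common = n_specific = 0
    for record in records:
        observed = [pop for pop in populations
                    if record.per_population_af.get(pop) not in (None,)
                    and record.per_population_af[pop] > 0]
        with_data = [pop for pop in populations
                     if record.per_population_af.get(pop) is not None]
        if with_data and len(observed) == len(with_data):
            labels[record.gnrs_id] = "common"
            n_common += 1
        elif len(observed) == 1:
            labels[record.gnrs_id] = "specific"
            n_specific += 1
        else:
            labels[record.gnrs_id] = "intermediate"
    total = len(records)
    summary = {
        "common_pct": percent(n_common, total) if total else math.nan,
        "specific_pct": percent(n_specific, total) if total else math.nan,
    }
    return labels, summary


def growth_curve(nrs_sets: Mapping[str, set],
                 panel: pd.DataFrame,
                 afr_populations: Iterable[str] = ("AFR",),
                 orderings: int = 10,
                 seed: int = 0,
                 categories: Mapping[str, str] | None = None,
                 ) -> pd.DataFrame:
    """Mean cumulative distinct-NRS counts, non-AFR samples added first,
    random within-block permutation per replicate."""
    afr = set(afr_populations)
    pop_of = dict(zip(panel["sample"], panel["population"]))
    samples = [s for s in nrs_sets if s in pop_of]
    non_afr = [s for s in samples if pop_of[s] not in afr]
    afr_samples = [s for s in samples if pop_of[s] in afr]
    rng = np.random.default_rng(seed)
    cat_names = sorted(set(categories.values())) if categories else []
    totals = np.zeros((orderings, len(samples)))
    by_cat = {c: np.zeros((orderings, len(samples))) for c in cat_names}
    for rep in range(orderings):
        order = ([non_afr[i] for i in rng.permutation(len(non_afr))]
                 + [afr_samples[i] for i in rng.permutation(len(afr_samples))])
        seen: set = set()
        for i, sample in enumerate(order):
            seen |= set(nrs_sets[sample])
            totals[rep, i] = len(seen)
            for c in cat_names:
                by_cat[c][rep, i] = sum(
                    1 for x in seen if categories.get(x) == c)
    out = pd.DataFrame({"n": np.arange(1, len(samples) + 1),
                        "total": totals.mean(axis=0)})
    for c in cat_names:
        out[c] = by_cat[c].mean(axis=0)
    return out


def compute_n50(lengths: Sequence[int]) -> int:
    """Smallest L with sum(lengths >= L) >= half the total length."""
    if not lengths:
        raise ValueError("no lengths")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2.0
    acc = 0
    for L in ordered:
        acc += L
        if acc >= half:
            return int(L)
    return int(ordered[-1])


def annotate_genic(catalogue: NrsCatalogue, genes: Sequence[Gene]
                   ) -> dict[str, str]:
    """Insertion-point context with exon > intron > intergenic precedence;
    unplaced records are labelled 'unplaced'."""
    out: dict[str, str] = {}
    for record in catalogue.records:
        if not record.placed:
            out[record.gnrs_id] = "unplaced"
            continue
        context = "intergenic"
        for gene in genes:
            if gene.chrom != record.chrom or not (
                    gene.start <= record.position < gene.end):
                continue
            in_exon = any(s <= record.position < e for s, e in gene.exons)
            if in_exon:
                context = "exon_coding" if gene.coding else "exon_noncoding"
                break
            context = "intron"
        out[record.gnrs_id] = context
    return out


def enrichment_fisher(hits: set, background: set,
                      term_sets: Mapping[str, set]) -> pd.DataFrame:
    """Per-term 2x2 Fisher exact test with BH correction across terms.

    Empty terms (no overlap with the background) are reported with a
    ``skipped`` flag and excluded from the correction.
    """
    hits = hits & background
    rows = []
    for term, members in term_sets.items():
        members = members & background
        if not members:
            rows.append({"term": term, "odds_ratio": math.nan,
                         "p": math.nan, "skipped": True,
                         "hit_in_term": 0, "term_size": 0})
            continue
        a = len(hits & members)
        b = len(hits - members)
        c = len(members - hits)
        d = len(background - hits - members)
        odds_ratio, p = _scipy_stats.fisher_exact([[a, b], [c, d]],
                                                  alternative="greater")
        rows.append({"term": term, "odds_ratio": float(odds_ratio),
                     "p": float(p), "skipped": False,
                     "hit_in_term": a, "term_size": len(members)})
    frame = pd.DataFrame(rows)
    tested = ~frame["skipped"]
    frame["q"] = math.nan
    if tested.any():
        from .association import bh_fdr
        _, qvals = bh_fdr(frame.loc[tested, "p"].to_numpy(), 0.05)
        frame.loc[tested, "q"] = qvals
    return frame


def catalogue_summary(catalogue: NrsCatalogue) -> pd.DataFrame:
    """Table-1 style summary: count, total length, average length, per
    placed / unplaced / total."""
    rows = []
    for label, records in (("placed", catalogue.placed_records),
                           ("unplaced", catalogue.unplaced_records),
                           ("total", catalogue.records)):
        count = len(records)
        total = sum(r.length for r in records)
        rows.append({
            "category": label,
            "count": count,
            "total_length_bp": total,
            "average_length_bp": average_length(total, count)
            if count else 0,
        })
    return pd.DataFrame(rows)
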