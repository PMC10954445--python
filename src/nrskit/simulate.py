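"""Synthetic multi-population assembly panels with planted insertion events.

Every input the pipeline consumes — reference genome with annotation
tracks, per-sample contigs with depth tracks, sample panel with trios and
platform labels, expression/phenotype tables and a tag-SNP panel — is
generated here from one explicit seed, together with a truth set for
recall and calibration accounting.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import Gene, ReferenceGenome
from .seqcore.taxon import load_bundled_satellites

MIN_EVENT_LENGTH = 50
EVENT_CLASSES = ("tandem_repeat", "mobile_element_like", "unique_novel")

# host-like base composition (GC ~0.42)
_HOST_P = np.array([0.29, 0.21, 0.21, 0.29])
# contaminant composition (GC ~0.68), mirrors the bundled foreign profile
_FOREIGN_P = np.array([0.16, 0.34, 0.34, 0.16])
_BASES = np.array(list("ACGT"))

# named substreams so stages can be re-run independently
_STREAMS = {
    "reference": 1,
    "events": 2,
    "presence": 3,
    "assembly": 4,
    "expression": 5,
    "phenotype": 6,
    "snp": 7,
}


def _rng(seed: int, stage: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stage], extra])


def _random_seq(rng: np.random.Generator, n: int,
                p: np.ndarray = _HOST_P) -> str:
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


@dataclass(frozen=True)
class EventSpec:
    """One planted insertion event class entry of the configuration."""
    event_class: str
    length: int
    af: Mapping[str, float]
    count: int = 1
    selection: bool = False

    def validate(self, populations: Sequence[str]) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")
        if self.length < MIN_EVENT_LENGTH:
            raise ValueError(
                f"event length {self.length} < {MIN_EVENT_LENGTH} bp")
        for pop, f in self.af.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"AF {f} for {pop} outside [0, 1]")


@dataclass(frozen=True)
class DepthBait:
    """Planted over/under-deep contig interval for depth-filter testing."""
    sample: str
    factor: float          # multiple of the sample mean depth
    length: int = 2000


@dataclass(frozen=True)
class TaggedSnp:
    event_index: int
    r2: float
    offset: int = 50_000   # signed distance from the event insertion point


@dataclass(frozen=True)
class SnpPanelConfig:
    n_snps: int = 0
    tagged: tuple[TaggedSnp, ...] = ()


@dataclass(frozen=True)
class SimConfig:
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_samples_per_population: Mapping[str, int] = field(
        default_factory=lambda: {"AFR": 10, "EAS": 10})
    n_trios: int = 0
    events: tuple[EventSpec, ...] = ()
    contaminant_fraction: float = 0.0
    depth_mean: float = 20.0
    platforms: tuple[str, ...] = ("ONT", "HiFi")
    platform_assignment: Mapping[str, str] | None = None
    fragmentation_rate: float = 0.0       # expected breaks per bp
    depth_baits: tuple[DepthBait, ...] = ()
    n_satellite_arrays_per_chrom: int = 1
    satellite_copies: int = 20
    n_genes_per_chrom: int = 8
    gene_length: int = 5000
    eqtl_effects: tuple[tuple[int, str, float], ...] = ()   # (event, transcript, beta)
    gwas_effects: tuple[tuple[int, str, float], ...] = ()   # (event, trait, beta)
    quantitative_traits: tuple[str, ...] = ("trait_q",)
    binary_traits: tuple[str, ...] = ()
    snp_panel: SnpPanelConfig = SnpPanelConfig()
    min_event_spacing: int = 2500
    seed: int = 0

    @property
    def populations(self) -> list[str]:
        return list(self.n_samples_per_population)

    def validate(self) -> None:
        for spec in self.events:
            spec.validate(self.populations)
        if not 0.0 <= self.contaminant_fraction < 1.0:
            raise ValueError("contaminant_fraction must be in [0, 1)")
        for tag in self.snp_panel.tagged:
            if abs(tag.offset) > 100_000:
                raise ValueError(
                    f"tagged SNP offset {tag.offset} exceeds the 100 kb "
                    "LD window")
            if not 0.0 <= tag.r2 <= 1.0:
                raise ValueError("target r2 outside [0, 1]")


@dataclass(frozen=True)
class SampleInfo:
    sample: str
    population: str
    platform: str
    sex: str               # M | F
    trio_id: str           # "" if not in a trio
    trio_role: str         # father | mother | child | none


@dataclass
class Event:
    event_id: str
    chrom: str
    position: int          # 0-based between-base insertion point
    sequence: str
    event_class: str
    af: Mapping[str, float]
    selection: bool = False
    # sample -> (hap1 carries, hap2 carries)
    presence: dict[str, tuple[bool, bool]] = field(default_factory=dict)

    def dosage(self, sample: str) -> int:
        h1, h2 = self.presence.get(sample, (False, False))
        return int(h1) + int(h2)

    def carrier_samples(self) -> list[str]:
        return [s for s, (a, b) in self.presence.items() if a or b]


@dataclass
class TruthSet:
    events: list[Event]
    samples: list[SampleInfo]
    trio_pedigree: dict[str, tuple[str, str]]
    planted_selection_loci: list[str]
    planted_associations: list[tuple[str, str, float]]
    unanchorable: set[tuple[str, str]] = field(default_factory=set)  # (sample, event)
    depth_baits: list[tuple[str, str, int, int, float]] = field(
        default_factory=list)   # (sample, contig, start, end, depth)

    @property
    def non_offspring_samples(self) -> list[str]:
        children = set(self.trio_pedigree)
        return [s.sample for s in self.samples if s.sample not in children]

    def panel_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "sample": s.sample, "population": s.population,
            "platform": s.platform, "sex": s.sex,
            "trio_id": s.trio_id, "trio_role": s.trio_role,
        } for s in self.samples])


@dataclass
class SampleAssembly:
    sample: str
    contigs: dict[str, str]
    # rows (contig, start, end, depth), 0-based half-open
    depth_track: list[tuple[str, int, int, float]]
    mean_depth: float


def build_reference(config: SimConfig) -> ReferenceGenome:
    """Seeded random genome with centromere, satellite arrays and genes."""
    config.validate()
    rng = _rng(config.seed, "reference")
    monomers = load_bundled_satellites()
    monomer_names = sorted(monomers)
    L = config.chrom_length
    cen_half = max(len(monomers[monomer_names[0]]) * config.satellite_copies,
                   2000) // 2
    needed = (4 * cen_half
              + config.n_genes_per_chrom * 2 * config.gene_length)
    if L < needed:
        raise ValueError(
            f"chrom_length {L} too small for requested annotations "
            f"(needs >= {needed})")

    sequences: dict[str, str] = {}
    arms: dict[str, tuple[int, int]] = {}
    satellites: list[tuple[str, int, int, str]] = []
    genes: list[Gene] = []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        seq = list(_random_seq(rng, L))
        cen_start = L // 2 - cen_half
        # centromeric satellite array
        if config.n_satellite_arrays_per_chrom > 0:
            name = monomer_names[c % len(monomer_names)]
            array = (monomers[name]
                     * math.ceil(2 * cen_half / len(monomers[name])))
            array = array[:2 * cen_half]
            seq[cen_start:cen_start + len(array)] = array
            satellites.append((chrom, cen_start, cen_start + len(array), name))
            for extra in range(config.n_satellite_arrays_per_chrom - 1):
                name2 = monomer_names[(c + extra + 1) % len(monomer_names)]
                alen = len(monomers[name2]) * max(config.satellite_copies
                                                  // 2, 3)
                pos = int(rng.integers(L // 8, L // 4))
                arr2 = (monomers[name2] * math.ceil(alen
                                                    / len(monomers[name2])))
                arr2 = arr2[:alen]
                seq[pos:pos + alen] = arr2
                satellites.append((chrom, pos, pos + alen, name2))
        arms[chrom] = (cen_start, cen_start + 2 * cen_half)
        sequences[chrom] = "".join(seq)

        # genes on both arms, away from the centromere
        glen = config.gene_length
        n_genes = config.n_genes_per_chrom
        spots: list[int] = []
        half = n_genes - n_genes // 2
        for arm_lo, arm_hi, n_arm in (
                (2000, cen_start - glen - 2000, half),
                (cen_start + 2 * cen_half + 2000, L - glen - 2000,
                 n_genes // 2)):
            if n_arm <= 0:
                continue
            step = (arm_hi - arm_lo) // max(n_arm, 1)
            for g in range(n_arm):
                spots.append(arm_lo + g * step
                             + int(rng.integers(0, max(step - glen, 1))))
        for gi, start in enumerate(sorted(spots)):
            strand = "+" if rng.random() < 0.5 else "-"
            exon1 = (start, start + glen // 4)
            exon2 = (start + 3 * glen // 4, start + glen)
            genes.append(Gene(
                gene_id=f"{chrom}_g{gi + 1}", chrom=chrom, start=start,
                end=start + glen, strand=strand, exons=(exon1, exon2),
                coding=(gi % 3 != 2)))
    return ReferenceGenome(sequences=sequences, arms=arms,
                           satellites=satellites, genes=genes)


def _build_panel(config: SimConfig) -> tuple[list[SampleInfo],
                                             dict[str, tuple[str, str]]]:
    samples: list[SampleInfo] = []
    idx = 0
    for pop, n in config.n_samples_per_population.items():
        for i in range(n):
            name = f"{pop}_{i + 1:03d}"
            platform = (config.platform_assignment.get(name)
                        if config.platform_assignment
                        else config.platforms[idx % len(config.platforms)])
            samples.append(SampleInfo(
                sample=name, population=pop, platform=platform,
                sex="M" if idx % 2 == 0 else "F",
                trio_id="", trio_role="none"))
            idx += 1
    pedigree: dict[str, tuple[str, str]] = {}
    pops = config.populations
    for t in range(config.n_trios):
        pop = pops[t % len(pops)]
        members = [s for s in samples if s.population == pop
                   and s.trio_role == "none"]
        fathers = [s for s in members if s.sex == "M"]
        mothers = [s for s in members if s.sex == "F"]
        if not fathers or not mothers:
            raise ValueError("not enough samples to form requested trios")
        father, mother = fathers[0], mothers[0]
        trio_id = f"trio{t + 1}"
        child_name = f"{pop}_child{t + 1}"
        for parent, role in ((father, "father"), (mother, "mother")):
            i = samples.index(parent)
            samples[i] = replace(parent, trio_id=trio_id, trio_role=role)
        samples.append(SampleInfo(
            sample=child_name, population=pop,
            platform=config.platforms[0], sex="M" if t % 2 == 0 else "F",
            trio_id=trio_id, trio_role="child"))
        pedigree[child_name] = (father.sample, mother.sample)
    return samples, pedigree


def _mobile_element_libraries(seed: int) -> dict[str, str]:
    rng = _rng(seed, "events", 999)
    return {"short": _random_seq(rng, 300), "long": _random_seq(rng, 6000)}


def _event_sequence(spec: EventSpec, rng: np.random.Generator,
                    libraries: Mapping[str, str]) -> str:
    n = spec.length
    if spec.event_class == "tandem_repeat":
        motif_len = int(rng.integers(2, min(100, max(n // 4, 3)) + 1))
        motif = _random_seq(rng, motif_len)
        copies = math.ceil(n / motif_len)
        return (motif * copies)[:n]
    if spec.event_class == "mobile_element_like":
        lib = libraries["short"] if n <= 300 else libraries["long"]
        base = (lib * math.ceil(n / len(lib)))[:n]
        divergence = rng.uniform(0.01, 0.05)
        seq = np.array(list(base))
        n_mut = int(round(divergence * n))
        if n_mut:
            pos = rng.choice(n, size=n_mut, replace=False)
            shift = rng.integers(1, 4, size=n_mut)
            codes = np.searchsorted(_BASES, seq[pos])
            seq[pos] = _BASES[(codes + shift) % 4]
        return "".join(seq)
    return _random_seq(rng, n)


def _event_positions(ref: ReferenceGenome, n: int, spacing: int,
                     rng: np.random.Generator) -> list[tuple[str, int]]:
    chroms = sorted(ref.sequences)
    margin = 1500
    allowed: list[tuple[str, int, int]] = []
    for chrom in chroms:
        blocked = [(max(0, s - margin), e + margin)
                   for s, e in ref.excluded_intervals(chrom)]
        pos = margin
        L = len(ref.sequences[chrom]) - margin
        for bs, be in blocked + [(L, L)]:
            if bs > pos:
                allowed.append((chrom, pos, bs))
            pos = max(pos, be)
    total = sum(e - s for _, s, e in allowed)
    if total < n * spacing:
        raise ValueError("genome too small for requested number of events "
                         "at the configured spacing")
    slots: list[tuple[str, int]] = []
    for chrom, s, e in allowed:
        k = (e - s) // spacing
        for i in range(k):
            slots.append((chrom, s + i * spacing
                          + int(rng.integers(0, spacing // 2))))
    pick = rng.choice(len(slots), size=n, replace=False)
    return sorted(slots[i] for i in sorted(pick))


def simulate_population(ref: ReferenceGenome, config: SimConfig) -> TruthSet:
    """Sample diploid presence per event from population AFs; trio children
    inherit one haplotype per chromosome from each parent."""
    config.validate()
    samples, pedigree = _build_panel(config)
    rng_ev = _rng(config.seed, "events")
    rng_pr = _rng(config.seed, "presence")
    libraries = _mobile_element_libraries(config.seed)

    specs: list[EventSpec] = []
    for spec in config.events:
        specs.extend([spec] * spec.count)
    positions = _event_positions(ref, len(specs), config.min_event_spacing,
                                 rng_ev)
    events: list[Event] = []
    for i, (spec, (chrom, pos)) in enumerate(zip(specs, positions)):
        seq = _event_sequence(spec, rng_ev, libraries)
        events.append(Event(
            event_id=f"EV{i + 1:05d}", chrom=chrom, position=pos,
            sequence=seq, event_class=spec.event_class, af=dict(spec.af),
            selection=spec.selection))

    children = set(pedigree)
    chroms = sorted(ref.sequences)
    for event in events:
        for s in samples:
            if s.sample in children:
                continue
            f = float(event.af.get(s.population, 0.0))
            event.presence[s.sample] = (bool(rng_pr.random() < f),
                                        bool(rng_pr.random() < f))
    # per (child, chromosome): transmitted haplotype index from each parent
    transmit = {
        (child, chrom): (int(rng_pr.integers(2)), int(rng_pr.integers(2)))
        for child in sorted(children) for chrom in chroms
    }
    for event in events:
        for child, (father, mother) in pedigree.items():
            hf, hm = transmit[(child, event.chrom)]
            event.presence[child] = (event.presence[father][hf],
                                     event.presence[mother][hm])

    planted_assoc = []
    for eff_list, kind in ((config.eqtl_effects, "transcript"),
                           (config.gwas_effects, "trait")):
        for event_idx, target, beta in eff_list:
            planted_assoc.append((events[event_idx].event_id, target,
                                  float(beta)))
    return TruthSet(
        events=events, samples=samples, trio_pedigree=pedigree,
        planted_selection_loci=[e.event_id for e in events if e.selection],
        planted_associations=planted_assoc)


def _splice_haplotype(ref: ReferenceGenome, chrom: str,
                      inserts: list[tuple[int, str]]) -> tuple[str, list[int]]:
    """Insert sequences at reference points; returns (sequence, offsets of
    each insertion start in haplotype coordinates)."""
    base = ref.sequences[chrom]
    parts: list[str] = []
    starts: list[int] = []
    prev = 0
    offset = 0
    for pos, seq in sorted(inserts):
        parts.append(base[prev:pos])
        offset += pos - prev
        starts.append(offset)
        parts.append(seq)
        offset += len(seq)
        prev = pos
    parts.append(base[prev:])
    return "".join(parts), starts


def emit_assembly(ref: ReferenceGenome, truth: TruthSet, config: SimConfig,
                  sample: str) -> SampleAssembly:
    """Contigs for one sample: reference haplotypes with its events spliced
    in, Poisson fragmentation, contaminant contigs and depth-bait tracks."""
    sample_idx = [s.sample for s in truth.samples].index(sample)
    rng = _rng(config.seed, "assembly", sample_idx)
    contigs: dict[str, str] = {}
    depth: list[tuple[str, int, int, float]] = []
    ci = 0
    for chrom in sorted(ref.sequences):
        for hap in (0, 1):
            inserts = [(e.position, e.sequence) for e in truth.events
                       if e.chrom == chrom and e.presence.get(
                           sample, (False, False))[hap]]
            hap_seq, ins_starts = _splice_haplotype(ref, chrom, inserts)
            breaks: list[int] = []
            if config.fragmentation_rate > 0:
                n_breaks = rng.poisson(config.fragmentation_rate
                                       * len(hap_seq))
                breaks = sorted(int(b) for b in rng.integers(
                    1, len(hap_seq), size=n_breaks))
            bounds = [0] + breaks + [len(hap_seq)]
            for s, e in zip(bounds[:-1], bounds[1:]):
                if e - s < 1:
                    continue
                ci += 1
                name = f"{sample}_h{hap + 1}_c{ci}"
                contigs[name] = hap_seq[s:e]
                depth.append((name, 0, e - s, config.depth_mean))
    n_host = len(contigs)
    if config.contaminant_fraction > 0:
        n_cont = round(config.contaminant_fraction * n_host
                       / (1 - config.contaminant_fraction))
        n_cont = max(n_cont, 1)
        for j in range(n_cont):
            ci += 1
            name = f"{sample}_contaminant_c{ci}"
            length = int(rng.integers(2000, 20000))
            contigs[name] = _random_seq(rng, length, _FOREIGN_P)
            depth.append((name, 0, length, config.depth_mean))

    baits = [b for b in config.depth_baits if b.sample == sample]
    truth_baits = [b for b in truth.depth_baits if b[0] == sample]
    if baits and not truth_baits:
        host_names = [n for n in contigs if "_contaminant_" not in n]
        for b in baits:
            target = max(host_names, key=lambda n: len(contigs[n]))
            clen = len(contigs[target])
            start = min(clen // 3, clen - 1)
            end = min(start + b.length, clen)
            new_rows = []
            for name, s, e, d in depth:
                if name != target:
                    new_rows.append((name, s, e, d))
                    continue
                if start > s:
                    new_rows.append((name, s, start, d))
                new_rows.append((name, start, end,
                                 b.factor * config.depth_mean))
                if end < e:
                    new_rows.append((name, end, e, d))
            depth = new_rows
            truth.depth_baits.append((sample, target, start, end,
                                      b.factor * config.depth_mean))
    total_bp = sum(e - s for _, s, e, _ in depth)
    mean_depth = (sum((e - s) * d for _, s, e, d in depth) / total_bp
                  if total_bp else config.depth_mean)

    # truth bookkeeping: events whose every occurrence lacks 1 kb flanks
    for event in truth.events:
        pres = event.presence.get(sample, (False, False))
        if not any(pres):
            continue
        intact = False
        for name, seq in contigs.items():
            i = seq.find(event.sequence)
            if i >= 1000 and len(seq) - (i + len(event.sequence)) >= 1000:
                intact = True
                break
        if not intact:
            truth.unanchorable.add((sample, event.event_id))
    return SampleAssembly(sample=sample, contigs=contigs,
                          depth_track=depth, mean_depth=mean_depth)


def emit_assemblies(ref: ReferenceGenome, truth: TruthSet,
                    config: SimConfig) -> Iterator[SampleAssembly]:
    for s in truth.samples:
        yield emit_assembly(ref, truth, config, s.sample)


def simulate_expression(truth: TruthSet, config: SimConfig,
                        ref: ReferenceGenome,
                        noise_sd: float = 1.0) -> pd.DataFrame:
    """Transcripts x samples expression: baseline + beta * dosage + noise."""
    rng = _rng(config.seed, "expression")
    transcripts = [g.gene_id for g in ref.genes]
    known = set(transcripts)
    effects: dict[str, list[tuple[str, float]]] = {}
    for event_idx, transcript, beta in config.eqtl_effects:
        if transcript not in known:
            raise ValueError(
                f"transcript {transcript!r} has no TSS annotation")
        effects.setdefault(transcript, []).append(
            (truth.events[event_idx].event_id, float(beta)))
    events_by_id = {e.event_id: e for e in truth.events}
    sample_names = [s.sample for s in truth.samples]
    data = np.empty((len(transcripts), len(sample_names)))
    for ti, transcript in enumerate(transcripts):
        baseline = rng.normal(10.0, 2.0)
        noise = (rng.normal(0.0, noise_sd, size=len(sample_names))
                 if noise_sd > 0 else np.zeros(len(sample_names)))
        row = baseline + noise
        for event_id, beta in effects.get(transcript, []):
            dosage = np.array([events_by_id[event_id].dosage(s)
                               for s in sample_names], dtype=float)
            row = row + beta * dosage
        data[ti] = row
    return pd.DataFrame(data, index=transcripts, columns=sample_names)


def simulate_phenotypes(truth: TruthSet, config: SimConfig,
                        noise_sd: float = 1.0) -> pd.DataFrame:
    """Phenotype table with age/sex/BMI covariates and planted effects."""
    rng = _rng(config.seed, "phenotype")
    rows = []
    for s in truth.samples:
        rows.append({
            "sample": s.sample,
            "age": float(rng.integers(20, 70)),
            "sex": 1.0 if s.sex == "M" else 0.0,
            "BMI": float(np.round(rng.normal(23.0, 3.0), 1)),
        })
    table = pd.DataFrame(rows).set_index("sample")
    events_by_id = {e.event_id: e for e in truth.events}
    effects: dict[str, list[tuple[str, float]]] = {}
    for event_idx, trait, beta in config.gwas_effects:
        effects.setdefault(trait, []).append(
            (truth.events[event_idx].event_id, float(beta)))
    for trait in config.quantitative_traits:
        noise = (rng.normal(0.0, noise_sd, size=len(table))
                 if noise_sd > 0 else 0.0)
        value = (0.02 * table["age"] + 0.3 * table["sex"]
                 + 0.05 * table["BMI"] + noise)
        for event_id, beta in effects.get(trait, []):
            dosage = np.array([events_by_id[event_id].dosage(s)
                               for s in table.index], dtype=float)
            value = value + beta * dosage
        table[trait] = value
    for trait in config.binary_traits:
        eta = -0.5 + 0.01 * table["age"] + 0.2 * table["sex"]
        for event_id, beta in effects.get(trait, []):
            dosage = np.array([events_by_id[event_id].dosage(s)
                               for s in table.index], dtype=float)
            eta = eta + beta * dosage
        prob = 1.0 / (1.0 + np.exp(-eta))
        table[trait] = (rng.random(len(table)) < prob).astype(int)
    return table


def simulate_snp_panel(truth: TruthSet, config: SimConfig,
                       ref: ReferenceGenome
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SNP dosage matrix (snps x samples) plus a catalogue-style table
    (id, chrom, position, association p).

    Tagged SNPs copy the event's haplotypes with per-haplotype flip
    probability (1 - sqrt(r2)) / 2, achieving the target r2 in
    expectation (exactly identical genotypes at r2 = 1).
    """
    config.validate()
    rng = _rng(config.seed, "snp")
    sample_names = [s.sample for s in truth.samples]
    chrom_lengths = ref.chrom_lengths
    rows, meta = [], []
    snp_i = 0
    for tag in config.snp_panel.tagged:
        event = truth.events[tag.event_index]
        pos = event.position + tag.offset
        if not 0 <= pos < chrom_lengths[event.chrom]:
            raise ValueError("tagged SNP position outside its chromosome")
        flip = (1.0 - math.sqrt(tag.r2)) / 2.0
        dosage = []
        for s in sample_names:
            h1, h2 = event.presence.get(s, (False, False))
            a1 = int(h1) ^ int(rng.random() < flip)
            a2 = int(h2) ^ int(rng.random() < flip)
            dosage.append(a1 + a2)
        snp_i += 1
        snp_id = f"SNP{snp_i:05d}"
        rows.append(dosage)
        meta.append({"snp": snp_id, "chrom": event.chrom, "position": pos,
                     "p": 1e-12, "tagged_event": event.event_id})
    n_untagged = max(config.snp_panel.n_snps - len(meta), 0)
    chroms = sorted(chrom_lengths)
    for _ in range(n_untagged):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(0, chrom_lengths[chrom]))
        maf = float(rng.uniform(0.05, 0.5))
        dosage = rng.binomial(2, maf, size=len(sample_names)).tolist()
        snp_i += 1
        rows.append(dosage)
        meta.append({"snp": f"SNP{snp_i:05d}", "chrom": chrom,
                     "position": pos,
                     "p": float(10 ** rng.uniform(-7, 0)),
                     "tagged_event": ""})
    genotypes = pd.DataFrame(rows, index=[m["snp"] for m in meta],
                             columns=sample_names, dtype=int)
    return genotypes, pd.DataFrame(meta)
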