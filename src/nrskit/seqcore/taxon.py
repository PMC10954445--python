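"""Composition-based taxon classification of assembly segments.

Stands in for a database search: each candidate sequence is scored by a
per-base log-likelihood under GC + tetranucleotide profiles of the host
and of known foreign (contaminant) composition models.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources as _importlib_resources
from typing import Mapping, Sequence

import numpy as np

from ._encode import encode, kmer_codes

PROFILE_WINDOW = 300       # shorter sequences are not classifiable
DEFAULT_MARGIN = 0.30      # nats/base separating best from runner-up
_GC_SD = 0.08


@dataclass(frozen=True)
class TaxonLabel:
    value: str             # chordate | non_chordate | unclassified
    source: str            # primary | secondary

    def __post_init__(self) -> None:
        if self.value not in ("chordate", "non_chordate", "unclassified"):
            raise ValueError(f"bad taxon value: {self.value}")


class CompositionProfile:
    """GC + tetranucleotide log-probability model of a sequence source."""

    def __init__(self, name: str, gc: float, tetra_freqs: np.ndarray):
        if tetra_freqs.shape != (256,):
            raise ValueError("tetranucleotide profile must have 256 entries")
        self.name = name
        self.gc = float(gc)
        freqs = np.clip(tetra_freqs, 1e-9, None)
        self._logp = np.log(freqs / freqs.sum())

    @classmethod
    def from_base_probs(cls, name: str, base_probs: Sequence[float],
                        cpg_boost: float = 1.0) -> "CompositionProfile":
        """Independent-base model; ``cpg_boost`` multiplies words containing
        the CG dinucleotide to shape a distinct tetranucleotide signature."""
        p = np.asarray(base_probs, dtype=float)
        p = p / p.sum()
        tetra = np.zeros(256)
        for word in range(256):
            bases = [(word >> (2 * (3 - i))) & 3 for i in range(4)]
            prob = float(np.prod([p[b] for b in bases]))
            has_cpg = any(bases[i] == 1 and bases[i + 1] == 2
                          for i in range(3))
            tetra[word] = prob * (cpg_boost if has_cpg else 1.0)
        gc = float(p[1] + p[2])
        return cls(name, gc, tetra)

    @classmethod
    def from_sequence(cls, name: str, seq: str) -> "CompositionProfile":
        codes = encode(seq)
        kmers, _ = kmer_codes(codes, 4)
        counts = np.bincount(kmers, minlength=256).astype(float)
        acgt = codes[codes < 4]
        gc = float(((acgt == 1) | (acgt == 2)).mean()) if acgt.size else 0.5
        return cls(name, gc, counts + 1.0)

    def log_likelihood_per_base(self, seq: str) -> float:
        codes = encode(seq)
        kmers, _ = kmer_codes(codes, 4)
        if kmers.size == 0:
            return -np.inf
        tetra_ll = float(self._logp[kmers].mean())
        acgt = codes[codes < 4]
        gc_obs = float(((acgt == 1) | (acgt == 2)).mean())
        gc_ll = -0.5 * ((gc_obs - self.gc) / _GC_SD) ** 2
        return tetra_ll + gc_ll / max(len(seq), 1)


def classify_taxon(seq: str, host_profile: CompositionProfile,
                   foreign_profiles: Sequence[CompositionProfile],
                   window: int = PROFILE_WINDOW,
                   margin: float = DEFAULT_MARGIN,
                   source: str = "primary") -> TaxonLabel:
    """Label a sequence chordate / non_chordate / unclassified.

    The winning profile must beat the best profile of the other group by
    ``margin`` nats per base, otherwise the call is left unclassified.
    """
    informative = sum(1 for c in seq if c in "ACGTacgt")
    if informative < window:
        return TaxonLabel("unclassified", source)
    host_ll = host_profile.log_likelihood_per_base(seq)
    foreign_ll = max(p.log_likelihood_per_base(seq)
                     for p in foreign_profiles) if foreign_profiles else -np.inf
    if not math.isfinite(host_ll) and not math.isfinite(foreign_ll):
        return TaxonLabel("unclassified", source)
    if host_ll >= foreign_ll + margin:
        return TaxonLabel("chordate", source)
    if foreign_ll >= host_ll + margin:
        return TaxonLabel("non_chordate", source)
    return TaxonLabel("unclassified", source)


def load_bundled_profiles() -> tuple[CompositionProfile,
                                     list[CompositionProfile]]:
    """Host + foreign profiles from the packaged composition table."""
    path = _importlib_resources.files("nrskit.resources").joinpath(
        "composition_profiles.tsv")
    gc_by_name: dict[str, float] = {}
    tetra: dict[str, np.ndarray] = {}
    names: list[str] = []
    with path.open() as handle:
        header = handle.readline().rstrip("\n").split("\t")
        names = header[1:]
        for name in names:
            tetra[name] = np.zeros(256)
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "#GC":
                for name, value in zip(names, fields[1:]):
                    gc_by_name[name] = float(value)
                continue
            word = fields[0]
            code = 0
            for ch in word:
                code = (code << 2) | "ACGT".index(ch)
            for name, value in zip(names, fields[1:]):
                tetra[name][code] = float(value)
    host = CompositionProfile("host", gc_by_name["host"], tetra["host"])
    foreign = [CompositionProfile(n, gc_by_name[n], tetra[n])
               for n in names if n != "host"]
    return host, foreign


def load_bundled_satellites() -> dict[str, str]:
    """Satellite monomer library bundled with the package."""
    path = _importlib_resources.files("nrskit.resources").joinpath(
        "satellites.fa")
    monomers: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with path.open() as handle:
        for line in handle:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    monomers[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        monomers[name] = "".join(chunks)
    return monomers
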