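"""Bundled desk-scale panel configurations used by the test suite, the
acceptance report and the documentation examples."""
from __future__ import annotations

from .simulate import EventSpec, SimConfig


def demo_config(seed: int = 42) -> SimConfig:
    """Two chromosomes x 1 Mb, 60 samples across three populations with
    three trios, 300 planted events spanning all three classes."""
    events = (
        EventSpec("unique_novel", 300,
                  {"AFR": 0.5, "EAS": 0.3, "AMR": 0.4}, count=80),
        EventSpec("unique_novel", 1000,
                  {"AFR": 0.6, "EAS": 0.2, "AMR": 0.3}, count=70),
        EventSpec("tandem_repeat", 200,
                  {"AFR": 0.5, "EAS": 0.5, "AMR": 0.5}, count=60),
        EventSpec("tandem_repeat", 600,
                  {"AFR": 0.3, "EAS": 0.6, "AMR": 0.2}, count=40),
        EventSpec("mobile_element_like", 300,
                  {"AFR": 0.4, "EAS": 0.4, "AMR": 0.4}, count=30),
        EventSpec("mobile_element_like", 2000,
                  {"AFR": 0.2, "EAS": 0.5, "AMR": 0.3}, count=20),
    )
    return SimConfig(
        n_chromosomes=2, chrom_length=1_000_000,
        n_samples_per_population={"AFR": 20, "EAS": 20, "AMR": 17},
        n_trios=3, events=events, depth_mean=20.0, seed=seed)


def small_config(seed: int = 7) -> SimConfig:
    """One chromosome x 400 kb, 8 samples + one trio; quick unit-test
    panel exercising every stage."""
    events = (
        EventSpec("unique_novel", 400,
                  {"AFR": 0.6, "EAS": 0.4}, count=6),
        EventSpec("tandem_repeat", 200,
                  {"AFR": 0.5, "EAS": 0.5}, count=3),
        EventSpec("mobile_element_like", 300,
                  {"AFR": 1.0, "EAS": 1.0}, count=2),
    )
    return SimConfig(
        n_chromosomes=1, chrom_length=400_000,
        n_samples_per_population={"AFR": 4, "EAS": 4},
        n_trios=1, events=events, n_genes_per_chrom=4, seed=seed)
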