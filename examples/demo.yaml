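# Desk-scale demo panel: 2 chromosomes x 1 Mb, 60 samples (3 trios),
# 300 planted insertion events across all three classes.
n_chromosomes: 2
chrom_length: 1000000
n_samples_per_population:
  AFR: 20
  EAS: 20
  AMR: 17
n_trios: 3
depth_mean: 20.0
events:
  - {event_class: unique_novel, length: 300, af: {AFR: 0.5, EAS: 0.3, AMR: 0.4}, count: 80}
  - {event_class: unique_novel, length: 1000, af: {AFR: 0.6, EAS: 0.2, AMR: 0.3}, count: 70}
  - {event_class: tandem_repeat, length: 200, af: {AFR: 0.5, EAS: 0.5, AMR: 0.5}, count: 60}
  - {event_class: tandem_repeat, length: 600, af: {AFR: 0.3, EAS: 0.6, AMR: 0.2}, count: 40}
  - {event_class: mobile_element_like, length: 300, af: {AFR: 0.4, EAS: 0.4, AMR: 0.4}, count: 30}
  - {event_class: mobile_element_like, length: 2000, af: {AFR: 0.2, EAS: 0.5, AMR: 0.3}, count: 20}
seed: 42
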