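# Measure registry: tail convention and handling per evolutionary measure.
# upper: larger values are the interesting tail (one-tailed empirical p).
# two_sided: extremes in either direction are meaningful (doubled smaller tail).
# magnitude: region-level evaluation uses |value| (iHS sign is allele-polarity
# dependent; the magnitude is what marks a sweep). Configurable.
fst:
  tail: upper
  provenance: computed
ihs:
  tail: upper
  provenance: computed
  magnitude: true
xpehh:
  tail: upper
  provenance: computed
ies:
  tail: upper
  provenance: computed
beta:
  tail: upper
  provenance: computed
alignment_block_age:
  tail: two_sided
  provenance: computed
phastcons:
  tail: upper
  provenance: ingested
gerp:
  tail: upper
  provenance: ingested
linsight:
  tail: upper
  provenance: ingested
phylop:
  tail: two_sided
  provenance: ingested
tmrca:
  tail: two_sided
  provenance: ingested
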