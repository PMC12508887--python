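# Demo pipeline configuration: synthetic bacteriocyte phantom end-to-end.
seed: 42
output: mqa_demo_out
phantom:
  preset: bacteriocyte
  snr: 30
preprocess:
  stage_order: [crr, baseline, sg]
cluster:
  k: 5
  n_pcs: 10
quantify:
  internal_standard: {center: 1341, half_width: 8, label: threonine}
  windows:
    glycogen: {center: 484, half_width: 8}
    nadh: {center: 1114, half_width: 8}
    squalene: {center: 1666, half_width: 8}
    lanosterol: {center: 1643, half_width: 8}
    cholesterol: {center: 1083, half_width: 8}
    glucose: {center: 1127, half_width: 8}
    tryptophan: {center: 1557, half_width: 8}
  local_baseline: false
group_tag: demo
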