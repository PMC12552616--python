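# (AG)6(AG-G137C): sensing cysteine moved to 137, next to the narrowest part
# of the barrel; diastereomer pairs resolved for all straight-chain aldehydes
# (splits 0.4-1.6%).  Anchored on printed values: butanal diastereomer B
# 95.9%, pentanal diastereomer A 95.8%, and the isomer separation between
# diastereomers B of butanal and 2-methylpropanal, 0.25%.
pore:
  name: (AG)6(AG-G137C)
  open_current_pa: -129.0
  potential_mv: -50.0
  rms_noise_pa: 1.0
  level_jitter_pct: 0.05
  provenance: {level_jitter_pct: derived, open_current_pa: interpolated, potential_mv: printed, rms_noise_pa: interpolated}
analytes:
  - name: ethanal
    khyd: 1.20
    k_on_obs: 0.250
    diastereomers:
      - {label: A, ires_pct: 98.50, k_off: 9.4, fraction: 0.5}
      - {label: B, ires_pct: 98.10, k_off: 9.4, fraction: 0.5}
    provenance: {khyd: interpolated, k_on_obs: interpolated, ires_pct: interpolated, k_off: printed}
  - name: propanal
    khyd: 0.70
    k_on_obs: 0.294
    diastereomers:
      - {label: A, ires_pct: 97.80, k_off: 8.8, fraction: 0.5}
      - {label: B, ires_pct: 97.20, k_off: 8.8, fraction: 0.5}
    provenance: {khyd: interpolated, k_on_obs: derived, ires_pct: interpolated, k_off: interpolated}
  - name: 2-methylpropanal
    khyd: 0.45
    k_on_obs: 0.320
    diastereomers:
      - {label: A, ires_pct: 96.85, k_off: 8.0, fraction: 0.5}
      - {label: B, ires_pct: 96.15, k_off: 8.0, fraction: 0.5}
    provenance: {khyd: interpolated, k_on_obs: interpolated, ires_pct: derived, k_off: interpolated}
  - name: butanal
    khyd: 0.48
    k_on_obs: 0.310
    diastereomers:
      - {label: A, ires_pct: 96.70, k_off: 7.6923, fraction: 0.5}
      - {label: B, ires_pct: 95.90, k_off: 7.6923, fraction: 0.5}
    provenance: {khyd: interpolated, k_on_obs: derived, ires_pct: printed, k_off: derived}
  - name: pentanal
    khyd: 0.45
    k_on_obs: 0.290
    diastereomers:
      - {label: A, ires_pct: 95.80, k_off: 6.5, fraction: 0.5}
      - {label: B, ires_pct: 94.80, k_off: 6.5, fraction: 0.5}
    provenance: {khyd: interpolated, k_on_obs: interpolated, ires_pct: printed, k_off: interpolated}
  - name: hexanal
    khyd: 0.45
    k_on_obs: 0.248
    diastereomers:
      - {label: A, ires_pct: 94.75, k_off: 5.0, fraction: 0.5}
      - {label: B, ires_pct: 93.55, k_off: 5.0, fraction: 0.5}
    provenance: {khyd: interpolated, k_on_obs: interpolated, ires_pct: interpolated, k_off: printed}
  - name: heptanal
    khyd: 0.42
    k_on_obs: 0.210
    diastereomers:
      - {label: A, ires_pct: 93.80, k_off: 5.0, fraction: 0.5}
      - {label: B, ires_pct: 92.40, k_off: 5.0, fraction: 0.5}
    provenance: {khyd: interpolated, k_on_obs: interpolated, ires_pct: interpolated, k_off: printed}
  - name: octanal
    khyd: 0.40
    k_on_obs: 0.200
    diastereomers:
      - {label: A, ires_pct: 92.80, k_off: 5.0, fraction: 0.5}
      - {label: B, ires_pct: 91.20, k_off: 5.0, fraction: 0.5}
    provenance: {khyd: interpolated, k_on_obs: interpolated, ires_pct: interpolated, k_off: printed}
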