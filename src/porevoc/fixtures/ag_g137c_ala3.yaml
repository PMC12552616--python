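# (AG)6(AG-G137C-Ala3): AG-G137C with N121A/N123A/N139A around the sensing
# site to reduce steric hindrance; used for butanal vs 2-methylpropanal chain
# isomer resolution via diastereomers A (printed separation 0.42%).
pore:
  name: (AG)6(AG-G137C-Ala3)
  open_current_pa: -129.0
  potential_mv: -50.0
  rms_noise_pa: 1.0
  level_jitter_pct: 0.05
  provenance: {level_jitter_pct: derived, open_current_pa: interpolated, potential_mv: printed, rms_noise_pa: interpolated}
analytes:
  - name: propanal
    khyd: 0.70
    k_on_obs: 0.294
    diastereomers:
      - {label: A, ires_pct: 97.60, k_off: 8.8, fraction: 0.5}
      - {label: B, ires_pct: 96.90, k_off: 8.8, fraction: 0.5}
    provenance: {khyd: interpolated, k_on_obs: derived, ires_pct: interpolated, k_off: interpolated}
  - name: 2-methylpropanal
    khyd: 0.45
    k_on_obs: 0.320
    diastereomers:
      - {label: A, ires_pct: 96.92, k_off: 8.0, fraction: 0.5}
      - {label: B, ires_pct: 96.10, k_off: 8.0, fraction: 0.5}
    provenance: {khyd: interpolated, k_on_obs: interpolated, ires_pct: derived, k_off: interpolated}
  - name: butanal
    khyd: 0.48
    k_on_obs: 0.310
    diastereomers:
      - {label: A, ires_pct: 96.50, k_off: 7.6923, fraction: 0.5}
      - {label: B, ires_pct: 95.60, k_off: 7.6923, fraction: 0.5}
    provenance: {khyd: interpolated, k_on_obs: derived, ires_pct: interpolated, k_off: derived}
  - name: pentanal
    khyd: 0.45
    k_on_obs: 0.290
    diastereomers:
      - {label: A, ires_pct: 95.50, k_off: 6.5, fraction: 0.5}
      - {label: B, ires_pct: 94.40, k_off: 6.5, fraction: 0.5}
    provenance: {khyd: interpolated, k_on_obs: interpolated, ires_pct: interpolated, k_off: interpolated}
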