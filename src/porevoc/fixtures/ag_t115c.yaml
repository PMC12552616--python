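# (AG)6(AG-T115C): reference aldehyde-sensing pore.
# AG = aHL-K8A-M113G-K131G-K147G with one cysteine-bearing subunit at 115.
# Per-number provenance: "printed" = stated in the main text, "interpolated" =
# filled in (e.g. by the ~0.7%/CH2 level rule or typical hydration constants),
# "derived" = computed from printed quantities (e.g. butanal k_off = 1/0.130 s).
pore:
  name: (AG)6(AG-T115C)
  open_current_pa: -129.0
  potential_mv: -50.0
  rms_noise_pa: 1.0
  level_jitter_pct: 0.05
  provenance: {level_jitter_pct: derived, open_current_pa: printed, potential_mv: printed, rms_noise_pa: interpolated}
analytes:
  - name: ethanal
    khyd: 1.20
    k_on_obs: 0.250
    diastereomers:
      - {label: A, ires_pct: 99.4, k_off: 9.4, fraction: 1.0}
    provenance: {khyd: interpolated, k_on_obs: interpolated, ires_pct: interpolated, k_off: printed}
  - name: propanal
    khyd: 0.70
    k_on_obs: 0.294
    diastereomers:
      - {label: A, ires_pct: 98.7, k_off: 8.8, fraction: 1.0}
    provenance: {khyd: interpolated, k_on_obs: derived, ires_pct: printed, k_off: interpolated}
  - name: 2-methylpropanal
    khyd: 0.45
    k_on_obs: 0.320
    diastereomers:
      - {label: A, ires_pct: 98.1, k_off: 8.0, fraction: 1.0}
    provenance: {khyd: interpolated, k_on_obs: interpolated, ires_pct: printed, k_off: interpolated}
  - name: butanal
    khyd: 0.48
    k_on_obs: 0.310
    diastereomers:
      - {label: A, ires_pct: 97.9, k_off: 7.6923, fraction: 1.0}
    provenance: {khyd: interpolated, k_on_obs: derived, ires_pct: printed, k_off: derived}
  - name: benzaldehyde
    khyd: 0.01
    k_on_obs: 0.420
    diastereomers:
      - {label: A, ires_pct: 97.5, k_off: 6.0, fraction: 1.0}
    provenance: {khyd: interpolated, k_on_obs: interpolated, ires_pct: printed, k_off: interpolated}
  - name: pentanal
    khyd: 0.45
    k_on_obs: 0.290
    diastereomers:
      - {label: A, ires_pct: 97.0, k_off: 6.5, fraction: 1.0}
    provenance: {khyd: interpolated, k_on_obs: interpolated, ires_pct: interpolated, k_off: interpolated}
  - name: phenylacetaldehyde
    khyd: 0.35
    k_on_obs: 0.280
    diastereomers:
      - {label: A, ires_pct: 96.6, k_off: 5.5, fraction: 1.0}
    provenance: {khyd: interpolated, k_on_obs: interpolated, ires_pct: printed, k_off: interpolated}
  - name: hexanal
    khyd: 0.45
    k_on_obs: 0.248
    diastereomers:
      - {label: A, ires_pct: 96.1, k_off: 5.0, fraction: 1.0}
    provenance: {khyd: interpolated, k_on_obs: interpolated, ires_pct: printed, k_off: printed}
  - name: heptanal
    khyd: 0.42
    k_on_obs: 0.210
    diastereomers:
      - {label: A, ires_pct: 95.69, k_off: 5.0, fraction: 0.5}
      - {label: B, ires_pct: 95.40, k_off: 5.0, fraction: 0.5}
    provenance: {khyd: interpolated, k_on_obs: interpolated, ires_pct: derived, k_off: printed}
  - name: octanal
    khyd: 0.40
    k_on_obs: 0.200
    diastereomers:
      - {label: A, ires_pct: 95.00, k_off: 5.0, fraction: 0.5}
      - {label: B, ires_pct: 94.61, k_off: 5.0, fraction: 0.5}
    provenance: {khyd: interpolated, k_on_obs: interpolated, ires_pct: derived, k_off: printed}
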