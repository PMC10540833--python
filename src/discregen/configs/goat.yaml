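# Goat lumbar (L3-4) disc parameters. See rat.yaml for the source vocabulary.
species: goat
geometry:
  # NP height tuned so a 1e6-cell dose is 30.0% of the healthy NP population
  # (printed anchor; 5.5e6 then gives 165%).
  np_semi_lateral: {value: 7.5, units: mm, source: derived}
  np_semi_ap: {value: 5.5, units: mm, source: derived}
  af_semi_lateral: {value: 12.0, units: mm, source: derived}
  af_semi_ap: {value: 9.0, units: mm, source: derived}
  height: {value: 4.2873, units: mm, source: derived}
diffusion:
  np:
    glucose: {axial: 1.22, radial: 1.22, units: mm^2/h, source: table1}
    oxygen: {axial: 5.0, radial: 5.0, units: mm^2/h, source: table1}
    lactate: {axial: 1.62, radial: 1.62, units: mm^2/h, source: table1}
  af:
    glucose: {axial: 0.7, radial: 0.52, units: mm^2/h, source: table1}
    oxygen: {axial: 3.78, radial: 3.78, units: mm^2/h, source: table1}
    lactate: {axial: 1.2, radial: 1.2, units: mm^2/h, source: table1}
metabolic_rates:
  np:
    vmax_o2: {value: 8.0, units: nmol/10^6 cells/h, source: derived}
    lpr: {value: 55.0, units: nmol/10^6 cells/h, source: derived}
    km_o2: {value: 3.8, units: uM, source: literature}
  af:
    vmax_o2: {value: 12.0, units: nmol/10^6 cells/h, source: derived}
    lpr: {value: 60.0, units: nmol/10^6 cells/h, source: derived}
    km_o2: {value: 3.8, units: uM, source: literature}
cell_densities:
  np: {value: 6.0e3, units: cells/mm^3, source: measured}
  af: {value: 16.0e3, units: cells/mm^3, source: measured}
gag:
  native_content_dw: {np: 335.0, af: 95.0, units: ug/mg DW, source: table2}
  degenerated_content_vol: {np: 47.4, af: 26.9, units: ug/mm^3, source: table2}
  synthesis_rate: {value: 9.08, units: pg/cell/day, source: table2}
  half_life: {value: 11.0, units: years, source: table2}
  dw_conversion: {value: 0.283, units: mg DW/mm^3, source: derived}
  # native NP content per volume: 335 x 0.283
  reference_content_vol: {value: 94.805, units: ug/mm^3, source: derived}
boundaries:
  # calibrated against the printed central targets (1.4 mM glucose, pH 6.9,
  # 2% O2 at the L3-4 center); see analysis/03.
  periannular:
    glucose: {value: 2.135, units: mM, source: calibrated}
    oxygen: {value: 68.93, units: uM, source: calibrated}
    ph: {value: 7.030, units: pH, source: calibrated}
  np_cep_interface:
    glucose: {value: 1.660, units: mM, source: calibrated}
    oxygen: {value: 54.16, units: uM, source: calibrated}
    ph: {value: 6.930, units: pH, source: calibrated}
oxygen_solubility: {value: 10.5, units: uM/%O2, source: literature}
ph_coupling:
  reference_lactate: {value: 1.0, units: mM, source: literature}
  reference_ph: {value: 7.35, units: pH, source: calibrated}
  sensitivity: {value: 0.08, units: pH/mM, source: literature}
lactate_glucose_ratio: {value: 2.0, units: mol/mol, source: literature}
glucose_km: {value: 0.5, units: mM, source: literature}
injury:
  # chondroitinase ABC: 50% GAG loss, 50% cellularity loss in the NP
  gag_reduction: {value: 0.5, units: fraction, source: measured}
  cellularity_reduction: {value: 0.5, units: fraction, source: literature}
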