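# Rat caudal (Cd7-8) disc parameters, canonical-ish units with provenance.
# sources: table1/table2 = transcribed tables; measured = quantified in the
# originating study; derived = back-computed or tuned to printed anchors;
# literature = external values; calibrated = produced by boundary calibration.
species: rat
geometry:
  # idealized elliptic cylinder; NP height tuned so the 25k-cell dose is 3.0%
  # of the healthy NP population (printed anchor); flat endplates.
  np_semi_lateral: {value: 1.7, units: mm, source: derived}
  np_semi_ap: {value: 1.7, units: mm, source: derived}
  af_semi_lateral: {value: 2.2, units: mm, source: derived}
  af_semi_ap: {value: 2.2, units: mm, source: derived}
  height: {value: 0.9765, units: mm, source: derived}
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
  # OCR/LPR magnitudes are shown only as bar charts in the source study;
  # these defaults respect the printed orderings (rat NP LPR highest of all
  # NP cells; AF OCR > NP OCR within animal species).
  np:
    vmax_o2: {value: 10.0, units: nmol/10^6 cells/h, source: derived}
    lpr: {value: 90.0, units: nmol/10^6 cells/h, source: derived}
    km_o2: {value: 3.8, units: uM, source: literature}
  af:
    vmax_o2: {value: 12.0, units: nmol/10^6 cells/h, source: derived}
    lpr: {value: 60.0, units: nmol/10^6 cells/h, source: derived}
    km_o2: {value: 3.8, units: uM, source: literature}
cell_densities:
  np: {value: 94.0e3, units: cells/mm^3, source: measured}
  af: {value: 93.0e3, units: cells/mm^3, source: measured}
gag:
  native_content_dw: {np: 95.2, af: 37.5, units: ug/mg DW, source: table2}
  degenerated_content_vol: {np: 0.0, af: 10.6, units: ug/mm^3, source: table2}
  synthesis_rate: {value: 6.19, units: pg/cell/day, source: table2}
  half_life: {value: 11.0, units: years, source: table2}
  # back-computed from the rat AF / goat rows of the degenerated-content table
  dw_conversion: {value: 0.283, units: mg DW/mm^3, source: derived}
  # native NP content per volume: 95.2 ug/mg DW x 0.283 mg DW/mm^3
  reference_content_vol: {value: 26.9416, units: ug/mm^3, source: derived}
boundaries:
  # produced by calibrate_boundaries against the printed central targets
  # (2 mM glucose, pH 6.9, 1.5% O2 at the Cd7-8 center); see analysis/03.
  periannular:
    glucose: {value: 2.967, units: mM, source: calibrated}
    oxygen: {value: 59.67, units: uM, source: calibrated}
    ph: {value: 7.039, units: pH, source: calibrated}
  np_cep_interface:
    glucose: {value: 2.332, units: mM, source: calibrated}
    oxygen: {value: 46.40, units: uM, source: calibrated}
    ph: {value: 6.939, units: pH, source: calibrated}
oxygen_solubility: {value: 10.5, units: uM/%O2, source: literature}
ph_coupling:
  reference_lactate: {value: 1.0, units: mM, source: literature}
  reference_ph: {value: 7.35, units: pH, source: calibrated}
  sensitivity: {value: 0.08, units: pH/mM, source: literature}
lactate_glucose_ratio: {value: 2.0, units: mol/mol, source: literature}
glucose_km: {value: 0.5, units: mM, source: literature}
injury:
  # needle puncture: complete GAG loss, 75% cellularity loss in the NP
  gag_reduction: {value: 1.0, units: fraction, source: measured}
  cellularity_reduction: {value: 0.75, units: fraction, source: literature}
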