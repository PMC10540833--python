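# Human lumbar (L4-5) disc at Grade III degeneration.
# The simulated initial state IS Grade III (degenerated_content_vol and the
# configured densities); no further injury is applied. Trajectories are
# normalized to the Grade II NP content. See rat.yaml for source vocabulary.
species: human_grade3
geometry:
  # NP height tuned so NP volume = 12 x goat NP volume (printed scale anchor;
  # also ~800 x rat NP volume).
  np_semi_lateral: {value: 16.5, units: mm, source: derived}
  np_semi_ap: {value: 12.3, units: mm, source: derived}
  af_semi_lateral: {value: 25.0, units: mm, source: derived}
  af_semi_ap: {value: 18.5, units: mm, source: derived}
  height: {value: 10.4561, units: mm, source: derived}
diffusion:
  np:
    glucose: {axial: 1.17, radial: 1.17, units: mm^2/h, source: table1}
    oxygen: {axial: 4.81, radial: 4.81, units: mm^2/h, source: table1}
    lactate: {axial: 1.56, radial: 1.56, units: mm^2/h, source: table1}
  af:
    glucose: {axial: 0.45, radial: 0.37, units: mm^2/h, source: table1}
    oxygen: {axial: 3.08, radial: 2.20, units: mm^2/h, source: table1}
    lactate: {axial: 0.61, radial: 0.50, units: mm^2/h, source: table1}
metabolic_rates:
  # human NP OCR lowest across species (printed ordering)
  np:
    vmax_o2: {value: 5.0, units: nmol/10^6 cells/h, source: derived}
    lpr: {value: 50.0, units: nmol/10^6 cells/h, source: derived}
    km_o2: {value: 3.8, units: uM, source: literature}
  af:
    vmax_o2: {value: 8.0, units: nmol/10^6 cells/h, source: derived}
    lpr: {value: 55.0, units: nmol/10^6 cells/h, source: derived}
    km_o2: {value: 3.8, units: uM, source: literature}
cell_densities:
  # Grade III densities from literature (not quantified in the source study);
  # NP value consistent with "goat has a 4-fold higher NP density than human"
  # and the 1-40M = ~10-383% dose-fraction anchors.
  np: {value: 1.4e3, units: cells/mm^3, source: literature}
  af: {value: 5.0e3, units: cells/mm^3, source: literature}
  dose_reference: {value: 1.4e3, units: cells/mm^3, source: literature}
gag:
  # native = Grade II tissue; degenerated = Grade III tissue (both literature)
  native_content_dw: {np: 537.8, af: 153.0, units: ug/mg DW, source: table2}
  degenerated_content_vol: {np: 80.7, af: 30.3, units: ug/mm^3, source: table2}
  synthesis_rate: {value: 8.48, units: pg/cell/day, source: table2}
  half_life: {value: 11.0, units: years, source: table2}
  dw_conversion: {value: 0.283, units: mg DW/mm^3, source: literature}
  # Grade II NP content per volume: 537.8 x 0.283 (normalization reference)
  reference_content_vol: {value: 152.1974, units: ug/mm^3, source: derived}
boundaries:
  # no intradiscal probe data exist for human; plasma-derived periannular
  # values with CEP-attenuated NP interface values from prior disc models
  periannular:
    glucose: {value: 4.5, units: mM, source: literature}
    oxygen: {value: 58.0, units: uM, source: literature}
    ph: {value: 7.35, units: pH, source: literature}
  np_cep_interface:
    glucose: {value: 3.5, units: mM, source: literature}
    oxygen: {value: 45.0, units: uM, source: literature}
    ph: {value: 7.25, units: pH, source: literature}
oxygen_solubility: {value: 10.5, units: uM/%O2, source: literature}
ph_coupling:
  reference_lactate: {value: 1.0, units: mM, source: literature}
  reference_ph: {value: 7.35, units: pH, source: literature}
  sensitivity: {value: 0.08, units: pH/mM, source: literature}
lactate_glucose_ratio: {value: 2.0, units: mol/mol, source: literature}
glucose_km: {value: 0.5, units: mM, source: literature}
injury:
  # Grade III is encoded directly in the initial state; no extra injury step
  gag_reduction: {value: 0.0, units: fraction, source: derived}
  cellularity_reduction: {value: 0.0, units: fraction, source: derived}
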