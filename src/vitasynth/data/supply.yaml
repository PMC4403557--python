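# Constants for the microbiota-to-host vitamin supply model.
#
# cell: the colonic bacterial biomass model.  n_cells is the assumed number
# of bacterial cells in the colonic space; cell_dry_mass and cell_volume are
# E. coli reference values; dead_fraction is the measured fraction of dead
# (lysed, hence vitamin-releasing) cells in fecal matter; growth_rate is the
# anaerobic E. coli growth rate used to integrate per-hour production rates.
#
# vitamins: per-vitamin supply parameters.
#   conc_mmol_per_gdw  canonical intracellular concentration (mmol/gDW)
#   dri_mg_per_day     dietary reference intake, averaged male/female 19-50
#   hgm_producer_ratio predicted fraction of gut-microbiome producers
#   molar_mass_g_per_mol  molar mass of the measured chemical form (ChEBI);
#                      derivative forms where noted in molar_mass_form
#
# measurements: literature intracellular measurements in their original
# units, convertible to mmol/gDW with to_mmol_per_gdw.  Units:
#   molar                     mol/L of cell volume
#   mass_per_volume           g/L of cell volume (needs molar mass)
#   molecules_per_cell        molecules per cell
#   mass_per_gDW              g per g dry weight (needs molar mass)
#   production_rate_per_mgDW  mol h^-1 mgDW^-1 (needs growth rate)
# The pantothenate measurement is an upper bound (< 1 uM); the supply model
# is a maximal estimate throughout, so the bound is used as the value.

avogadro: 6.02214e+23

cell:
  n_cells: 1.0e+14
  cell_dry_mass: 4.89e-13
  dead_fraction: 0.317
  cell_volume: 1.1e-15
  growth_rate: 0.26

vitamins:
  biotin:
    conc_mmol_per_gdw: 9.0e-7
    dri_mg_per_day: 0.03
    hgm_producer_ratio: 0.40
    molar_mass_g_per_mol: 244.31
    molar_mass_form: biotin
  cobalamin:
    conc_mmol_per_gdw: 8.5e-8
    dri_mg_per_day: 0.0024
    hgm_producer_ratio: 0.42
    molar_mass_g_per_mol: 1329.35
    molar_mass_form: cobalamin
  folate:
    conc_mmol_per_gdw: 5.0e-5
    dri_mg_per_day: 0.4
    hgm_producer_ratio: 0.43
    molar_mass_g_per_mol: 443.41
    molar_mass_form: dihydrofolic acid
  niacin:
    conc_mmol_per_gdw: 3.3e-3
    dri_mg_per_day: 15.0
    hgm_producer_ratio: 0.63
    molar_mass_g_per_mol: 123.11
    molar_mass_form: nicotinic acid
  pantothenate:
    conc_mmol_per_gdw: 2.3e-6
    dri_mg_per_day: 5.0
    hgm_producer_ratio: 0.51
    molar_mass_g_per_mol: 219.23
    molar_mass_form: pantothenic acid
  pyridoxine:
    conc_mmol_per_gdw: 5.8e-4
    dri_mg_per_day: 1.3
    hgm_producer_ratio: 0.50
    molar_mass_g_per_mol: 249.16
    molar_mass_form: pyridoxine 5'-phosphate
  riboflavin:
    conc_mmol_per_gdw: 9.0e-6
    dri_mg_per_day: 1.2
    hgm_producer_ratio: 0.65
    molar_mass_g_per_mol: 376.36
    molar_mass_form: riboflavin
  thiamin:
    conc_mmol_per_gdw: 8.7e-6
    dri_mg_per_day: 1.15
    hgm_producer_ratio: 0.56
    molar_mass_g_per_mol: 345.3
    molar_mass_form: thiamine monophosphate

measurements:
  biotin:
    value: 4.0e-5
    unit: molar
    organism: "Escherichia coli"
  cobalamin:
    value: 5.0e-5
    unit: mass_per_volume
    organism: "Lactobacillus reuteri CE"
  riboflavin:
    value: 4.0e-6
    unit: molar
    organism: "Escherichia coli"
  folate:
    value: 2.2e-5
    unit: molar
    organism: "Lactobacillus casei"
  niacin:
    value: 1.12e+6
    unit: molecules_per_cell
    organism: "Escherichia coli"
  pantothenate:
    value: 1.0e-6
    unit: molar
    organism: "Escherichia coli"
  pyridoxine:
    value: 1.5e-10
    unit: production_rate_per_mgDW
    organism: "Escherichia coli"
  thiamin:
    value: 3.0e-6
    unit: mass_per_gDW
    organism: "Lactobacillus fermenti"
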