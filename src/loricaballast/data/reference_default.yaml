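# Default particle mass reference for tintinnid lorica ballast accounting.
#
# Coccolith per-lith CaCO3 masses (pg) follow published coccolith weight
# estimates; diatom fragment biovolumes (um3) are characteristic values for
# the fragment classes seen on loricae. Copy and edit this file, then pass
# it via --reference, to run sensitivity analyses.
coccoliths:
  Emiliania:
    lith_mass: 4
    lith_size: [3, 4]
    shape_class: placolith-ellipsoidal
    source: ellipsoidal liths 3-4 um long; morphotypes not discriminated
  Gladiolithus:
    lith_mass: 4
    lith_size: null
    shape_class: lath-like
    source: deep-photic lath-like liths
  Syracosphaera:
    lith_mass: 10
    lith_size: [4, 5.6]
    shape_class: placolith-ellipsoidal
    source: ellipsoidal liths up to 5.6 um long
  Umbilicosphaera:
    lith_mass: 16
    lith_size: null
    shape_class: placolith-discoidal
    source: circular placoliths
  Florisphaera:
    lith_mass: 20
    lith_size: null
    shape_class: lath-like
    source: polygonal deep-photic liths
  Rhabdosphaera:
    lith_mass: 60
    lith_size: [8, 12]
    shape_class: prolate-rhabdolith
    source: prolate rhabdoliths up to 12 um long
  Calcidiscus:
    lith_mass: 124
    lith_size: [9, 9]
    shape_class: placolith-discoidal
    source: discoidal liths 9 um diameter
  Helicosphaera:
    lith_mass: 140
    lith_size: [6, 12]
    shape_class: placolith-ellipsoidal
    source: helical-flanged liths 6-12 um long
  Coccolithus:
    lith_mass: 152
    lith_size: [6, 7.8]
    shape_class: placolith-ellipsoidal
    source: placoliths up to 7.8 um long
diatom_particles:
  Pseudo-nitzschia/fragment: {biovolume: 25}
  Chaetoceros/fragment: {biovolume: 40}
  Fragilariopsis/fragment: {biovolume: 63}
  Thalassiothrix/fragment: {biovolume: 100}
  Eucampia/fragment: {biovolume: 250}
  Coscinodiscus/fragment: {biovolume: 375}
  Fragilariopsis pseudonana/whole_cell: {biovolume: 100}
constants:
  si_pmol_per_um3: 0.0005
  si_pg_per_pmol: 28
  lorica_dry_weight: 40000
  lorica_dry_weight_sd: 20000
# Taxa observed on loricae without a published per-lith mass, mapped to a
# morphologically analogous taxon. Umbellosphaera and Calciosolenia are
# deliberately absent: record their contributions directly as mass_pg.
aliases:
  Gephyrocapsa: Emiliania
  Coronosphaera: Syracosphaera
  Alisphaera: Emiliania
  Syracosphaera mediterranea: Syracosphaera
  Gephyrocapsa oceanica: Emiliania
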