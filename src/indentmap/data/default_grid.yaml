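# Default 31-site femoral-condyle testing grid.
# Layout (two anterior->posterior columns per condyle, 0.15 mm pitch)
# and the anterior/posterior split are declared package defaults;
# the analysis uses only site labels and per-site surface angles.
sites:
- site_id: L1
  condyle: lateral
  subregion: anterior
  x_mm: -0.6
  y_mm: -0.0
- site_id: L2
  condyle: lateral
  subregion: anterior
  x_mm: -0.45
  y_mm: -0.0
- site_id: L3
  condyle: lateral
  subregion: anterior
  x_mm: -0.6
  y_mm: -0.15
- site_id: L4
  condyle: lateral
  subregion: anterior
  x_mm: -0.45
  y_mm: -0.15
- site_id: L5
  condyle: lateral
  subregion: anterior
  x_mm: -0.6
  y_mm: -0.3
- site_id: L6
  condyle: lateral
  subregion: anterior
  x_mm: -0.45
  y_mm: -0.3
- site_id: L7
  condyle: lateral
  subregion: anterior
  x_mm: -0.6
  y_mm: -0.45
- site_id: L8
  condyle: lateral
  subregion: posterior
  x_mm: -0.45
  y_mm: -0.45
- site_id: L9
  condyle: lateral
  subregion: posterior
  x_mm: -0.6
  y_mm: -0.6
- site_id: L10
  condyle: lateral
  subregion: posterior
  x_mm: -0.45
  y_mm: -0.6
- site_id: L11
  condyle: lateral
  subregion: posterior
  x_mm: -0.6
  y_mm: -0.75
- site_id: L12
  condyle: lateral
  subregion: posterior
  x_mm: -0.45
  y_mm: -0.75
- site_id: L13
  condyle: lateral
  subregion: posterior
  x_mm: -0.6
  y_mm: -0.9
- site_id: L14
  condyle: lateral
  subregion: posterior
  x_mm: -0.45
  y_mm: -0.9
- site_id: M1
  condyle: medial
  subregion: anterior
  x_mm: 0.45
  y_mm: -0.0
- site_id: M2
  condyle: medial
  subregion: anterior
  x_mm: 0.6
  y_mm: -0.0
- site_id: M3
  condyle: medial
  subregion: anterior
  x_mm: 0.45
  y_mm: -0.15
- site_id: M4
  condyle: medial
  subregion: anterior
  x_mm: 0.6
  y_mm: -0.15
- site_id: M5
  condyle: medial
  subregion: anterior
  x_mm: 0.45
  y_mm: -0.3
- site_id: M6
  condyle: medial
  subregion: anterior
  x_mm: 0.6
  y_mm: -0.3
- site_id: M7
  condyle: medial
  subregion: anterior
  x_mm: 0.45
  y_mm: -0.45
- site_id: M8
  condyle: medial
  subregion: anterior
  x_mm: 0.6
  y_mm: -0.45
- site_id: M9
  condyle: medial
  subregion: posterior
  x_mm: 0.45
  y_mm: -0.6
- site_id: M10
  condyle: medial
  subregion: posterior
  x_mm: 0.6
  y_mm: -0.6
- site_id: M11
  condyle: medial
  subregion: posterior
  x_mm: 0.45
  y_mm: -0.75
- site_id: M12
  condyle: medial
  subregion: posterior
  x_mm: 0.6
  y_mm: -0.75
- site_id: M13
  condyle: medial
  subregion: posterior
  x_mm: 0.45
  y_mm: -0.9
- site_id: M14
  condyle: medial
  subregion: posterior
  x_mm: 0.6
  y_mm: -0.9
- site_id: M15
  condyle: medial
  subregion: posterior
  x_mm: 0.45
  y_mm: -1.05
- site_id: M16
  condyle: medial
  subregion: posterior
  x_mm: 0.6
  y_mm: -1.05
- site_id: M17
  condyle: medial
  subregion: posterior
  x_mm: 0.45
  y_mm: -1.2
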