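# Synthetic stand-in for a 28 -> 20 mm tapered main body
# (Endurant ENBF-28-20-class). Heights/peak counts/gaps are plausible
# values for this parametric family, not manufacturer data.
name: synthetic_main_body_28_20
launcher_diameter: 6.0
inter_stent_gap: 2.0
stents:
  - {n_peaks: 5, height: 14.0, diameter_proximal: 28.0, diameter_distal: 28.0, axial_position: 0.0}
  - {n_peaks: 5, height: 14.0, diameter_proximal: 28.0, diameter_distal: 27.0, axial_position: 16.0}
  - {n_peaks: 5, height: 14.0, diameter_proximal: 26.0, diameter_distal: 25.0, axial_position: 32.0}
  - {n_peaks: 5, height: 14.0, diameter_proximal: 24.0, diameter_distal: 23.0, axial_position: 48.0}
  - {n_peaks: 5, height: 14.0, diameter_proximal: 22.0, diameter_distal: 21.0, axial_position: 64.0}
  - {n_peaks: 5, height: 14.0, diameter_proximal: 20.0, diameter_distal: 20.0, axial_position: 80.0}
fenestrations: []
markers: []
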