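# Synthetic stand-in for a fenestrated 28 mm main body: the proximal stent
# carries right-renal, mesenteric and left-renal fenestrations with
# radiopaque markers (auto-placed at each rim centroid and rim top).
# Geometry is plausible for this parametric family, not manufacturer data.
name: synthetic_fenestrated_28
launcher_diameter: 6.0
inter_stent_gap: 2.0
stents:
  - {n_peaks: 5, height: 16.0, diameter_proximal: 28.0, diameter_distal: 28.0, axial_position: 0.0}
  - {n_peaks: 5, height: 14.0, diameter_proximal: 28.0, diameter_distal: 27.0, axial_position: 17.0}
  - {n_peaks: 5, height: 14.0, diameter_proximal: 26.0, diameter_distal: 24.0, axial_position: 33.0}
  - {n_peaks: 5, height: 14.0, diameter_proximal: 23.0, diameter_distal: 21.0, axial_position: 49.0}
  - {n_peaks: 5, height: 14.0, diameter_proximal: 20.0, diameter_distal: 19.0, axial_position: 65.0}
fenestrations:
  - {stent: 0, angle_deg: -75.0, axial_offset: -2.0, radius: 3.0}   # right renal
  - {stent: 0, angle_deg: 0.0, axial_offset: 3.0, radius: 3.0}      # mesenteric
  - {stent: 0, angle_deg: 70.0, axial_offset: -1.0, radius: 3.0}    # left renal
markers: auto
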