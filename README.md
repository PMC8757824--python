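# fmvsd — fast virtual stent-graft deployment from a single X-ray view

During fenestrated endovascular aneurysm repair (FEVAR), a fabric-covered
lattice of Z-shaped wire stents is deployed inside the abdominal aorta,
and its fenestrations must end up facing the renal and mesenteric ostia.
The operator usually sees only 2D fluoroscopy from a mobile C-arm; this
package reconstructs the *3D* deployed configuration of the device from a
single calibrated X-ray image, the registered vessel geometry, and the
device specification — fast enough to be useful during the intervention.
It is aimed at researchers in image-guided cardiovascular simulation who
need a desk-scale, fully synthetic-testable implementation of the
two-stage hybrid method: image constraints + corotational beam finite
elements.

## Method in brief

**Stage 1 (global, sub-second).** The device is reduced to its
centerline: one corotational beam per stent (E = 10 MPa, ν = 0.3),
neighbours coupled in translation but free in rotation. Each beam midpoint
is tethered to the back-projection ray of its stent's observed 2D
barycenter; wall contact keeps the chain inside the artery. After
relaxation, each stent is reconstructed geometrically around its new
barycenter **B**₃D: every rest-cloud vector **V** is scaled radially by
the measured/nominal deployment-diameter ratio, interpolated linearly
proximal → distal.

**Stage 2 (per stent, seconds to minutes).** The axial rotation Φ is
recovered by differential evolution on d(Φ), the mean nearest-neighbour
pixel distance between the projected stent and the target pixel set —
modulo the periodic angle θ = 2π/n_peaks for plain Z-stents, or uniquely
via the marker-only distance d_RM for fenestrated stents with radiopaque
markers. Each stent's full strut model (316L wire, ⌀ 0.125 mm,
corotational Euler–Bernoulli beams on the 12×12 elementary stiffness
**K**) is then crimped to the launcher diameter, released, and relaxed by
dynamic relaxation inside its rigid *deployment box* — the Boolean
intersection of the back-projection polyhedron of the stent's 2D convex
hull with the vessel volume — under spring-dashpot penalty contact.

**Evaluation.** D_B (barycenter distance) and D_PC (directed mean
nearest-neighbour cloud distance) per stent, plus fenestration centroid
distances; quality classes: excellent < 3 mm, good < 5 mm, insufficient
≥ 5 mm. A seeded synthetic generator supplies vessels, ground-truth
deployments and rendered single-view targets, so the whole chain is
testable without any clinical data.

See `docs/methods.md` for the model, the numerical choices and their
rationale, and what the synthetic validation does and does not show.

## Worked example

Generate a synthetic fenestrated case (vessel STL + centerline, device
YAML, projection JSON, rendered target PNG with per-stent masks, ground
truth) and run the full two-stage method on it:

```sh
fmvsd-synth democase --preset fenestrated --seed 7
fmvsd run democase --seed 7
```

which prints (numbers from this exact invocation):

```
report written to democase/report.json
{
  "D_B": {
    "mean": 0.19537388024647523,
    "std": 0.13204045710325857,
    "max": 0.4032757664945348,
    "min": 0.01733896239337299
  },
  "D_PC": {
    "mean": 0.24011690199285002,
    "std": 0.12020215166047114,
    "max": 0.42034496893454304,
    "min": 0.11855307210915446
  },
  "n_stents": 5
}
```

Every stent's positioning error D_B and combined positioning + deployment
error D_PC is a fraction of a millimetre — *excellent* on the < 3 mm
clinical scale. `democase/report.json` additionally contains the
recovered per-stent rotations (marker-based, hence unique, for the
fenestrated proximal stent; modulo θ = 72° for the plain 5-peak stents),
the measured apparent diameters in mm, and the three fenestration
centroid distances — 0.088, 0.087 and 0.087 mm in this run.
`fmvsd run CASE --stage 1` runs the sub-second global stage alone;
`--stents 0,1` restricts individual deployment to the stents of interest,
as one would intraoperatively.

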