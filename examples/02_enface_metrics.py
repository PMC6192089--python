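"""Enface maps and ETDRS central-subfield metrics for one synthetic eye.

Builds a phantom wide enough to hold the full 1-mm central subfield,
with an intraretinal cyst in the INL and an operator-annotated
disruption zone on the INL/OPL interface. Computes per-layer thickness
and reflectance-ratio metrics, the central subfield thickness (CST),
percent disrupted areas, and the DME classification. Disrupted pixels
are excluded from every metric, so the INL_d percentage is nonzero
while the INL thickness average uses only intact columns.
"""

from octlayers import apply_disruptions, classify_dme, compute_layer_metrics, ScanGeometry
from octlayers.synth import Cyst, DisruptionZone, PhantomSpec, generate_phantom

geometry = ScanGeometry(n_bscans=17, n_ascans=200, n_depth=160)
spec = PhantomSpec(
    geometry=geometry,
    inner_surface_um=120.0,
    noise_sigma=0.05,
    cysts=[Cyst(layer="INL", center=(8.0, 100.0), semi_axes_um=(15.0, 80.0, 100.0))],
    disruption_zones=[DisruptionZone(4, b_start=6, b_end=10, x_start=85, x_end=115)],
)
volume, truth, annotations = generate_phantom(spec, seed=11)
interfaces = apply_disruptions(truth, annotations)

metrics, disruption = compute_layer_metrics(volume, interfaces)

print("central-subfield thickness metrics (um):")
for name in ("NFL_T", "GCLIPL_T", "INL_T", "OPL_T", "ONL_T", "OSL_T"):
    print(f"  {name:<9} {getattr(metrics, name):6.1f}")
print("reflectance ratios (layer / RPE):")
for name in ("NFL_R", "GCLIPL_R", "INL_R", "OPL_R", "ONL_R", "OSL_R"):
    print(f"  {name:<9} {getattr(metrics, name):6.3f}")
print(f"CST = {metrics.CST:.1f} um")
print("percent disrupted area:", disruption.as_dict())
print("DME (male thresholds):", classify_dme(metrics.CST, "male"))
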