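"""Limit of detection and assay feasibility figures.

Computes the LOD response level (blank mean + 3 SD) for the buffer and
serum noise presets, inverts the dose-response model for the LOD
concentration and the molecule count it corresponds to, and prints the
transport/screening/packing numbers that make single-molecule read-out
plausible on a millimetre-scale gate.
"""

from zeptoassay import assay_metrics as am
from zeptoassay import dose_model as dm

for name, noise in am.NOISE_PRESETS.items():
    level = am.lod_response_level(noise)
    print(f"{name:6s} noise ({noise.mean:.1%} +/- {noise.sd:.1%}) -> LOD level {level:.1%}")

model = dm.equal_domain_model(5.92, r_max=0.65)  # 1e11-antibody domains
c_lod = dm.invert_for_lod(model, am.lod_response_level(am.NOISE_PRESETS["serum"]))
n, sd = am.lod_in_molecules(c_lod)
print(f"\nserum LOD on the large-domain model: {c_lod:.1f} zM = {n} +/- {sd} molecules")
n, sd = am.lod_in_molecules(250.0)
print(f"a 250 zM LOD corresponds to {n} +/- {sd} molecules in 100 ul")
n, sd = am.lod_in_molecules(10.0)
print(f"a 10 zM LOD corresponds to  {n} +/- {sd} molecule in 100 ul")

rmsd = am.diffusion_rmsd(4e-11, 600.0)
print(f"\nIgG diffusion RMSD over 10 min: {rmsd * 1e3:.2f} mm (droplet-scale)")
geom = am.sam_geometry_report(am.SamGeometry())
print(f"antibody density: {geom['density_per_um2']:.3g} per um^2")
print(f"chains per antibody footprint: {geom['chains_per_footprint']:.0f}")
print(f"Debye length, 162 mM saline: {am.debye_length(0.162):.2f} nm")
print(f"Debye length, ~9 uM water:   {am.debye_length(9.24e-6):.0f} nm")
print(f"run validation at 6% drift: {am.validate_run(0.06).value}")
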