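"""Simulate and fit a domain-flipping dose-response curve.

Generates a synthetic calibration dataset — one simulated gate incubated
most-dilute-first through a decade dilution series, with single bindings
irreversibly flipping whole monolayer domains and buffer-level control
noise added — then fits the equal-domain model and reports the recovered
saturation response and domain count with standard errors.
"""

from zeptoassay import dose_model as dm
from zeptoassay.assay_metrics import NoiseStats
from zeptoassay.synthetic_data import GeneratorConfig, gen_dose_dataset

truth = dm.equal_domain_model(6, r_max=0.65)
cfg = GeneratorConfig(
    seed=17,
    control_noise=NoiseStats(0.0, 0.01),
    domain_model=truth,
    dilution=(6.67e4, 3.0, 11, 0.0, 100.0),
)
data, _ = gen_dose_dataset(cfg, n_replicates=5)

print("cumulative dose (molecules) vs response:")
for lam, r, s in zip(data.doses, data.responses, data.sigmas):
    print(f"  lambda = {lam:10.3f}   DI/I0 = {r:6.3f} +/- {s:.3f}")

fit = dm.fit_dose_curve(data, parametrization="equal")
print("\n" + fit.report())
lo, hi = fit.conf_interval("n_domains")
print(f"n_domains 95% CI: [{lo:.2f}, {hi:.2f}]   (truth: 6)")
print(f"steepness index R(1)/r_max: {dm.steepness_index(fit.model):.4f}")
# Fewer, larger domains make the curve steeper at single-molecule doses;
# the fitted domain count quantifies that amplification.
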