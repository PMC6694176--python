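"""Fit an environmental exposure distribution to censored residue data.

Generates a synthetic field-crop clothianidin dataset (82 soil samples, ~96%
detections, LOD 0.05 ng/g), fits the four candidate families by censored
maximum likelihood, selects by AIC, bootstraps the parameters, and prints the
exceedance probability of the solitary-bee benchmark.
"""

import nestrisk as nr

cfg = nr.study_like_presets()["fieldcrop_clothianidin"]
ds = nr.gen_residues(cfg)
print(nr.detection_summary(ds).to_string(index=False))

samples = nr.censored_from_residues(ds, analyte="clothianidin", matrix="soil")
fit = nr.select_family(samples)
fit = nr.with_bootstrap(fit, samples, n_iter=1000, seed=1)
names = ", ".join(f"{n}={v:.3f}" for n, v in zip(fit.param_names(), fit.params))
print(f"\nAIC-selected family: {fit.family} ({names}), AIC {fit.aic:.1f}")

# chronic-soil benchmark for the surrogate solitary-bee endpoint (35.88/10)
profile = nr.build_exposure_profile()
benchmark = nr.benchmark_concentration(35.88 / 10, profile.soil_chronic_g)
res = nr.exceedance(fit, benchmark, endpoint_kind="solitary_surrogate")
print(f"benchmark {benchmark:.4f} ng/g -> exceedance "
      f"{res.probability:.1%} (95% CI {res.ci_lo:.1%}-{res.ci_hi:.1%})")
print("\nExceedance is the probability that a random field's soil exceeds the")
print("concentration delivering the lethal benchmark dose; above 5% the risk")
print("is considered unacceptable (less than 95% of the population protected).")
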