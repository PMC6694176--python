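"""Full probabilistic risk assessment over synthetic monitoring scenarios.

Combines the Cucurbita-like synthetic presets into one residue dataset and
runs the whole pipeline: censored fit + AIC selection per analyte, bootstrap,
benchmark conversion for each endpoint kind, and exceedance across both
exposure scenarios and five soil-to-bee translocation fractions.
"""

import nestrisk as nr

presets = nr.study_like_presets()
obs = []
for name in ("cucurbita_clothianidin", "cucurbita_imidacloprid",
             "cucurbita_chlorantraniliprole", "cucurbita_thiamethoxam"):
    obs.extend(nr.gen_residues(presets[name]).observations)
ds = nr.ResidueDataset.from_observations(obs)

results = nr.run_risk_assessment(
    ds, nr.build_exposure_profile(), nr.table1_endpoints(),
    n_boot=500, seed=42,
)

ok = results[~results["status"].str.startswith("not assessed")]
full = ok[ok["translocation"] == 1.0]
print("exceedance at 100% translocation:")
print(full[["analyte", "scenario", "endpoint_kind", "benchmark_ng_g",
            "exceedance", "acceptable"]].to_string(index=False))

refused = results[results["status"].str.startswith("not assessed")]
print(f"\nnot assessed: {', '.join(refused['analyte'])} "
      "(no quantifiable residues, mirroring compounds detected only below LOQ)")
print("\nChronic rows always exceed their acute counterparts (15x smaller")
print("benchmark), and surrogate endpoints exceed honey-bee geomeans (10x")
print("smaller benchmark); 'acceptable' applies the 5% risk threshold.")
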