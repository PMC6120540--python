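"""Subject-specific direct signal control on a synthetic 7T head.

Generates an 8-channel synthetic field model, optimizes the per-pulse RF
shims under the 1 W average / 85 W peak per-channel power limits, and
compares the centre-of-k-space echo homogeneity against quadrature and
static shimming.
"""

from dscflair import (
    DSCConfig,
    PowerModel,
    SynthConfig,
    build_base_train,
    compare_methods,
    dsc_optimize,
    quadrature_solution,
    static_mls_shim,
    synth_fields,
)

train = build_base_train()
pm = PowerModel()
fm = synth_fields(SynthConfig(seed=1, grid_shape=(16, 16, 16)))
print(f"subject: {fm.n_voxels} masked voxels, {fm.n_channels} channels")

sol = dsc_optimize(fm, train, pm, DSCConfig(maxiter=60, max_opt_voxels=150))
print(f"DSC cost {sol.initial_cost:.3g} -> {sol.final_cost:.3g}; "
      f"max avg power {sol.power_report.max_avg:.3f} W, "
      f"max peak {sol.power_report.max_peak:.1f} W")

static = static_mls_shim(fm, train, pm)
df = compare_methods(fm, train, {
    "quadrature": quadrature_solution(train.n_pulses, fm.n_channels),
    "static": static,
    "DSC": sol,
})
print(df[["cov", "p10"]].round(3))
# CoV is the spread of the predicted centre-echo signal over the brain;
# P10 the fraction of voxels within 10% of the ideal target.  DSC should
# cut CoV and raise P10 well above the quadrature and static rows.
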