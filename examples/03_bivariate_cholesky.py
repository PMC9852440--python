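"""Decompose a cross-trait correlation into genetic/environmental parts.

Simulates two traits whose correlation of 0.25 is 88% genetically mediated
(the within-twin cross-trait covariance is 0.22 genetic, 0.03 nonshared
environmental), then recovers that split with a bivariate Cholesky fit.
"""

from twinconfound import (
    TwinSimConfig,
    cross_twin_cross_trait,
    fit_bivariate_cholesky,
    simulate_bivariate_twins,
)

cfg = TwinSimConfig(
    n_mz=20000, n_dz=20000,
    a2=(0.4, 0.4), c2=(0.0, 0.0), e2=(0.6, 0.6),
    rA=0.55, rC=0.0, rE=0.05,
    seed=2, trait_names=("media_use", "mental_health"),
)
pairs = simulate_bivariate_twins(cfg)

mats = cross_twin_cross_trait(pairs, "media_use", "mental_health")
print("cross-twin cross-trait r:  MZ = "
      f"{mats['MZ'].loc['media_use_t1', 'mental_health_t2']:.3f},  DZ = "
      f"{mats['DZ'].loc['media_use_t1', 'mental_health_t2']:.3f}")

paths, dec = fit_bivariate_cholesky(pairs, "media_use", "mental_health", seed=3)
print(f"phenotypic r = {dec.r_ph:.3f}")
print(f"rphA = {dec.prop_a:.2f}, rphC = {dec.prop_c:.2f}, rphE = {dec.prop_e:.2f}")
print(f"genetic correlation rA = {dec.rA:.2f}")

# The MZ cross-twin cross-trait correlation is about twice the DZ one,
# the signature of genetic mediation; rphA ~ 0.88 says 88% of the trait
# correlation travels through shared genetic influences.
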