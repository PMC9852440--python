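"""Simulate a twin cohort and recover its intraclass correlations.

Generates MZ and DZ pairs at the group sizes of a large UK twin register
(~2,900 MZ and ~4,900 DZ pairs) with 43% additive-genetic variance, then
residualises for age/sex, normalises with the van der Waerden transform and
reports the MZ/DZ intraclass correlations that drive every twin model.
"""

from twinconfound import (
    TwinSimConfig,
    intraclass_correlation,
    residualize,
    simulate_univariate_twins,
    vdw_transform,
)

cfg = TwinSimConfig(
    n_mz=2890, n_dz=4879, a2=0.43, c2=0.0, e2=0.57,
    beta_age=0.05, beta_sex=0.1, seed=1,
)
pairs = simulate_univariate_twins(cfg)

for slot in ("1", "2"):
    col = f"trait_{slot}"
    resid = residualize(pairs[col], pairs["age"], pairs[f"sex{slot}"])
    pairs[col] = vdw_transform(resid)

for grp in ("MZ", "DZ"):
    icc = intraclass_correlation(pairs, "trait", grp)
    print(f"{grp}: r = {icc.r:.3f} (95% CI {icc.ci_low:.3f}-{icc.ci_high:.3f}, "
          f"n = {icc.n} pairs)")

# With a2 = 0.43 and no shared environment, the population values are
# rMZ = 0.43 and rDZ = 0.215: MZ co-twins share all genetic influences,
# DZ co-twins half of them.  Sample values differ by Monte Carlo noise.
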