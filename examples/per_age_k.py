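"""Detect slow-growing juveniles and price their environmental k per age.

Some year-classes grow up under worse conditions (colder nursery areas) and
their youngest ages fall below the line fitted to older fish. The detector
drops the youngest ages until the remaining linear fit clears R^2 >= 0.98;
the excluded ages then get an individual k_a = dL_a / (L_max - L_a) against
the shared mean L_max of the core fits.
"""

import growthlaw as gl

spec = gl.SyntheticSpec(
    params=gl.GrowthParams(k=0.3, L_max=354.0),
    n_cohorts=5,
    k_overrides={1: 0.15, 2: 0.15},  # juvenile growth halved at ages 1-2
    noise_sd=1.0,
    seed=7,
)
cohorts = gl.extract_cohorts(gl.generate_table(spec))

det = gl.detect_deviating_ages(cohorts[0])
print(f"cohort {cohorts[0].birth_year}: excluded young ages "
      f"{[int(a) for a in det.excluded_ages]}, "
      f"core fit R^2 = {det.fit.r2:.4f}")

yk = gl.k_by_yearclass(cohorts)
print(f"shared L_max = {yk.shared_L_max:.1f} mm")
print("birth  age   k      source")
for e in yk.estimates[:12]:
    print(f"{e.birth_year}   {e.age}    {e.k:.3f}  {e.source}")
print("...")
print()
print("on-line ages share the cohort's regression slope (k ~ 0.3); off-line")
print("juvenile ages recover the suppressed k ~ 0.15 individually.")
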