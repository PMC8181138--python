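"""Evaluate the age-adjusted rib fracture risk function.

Loads the shipped reference log-normal parameters, evaluates the fracture
risk at a few (strain, age) points, inverts the curve, and reports the
per-decade aging effect.
"""

import ribrisk as rr

params = rr.reference_parameters("lognormal")
print(f"reference model: {params.family.value} "
      f"(alpha={params.alpha}, beta0={params.beta0}, beta1={params.beta1})")

for age in (25, 45, 75):
    risk = rr.fracture_risk(0.02, age, params)
    print(f"risk at 2% true strain, age {age}: {100 * risk:5.1f}%")
# at 0.02 true strain the risk rises from a few percent for a young adult
# to above one-half for a 75-year-old: the age effect dominates.

s50 = rr.strain_at_risk(0.50, 75, params)
print(f"strain giving 50% risk at age 75: {s50:.4f} (true strain)")

factor, reduction = rr.decade_strain_factor(params.beta1)
print(f"decade acceleration factor: {100 * factor:.1f}% "
      f"(failure strain falls {100 * reduction:.1f}% per decade of aging)")
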