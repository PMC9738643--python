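"""Should this patient have gone to surgery?

Evaluates the treat/no-treat decision tree at the pre-surgical posterior
probability of a GI foreign body, using the clinical team's elicited
outcome utilities, and locates the treatment threshold by one-way
sensitivity analysis.
"""

import bayesdca as b

case = b.ferret_case()

p_fb = b.posterior(case.belief("pre-surgical"))["GI Foreign Body"]
decision = b.expected_values(p_fb, case.utilities)

print(b.decision_tree_text(decision, "GI FB", "surgery", "no surgery"))
print()
print(
    f"Treatment threshold: {decision.threshold:.0f}% "
    f"(benefit {case.utilities.benefit:.0f} / harm {case.utilities.harm:.0f})"
)
print(
    f"P(GI FB) = {p_fb:.0f}% is below the threshold, so medical management "
    "was the higher-expected-value choice."
)
print()

# The threshold shifts with whose utilities you use
for k, u in enumerate(case.utilities_experts, start=1):
    print(f"clinician {k}: threshold {b.treatment_threshold(u):.0f}%")
print()

# The sweep's interpolated crossing equals the closed-form threshold
sweep = b.sensitivity_sweep(case.utilities, step=1.0)
print(f"sensitivity-sweep crossing: {sweep.crossing:.1f}%")
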