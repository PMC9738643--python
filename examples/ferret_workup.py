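"""Rank a differential diagnosis as diagnostic evidence accumulates.

Loads the bundled ferret case (lethargy/anorexia/diarrhea; suspected GI
foreign body), computes the posterior over all seven differentials from
the composite three-expert priors and the five pre-surgical findings,
and shows the step-by-step trajectory.
"""

import bayesdca as b

case = b.ferret_case()
belief = case.belief("pre-surgical")

result = b.posterior(belief)
print("Posterior after the full pre-surgical workup (percent):")
print(result.as_series().round(1).to_string())
print()
print(f"Most likely diagnosis: {result.top()} ({result[result.top()]:.0f}%)")
print()

# How each finding moved the differential, in workup order.  The first
# row is the prior alone; each later row adds one finding.
traj = b.trajectory(belief)
print("Posterior trajectory (rows = evidence steps):")
print(traj.as_frame().round(1).to_string())
print()
print(
    "Reading: the GI foreign-body probability starts at "
    f"{traj[0]['GI Foreign Body']:.0f}% on priors alone and ends at "
    f"{traj.final['GI Foreign Body']:.0f}% after all five findings — the "
    "workup as a whole made a foreign body LESS likely, not more."
)
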