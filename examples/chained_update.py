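"""Chain posteriors across reference time points.

When new evidence arrives after an intervention (here: exploratory
laparotomy, lymph-node cytology, and the post-surgical clinical course),
the pre-surgical posterior becomes the prior for the later stage.  The
unrounded posterior is carried forward — chaining is then exactly
equivalent to a single update over all eight findings.
"""

import bayesdca as b

case = b.ferret_case()

pre = b.posterior(case.belief("pre-surgical"))
stage2 = case.stage("post-surgical")
final = b.chain(pre, stage2.conditional_mapping(case.differential), stage2.findings)

print("Posterior at time of euthanasia (percent):")
print(final.as_series().round(2).to_string())
print()
print(
    f"Pre-surgery, GI foreign body stood at {pre['GI Foreign Body']:.0f}% "
    f"(second most likely); after surgery found no foreign body and the "
    f"patient failed to improve, it fell to {final['GI Foreign Body']:.0f}%, "
    f"while bacterial gastroenteritis rose to "
    f"{final['Bacterial Gastroenteritis']:.0f}%."
)
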