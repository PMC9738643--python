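# bayesdca

Bayesian differential diagnosis and clinical decision analysis from
multi-expert probability elicitations.

Clinicians — the package grew out of a veterinary (exotic-animal) use
case, but nothing in it is species-specific — routinely face questions
of the form *"given this signalment, history and workup, which diagnosis
is most likely, and is that likely enough to justify an invasive
intervention?"*. Published prevalence data are often missing, so the
inputs here are **structured expert elicitations**: each expert rates,
on a 0–100 percent scale with a 1% floor,

* a prior probability for each diagnosis $D_i$ in an exhaustive,
  mutually exclusive differential set, and
* a conditional probability $P(F_j \mid D_i)$ — the percentage of
  patients with diagnosis $D_i$ that would show finding $F_j$.

`bayesdca` pools a panel cell-by-cell (arithmetic mean by default),
updates the differential with the product form of Bayes' theorem under
conditional independence of findings,

$$P(D_i \mid F_1, \dots, F_n) = \frac{P(D_i)\,\prod_j P(F_j \mid D_i)}
  {\sum_k P(D_k)\,\prod_j P(F_j \mid D_k)} \times 100\%,$$

chains posteriors across reference time points (yesterday's posterior is
today's prior), and evaluates the treat/no-treat decision tree under
elicited outcome utilities. The expected value of each choice is the
probability-weighted mean of its leaf utilities, and the **treatment
threshold** — the disease probability at which the two choices break
even — is

$$p^\* = \frac{1}{1 + B/H}, \qquad
  B = U_{\text{treated disease}} - U_{\text{untreated disease}}, \quad
  H = U_{\text{untreated no disease}} - U_{\text{treated no disease}}.$$

Conditioning on a *subset* of the evidence turns the same machinery into
a quantitative lens on cognitive bias: anchoring and confirmation bias
are exactly "what did the decision look like if you only counted the
confirming test?".

## Worked example

The bundled case is a ~1-year-old ferret with lethargy, anorexia and
diarrhea, suspected of a gastrointestinal foreign body (GI FB) and taken
to exploratory laparotomy; three outside ferret clinicians supplied the
probabilities and the original team the utilities. Was surgery the
right call?

```python
import bayesdca as b

case = b.ferret_case()
belief = case.belief("pre-surgical")

pre = b.posterior(belief)                       # priors + all 5 findings
print(pre.top(), round(pre["GI Foreign Body"]))  # Bacterial Gastroenteritis 31

d = b.decide(pre, "GI Foreign Body", case.utilities)
print(round(d.ev_treat), round(d.ev_no_treat), d.optimal, round(d.threshold))
# 67 76 no-treat 40
```

Running `python examples/surgery_decision.py` prints the full tree:

```
decision: surgery vs no surgery   (P[GI FB] = 30.7%)

[surgery] EV = 67.1
 |-- GI FB (30.7%)                            utility 83.3
 `-- no GI FB (69.3%)                         utility 60

[no surgery] EV = 76.5   <-- optimal
 |-- GI FB (30.7%)                            utility 23.3
 `-- no GI FB (69.3%)                         utility 100

Treatment threshold: 40% (benefit 60 / harm 40)
```

A 31% chance of a foreign body sits below the 40% threshold: medical
management had the higher expected value, and the laparotomy (which
found no foreign body) was, on the elicited numbers, the wrong choice.
The counterfactual (`examples/counterfactual_bias.py`) shows how the
choice looked through a biased lens — conditioning on the ultrasound
alone puts the probability at 64%, comfortably above threshold:

```
P(GI FB | all five findings)   = 31%
P(GI FB | ultrasound only)     = 64%
treatment threshold            = 40%
```

The other examples cover the evidence trajectory
(`ferret_workup.py`), chaining into the post-surgical stage where
bacterial gastroenteritis reaches 76% and GI FB falls to 4%
(`chained_update.py`), and synthetic-panel convergence
(`synthetic_panel.py`).

There is also a thin CLI over the same functions:

```bash
bayesdca report ferret                 # full two-stage analysis + tree
bayesdca posterior my_case.yaml --findings Ultrasonography
bayesdca threshold --utilities 83.3,60,23.3,100
bayesdca simulate panel ferret --n 10 --seed 1 --out panel/
```

Case files are YAML (see
`src/bayesdca/data/ferret_gi_foreign_body.yaml` for the template);
per-expert tables are plain CSV.

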