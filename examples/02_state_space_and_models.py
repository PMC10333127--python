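"""The amalgamated state space and the ten transition-rate models.

Reproduction mode (oviparous/viviparous) and eggshell mineralization
(membrane/parchment/rigid) are amalgamated into one six-state Markov model;
the eggshell component of viviparous states is hidden, because viviparous
taxa cannot preserve an eggshell.  Eight SMM variants cross four rate schemes
with independent vs switch-on dependency; extended embryo retention (EER) has
its own two-state models.
"""

import numpy as np

import paleoparity as pp

space = pp.build_space()
print("amalgamated states:", ", ".join(space.labels), "(* = hidden eggshell)")

for model in pp.ALL_MODELS:
    spec = pp.build_generator(model)
    print(f"{model:8s} k={spec.k} free rate parameter(s)")

# a bound generator: switch-on dependency freezes the eggshell while viviparous
spec = pp.build_generator("CER_sw")
q = spec.bind(np.array([0.004, 0.008]))  # repro, shell rates per Myr
print("\nCER_sw generator (rows sum to 0; V-background shell cells are 0):")
print(np.array_str(q, precision=4, suppress_small=True))

# observed codings become tip priors over the amalgamated states
for desc, coding in [
    ("oviparous, rigid shell", pp.parse_coding("t1", "oviparous", "rigid")),
    ("viviparous (shell unobservable)", pp.parse_coding("t2", "viviparous", "-")),
    ("mesosaur-style ambiguity", pp.parse_coding("t3", "viviparous/oviparous", "membrane")),
]:
    print(f"{desc:35s} -> tip prior {np.round(pp.tip_prior(coding), 3)}")

cm = pp.build_cost_matrix("sw", forbidden_cost=100.0)
print("\nswitch-on Sankoff costs (100 = practically impossible step):")
print(cm.costs)
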