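"""The Bayesian belief of a single decision unit, step by step.

A unit summarizes the displacement angles it has experienced by the
resultant (R0, Phi) and a count c; the posterior over its hidden direction
is a von Mises with unknown concentration handled numerically. The Bayes
unit presses according to the expected utility of pressing (a quadrature);
the Thompson unit draws one posterior sample of the same utility.
"""

import math

import numpy as np

import neurongame as ng
from neurongame.agent_models import BayesBelief

params = ng.AgentHyperParams()
rng = np.random.default_rng(0)

belief = BayesBelief()
f_aligned = ng.encode(1.0, params)
f_opposed = ng.encode(1.0 + math.pi, params)

print("uninformed unit: expected utility =",
      ng.bayes_activation(belief, f_aligned, params))

for n_obs in (3, 10, 50):
    angles = rng.vonmises(1.0, 4.0, size=n_obs) % (2 * math.pi)
    belief = ng.belief_update(BayesBelief(), angles)
    g_al = ng.bayes_activation(belief, f_aligned, params)
    g_op = ng.bayes_activation(belief, f_opposed, params)
    samples = [ng.thompson_activation(belief, f_aligned, rng, params)
               for _ in range(4000)]
    print(f"after {n_obs:>2} observations near 1.0 rad: "
          f"g(aligned)={g_al:+.3f} g(opposed)={g_op:+.3f} "
          f"Thompson mean={np.mean(samples):+.3f}")

# With no observations the expected utility is exactly zero (pressing is a
# coin flip). As evidence accumulates, the aligned activation approaches the
# maximum utility pi/2 ~ 1.571 and the opposed one its negative; the
# Thompson sample mean tracks the Bayes quadrature because posterior
# sampling is an unbiased one-sample estimate of the expected utility.
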