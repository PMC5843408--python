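"""Independent oracles used by the test suite.

These implementations are deliberately naive (exhaustive enumeration,
closed forms) and share no code with the package paths they check.
"""

import itertools
import math

import numpy as np
from scipy import stats


def hmm_forward_enumeration(outcomes, beta, c, d):
    """Posterior P(state = relief | outcomes) by brute-force path summation.

    Hidden two-state chain with symmetric transition [[1-b, b], [b, 1-b]],
    uniform initial state, observation likelihoods 0.5*(1+c)/(1-c) for a
    relief outcome and 0.5*(1-d)/(1+d) for no relief.  Sums over all
    2^(T+1) state paths.  Returns the filtering posterior after the last
    outcome.
    """
    T = len(outcomes)
    # state 0 = relief state, 1 = no-relief state
    trans = [[1 - beta, beta], [beta, 1 - beta]]
    def obs(r, s):
        if r == 1:
            return 0.5 * (1 + c) if s == 0 else 0.5 * (1 - c)
        return 0.5 * (1 - d) if s == 0 else 0.5 * (1 + d)
    post = [0.0, 0.0]
    for path in itertools.product((0, 1), repeat=T + 1):
        p = 0.5  # uniform initial state before the first transition
        for t in range(T):
            p *= trans[path[t]][path[t + 1]] * obs(outcomes[t], path[t + 1])
        post[path[-1]] += p
    z = post[0] + post[1]
    return post[0] / z


def xp_beta_closed_form(alpha):
    """Exceedance probability for K = 2 from the Beta posterior.

    r1 ~ Beta(a1, a2) marginally under Dirichlet(a1, a2);
    XP_1 = P(r1 > 1/2)."""
    a1, a2 = alpha
    p1 = float(stats.beta.sf(0.5, a1, a2))
    return np.array([p1, 1.0 - p1])


def gaussian_conjugate_log_marginal(y, sigma, mu0, sigma0):
    """Exact log marginal likelihood of y_i ~ N(theta, sigma^2) with
    theta ~ N(mu0, sigma0^2): y ~ N(mu0*1, sigma^2 I + sigma0^2 J)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    cov = sigma**2 * np.eye(n) + sigma0**2 * np.ones((n, n))
    return float(stats.multivariate_normal.logpdf(y, mean=np.full(n, mu0),
                                                  cov=cov))
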