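"""Closed-form hypergeometric oracles for rarefaction tests.

Richness after drawing m of N items without replacement is a sum of
per-variable presence indicators.  With A_i the set of items carrying
variable i and q_i = 1 - C(N-|A_i|, m)/C(N, m) the presence probability:

    E[S_m]   = sum_i q_i
    Var[S_m] = sum_i q_i (1-q_i)
             + 2 sum_{i<j} [ C(N-|A_i u A_j|, m)/C(N, m) - (1-q_i)(1-q_j) ]

This covers both species rarefaction (disjoint memberships: one species
per individual) and damage-type rarefaction (overlapping memberships: a
leaf may carry several DTs).  Everything here is exact combinatorics,
independent of the Monte-Carlo implementation under test.
"""

from itertools import combinations

from scipy.special import comb


def _absent_prob(n_total, n_member, m):
    return comb(n_total - n_member, m, exact=True) / comb(n_total, m, exact=True)


def expected_richness(memberships, n_total, m):
    """E[distinct variables] drawing m of n_total items without replacement."""
    return sum(1 - _absent_prob(n_total, len(a), m) for a in memberships)


def variance_richness(memberships, n_total, m):
    """Exact Var[distinct variables] for the same draw."""
    sets = [set(a) for a in memberships]
    q = [1 - _absent_prob(n_total, len(a), m) for a in sets]
    var = sum(qi * (1 - qi) for qi in q)
    for (i, a), (j, b) in combinations(enumerate(sets), 2):
        both_absent = _absent_prob(n_total, len(a | b), m)
        var += 2 * (both_absent - (1 - q[i]) * (1 - q[j]))
    return max(var, 0.0)


def species_memberships(counts):
    """Disjoint membership sets for an abundance vector."""
    out, start = [], 0
    for c in counts:
        if c > 0:
            out.append(set(range(start, start + int(c))))
        start += int(c)
    return out
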