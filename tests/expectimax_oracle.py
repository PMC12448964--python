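"""Exact expectimax oracle for tiny teacher POMDPs.

Independent of the tree-search implementation: enumerates every episode
trace in a block, propagates the exact joint distribution over (action
values, EMA estimates), branches on the block's success count, and applies
the belief-MDP Bellman recursion to a fixed depth.  Tractable only for
small N, T and depth; used to validate the Monte Carlo planner.
"""

import math


def _sigma(z):
    return 1.0 / (1.0 + math.exp(-z))


def enumerate_episode(q, eps, alpha, reward, k):
    """All (prob, outcome, q_after) branches of one episode at level ``k``.

    TD(0) updates with pre-episode bootstrap targets: correct step i takes
    q_i toward q_{i+1} (or toward the reward at the final step); the failed
    step and everything after it are untouched.
    """
    sig = [_sigma(q[i] + eps) for i in range(k)]
    branches = []
    for f in range(k):  # failure at 0-indexed step f
        p = math.prod(sig[:f]) * (1.0 - sig[f])
        qa = list(q)
        for i in range(f):
            qa[i] = q[i] + alpha * (q[i + 1] - q[i])
        branches.append((p, 0, tuple(qa)))
    p = math.prod(sig)
    qa = list(q)
    for i in range(k):
        boot = q[i + 1] if i + 1 < k else 0.0
        g = boot + (reward if i == k - 1 else 0.0)
        qa[i] = q[i] + alpha * (g - q[i])
    branches.append((p, 1, tuple(qa)))
    return branches


def enumerate_block(q, s_map, eps, alpha, reward, level, n_attempts, beta):
    """Joint distribution of (q, s_map, success count) after one interaction."""
    leaves = [(1.0, tuple(q), dict(s_map), 0)]
    for _ in range(n_attempts):
        nxt = []
        for p0, q0, s0, c0 in leaves:
            for p, outcome, qa in enumerate_episode(q0, eps, alpha, reward, level):
                if p == 0.0:
                    continue
                s1 = dict(s0)
                s1[level] = (1.0 - beta) * s1.get(level, 0.0) + beta * outcome
                nxt.append((p0 * p, qa, s1, c0 + outcome))
        leaves = nxt
    return leaves


def expectimax_values(q, s_map, eps, alpha, reward, level, spec, gamma, depth):
    """Exact Q-value of each move {-1, 0, +1} at a belief point state."""
    belief = [(1.0, tuple(q), dict(s_map))]
    return {a: _q_value(a, belief, eps, alpha, reward, level, spec, gamma, depth)
            for a in (-1, 0, 1)}


def _value(belief, eps, alpha, reward, level, spec, gamma, depth):
    if depth <= 0:
        return 0.0
    return max(_q_value(a, belief, eps, alpha, reward, level, spec, gamma, depth)
               for a in (-1, 0, 1))


def _q_value(a, belief, eps, alpha, reward, level, spec, gamma, depth):
    new_level = min(max(level + a, 1), spec.n_levels)
    by_count = {}
    immediate = 0.0
    for pb, qb, sb in belief:
        for p, qa, sa, c in enumerate_block(
            qb, sb, eps, alpha, reward, new_level,
            spec.attempts_per_interaction, spec.beta,
        ):
            w = pb * p
            terminal = (new_level == spec.n_levels and sa[new_level] >= spec.tau)
            if terminal:
                immediate += w
            else:
                by_count.setdefault(c, []).append((w, qa, sa))
    future = 0.0
    for _, group in sorted(by_count.items()):
        mass = sum(w for w, _, _ in group)
        if mass <= 0.0:
            continue
        cond = [(w / mass, qb, sb) for w, qb, sb in group]
        future += mass * _value(cond, eps, alpha, reward, new_level, spec,
                                gamma, depth - 1)
    return immediate + gamma * future
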