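"""Independent brute-force oracles used by the test suite and the
acceptance script. Deliberately naive: python loops, direct scipy matrix
exponentials, no scaling tricks, no code shared with the implementation's
pruning/accounting paths."""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from biogeoclim.dec import anagenetic_rate_matrix, cladogenesis_table


def _branch_matrix(space, params, schedule, child_age, parent_age):
    """Forward transition matrix along one branch, splitting at breakpoints
    (independent splitting logic: explicit boundary walk)."""
    n = space.n_states
    P = np.eye(n)
    if schedule is None:
        Q = anagenetic_rate_matrix(space, params)
        return expm(Q * (parent_age - child_age))
    cuts = sorted(
        [b for b in schedule.breaks if child_age < b < parent_age],
        reverse=True,
    )
    lo_edges = [parent_age] + cuts + [child_age]
    for hi, lo in zip(lo_edges, lo_edges[1:]):
        # epoch of this piece: count breakpoints at or above its top
        epoch = sum(1 for b in schedule.breaks if b >= hi)
        Q = anagenetic_rate_matrix(space, params, schedule.multipliers[epoch])
        P = P @ expm(Q * (hi - lo))
    return P


def dense_loglik_and_marginals(tree, tip_ranges, space, params, schedule=None):
    """Log-likelihood and per-node marginals by explicit enumeration.

    Enumerates every internal node's range state and cladogenetic outcome,
    multiplying branch transition probabilities. Exponential in tree size;
    intended for <= 3 tips.
    """
    clado = cladogenesis_table(space, params).as_dict()
    S = space.n_states
    tips = {lab: space.index(tip_ranges[lab]) for lab in tree.tip_labels}
    root = tree.root
    prior = 1.0 / (S - 1)

    # node marginals and likelihood: P(node = state, data) by clamping
    def clamped(v, state):
        """P(data) with node v clamped to `state` (node at its own age)."""

        def rec(u, su):
            if u == v and su != state:
                return 0.0
            if u < tree.n_tips:
                return 1.0 if su == tips[tree.tip_labels[u]] else 0.0
            kids = tree.children[u]
            if len(kids) == 1:
                c = kids[0]
                P = _branch_matrix(space, params, schedule,
                                   float(tree.ages[c]), float(tree.ages[u]))
                return sum(P[su, sc] * rec(c, sc) for sc in range(S))
            c1, c2 = kids
            P1 = _branch_matrix(space, params, schedule,
                                float(tree.ages[c1]), float(tree.ages[u]))
            P2 = _branch_matrix(space, params, schedule,
                                float(tree.ages[c2]), float(tree.ages[u]))
            tot = 0.0
            for l, r, w in clado.get(su, []):
                a = sum(P1[l, s1] * rec(c1, s1) for s1 in range(S))
                b = sum(P2[r, s2] * rec(c2, s2) for s2 in range(S))
                tot += w * a * b
            return tot

        return sum(prior * rec(root, s) for s in range(1, S))

    marginals = np.zeros((tree.n_nodes, S))
    for v in range(tree.n_nodes):
        for s in range(S):
            marginals[v, s] = clamped(v, s)
    lik = marginals[root].sum()
    marginals /= marginals.sum(axis=1, keepdims=True)
    return np.log(lik), marginals


def naive_dispersal_accounting(tree, node_latitudes, window):
    """Event list (child id, start age, displacement) by plain traversal."""
    hi, lo = max(window), min(window)
    out = []
    for child in range(tree.n_nodes):
        p = int(tree.parent[child])
        if p < 0:
            continue
        dlat = abs(node_latitudes[child] - node_latitudes[p])
        start = float(tree.ages[p])
        if dlat > 1e-12 and lo <= start <= hi:
            out.append((child, start, dlat))
    return out


def naive_domain_map(train, grid_mat, grid_map, land, ranges):
    """DOMAIN suitability by scalar double loop over (cells x points)."""
    nlat, nlon = grid_mat.shape
    out = np.full((nlat, nlon), np.nan)
    for i in range(nlat):
        for j in range(nlon):
            if not land[i, j]:
                continue
            best = 0.0
            for p in train:
                d_mat = min(abs(grid_mat[i, j] - p[0]) / ranges[0], 1.0)
                d_map = min(abs(grid_map[i, j] - p[1]) / ranges[1], 1.0)
                sim = 1.0 - min((d_mat + d_map) / 2.0, 1.0)
                best = max(best, sim)
            out[i, j] = best
    return out
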