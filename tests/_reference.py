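"""Deliberately naive reference implementations used as oracles.

Everything here is written for clarity, not speed: exhaustive sorts,
per-element loops and two-pass statistics, independent of the package's
vectorized code paths.
"""

from __future__ import annotations

import math
import statistics

import numpy as np


def ref_neighbor_set(values, l, k, exclude_self=True):
    """k nearest cells of cell l by |v_i - v_l|, ties by ascending index."""
    ranked = []
    for i, v in enumerate(values):
        if exclude_self and i == l:
            continue
        ranked.append((abs(v - values[l]), i))
    ranked.sort()
    return {i for _, i in ranked[:k]}


def ref_cross_map_weight(sx, sy, m):
    inter = len(set(sx) & set(sy))
    if inter == 0:
        return 0.0
    p_xy = inter / m
    p_x = len(sx) / m
    p_y = len(sy) / m
    return p_xy * math.log(p_xy / (p_x * p_y))


def ref_loo_sd_term(values, l):
    rest = [v for i, v in enumerate(values) if i != l]
    return abs(statistics.stdev(values) - statistics.stdev(rest))


def ref_local_entropy(weights, sd_term):
    w = [x for x in weights if x > 0]
    q = len(w)
    if q <= 1:
        return 0.0
    total = sum(w)
    p = [x / total for x in w]
    ent = -sum(pi * math.log(pi) for pi in p) / q
    return ent * sd_term


def ref_entropy_matrix(dataset, background, k_for=None):
    """Gene x cell local entropies via exhaustive per-cell recomputation.

    ``k_for``: optional map group-size -> k; defaults to ceil(sqrt(M)).
    """
    genes = [g for g in dataset.gene_ids if g in background.genes()]
    gi = dataset.gene_index()
    adj = {g: set() for g in genes}
    for a, b in background.edges():
        if a in adj and b in adj:
            adj[a].add(b)
            adj[b].add(a)
    out = np.zeros((len(genes), dataset.n_cells))
    for stage in dataset.stages_present():
        cols = list(dataset.stage_columns(stage))
        m = len(cols)
        k = (k_for or {}).get(m, math.ceil(math.sqrt(m)))
        vals = {g: [dataset.values[gi[g], c] for c in cols] for g in genes}
        for local_l in range(m):
            nn = {g: ref_neighbor_set(vals[g], local_l, k) for g in genes}
            for row, g in enumerate(genes):
                weights = [
                    ref_cross_map_weight(nn[g], nn[b], m) for b in sorted(adj[g])
                ]
                sd = ref_loo_sd_term(vals[g], local_l)
                out[row, cols[local_l]] = ref_local_entropy(weights, sd)
    return genes, out


def ref_cell_score(column_items, top_fraction):
    """column_items: list of (gene, value); returns (H, top genes)."""
    g = len(column_items)
    s = max(1, math.ceil(top_fraction * g))
    ranked = sorted(column_items, key=lambda kv: (-kv[1], kv[0]))[:s]
    return sum(v for _, v in ranked), [gname for gname, _ in ranked]


def ref_t_sf_df2(t):
    """Closed-form upper-tail one-sided P of the t distribution with df = 2."""
    return 0.5 - 0.5 * t / math.sqrt(t * t + 2.0)
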