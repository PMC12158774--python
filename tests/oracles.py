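"""Independent brute-force oracles used by the test suite.

These deliberately re-derive the rules from their plain-language statement
(loops, exhaustive enumeration) without touching the package implementations
they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_otsu(values, nbins: int = 256) -> float | None:
    """Exhaustive Otsu: try every split of an nbins histogram, maximize
    between-class variance, return the upper edge of the best class-0 bin."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0 or values.min() == values.max():
        return None
    hist, edges = np.histogram(values, bins=nbins)
    centres = (edges[:-1] + edges[1:]) / 2.0
    total = hist.sum()
    best_k, best_var = None, -1.0
    for k in range(nbins - 1):
        n0 = hist[: k + 1].sum()
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            var = -math.inf
        else:
            m0 = (hist[: k + 1] * centres[: k + 1]).sum() / n0
            m1 = (hist[k + 1:] * centres[k + 1:]).sum() / n1
            var = (n0 / total) * (n1 / total) * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_k = var, k
    return float(edges[best_k + 1])


def brute_force_two_pass(pre: np.ndarray, post: np.ndarray, d_matching: float) -> set:
    """Literal two-pass nearest-first pairing; returns {(post_i, pre_j)}."""
    edges = set()
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    # pass 1: each post takes its nearest pre
    for i in range(post.shape[0]):
        best_j, best_d = None, math.inf
        for j in range(pre.shape[0]):
            d = math.dist(post[i], pre[j])
            if d < best_d:
                best_j, best_d = j, d
        if best_j is not None and best_d < d_matching:
            edges.add((i, best_j))
    # pass 2: floating pres take their nearest post
    paired = {j for _, j in edges}
    for j in range(pre.shape[0]):
        if j in paired:
            continue
        best_i, best_d = None, math.inf
        for i in range(post.shape[0]):
            d = math.dist(post[i], pre[j])
            if d < best_d:
                best_i, best_d = i, d
        if best_i is not None and best_d < d_matching:
            edges.add((best_i, j))
    return edges


def brute_force_assignment_counts(
    auto: np.ndarray, gt: np.ndarray, r_matching: float, big_cost: float = 1e6
) -> tuple[int, int, int]:
    """Exhaustive minimum-total-cost one-to-one assignment with cutoff.

    Enumerates every complete assignment of the smaller point set, with
    distances above the cutoff capped at ``big_cost``; pairs realized above
    the cutoff dissolve into FP + FN. Returns (tp, fp, fn).
    """
    auto = np.asarray(auto, float).reshape(-1, 3)
    gt = np.asarray(gt, float).reshape(-1, 3)
    na, ng = auto.shape[0], gt.shape[0]
    if na == 0 or ng == 0:
        return 0, na, ng
    C = np.linalg.norm(auto[:, None, :] - gt[None, :, :], axis=2)
    capped = np.where(C > r_matching, big_cost, C)
    best_cost, best_pairs = math.inf, []
    if na <= ng:
        for perm in itertools.permutations(range(ng), na):
            cost = sum(capped[a, g] for a, g in enumerate(perm))
            if cost < best_cost:
                best_cost = cost
                best_pairs = list(enumerate(perm))
    else:
        for perm in itertools.permutations(range(na), ng):
            cost = sum(capped[a, g] for g, a in enumerate(perm))
            if cost < best_cost:
                best_cost = cost
                best_pairs = [(a, g) for g, a in enumerate(perm)]
    kept = [(a, g) for a, g in best_pairs if C[a, g] <= r_matching]
    tp = len(kept)
    return tp, na - tp, ng - tp
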