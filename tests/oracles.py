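"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written in plain Python (dicts, loops, math.log),
deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter


def oracle_vi(labels_a: dict, labels_b: dict) -> float:
    """Variation of information from raw chip->term mappings, computed
    via explicit contingency counts over the commonly labelled chips."""
    common = sorted(set(labels_a) & set(labels_b))
    n = len(common)
    ca = Counter(labels_a[c] for c in common)
    cb = Counter(labels_b[c] for c in common)
    joint = Counter((labels_a[c], labels_b[c]) for c in common)

    def h(counts):
        return -sum((v / n) * math.log(v / n) for v in counts.values())

    mi = sum((v / n) * math.log((v / n) / ((ca[a] / n) * (cb[b] / n)))
             for (a, b), v in joint.items())
    return h(ca) + h(cb) - 2.0 * mi


def oracle_mi(labels_a: dict, labels_b: dict) -> float:
    common = sorted(set(labels_a) & set(labels_b))
    n = len(common)
    ca = Counter(labels_a[c] for c in common)
    cb = Counter(labels_b[c] for c in common)
    joint = Counter((labels_a[c], labels_b[c]) for c in common)
    return sum((v / n) * math.log((v / n) / ((ca[a] / n) * (cb[b] / n)))
               for (a, b), v in joint.items())


def oracle_q_matrix(hyp_labels, prior, eps: float, data_size: int):
    """Exhaustive transition matrix for posterior-sampling learners:
    plain loops over every (site, label) data sequence."""
    K = len(hyp_labels)
    N = len(hyp_labels[0])
    Q = [[0.0] * K for _ in range(K)]
    observations = list(itertools.product(range(N), (0, 1)))
    for data in itertools.product(observations, repeat=data_size):
        liks = []
        for h in range(K):
            lik = 1.0
            for site, label in data:
                lik *= (1.0 - eps) if hyp_labels[h][site] == label else eps
            liks.append(lik / (N ** data_size))
        z = sum(prior[h] * liks[h] for h in range(K))
        for i in range(K):
            post_i = prior[i] * liks[i] / z
            for j in range(K):
                Q[i][j] += post_i * liks[j]
    return Q


def oracle_nearest_exemplar(grid, examples, embed_fn):
    """Per-chip nearest-exemplar term (None where tied between terms)."""
    out = {}
    for chip in grid:
        pos = embed_fn(chip)
        best = None
        for ex_chip_id, term in examples:
            echip = grid.chips[grid.index(ex_chip_id)]
            epos = embed_fn(echip)
            d = math.dist(pos, epos)
            if best is None or d < best[0] - 1e-12:
                best = (d, {term})
            elif abs(d - best[0]) <= 1e-12:
                best[1].add(term)
        out[chip.chip_id] = next(iter(best[1])) if len(best[1]) == 1 else None
    return out
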