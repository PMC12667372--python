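"""Independent brute-force oracles used across the test suite.

Everything here deliberately avoids the code paths it checks: plain python
loops, float arithmetic and exhaustive enumeration only.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from obliphase import engine as eng
from obliphase.oblivious import Secret
from obliphase.pbwt import ConditionedPanel


def naive_top_s(alleles: np.ndarray, target: np.ndarray, pos: int, S: int):
    """Top-S haplotypes by suffix-match length ending just before ``pos``
    (ties to the smaller id), by direct scanning of the uncompressed panel."""
    n_hap = alleles.shape[0]
    lengths = np.zeros(n_hap, dtype=int)
    for h in range(n_hap):
        ln = 0
        while pos - 1 - ln >= 0 and alleles[h, pos - 1 - ln] == target[pos - 1 - ln]:
            ln += 1
        lengths[h] = ln
    order = sorted(range(n_hap), key=lambda h: (-lengths[h], h))
    return set(order[:S]), lengths


def make_conditioned(alleles: np.ndarray, is_pad=None) -> ConditionedPanel:
    """Wrap a plain allele matrix as a conditioned panel for HMM tests."""
    k = alleles.shape[0]
    if is_pad is None:
        is_pad = np.zeros(k, dtype=bool)
    return ConditionedPanel(
        hap_ids=[Secret(i) for i in range(k)],
        is_pad=Secret(np.asarray(is_pad, dtype=bool)),
        bitmap=Secret(np.ones(1, dtype=bool)),
        alleles=np.asarray(alleles, dtype=np.int8),
        k_cap=k,
    )


def enumerate_hmm(graph, cond, params):
    """Exhaustive float reference for the diploid HMM.

    Enumerates every option path; for each, runs a plain float forward
    (sum-product) and Viterbi (max-product) over the (k1, k2) copy states.
    Returns per-boundary joint option posteriors, the per-path total
    likelihoods and the per-path max-product scores.
    """
    g = graph.genotypes
    n = g.size
    k = cond.k_cap
    pad = cond.is_pad.expose()
    w = np.where(pad, 0.0, 1.0 / (k - pad.sum()))
    hap = cond.alleles.astype(int)
    rho, eps = params.rho, params.eps
    seg_of = np.empty(n, dtype=int)
    for s, seg in enumerate(graph.segments):
        seg_of[seg.start : seg.end] = s
    paths = list(product(*[range(s.n_options) for s in graph.segments]))
    liks, maxliks = {}, {}
    for path in paths:
        est = eng.expand_options(graph, list(path))
        a_a, a_b = est.hap_a, est.hap_b

        def em(i):
            ea = np.where(hap[:, i] == a_a[i], 1 - eps, eps)
            eb = np.where(hap[:, i] == a_b[i], 1 - eps, eps)
            return ea[:, None] * eb[None, :]

        f = w[:, None] * w[None, :] * em(0) / graph.segments[0].n_options
        m = f.copy()
        for i in range(1, n):
            r = rho[i - 1]
            f = (1 - r) * f + r * w[:, None] * f.sum(axis=0)[None, :]
            f = (1 - r) * f + r * w[None, :] * f.sum(axis=1)[:, None]
            m1 = np.maximum((1 - r) * m, r * w[:, None] * m.max(axis=0)[None, :])
            m = np.maximum((1 - r) * m1, r * w[None, :] * m1.max(axis=1)[:, None])
            if seg_of[i] != seg_of[i - 1]:
                c = 1.0 / graph.segments[seg_of[i]].n_options
                f *= c
                m *= c
            f *= em(i)
            m *= em(i)
        liks[path] = float(f.sum())
        maxliks[path] = float(m.max())
    total = sum(liks.values())
    posts = []
    for s in range(len(graph.segments) - 1):
        joint = np.zeros(
            (graph.segments[s].n_options, graph.segments[s + 1].n_options)
        )
        for path, lk in liks.items():
            joint[path[s], path[s + 1]] += lk
        posts.append(joint / total)
    return posts, liks, maxliks


def phase_class(graph, path):
    """Canonical representative of a path under the global haplotype swap."""
    comp = tuple(s.n_options - 1 - o for s, o in zip(graph.segments, path))
    return min(tuple(path), comp)


def random_small_instance(rng, max_segments=4, max_k=4, max_sites=12,
                          h_seg_max=3):
    """Random HMM instance small enough for exhaustive enumeration."""
    n = int(rng.integers(4, max_sites + 1))
    k = int(rng.integers(1, max_k + 1))
    h_seg = int(rng.integers(1, h_seg_max + 1))
    g = rng.integers(0, 3, n)
    while (g == 1).sum() > max_segments * h_seg:
        g[rng.integers(n)] = rng.choice([0, 2])
    graph = eng.build_genotype_graph(g, h_seg)
    alleles = rng.integers(0, 2, (k, n))
    pad = np.zeros(k, dtype=bool)
    if k > 1 and rng.random() < 0.3:
        pad[-1] = True
    cond = make_conditioned(alleles, pad)
    params = eng.make_hmm_params(
        n, k, None,
        ne=float(rng.uniform(100, 20000)),
        eps=float(rng.uniform(1e-4, 0.05)),
    )
    return graph, cond, params
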