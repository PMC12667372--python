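"""MCMC phasing engine: genotype graph, diploid Li-Stephens HMM, sampling.

The target's heterozygous sites are segmented into short runs (three hets by
default); enumerating the phases of each segment yields a *genotype graph*
whose paths are exactly the haplotype pairs consistent with the genotypes.
Conditional on a small panel of reference haplotypes selected by the
compressed PBWT, a diploid Li-Stephens HMM with state (k1, k2, segment
option) scores those paths: each target haplotype copies from one reference
haplotype, switching with probability rho per interval and mismatching with
probability eps per site.  Forward-backward posteriors over the option
transitions between adjacent segments drive Gibbs-style resampling of the
phase (burn-in), merging of high-confidence adjacent segments (pruning), and
a final max-product Viterbi decode (main iterations).

All secret-dependent arithmetic runs in dynamically scaled fixed point
(:mod:`obliphase.fixedpoint`); per-site rescaling is a power-of-two row
normalisation (value preserving), and exact constant-time division is applied
where true probabilities are required -- posterior matrices and sampling
distributions.  The sequence of array operations depends only on public
shapes (window size, segment structure, panel capacity), never on genotype
or panel values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import fixedpoint as fx
from .fixedpoint import DfpRowMatrix
from .oblivious import ct_divide_frac, vemit
from .panel import HaplotypePanel, compress_panel
from .pbwt import (
    ConditionedPanel,
    build_conditioned_panel,
    build_trees,
    find_neighbors,
    insert_estimate,
    select_search_positions,
)

__all__ = [
    "Segment",
    "GenotypeGraph",
    "HmmParams",
    "PhaseEstimate",
    "TransitionPosterior",
    "PhaseConfig",
    "build_genotype_graph",
    "init_phase",
    "forward_backward",
    "sample_path",
    "prune",
    "viterbi_decode",
    "mcmc_run",
    "stitch_windows",
    "phase_window",
]

_I64 = np.int64


# ---------------------------------------------------------------------------
# genotype graph
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    """A run of heterozygous sites with its enumerated phase options.

    ``options[m, j]`` is the allele of haplotype A at the segment's j-th het
    site under option ``m``; haplotype B takes the complement at het sites
    and both equal the genotype at homozygous sites.  Options are indexed so
    that the global haplotype swap maps option ``m`` to ``n_opt - 1 - m``.
    """

    het_sites: np.ndarray  # site indices (within the window)
    options: np.ndarray  # (n_opt, n_het)
    start: int  # first site covered (inclusive)
    end: int  # one past the last site covered

    @property
    def n_options(self) -> int:
        return self.options.shape[0]


@dataclass
class GenotypeGraph:
    genotypes: np.ndarray  # {0,1,2}
    segments: list
    n_merges: int = 0

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def _enumerate_options(n_het: int) -> np.ndarray:
    m = np.arange(1 << n_het, dtype=_I64)
    return ((m[:, None] >> np.arange(n_het)[None, :]) & 1).astype(np.int8)


def build_genotype_graph(genotypes: np.ndarray, H_seg: int = 3) -> GenotypeGraph:
    """Segment the het sites into runs of at most ``H_seg`` and enumerate
    all phase options of each run."""
    g = np.asarray(genotypes, dtype=np.int8)
    if g.size and not np.isin(g, (0, 1, 2)).all():
        raise ValueError("genotypes must be dosages in {0, 1, 2} with no missing")
    if H_seg < 1:
        raise ValueError("H_seg must be >= 1")
    het = np.flatnonzero(g == 1)
    n_sites = g.size
    if het.size == 0:
        seg = Segment(het, _enumerate_options(0), 0, n_sites)
        return GenotypeGraph(g, [seg])
    chunks = [het[i : i + H_seg] for i in range(0, het.size, H_seg)]
    segments = []
    for k, chunk in enumerate(chunks):
        start = 0 if k == 0 else int(chunks[k][0])
        end = n_sites if k == len(chunks) - 1 else int(chunks[k + 1][0])
        segments.append(Segment(chunk, _enumerate_options(chunk.size), start, end))
    return GenotypeGraph(g, segments)


@dataclass
class PhaseEstimate:
    """A concrete phased haplotype pair plus the option index per segment."""

    hap_a: np.ndarray
    hap_b: np.ndarray
    option_idx: list

    def swapped(self) -> "PhaseEstimate":
        return PhaseEstimate(self.hap_b.copy(), self.hap_a.copy(),
                             list(self.option_idx))


def expand_options(graph: GenotypeGraph, option_idx: list) -> PhaseEstimate:
    """Materialise the haplotype pair selected by per-segment options."""
    g = graph.genotypes
    hap_a = (g // 2).astype(np.int8)
    hap_b = hap_a.copy()
    for seg, m in zip(graph.segments, option_idx):
        if seg.het_sites.size:
            pat = seg.options[m]
            hap_a[seg.het_sites] = pat
            hap_b[seg.het_sites] = 1 - pat
    return PhaseEstimate(hap_a, hap_b, list(option_idx))


def init_phase(genotypes, rng, H_seg: int = 3) -> PhaseEstimate:
    """Uniform random phase option per segment (seed-deterministic)."""
    graph = (genotypes if isinstance(genotypes, GenotypeGraph)
             else build_genotype_graph(genotypes, H_seg))
    opts = [int(rng.integers(seg.n_options)) for seg in graph.segments]
    return expand_options(graph, opts)


# ---------------------------------------------------------------------------
# HMM parameters
# ---------------------------------------------------------------------------

@dataclass
class HmmParams:
    """Li-Stephens parameters over the conditioned panel.

    ``rho[i]`` is the per-interval switch probability between sites i and
    i+1, derived from genetic distance d_i (cM) as 1 - exp(-0.04 Ne d_i / K)
    (the standard 4 Ne r / K scaling); ``eps`` the allele-copy error rate.
    """

    rho: np.ndarray
    eps: float
    n_states: int

    def __post_init__(self):
        if np.any(self.rho <= 0) or np.any(self.rho >= 1):
            raise ValueError("rho must lie strictly in (0, 1)")
        if not 0 < self.eps < 0.5:
            raise ValueError("eps must lie in (0, 0.5)")


DEFAULT_NE = 15_000
DEFAULT_EPS = 1e-4
DEFAULT_CM_PER_SITE = 0.01


def make_hmm_params(
    n_sites: int,
    k: int,
    cm_dist: np.ndarray | None = None,
    ne: float = DEFAULT_NE,
    eps: float = DEFAULT_EPS,
) -> HmmParams:
    if cm_dist is None:
        cm_dist = np.full(max(n_sites - 1, 0), DEFAULT_CM_PER_SITE)
    rho = 1.0 - np.exp(-0.04 * ne * np.asarray(cm_dist, dtype=float) / max(k, 1))
    rho = np.clip(rho, 1e-12, 1 - 1e-12)
    return HmmParams(rho=rho, eps=eps, n_states=k)


# ---------------------------------------------------------------------------
# fixed-point HMM internals
# ---------------------------------------------------------------------------

def _reshape(m: DfpRowMatrix, shape: tuple) -> DfpRowMatrix:
    return DfpRowMatrix(m.mantissa.reshape(shape), m.row_exp, m.frac_bits, m.dynamic)


def _broadcast_rows(m: DfpRowMatrix, n_rows: int) -> DfpRowMatrix:
    mant = np.broadcast_to(m.mantissa, (n_rows,) + m.mantissa.shape[1:]).copy()
    exp = np.broadcast_to(m.row_exp, (n_rows,)).copy()
    return DfpRowMatrix(mant, exp, m.frac_bits, m.dynamic)


@dataclass
class _Numerics:
    """Fixed-point encodings of the model constants for one window."""

    frac_bits: int
    dynamic: bool
    stay_m: np.ndarray  # (n_sites-1,) mantissa of 1 - rho
    switch_m: np.ndarray  # (n_sites-1,) mantissa of rho
    hit_m: int  # 1 - eps
    miss_m: int  # eps
    w_m: np.ndarray  # (K,) mantissa of the state prior (0 on padding)
    sw_w_m: list  # per interval: (K,) mantissa of rho * w  (built lazily)


def _make_numerics(params: HmmParams, cond: ConditionedPanel,
                   frac_bits: int, dynamic: bool) -> _Numerics:
    F = frac_bits
    is_pad = cond.is_pad.expose()
    k_eff = int(cond.k_cap - is_pad.sum())
    w_scalar = int(ct_divide_frac(np.array([1]), np.array([max(k_eff, 1)]), F)[0])
    w_m = np.where(is_pad, 0, w_scalar).astype(_I64)
    stay_m = fx.const_mantissa(1.0 - params.rho, F)
    switch_m = fx.const_mantissa(params.rho, F)
    sw_w = [fx.mulshift(sm, w_m, F) for sm in switch_m]
    return _Numerics(
        frac_bits=F,
        dynamic=dynamic,
        stay_m=stay_m,
        switch_m=switch_m,
        hit_m=int(fx.const_mantissa(1.0 - params.eps, F)),
        miss_m=int(fx.const_mantissa(params.eps, F)),
        w_m=w_m,
        sw_w_m=sw_w,
    )


def _emission(num: _Numerics, cond: ConditionedPanel, graph: GenotypeGraph,
              seg: Segment, site: int) -> np.ndarray:
    """Mantissa block (n_opt, K, K) of P(alleles | copy states), exponent 0."""
    h_col = cond.alleles[:, site].astype(_I64)  # (K,)
    g = int(graph.genotypes[site])
    n_opt = seg.n_options
    if g == 1:
        j = int(np.searchsorted(seg.het_sites, site))
        a_a = seg.options[:, j].astype(_I64)  # (n_opt,)
    else:
        a_a = np.full(n_opt, g // 2, dtype=_I64)
    a_b = np.where(graph.genotypes[site] == 1, 1 - a_a, a_a)
    em_a = np.where(h_col[None, :] == a_a[:, None], num.hit_m, num.miss_m)
    em_b = np.where(h_col[None, :] == a_b[:, None], num.hit_m, num.miss_m)
    return fx.mulshift(em_a[:, :, None], em_b[:, None, :], num.frac_bits)


def _ms(a, b, frac_bits: int):
    """Mantissa product shifted down by F (single multiply when it fits)."""
    if frac_bits <= 31:
        return (np.asarray(a, dtype=_I64) * np.asarray(b, dtype=_I64)) \
            >> frac_bits
    return fx.mulshift(a, b, frac_bits)


def _k_transition_fwd(f: DfpRowMatrix, num: _Numerics, interval: int,
                      k: int) -> DfpRowMatrix:
    """Li-Stephens transition along both copy-state axes.

    Fused mantissa kernel: within an option row every entry shares the row
    exponent, so sums and scalings stay in the integer domain with log2(K)
    headroom; the caller renormalises once per site.  The result is
    value-correct at the input row exponents.
    """
    F = num.frac_bits
    stay = int(num.stay_m[interval])
    sw_w = num.sw_w_m[interval]
    h = max(int(k - 1).bit_length(), 0)
    m = f.mantissa
    for axis in (1, 2):
        s = (m >> h).sum(axis=axis)  # (n_opt, K)
        if axis == 1:
            term = _ms(sw_w.reshape(1, k, 1), s[:, None, :], F - h)
        else:
            term = _ms(sw_w.reshape(1, 1, k), s[:, :, None], F - h)
        m = _ms(m, stay, F) + term
    return DfpRowMatrix(m, f.row_exp.copy(), F, f.dynamic)


def _k_transition_bwd(u: DfpRowMatrix, num: _Numerics, interval: int,
                      k: int) -> DfpRowMatrix:
    """Transposed kernel: b(k) = (1-rho) u(k) + rho * sum_k' w(k') u(k')."""
    F = num.frac_bits
    stay = int(num.stay_m[interval])
    switch = int(num.switch_m[interval])
    m = u.mantissa
    for axis in (1, 2):
        wc = (num.w_m.reshape(1, k, 1) if axis == 1
              else num.w_m.reshape(1, 1, k))
        s = _ms(m, wc, F).sum(axis=axis)  # bounded by the row max: sum w = 1
        term = _ms(s[:, None, :] if axis == 1 else s[:, :, None], switch, F)
        m = _ms(m, stay, F) + term
    return DfpRowMatrix(m, u.row_exp.copy(), F, u.dynamic)


def _full_shape(m: DfpRowMatrix, shape: tuple) -> DfpRowMatrix:
    mant = np.broadcast_to(m.mantissa, shape).copy()
    return DfpRowMatrix(mant, m.row_exp, m.frac_bits, m.dynamic)


def _segment_of_site(graph: GenotypeGraph) -> np.ndarray:
    seg_of = np.empty(graph.genotypes.size, dtype=_I64)
    for s, seg in enumerate(graph.segments):
        seg_of[seg.start : seg.end] = s
    return seg_of


@dataclass
class TransitionPosterior:
    """Joint posterior over the phase options of two adjacent segments.

    ``joint`` is a fixed-point probability matrix (mantissa at ``frac_bits``
    fractional bits, exponent 0) summing to 1.  Conditional rows
    (``rows()``) each sum to 1 within fixed-point tolerance.
    """

    joint: np.ndarray  # (n_opt_s, n_opt_s1) mantissas
    frac_bits: int

    def as_float(self) -> np.ndarray:
        return self.joint.astype(np.float64) / float(1 << self.frac_bits)

    def rows(self) -> np.ndarray:
        j = self.joint
        v = DfpRowMatrix(j.astype(_I64), np.zeros(j.shape[0], dtype=_I64),
                         self.frac_bits, True)
        return fx.to_real(fx.renormalize_distribution(v))


@dataclass
class FBResult:
    posteriors: list  # TransitionPosterior per boundary (n_segments - 1)
    first_marginal: np.ndarray  # fixed-point mantissas over segment-0 options
    frac_bits: int


def _init_forward(num: _Numerics, cond: ConditionedPanel, graph: GenotypeGraph,
                  F: int, dynamic: bool) -> DfpRowMatrix:
    k = cond.k_cap
    seg = graph.segments[0]
    w2 = fx.mulshift(num.w_m[:, None], num.w_m[None, :], F)  # (K,K)
    e0 = _emission(num, cond, graph, seg, 0)
    inv = int(fx.const_mantissa(1.0 / seg.n_options, F))
    mant = fx.mulshift(fx.mulshift(w2[None, :, :], e0, F), inv, F)
    f = DfpRowMatrix(mant, np.zeros(seg.n_options, dtype=_I64), F, dynamic)
    return fx.normalize_rows(f)


def forward_backward(graph: GenotypeGraph, cond: ConditionedPanel,
                     params: HmmParams, frac_bits: int = fx.DEFAULT_FRAC_BITS,
                     dynamic: bool = True) -> FBResult:
    """Diploid forward-backward over (k1, k2, segment option).

    Within a segment the option is fixed and only the copy states move; at
    segment boundaries the option transitions freely under a uniform prior
    and the joint posterior over adjacent options is accumulated.  All
    arithmetic is fixed point; rows are rescaled (power of two) every site
    and exact constant-time division is applied when posteriors are formed.
    """
    g = graph.genotypes
    n_sites = g.size
    k = cond.k_cap
    F = frac_bits
    num = _make_numerics(params, cond, F, dynamic)
    seg_of = _segment_of_site(graph)
    vemit("forward_backward", n_sites, k, graph.n_segments)

    # ---- forward sweep, storing f at every site -----------------------
    f_store: list = [None] * n_sites
    f = _init_forward(num, cond, graph, F, dynamic)
    f_store[0] = f
    for i in range(1, n_sites):
        seg_prev = graph.segments[int(seg_of[i - 1])]
        seg_cur = graph.segments[int(seg_of[i])]
        if seg_cur is seg_prev:
            f = _k_transition_fwd(f, num, i - 1, k)
        else:
            mixed = fx.col_sum(f)  # (1, K, K): sum over previous options
            mixed = _k_transition_fwd(mixed, num, i - 1, k)
            inv = int(fx.const_mantissa(1.0 / seg_cur.n_options, F))
            f = fx.mul_const(_broadcast_rows(mixed, seg_cur.n_options), inv)
        f = fx.mul_const(f, _emission(num, cond, graph, seg_cur, i))
        f_store[i] = f

    # ---- backward sweep with posterior accumulation --------------------
    n_seg = graph.n_segments
    posteriors: list = [None] * max(n_seg - 1, 0)
    ones = DfpRowMatrix(
        np.full((graph.segments[-1].n_options, k, k),
                1 << (F - 1), dtype=_I64),
        np.ones(graph.segments[-1].n_options, dtype=_I64), F, dynamic)
    b = ones
    for i in range(n_sites - 1, 0, -1):
        seg_cur = graph.segments[int(seg_of[i])]
        seg_prev = graph.segments[int(seg_of[i - 1])]
        u = fx.mul_const(b, _emission(num, cond, graph, seg_cur, i))
        if seg_cur is seg_prev:
            b = _k_transition_bwd(u, num, i - 1, k)
        else:
            s = int(seg_of[i - 1])
            posteriors[s] = _boundary_posterior(
                f_store[i - 1], u, num, i - 1, k, seg_cur.n_options)
            inv = int(fx.const_mantissa(1.0 / seg_cur.n_options, F))
            mixed = fx.col_sum(fx.mul_const(u, inv))  # (1,K,K)
            mixed = _k_transition_bwd(mixed, num, i - 1, k)
            b = _broadcast_rows(mixed, seg_prev.n_options)

    first = fx.mul_elementwise(f_store[0], _full_shape(b, f_store[0].shape)) \
        if b.shape == f_store[0].shape else f_store[0]
    marg = _row_mass(first, F)
    return FBResult(posteriors=posteriors, first_marginal=marg, frac_bits=F)


def _row_mass(m: DfpRowMatrix, F: int) -> np.ndarray:
    """Renormalised per-row total mass as fixed-point probabilities."""
    flat = m.mantissa.reshape(m.n_rows, -1)
    h = max(int(flat.shape[1] - 1).bit_length(), 0)
    sums = (flat >> h).sum(axis=1)
    exps = np.where(m.row_exp == fx.EXP_ZERO, fx.EXP_ZERO, m.row_exp + h)
    live = exps != fx.EXP_ZERO
    if not live.any():
        n = m.n_rows
        return np.full(n, (1 << F) // n, dtype=_I64)
    target = exps[live].max()
    shift = np.clip(np.where(live, target - exps, 63), 0, 63)
    aligned = np.where(live, sums >> shift, 0)
    v = DfpRowMatrix(aligned.reshape(1, -1), np.array([target]), F, True)
    return fx.prob_mantissa(fx.renormalize_distribution(v)).ravel()


def _boundary_posterior(f_prev: DfpRowMatrix, u: DfpRowMatrix, num: _Numerics,
                        interval: int, k: int, n_opt_next: int
                        ) -> TransitionPosterior:
    """Joint option posterior across one segment boundary."""
    F = num.frac_bits
    v = _k_transition_fwd(f_prev, num, interval, k)
    vm = v.mantissa.reshape(v.n_rows, -1)
    um = u.mantissa.reshape(u.n_rows, -1)
    h = max(int(vm.shape[1] - 1).bit_length(), 0)
    prod = fx.mulshift(vm[:, None, :], um[None, :, :], F) >> h
    sums = prod.sum(axis=2)  # (n_opt, n_opt_next)
    exps = v.row_exp[:, None] + u.row_exp[None, :] + h
    dead = (v.row_exp[:, None] <= fx.EXP_ZERO // 2) | \
           (u.row_exp[None, :] <= fx.EXP_ZERO // 2)
    exps = np.where(dead, fx.EXP_ZERO, exps)
    live = ~dead
    if not live.any() or not num.dynamic:
        total = sums if not num.dynamic else np.zeros_like(sums)
        vrow = DfpRowMatrix(total.reshape(1, -1),
                            np.zeros(1, dtype=_I64), F, True)
    else:
        target = exps[live].max()
        shift = np.clip(np.where(live, target - exps, 63), 0, 63)
        aligned = np.where(live, sums >> shift, 0)
        vrow = DfpRowMatrix(aligned.reshape(1, -1), np.array([target]), F, True)
    joint = fx.prob_mantissa(fx.renormalize_distribution(vrow)).reshape(sums.shape)
    return TransitionPosterior(joint=joint, frac_bits=F)


# ---------------------------------------------------------------------------
# sampling, pruning, decoding
# ---------------------------------------------------------------------------

def _sample_index(weights_m: np.ndarray, rng) -> int:
    """Inverse-CDF draw on fixed-point cumulative sums, full-scan select.

    Branch-free: one rng draw and one full scan regardless of the weights;
    an all-zero weight vector falls back to index 0.
    """
    c = np.cumsum(weights_m.astype(np.int64))
    total = int(c[-1])
    r = int(rng.integers(max(total, 1)))
    return min(int((c <= r).sum()), weights_m.size - 1)


def sample_path(post: FBResult, graph: GenotypeGraph, rng) -> PhaseEstimate:
    """Backward sampling of segment options from the transition posteriors."""
    n_seg = graph.n_segments
    if n_seg == 1:
        m = _sample_index(post.first_marginal, rng)
        return expand_options(graph, [m])
    opts = [0] * n_seg
    last_joint = post.posteriors[-1].joint
    opts[-1] = _sample_index(last_joint.sum(axis=0), rng)
    for s in range(n_seg - 2, -1, -1):
        joint = post.posteriors[s].joint
        nxt = opts[s + 1]
        sel = (np.arange(joint.shape[1]) == nxt).astype(np.int64)
        col = joint @ sel  # oblivious one-hot column read
        opts[s] = _sample_index(col, rng)
    return expand_options(graph, opts)


def _complement_index(n_opt: int) -> np.ndarray:
    return np.arange(n_opt)[::-1].copy()


def prune(graph: GenotypeGraph, post: FBResult, threshold: float = 0.999
          ) -> GenotypeGraph:
    """Merge adjacent segments whose best option transition is confident.

    Confidence is the swap-symmetrised joint mass of an option pair (a path
    and its global haplotype complement are the same phase).  Merged
    segments keep only the chosen transition and its complement, and are
    never re-split.
    """
    if graph.n_segments == 1:
        return graph
    F = post.frac_bits
    thr = int(round(threshold * (1 << F)))
    segments = list(graph.segments)
    merged: list = [segments[0]]
    tail_map = np.arange(segments[0].n_options)  # merged option -> tail option
    n_merges = graph.n_merges
    for s in range(graph.n_segments - 1):
        joint = post.posteriors[s].joint
        nxt = segments[s + 1]
        cur = merged[-1]
        # restrict rows to the surviving tail options of the merged head
        sub = joint[tail_map, :]
        sym = sub + sub[::-1, ::-1]
        best = int(sym.max())
        if best > thr and cur.het_sites.size and nxt.het_sites.size:
            i, j = np.unravel_index(int(np.argmax(sym)), sym.shape)
            pat = np.concatenate([cur.options[i], nxt.options[j]])
            options = np.stack([pat, 1 - pat])
            merged[-1] = Segment(
                het_sites=np.concatenate([cur.het_sites, nxt.het_sites]),
                options=options.astype(np.int8),
                start=cur.start,
                end=nxt.end,
            )
            tail_map = np.array([j, nxt.n_options - 1 - j])
            n_merges += 1
        else:
            merged.append(nxt)
            tail_map = np.arange(nxt.n_options)
    return GenotypeGraph(graph.genotypes, merged, n_merges)


def _k_transition_max(f: DfpRowMatrix, num: _Numerics, interval: int, k: int):
    """Max-product transition along both axes with compressed backpointers.

    Both the stay and switch candidates live at the row's exponent, so the
    compare-select runs directly on mantissas (constant-shape, branch-free).
    """
    F = num.frac_bits
    stay = int(num.stay_m[interval])
    sw_w = num.sw_w_m[interval]
    m = f.mantissa
    bps = []
    for axis in (1, 2):
        cmax = m.max(axis=axis)  # within-row: exps uniform
        carg = m.argmax(axis=axis)
        if axis == 1:
            term = _ms(sw_w.reshape(1, k, 1), cmax[:, None, :], F)
            carg_b = np.broadcast_to(carg[:, None, :], m.shape)
            own = np.arange(k).reshape(1, k, 1)
        else:
            term = _ms(sw_w.reshape(1, 1, k), cmax[:, :, None], F)
            carg_b = np.broadcast_to(carg[:, :, None], m.shape)
            own = np.arange(k).reshape(1, 1, k)
        stay_t = _ms(m, stay, F)
        term = np.broadcast_to(term, stay_t.shape)
        stay_wins = stay_t >= term
        m = np.where(stay_wins, stay_t, term)
        bp = np.where(stay_wins, np.broadcast_to(own, m.shape), carg_b)
        bps.append(bp.astype(np.int16))
    out = DfpRowMatrix(m, f.row_exp.copy(), F, f.dynamic)
    return out, bps


def viterbi_decode(graph: GenotypeGraph, cond: ConditionedPanel,
                   params: HmmParams, frac_bits: int = fx.DEFAULT_FRAC_BITS,
                   dynamic: bool = True):
    """Max-product decode of the most likely phase.

    Returns ``(PhaseEstimate, (exp, mantissa))`` where the second element is
    the fixed-point path likelihood, comparable across runs of the same
    window.  Max and argmax are computed by aligned mantissa comparison
    (constant-shape compare-select).
    """
    g = graph.genotypes
    n_sites = g.size
    k = cond.k_cap
    F = frac_bits
    num = _make_numerics(params, cond, F, dynamic)
    seg_of = _segment_of_site(graph)
    vemit("viterbi", n_sites, k, graph.n_segments)

    m = _init_forward(num, cond, graph, F, dynamic)
    bp1_store: list = [None] * n_sites
    bp2_store: list = [None] * n_sites
    bpo_store: list = [None] * n_sites
    for i in range(1, n_sites):
        seg_prev = graph.segments[int(seg_of[i - 1])]
        seg_cur = graph.segments[int(seg_of[i])]
        m, bps = _k_transition_max(m, num, i - 1, k)
        bp1_store[i], bp2_store[i] = bps
        if seg_cur is not seg_prev:
            target = m.row_exp.max()
            aligned = fx.align_rows(m, np.full(m.n_rows, target, dtype=_I64))
            bpo_store[i] = aligned.argmax(axis=0).astype(np.int16)  # (K,K)
            best = aligned.max(axis=0)[None, :, :]
            mixed = fx.normalize_rows(DfpRowMatrix(
                best, np.array([target]), F, dynamic))
            inv = int(fx.const_mantissa(1.0 / seg_cur.n_options, F))
            m = fx.mul_const(_broadcast_rows(mixed, seg_cur.n_options), inv)
        m = fx.mul_const(m, _emission(num, cond, graph, seg_cur, i))

    target = m.row_exp.max()
    aligned = fx.align_rows(m, np.full(m.n_rows, target, dtype=_I64))
    flat_idx = int(np.argmax(aligned))
    o, k1, k2 = np.unravel_index(flat_idx, m.shape)
    likelihood = (int(target), int(aligned.reshape(-1)[flat_idx]))

    opts = [0] * graph.n_segments
    opts[int(seg_of[n_sites - 1])] = int(o)
    for i in range(n_sites - 1, 0, -1):
        if bpo_store[i] is not None:
            o = int(bpo_store[i][k1, k2])
            opts[int(seg_of[i - 1])] = int(o)
        k2n = int(bp2_store[i][o, k1, k2])
        k1n = int(bp1_store[i][o, k1, k2n])
        k1, k2 = k1n, k2n
    return expand_options(graph, opts), likelihood


# ---------------------------------------------------------------------------
# the MCMC loop
# ---------------------------------------------------------------------------

DEFAULT_SCHEDULE = ("burnin",) * 5 + ("prune", "burnin", "prune", "burnin",
                                      "prune") + ("main",) * 5


@dataclass
class PhaseConfig:
    """Tunable parameters of the phasing run."""

    seed: int = 0
    S: int = 4
    H_seg: int = 3
    Ne: float = DEFAULT_NE
    eps: float = DEFAULT_EPS
    prune_threshold: float = 0.999
    schedule: tuple = DEFAULT_SCHEDULE
    window_min_segments: int = 20
    min_het_rate: float = 0.10
    k_max: int = 32
    frac_bits: int = 31
    dynamic_scaling: bool = True
    static_frac_bits: int = 52
    max_width: int = 32
    max_uniques: int = 256
    window_overlap: int = 100

    def window_size(self) -> int:
        """Sites per window so the expected het count covers
        ``window_min_segments`` segments at the minimum het rate."""
        return int(np.ceil(self.H_seg * self.window_min_segments
                           / self.min_het_rate))

    def numeric_mode(self):
        if self.dynamic_scaling:
            return self.frac_bits, True
        return self.static_frac_bits, False


def phase_window(genotypes: np.ndarray, panel: HaplotypePanel,
                 config: PhaseConfig, rng,
                 cm_dist: np.ndarray | None = None) -> PhaseEstimate:
    """Run the full MCMC schedule on one window."""
    g = np.asarray(genotypes, dtype=np.int8)
    if g.size != panel.n_sites:
        raise ValueError("target and panel cover different site sets")
    graph = build_genotype_graph(g, config.H_seg)
    est = init_phase(graph, rng)
    if graph.segments[0].het_sites.size == 0 and graph.n_segments == 1:
        return est  # nothing to phase
    cp = compress_panel(panel, config.max_width, config.max_uniques)
    trees = build_trees(cp)
    panel_alleles = panel.alleles
    F, dynamic = config.numeric_mode()
    best: tuple | None = None
    best_est = est
    for stage in config.schedule:
        positions = select_search_positions(graph, rng)
        sets = []
        for hap in (est.hap_a, est.hap_b):
            inserted = insert_estimate(trees, hap.astype(np.int64))
            for p in positions:
                sets.append(find_neighbors(trees, inserted, p, config.S))
        k_cap = min(len(sets) * config.S, config.k_max, panel.n_hap)
        cond = build_conditioned_panel(sets, cp, k_cap, panel_alleles)
        params = make_hmm_params(panel.n_sites, cond.k_cap, cm_dist,
                                 config.Ne, config.eps)
        if stage == "main":
            decoded, lik = viterbi_decode(graph, cond, params, F, dynamic)
            if best is None or lik > best:
                best, best_est = lik, decoded
            est = decoded
        else:
            fb = forward_backward(graph, cond, params, F, dynamic)
            est = sample_path(fb, graph, rng)
            if stage == "prune":
                new_graph = prune(graph, fb, config.prune_threshold)
                if new_graph.n_segments != graph.n_segments:
                    graph = new_graph
                    est = _remap_estimate(graph, est)
    return best_est if best is not None else est


def iteration_trace(genotypes: np.ndarray, panel: HaplotypePanel,
                    config: PhaseConfig, est_rng, pos_seed: int = 0):
    """Access trace of one full sampling iteration for a random phase secret.

    The genotype-graph shape, panel and search positions are held fixed
    (public); the phase estimate -- the secret input of an iteration -- is
    resampled from ``est_rng``.  Two calls with different ``est_rng`` draws
    must produce identical traces.
    """
    from .oblivious import trace_capture  # noqa: PLC0415

    g = np.asarray(genotypes, dtype=np.int8)
    graph = build_genotype_graph(g, config.H_seg)
    est = init_phase(graph, est_rng)
    pos_rng = np.random.default_rng(pos_seed)
    positions = select_search_positions(graph, pos_rng)
    cp = compress_panel(panel, config.max_width, config.max_uniques)
    trees = build_trees(cp)
    F, dynamic = config.numeric_mode()

    def _run():
        sets = []
        for hap in (est.hap_a, est.hap_b):
            inserted = insert_estimate(trees, hap.astype(np.int64))
            for p in positions:
                sets.append(find_neighbors(trees, inserted, p, config.S))
        k_cap = min(len(sets) * config.S, config.k_max, panel.n_hap)
        cond = build_conditioned_panel(sets, cp, k_cap, panel.alleles)
        params = make_hmm_params(panel.n_sites, cond.k_cap, None,
                                 config.Ne, config.eps)
        fb = forward_backward(graph, cond, params, F, dynamic)
        sample_path(fb, graph, np.random.default_rng(0))

    return trace_capture(_run)


def _remap_estimate(graph: GenotypeGraph, est: PhaseEstimate) -> PhaseEstimate:
    """Re-express a haplotype pair as options of a (newly pruned) graph."""
    opts = []
    for seg in graph.segments:
        if seg.het_sites.size == 0:
            opts.append(0)
            continue
        pat = est.hap_a[seg.het_sites]
        agree = (seg.options == pat[None, :]).sum(axis=1)
        opts.append(int(np.argmax(agree)))
    return expand_options(graph, opts)


def mcmc_run(genotypes: np.ndarray, panel: HaplotypePanel, config: PhaseConfig,
             rng=None, cm_dist: np.ndarray | None = None) -> PhaseEstimate:
    """Phase a full target: independent fixed-size windows, stitched.

    Windows overlap by ``config.window_overlap`` sites; the relative
    orientation of each successive window is flipped when that increases
    het-phase agreement over the overlap.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    g = np.asarray(genotypes, dtype=np.int8)
    if g.size != panel.n_sites:
        raise ValueError("target and panel cover different site sets")
    wsize = config.window_size()
    if g.size <= wsize:
        return phase_window(g, panel, config, rng, cm_dist)
    step = wsize - config.window_overlap
    starts = list(range(0, max(g.size - config.window_overlap, 1), step))
    pieces = []
    for s in starts:
        e = min(s + wsize, g.size)
        sub_panel = HaplotypePanel(
            panel.alleles[:, s:e],
            panel.site_ids[s:e],
            panel.positions[s:e],
        )
        sub_cm = None if cm_dist is None else cm_dist[s : e - 1]
        pieces.append((s, e, phase_window(g[s:e], sub_panel, config, rng,
                                          sub_cm)))
        if e == g.size:
            break
    return stitch_windows(pieces, g.size)


def stitch_windows(window_estimates: list, n_sites: int | None = None
                   ) -> PhaseEstimate:
    """Join overlapping window estimates into one haplotype pair.

    Each window is ``(start, end, PhaseEstimate)``.  The next window is
    flipped when flipping increases het-site agreement over the overlap with
    the current consensus; the overlap is then handed over at its midpoint.
    Deterministic in its inputs.
    """
    if not window_estimates:
        raise ValueError("no windows to stitch")
    window_estimates = sorted(window_estimates, key=lambda t: t[0])
    s0, e0, first = window_estimates[0]
    if n_sites is None:
        n_sites = max(e for _, e, _ in window_estimates)
    hap_a = np.zeros(n_sites, dtype=np.int8)
    hap_b = np.zeros(n_sites, dtype=np.int8)
    hap_a[s0:e0] = first.hap_a
    hap_b[s0:e0] = first.hap_b
    covered = e0
    for s, e, est in window_estimates[1:]:
        ov_lo, ov_hi = s, min(covered, e)
        ea, eb = est.hap_a, est.hap_b
        if ov_hi > ov_lo:
            cur = hap_a[ov_lo:ov_hi]
            het = hap_a[ov_lo:ov_hi] != hap_b[ov_lo:ov_hi]
            keep = (cur == ea[ov_lo - s : ov_hi - s]) & het
            flip = (cur == eb[ov_lo - s : ov_hi - s]) & het
            if flip.sum() > keep.sum():
                ea, eb = eb, ea
            mid = (ov_lo + ov_hi) // 2
        else:
            mid = s
        hap_a[mid:e] = ea[mid - s :]
        hap_b[mid:e] = eb[mid - s :]
        covered = max(covered, e)
    return PhaseEstimate(hap_a, hap_b, [])
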