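"""Dynamically scaled fixed-point matrices.

Real values are represented as signed 64-bit integer mantissas with ``F``
fractional bits plus one power-of-two exponent *per row*:

    value[i, j] = mantissa[i, j] * 2**(row_exp[i] - F)

After :func:`normalize_rows` the largest magnitude in every non-zero row lies
in ``[0.5, 1)`` (mantissa in ``[2**(F-1), 2**F)``), so nearly all mantissa
bits carry signal regardless of the absolute scale of the row -- the property
that keeps long products of small probabilities from underflowing to zero.
All-zero rows carry the reserved exponent :data:`EXP_ZERO`.

Every operation is built from integer adds, multiplies and uniform bit
shifts; shift amounts are computed with branch-free bit tricks and applied
to whole rows at once, so the sequence of memory accesses depends only on
the matrix shape.  Rounding is truncation (arithmetic right shift, toward
negative infinity); the sub-ulp bias this introduces is absorbed by the
per-operation tolerance budget.

A ``dynamic=False`` matrix freezes every row exponent at zero, giving the
classic static fixed-point scheme (e.g. ``F = 52``) that the dynamic scheme
is designed to outperform: with static scaling, long chains of small factors
underflow and whole distributions collapse to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .oblivious import ct_divide_frac, vemit

__all__ = [
    "DfpRowMatrix",
    "EXP_ZERO",
    "DEFAULT_FRAC_BITS",
    "from_real",
    "to_real",
    "normalize_rows",
    "add",
    "mul_elementwise",
    "mul_const",
    "sum_axis",
    "col_sum",
    "matvec",
    "renormalize_distribution",
    "maximum",
    "align_rows",
    "mulshift",
    "const_mantissa",
]

DEFAULT_FRAC_BITS = 60
EXP_ZERO = -(1 << 40)  # reserved exponent of all-zero rows
_I64 = np.int64


@dataclass
class DfpRowMatrix:
    """Integer mantissas with one power-of-two scaling exponent per row.

    ``mantissa`` has shape ``(R, ...)``; the leading axis indexes rows and
    ``row_exp`` has shape ``(R,)``.  Trailing axes are free (a vector is a
    single row, the phasing engine uses ``(options, K, K)`` blocks).
    """

    mantissa: np.ndarray
    row_exp: np.ndarray
    frac_bits: int = DEFAULT_FRAC_BITS
    dynamic: bool = True

    @property
    def n_rows(self) -> int:
        return self.mantissa.shape[0]

    @property
    def shape(self) -> tuple:
        return self.mantissa.shape

    def copy(self) -> "DfpRowMatrix":
        return DfpRowMatrix(
            self.mantissa.copy(), self.row_exp.copy(), self.frac_bits, self.dynamic
        )

    def _exp_bcast(self) -> np.ndarray:
        return self.row_exp.reshape((self.n_rows,) + (1,) * (self.mantissa.ndim - 1))


def vector(mantissa: np.ndarray, exp: int, frac_bits: int = DEFAULT_FRAC_BITS,
           dynamic: bool = True) -> DfpRowMatrix:
    """A DfpVector: single-row matrix over a trailing value axis."""
    m = np.asarray(mantissa, dtype=_I64).reshape(1, -1)
    return DfpRowMatrix(m, np.array([exp], dtype=_I64), frac_bits, dynamic)


# ---------------------------------------------------------------------------
# bit-level helpers
# ---------------------------------------------------------------------------

def _bit_length(x: np.ndarray) -> np.ndarray:
    """Bit length of non-negative int64 values, branch-free."""
    x = x.astype(np.uint64)
    for s in (1, 2, 4, 8, 16, 32):
        x = x | (x >> np.uint64(s))
    return np.bitwise_count(x).astype(_I64)


def _shift_rows(mantissa: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Apply per-row shifts (positive = left) uniformly; clipped to +/-63."""
    s = np.minimum(np.maximum(shift, -63), 63)
    left = np.maximum(s, 0)
    right = np.maximum(-s, 0)
    return (mantissa << left) >> right


_MASK31 = (1 << 31) - 1


def mulshift(a: np.ndarray, b, shift: int) -> np.ndarray:
    """Exact ``floor(a * b / 2**shift)`` for int64 operands, |a|,|b| < 2**61.

    The 128-bit intermediate product is formed from 31-bit limbs so that every
    partial product fits in a signed 64-bit word; requires 31 <= shift <= 62.
    """
    if not 31 <= shift <= 62:
        raise ValueError("mulshift supports 31 <= shift <= 62")
    a = np.asarray(a, dtype=_I64)
    b = np.asarray(b, dtype=_I64)
    vemit("mulshift", np.broadcast_shapes(a.shape, b.shape))
    if shift == 31:
        # operands bounded by 2**31 (normalised mantissas at F = 31):
        # the product fits a single signed 64-bit word
        return (a * b) >> 31
    a1, a0 = a >> 31, a & _MASK31
    b1, b0 = b >> 31, b & _MASK31
    t2 = a1 * b1
    t0 = a0 * b0
    m = a1 * b0 + a0 * b1 + (t0 >> 31)
    # a*b = t2*2^62 + m*2^31 + (t0 & MASK31); the sub-2^shift residue is
    # provably < 2^shift so it never contributes to the floor.
    return (t2 << (62 - shift)) + (m >> (shift - 31))


def const_mantissa(x, frac_bits: int = DEFAULT_FRAC_BITS) -> np.ndarray:
    """Encode public constants in [-2, 2) as mantissas at exponent 0."""
    return np.round(np.asarray(x, dtype=np.float64) * float(1 << frac_bits)).astype(_I64)


# ---------------------------------------------------------------------------
# encoding boundary
# ---------------------------------------------------------------------------

def from_real(x, frac_bits: int = DEFAULT_FRAC_BITS, dynamic: bool = True) -> DfpRowMatrix:
    """Encode a real matrix; reals exist only at this ingest/egress boundary."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    r = x.shape[0]
    if dynamic:
        maxabs = np.max(np.abs(x).reshape(r, -1), axis=1)
        _, e = np.frexp(maxabs)
        exp = np.where(maxabs > 0, e.astype(_I64), EXP_ZERO)
        scale = np.exp2(frac_bits - np.where(maxabs > 0, exp, 0).astype(np.float64))
        mant = np.round(x * scale.reshape((r,) + (1,) * (x.ndim - 1))).astype(_I64)
        out = DfpRowMatrix(mant, exp, frac_bits, True)
        return normalize_rows(out)
    mant = np.round(x * float(1 << frac_bits)).astype(_I64)
    return DfpRowMatrix(mant, np.zeros(r, dtype=_I64), frac_bits, False)


def to_real(m: DfpRowMatrix) -> np.ndarray:
    """Evaluate the representation formula in double precision."""
    e = np.where(m.row_exp == EXP_ZERO, 0, m.row_exp) - m.frac_bits
    scale = np.exp2(e.astype(np.float64))
    return m.mantissa.astype(np.float64) * scale.reshape(
        (m.n_rows,) + (1,) * (m.mantissa.ndim - 1)
    )


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

def normalize_rows(m: DfpRowMatrix) -> DfpRowMatrix:
    """Rescale each row so its largest magnitude falls in [0.5, 1).

    Value-preserving apart from right-shift truncation (at most one ulp per
    entry).  Idempotent; all-zero rows get the reserved exponent.  Static
    matrices are returned unchanged (their exponents are frozen at zero).
    """
    if not m.dynamic:
        return m
    flat = np.abs(m.mantissa).reshape(m.n_rows, -1)
    vemit("normalize", m.shape)
    maxabs = flat.max(axis=1)
    nb = _bit_length(maxabs)
    shift = np.where(maxabs > 0, m.frac_bits - nb, 0)
    mant = _shift_rows(m.mantissa, shift.reshape(m._exp_bcast().shape))
    exp = np.where(maxabs > 0, m.row_exp - shift, EXP_ZERO)
    return DfpRowMatrix(mant, exp.astype(_I64), m.frac_bits, True)


def align_rows(m: DfpRowMatrix, target_exp: np.ndarray) -> np.ndarray:
    """Mantissas re-expressed at the given per-row exponents (>= current)."""
    shift = np.maximum(target_exp - np.where(m.row_exp == EXP_ZERO,
                                             target_exp, m.row_exp), 0)
    return _shift_rows(m.mantissa, -shift.reshape(m._exp_bcast().shape))


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def _check_pair(a: DfpRowMatrix, b: DfpRowMatrix) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.frac_bits != b.frac_bits or a.dynamic != b.dynamic:
        raise ValueError("operands must share frac_bits and scaling mode")


def add(a: DfpRowMatrix, b: DfpRowMatrix) -> DfpRowMatrix:
    """Row-wise aligned addition with one headroom bit against overflow."""
    _check_pair(a, b)
    vemit("dfp_add", a.shape)
    if not a.dynamic:
        return DfpRowMatrix(a.mantissa + b.mantissa, a.row_exp.copy(),
                            a.frac_bits, False)
    target = np.maximum(a.row_exp, b.row_exp) + 1
    target = np.where((a.row_exp == EXP_ZERO) & (b.row_exp == EXP_ZERO),
                      EXP_ZERO + 1, target)
    mant = align_rows(a, target) + align_rows(b, target)
    return normalize_rows(DfpRowMatrix(mant, target.astype(_I64), a.frac_bits, True))


def mul_elementwise(a: DfpRowMatrix, b: DfpRowMatrix) -> DfpRowMatrix:
    """Element-wise product; row exponents add, mantissas multiply at
    double width and shift back down by F."""
    _check_pair(a, b)
    mant = mulshift(a.mantissa, b.mantissa, a.frac_bits)
    if not a.dynamic:
        return DfpRowMatrix(mant, a.row_exp.copy(), a.frac_bits, False)
    exp = a.row_exp + b.row_exp
    exp = np.where((a.row_exp == EXP_ZERO) | (b.row_exp == EXP_ZERO), EXP_ZERO, exp)
    return normalize_rows(DfpRowMatrix(mant, exp.astype(_I64), a.frac_bits, True))


def mul_const(a: DfpRowMatrix, c_mant, c_exp: int = 0) -> DfpRowMatrix:
    """Multiply by a broadcastable block of mantissas at a shared exponent.

    Used for public model constants and secret-but-shape-public factors such
    as emission tables: ``c`` represents ``c_mant * 2**(c_exp - F)``.
    """
    mant = mulshift(a.mantissa, np.asarray(c_mant, dtype=_I64), a.frac_bits)
    if not a.dynamic:
        return DfpRowMatrix(mant, a.row_exp.copy(), a.frac_bits, False)
    exp = np.where(a.row_exp == EXP_ZERO, EXP_ZERO, a.row_exp + c_exp)
    return normalize_rows(DfpRowMatrix(mant, exp.astype(_I64), a.frac_bits, True))


def _headroom(n: int) -> int:
    return max(int(n - 1).bit_length(), 0)


def sum_axis(a: DfpRowMatrix, axis: int) -> DfpRowMatrix:
    """Sum within rows along a trailing axis, with log2(n) headroom bits."""
    if axis == 0:
        raise ValueError("use col_sum to reduce across rows")
    n = a.shape[axis]
    h = _headroom(n)
    vemit("dfp_sum_axis", a.shape, axis)
    if not a.dynamic:
        return DfpRowMatrix(a.mantissa.sum(axis=axis), a.row_exp.copy(),
                            a.frac_bits, False)
    mant = (a.mantissa >> h).sum(axis=axis)
    exp = np.where(a.row_exp == EXP_ZERO, EXP_ZERO, a.row_exp + h)
    return normalize_rows(DfpRowMatrix(mant, exp.astype(_I64), a.frac_bits, True))


def col_sum(m: DfpRowMatrix) -> DfpRowMatrix:
    """Column-wise sum across rows: all rows are first brought to the highest
    scale (plus headroom) to minimise precision loss."""
    vemit("dfp_col_sum", m.shape)
    if not m.dynamic:
        mant = m.mantissa.sum(axis=0, keepdims=True)
        return DfpRowMatrix(mant, np.zeros(1, dtype=_I64), m.frac_bits, False)
    h = _headroom(m.n_rows)
    live = m.row_exp != EXP_ZERO
    if not live.any():
        mant = np.zeros((1,) + m.shape[1:], dtype=_I64)
        return DfpRowMatrix(mant, np.array([EXP_ZERO], dtype=_I64), m.frac_bits, True)
    target = np.full(m.n_rows, m.row_exp[live].max() + h, dtype=_I64)
    mant = align_rows(m, target).sum(axis=0, keepdims=True)
    return normalize_rows(
        DfpRowMatrix(mant, target[:1].copy(), m.frac_bits, True)
    )


def matvec(m: DfpRowMatrix, v: DfpRowMatrix) -> DfpRowMatrix:
    """Row-by-vector dot products: elementwise product then per-row sum,
    with results aligned to a common exponent as a single-row vector."""
    if v.n_rows != 1 or m.shape[1:] != v.shape[1:]:
        raise ValueError("matvec needs a single-row vector matching m's rows")
    prod = mulshift(m.mantissa, v.mantissa, m.frac_bits)
    h = _headroom(int(np.prod(m.shape[1:])))
    vemit("dfp_matvec", m.shape)
    if not m.dynamic:
        mant = prod.reshape(m.n_rows, -1).sum(axis=1).reshape(1, -1)
        return DfpRowMatrix(mant, np.zeros(1, dtype=_I64), m.frac_bits, False)
    sums = (prod.reshape(m.n_rows, -1) >> h).sum(axis=1)
    exps = np.where((m.row_exp == EXP_ZERO) | (v.row_exp[0] == EXP_ZERO),
                    EXP_ZERO, m.row_exp + v.row_exp[0] + h)
    live = exps != EXP_ZERO
    if not live.any():
        return DfpRowMatrix(np.zeros((1, m.n_rows), dtype=_I64),
                            np.array([EXP_ZERO], dtype=_I64), m.frac_bits, True)
    target = exps[live].max()
    mant = _shift_rows(sums, -(np.where(live, target - exps, 0))).reshape(1, -1)
    mant = np.where(live.reshape(1, -1), mant, 0)
    return normalize_rows(DfpRowMatrix(mant, np.array([target], dtype=_I64),
                                       m.frac_bits, True))


def renormalize_distribution(v: DfpRowMatrix) -> DfpRowMatrix:
    """Divide each row by its sum so entries sum to 1 (+/- n ulp).

    Division is constant-time restoring long division with ``F`` iterations.
    All-zero rows become the uniform distribution 1/n -- the stated
    convention that keeps downstream sampling total.  Entries are assumed
    non-negative (probability mass).
    """
    flat = v.mantissa.reshape(v.n_rows, -1)
    n = flat.shape[1]
    h = _headroom(n)
    num = flat >> h
    den = num.sum(axis=1, keepdims=True)
    q = ct_divide_frac(num, den, v.frac_bits)
    uniform = (1 << v.frac_bits) // n
    q = np.where(den == 0, uniform, q)
    out = DfpRowMatrix(q.reshape(v.shape), np.zeros(v.n_rows, dtype=_I64),
                       v.frac_bits, v.dynamic)
    return normalize_rows(out)


def prob_mantissa(v: DfpRowMatrix) -> np.ndarray:
    """Mantissas re-expressed at exponent 0 (``value * 2**F`` as integers).

    Intended for normalised probability vectors whose values lie in [0, 1],
    so the result always fits; all-zero rows yield zeros.
    """
    e = np.where(v.row_exp == EXP_ZERO, 0, v.row_exp)
    return _shift_rows(v.mantissa, e.reshape(v._exp_bcast().shape))


def maximum(a: DfpRowMatrix, b: DfpRowMatrix) -> DfpRowMatrix:
    """Element-wise maximum after aligning row scales (for Viterbi)."""
    _check_pair(a, b)
    vemit("dfp_max", a.shape)
    if not a.dynamic:
        return DfpRowMatrix(np.maximum(a.mantissa, b.mantissa),
                            a.row_exp.copy(), a.frac_bits, False)
    target = np.maximum(a.row_exp, b.row_exp)
    mant = np.maximum(align_rows(a, target), align_rows(b, target))
    return normalize_rows(DfpRowMatrix(mant, target.astype(_I64), a.frac_bits, True))
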