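"""Data-oblivious building blocks.

Every operation in this module has a memory-access pattern and control flow
that depend only on *public* shape parameters (array lengths, bit widths),
never on the values of the data being processed.  Secret-derived values are
carried in :class:`Secret` wrappers; arrays may only be indexed by a secret
through :func:`oblivious_read` / :func:`oblivious_write`, which scan the whole
array on every access (linear-scanning ORAM).  Branches on secret conditions
are replaced by :func:`cond_select`, which materialises both operands.

The obliviousness contract is *algorithmic*: a trace harness
(:func:`trace_capture`) records the sequence of instrumented accesses, and the
test suite asserts that traces are byte-identical across different secret
inputs of the same shape.  No claim is made about microarchitectural timing,
which a high-level language cannot control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np

__all__ = [
    "Secret",
    "AccessTrace",
    "trace_capture",
    "oblivious_read",
    "oblivious_write",
    "cond_select",
    "bitonic_sort",
    "bitonic_network_size",
    "oblivious_filter",
    "ct_divide",
    "ct_divide_frac",
    "one_hot",
    "SENTINEL",
]


# ---------------------------------------------------------------------------
# Access-trace harness
# ---------------------------------------------------------------------------

@dataclass
class AccessTrace:
    """Ordered record of instrumented memory accesses and vector operations.

    Events are tuples whose entries are public quantities only (operation
    tags, array lengths, loop indices, shapes).  For a fixed set of public
    shape parameters the trace must be a deterministic function of those
    shapes alone -- identical across all secret inputs.
    """

    events: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AccessTrace) and self.events == other.events


_RECORDER: AccessTrace | None = None


def _emit(*event: Any) -> None:
    if _RECORDER is not None:
        _RECORDER.events.append(event)


def vemit(tag: str, *shape: Any) -> None:
    """Record a coarse event for a vectorised whole-array operation.

    A single numpy call over a fixed-shape array touches every element in a
    fixed order; one event carrying the tag and the shape is the faithful
    trace-level description of such an access.
    """
    if _RECORDER is not None:
        _RECORDER.events.append((tag,) + shape)


def trace_capture(op_closure: Callable[[], Any]) -> AccessTrace:
    """Run ``op_closure`` and return the trace of instrumented accesses."""
    global _RECORDER
    previous = _RECORDER
    trace = AccessTrace()
    _RECORDER = trace
    try:
        op_closure()
    finally:
        _RECORDER = previous
    return trace


# ---------------------------------------------------------------------------
# Secret tagging
# ---------------------------------------------------------------------------

class Secret:
    """A value derived from user input.

    Any arithmetic or comparison involving a ``Secret`` yields a ``Secret``.
    Using a ``Secret`` where a plain value is required (array subscript, ``if``
    condition, ``len``) raises immediately, so accidental secret-dependent
    indexing or branching fails loudly.  ``expose()`` is the single, explicit
    declassification point.
    """

    __slots__ = ("value",)
    __array_ufunc__ = None  # keep numpy from consuming us in mixed expressions

    def __init__(self, value: Any):
        if isinstance(value, Secret):
            value = value.value
        self.value = value

    # -- explicit declassification -------------------------------------
    def expose(self) -> Any:
        """Explicitly convert to a non-secret value (contract boundary)."""
        return self.value

    # -- contract violations -------------------------------------------
    def __bool__(self) -> bool:
        raise TypeError("cannot branch on a Secret; use cond_select")

    def __index__(self) -> int:
        raise TypeError("cannot index with a Secret; use oblivious_read/write")

    def __repr__(self) -> str:
        return "Secret(<hidden>)"

    # -- arithmetic: always returns Secret ------------------------------
    def _bin(self, other: Any, op: Callable[[Any, Any], Any]) -> "Secret":
        other_v = other.value if isinstance(other, Secret) else other
        return Secret(op(self.value, other_v))

    def __add__(self, o):
        return self._bin(o, lambda a, b: a + b)

    __radd__ = __add__

    def __sub__(self, o):
        return self._bin(o, lambda a, b: a - b)

    def __rsub__(self, o):
        return self._bin(o, lambda a, b: b - a)

    def __mul__(self, o):
        return self._bin(o, lambda a, b: a * b)

    __rmul__ = __mul__

    def __and__(self, o):
        return self._bin(o, lambda a, b: a & b)

    __rand__ = __and__

    def __or__(self, o):
        return self._bin(o, lambda a, b: a | b)

    __ror__ = __or__

    def __xor__(self, o):
        return self._bin(o, lambda a, b: a ^ b)

    __rxor__ = __xor__

    def __invert__(self):
        return Secret(~self.value)

    def __neg__(self):
        return Secret(-self.value)

    def __lshift__(self, o):
        return self._bin(o, lambda a, b: a << b)

    def __rshift__(self, o):
        return self._bin(o, lambda a, b: a >> b)

    def __eq__(self, o):  # type: ignore[override]
        return self._bin(o, lambda a, b: a == b)

    def __ne__(self, o):  # type: ignore[override]
        return self._bin(o, lambda a, b: a != b)

    def __lt__(self, o):
        return self._bin(o, lambda a, b: a < b)

    def __le__(self, o):
        return self._bin(o, lambda a, b: a <= b)

    def __gt__(self, o):
        return self._bin(o, lambda a, b: a > b)

    def __ge__(self, o):
        return self._bin(o, lambda a, b: a >= b)

    __hash__ = None  # type: ignore[assignment]


def _sval(x: Any) -> Any:
    return x.value if isinstance(x, Secret) else x


# ---------------------------------------------------------------------------
# Linear-scanning ORAM
# ---------------------------------------------------------------------------

def oblivious_read(arr: Sequence | np.ndarray, idx: Secret | int) -> Secret:
    """Read ``arr[idx]`` touching every element in fixed ascending order.

    Out-of-range indices yield the sentinel value 0 rather than raising:
    a data-dependent exception would itself be a side channel.
    """
    i = _sval(idx)
    a = np.asarray(arr)
    n = a.shape[0]
    if _RECORDER is not None:
        for k in range(n):
            _RECORDER.events.append(("read", n, k))
    sel = (np.arange(n) == i)
    if a.ndim == 1:
        out = (a * sel).sum()
        return Secret(out.item() if np.isscalar(i) or np.ndim(i) == 0 else out)
    # rows: one-hot contraction touches every row uniformly
    return Secret(np.tensordot(sel.astype(a.dtype), a, axes=(0, 0)))


def oblivious_write(arr: np.ndarray | list, idx: Secret | int, v: Secret | Any):
    """Set ``arr[idx] = v`` rewriting every position (unchanged values too)."""
    i = _sval(idx)
    val = _sval(v)
    n = len(arr)
    if _RECORDER is not None:
        for k in range(n):
            _RECORDER.events.append(("write", n, k))
    if isinstance(arr, np.ndarray):
        sel = np.arange(n) == i
        arr[:] = np.where(sel, val, arr)
    else:
        for k in range(n):
            sel = int(k == i)
            arr[k] = arr[k] + (val - arr[k]) * sel  # branch-free two-way mux
    return arr


def one_hot(idx: Secret | int, n: int, dtype=np.int64) -> Secret:
    """Length-``n`` indicator vector of a (secret) index, built by full scan."""
    vemit("one_hot", n)
    return Secret((np.arange(n) == _sval(idx)).astype(dtype))


# ---------------------------------------------------------------------------
# Deterministic multiplexer
# ---------------------------------------------------------------------------

def cond_select(c: Secret | bool, a: Any, b: Any) -> Secret:
    """Return ``a`` if ``c`` else ``b`` with both operands materialised.

    The trace contains no branch on ``c``; numeric operands are combined
    arithmetically, arbitrary objects through a constant-shape two-way mux.
    """
    cv = _sval(c)
    av, bv = _sval(a), _sval(b)
    _emit("mux", np.shape(av), np.shape(bv))
    if isinstance(av, np.ndarray) or isinstance(bv, np.ndarray) or np.ndim(cv) > 0:
        return Secret(np.where(cv, av, bv))
    if isinstance(av, (int, float, np.integer, np.floating)) and isinstance(
        bv, (int, float, np.integer, np.floating)
    ):
        m = int(bool(cv))
        return Secret(bv + (av - bv) * m)
    pair = (bv, av)  # both already materialised; fixed two-slot table
    return Secret(pair[int(bool(cv))])


# ---------------------------------------------------------------------------
# Bitonic sorting network
# ---------------------------------------------------------------------------

class _Sentinel:
    """Padding element for sort/filter; sorts after every real element."""

    def __repr__(self) -> str:
        return "SENTINEL"


SENTINEL = _Sentinel()


def _next_pow2(n: int) -> int:
    p = 1
    while p < n:
        p *= 2
    return p


def bitonic_network_size(n: int) -> int:
    """Compare-exchange count of the padded power-of-two network."""
    m = _next_pow2(max(n, 1))
    k = m.bit_length() - 1
    return m * k * (k + 1) // 4


def bitonic_sort(items: Sequence, key: Callable[[Any], Any] | None = None) -> list:
    """Sort ascending by ``key`` with a data-independent comparison network.

    Input of any length is padded to the next power of two with sentinels
    that carry a maximal key; padding is stripped before returning.  Bitonic
    networks are not stable, so stability is enforced with the composite key
    ``(key(x), original_index)``.
    """
    n = len(items)
    if key is None:
        key = lambda x: x
    # composite keys: (class, key, original index); sentinels in class 1
    entries: list = [[(0, key(_sval(x)), i), _sval(x)] for i, x in enumerate(items)]
    m = _next_pow2(max(n, 1))
    for i in range(n, m):
        entries.append([(1, 0, i), SENTINEL])

    size = 2
    while size <= m:
        stride = size // 2
        while stride > 0:
            for i in range(m):
                partner = i ^ stride
                if partner > i:
                    ascending = (i & size) == 0
                    _emit("cmpx", m, i, partner, ascending)
                    a, b = entries[i], entries[partner]
                    swap = (a[0] > b[0]) == ascending
                    lo, hi = (b, a) if swap else (a, b)
                    entries[i], entries[partner] = lo, hi
            stride //= 2
        size *= 2
    return [e[1] for e in entries[:n]]


# ---------------------------------------------------------------------------
# Oblivious filtering
# ---------------------------------------------------------------------------

def oblivious_filter(
    items: Sequence, mask: Sequence, out_len: int
) -> list:
    """Compact the masked elements to the front and truncate to ``out_len``.

    Selected elements keep their relative order (sort by ``(1 - mask, index)``
    with a stable network).  If fewer than ``out_len`` elements are selected,
    the tail is padded with :data:`SENTINEL`; if more are selected, the excess
    with the largest original indices is dropped deterministically.
    """
    n = len(items)
    mvals = [int(bool(_sval(m))) for m in mask]
    if len(mvals) != n:
        raise ValueError("mask length must equal item count")
    order = bitonic_sort(list(range(n)), key=lambda i: (1 - mvals[i], i))
    n_sel = sum(mvals)  # secret count, used only through cond_select below
    out = []
    for slot in range(out_len):
        if slot < n:
            keep = Secret(slot < n_sel)
            out.append(cond_select(keep, order[slot], None).expose())
        else:
            out.append(None)
    return [SENTINEL if i is None else items[i] for i in out]


# ---------------------------------------------------------------------------
# Constant-time long division
# ---------------------------------------------------------------------------

def _restoring_divide(num, den, width: int):
    """floor(num/den) for non-negative num via restoring long division.

    Exactly ``width`` shift/compare/subtract iterations regardless of the
    operand values.  Supports python ints and numpy integer arrays.
    """
    is_np = isinstance(num, np.ndarray) or isinstance(den, np.ndarray)
    if is_np:
        num = np.asarray(num, dtype=np.int64)
        den = np.asarray(den, dtype=np.int64)
        q = np.zeros(np.broadcast_shapes(num.shape, den.shape), dtype=np.int64)
        r = np.zeros_like(q)
    else:
        q, r = 0, 0
    for i in range(width - 1, -1, -1):
        _emit("div_iter", width, i)
        r = (r << 1) | ((num >> i) & 1)
        ge = (r >= den) & (den > 0)
        if is_np:
            gi = ge.astype(np.int64)
        else:
            gi = int(ge)
        r = r - gi * den
        q = q | (gi << i)
    return q


def ct_divide(num: Secret | int, den: Secret | int, width: int = 64) -> Secret:
    """Floor division ``num // den`` in exactly ``width`` iterations.

    ``den == 0`` yields the all-ones sentinel ``2**width - 1`` instead of
    trapping.  Negative numerators follow floor semantics (round toward
    negative infinity), matching python's ``//``.
    """
    n, d = _sval(num), _sval(den)
    is_np = isinstance(n, np.ndarray) or isinstance(d, np.ndarray)
    if is_np:
        n = np.asarray(n, dtype=np.int64)
        d = np.asarray(d, dtype=np.int64)
        neg = (n < 0).astype(np.int64)
        mag = np.abs(n) - neg  # |n|-1 for negatives: floor = -(div+1)
        q = _restoring_divide(mag, d, width)
        q = (1 - neg) * q - neg * (q + 1)
        sentinel = (d == 0).astype(np.int64)
        q = (1 - sentinel) * q + sentinel * ((1 << width) - 1)
        return Secret(q)
    neg = 1 if n < 0 else 0
    mag = (-n if neg else n) - neg
    q = _restoring_divide(mag, d, width)
    q = -(q + 1) if neg else q
    if d == 0:
        q = (1 << width) - 1
    return Secret(q)


def ct_divide_frac(num, den, frac_bits: int) -> np.ndarray:
    """floor(num * 2**frac_bits / den) for 0 <= num <= den, vectorised.

    Used to renormalise fixed-point probability vectors: the quotient is the
    fraction ``num/den`` with ``frac_bits`` fractional bits.  Runs exactly
    ``frac_bits`` iterations (plus one equality pre-step) for any operands;
    ``den == 0`` yields 0.
    """
    num = np.asarray(num, dtype=np.int64)
    den = np.asarray(den, dtype=np.int64)
    vemit("ctdiv_frac", num.shape, frac_bits)
    whole = ((num >= den) & (den > 0)).astype(np.int64)
    q = whole << frac_bits
    r = num - whole * den
    for i in range(frac_bits - 1, -1, -1):
        r = r << 1
        ge = ((r >= den) & (den > 0)).astype(np.int64)
        r = r - ge * den
        q = q | (ge << i)
    return q
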