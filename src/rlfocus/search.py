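"""Classical autofocus searches over a focal stack.

Baselines against the learned agent: an exhaustive sweep (oracle and worst
case), golden-section search and Fibonacci search, both exploiting the
unimodality of the sharpness curve.  "Time step" for these methods is the
number of *probes* — distinct lens settings at which an image is captured
and scored; probed values are cached so no index is ever scored twice.

On noiseless synthetic stacks the sharpness curve is strictly unimodal and
both bracketing searches return exactly the sweep argmax (verified
exhaustively in the test suite).  On noisy stacks they still run, but the
result carries a warning when the probed values themselves betray
non-unimodality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .measures import measure as _measure
from .simulate import FocalStack

__all__ = [
    "SearchResult",
    "sweep_search",
    "golden_section_search",
    "fibonacci_search",
    "golden_probe_bound",
    "fibonacci_probe_bound",
]

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass
class SearchResult:
    best_index: int
    probes: int
    trace: list[int] = field(default_factory=list)
    warning: str | None = None

    def __post_init__(self) -> None:
        if self.probes != len(self.trace):
            raise ValueError("probes must equal len(trace)")
        if self.best_index not in self.trace:
            raise ValueError("best_index must have been probed")


class _Prober:
    """Caches sharpness evaluations by frame index and records the trace.

    Accepts either a :class:`FocalStack` (frames are scored with the named
    measure on demand) or a precomputed 1-D sequence of per-frame sharpness
    values.
    """

    def __init__(self, stack, measure_name: str) -> None:
        if isinstance(stack, FocalStack):
            self.n = stack.n_frames
            self._eval = lambda i: _measure(stack.frames[i], measure_name)
        else:
            curve = np.asarray(stack, dtype=np.float64)
            if curve.ndim != 1:
                raise ValueError("expected a FocalStack or a 1-D sharpness curve")
            self.n = len(curve)
            self._eval = lambda i: float(curve[i])
        if self.n == 0:
            raise ValueError("stack must be non-empty")
        self.values: dict[int, float] = {}
        self.trace: list[int] = []

    def __call__(self, index: int) -> float:
        index = int(index)
        if index not in self.values:
            self.values[index] = self._eval(index)
            self.trace.append(index)
        return self.values[index]

    def result(self) -> SearchResult:
        best = min(
            (i for i in self.values), key=lambda i: (-self.values[i], i)
        )  # highest value, lowest index on ties
        warning = None
        if not _probes_unimodal(self.values):
            warning = "unimodality not guaranteed: probed values are not unimodal"
        return SearchResult(
            best_index=best, probes=len(self.trace), trace=list(self.trace), warning=warning
        )


def _probes_unimodal(values: dict[int, float]) -> bool:
    idx = sorted(values)
    vals = [values[i] for i in idx]
    peak = int(np.argmax(vals))
    rising = all(vals[i] < vals[i + 1] for i in range(peak))
    falling = all(vals[i] > vals[i + 1] for i in range(peak, len(vals) - 1))
    return rising and falling


def sweep_search(stack, measure_name: str = "energy") -> SearchResult:
    """Probe every frame; the brute-force oracle and worst case."""
    probe = _Prober(stack, measure_name)
    for i in range(probe.n):
        probe(i)
    return probe.result()


def golden_probe_bound(n_frames: int, tol_indices: int = 2) -> int:
    """Worst-case probe count of :func:`golden_section_search`.

    The real-valued bracket shrinks by the golden ratio each iteration from
    width n-1 down to ``tol``; two initial probes, at most one new probe per
    iteration, plus at most ``tol + 1`` closing probes inside the final
    bracket.
    """
    if n_frames <= 1:
        return max(n_frames, 0)
    tol = max(tol_indices, 1)
    width = n_frames - 1
    iters = 0 if width <= tol else math.ceil(math.log(tol / width) / math.log(_INVPHI))
    return min(n_frames, 2 + iters + tol + 1)


def golden_section_search(
    stack, measure_name: str = "energy", tol_indices: int = 2
) -> SearchResult:
    """Golden-section search for the sharpest frame.

    Maintains a real-valued bracket on [0, n-1], probing the rounded interior
    points; terminates when the bracket width drops to ``tol_indices`` and
    then scores every integer left inside the bracket, so on a strictly
    unimodal curve the returned index is the exact argmax.
    """
    probe = _Prober(stack, measure_name)
    n = probe.n
    if n <= 2:
        for i in range(n):
            probe(i)
        return probe.result()

    tol = max(tol_indices, 1)
    lo, hi = 0.0, float(n - 1)
    c = hi - _INVPHI * (hi - lo)
    d = lo + _INVPHI * (hi - lo)
    fc, fd = probe(round(c)), probe(round(d))
    while hi - lo > tol:
        if round(c) == round(d):
            break  # bracket narrower than one frame spacing
        if fc < fd:
            lo, c, fc = c, d, fd
            d = lo + _INVPHI * (hi - lo)
            fd = probe(round(d))
        else:
            hi, d, fd = d, c, fc
            c = hi - _INVPHI * (hi - lo)
            fc = probe(round(c))
    for i in range(int(math.floor(lo)), int(math.ceil(hi)) + 1):
        if 0 <= i < n:
            probe(i)
    return probe.result()


def _fibonacci_upto(limit: int) -> list[int]:
    fib = [1, 1]
    while fib[-1] < limit:
        fib.append(fib[-1] + fib[-2])
    return fib


def fibonacci_probe_bound(n_frames: int, tol_indices: int = 2) -> int:
    """Worst-case probe count of :func:`fibonacci_search`.

    With k the smallest index such that F(k) >= n + 1 (domain padded to
    length F(k) - 1), the elimination runs k - 2 levels with one new probe
    per level after the first two, never exceeding k - 1 probes; closing
    probes inside the final window are already counted by the schedule.
    """
    if n_frames <= 2:
        return max(n_frames, 0)
    fib = _fibonacci_upto(n_frames + 1)
    return min(n_frames, len(fib) - 1)


def fibonacci_search(
    stack, measure_name: str = "energy", tol_indices: int = 2
) -> SearchResult:
    """Fibonacci search for the sharpest frame.

    The index range is padded to a virtual window of length F(k) - 1 (padded
    positions score -inf, preserving unimodality); each elimination level
    shrinks the window by one Fibonacci ratio, reusing one interior probe.
    Stops once the window is at most ``tol_indices`` wide and scores the
    remaining integers inside it.
    """
    probe = _Prober(stack, measure_name)
    n = probe.n
    if n <= 2:
        for i in range(n):
            probe(i)
        return probe.result()

    def padded(i: int) -> float:
        return probe(i) if i < n else -math.inf

    tol = max(tol_indices, 1)
    fib = _fibonacci_upto(n + 1)
    k = len(fib) - 1  # F(k) >= n + 1; window = [a, a + F(k) - 2]
    a = 0
    while k >= 3:
        b = a + fib[k] - 2
        if min(b, n - 1) - a < max(tol, 1):
            break
        m1 = a + fib[k - 2] - 1
        m2 = a + fib[k - 1] - 1
        if padded(m1) >= padded(m2):
            pass  # keep [a, m2 - 1]; window length F(k-1) - 1
        else:
            a = m1 + 1  # keep [m1 + 1, b]; same length
        k -= 1
    for i in range(a, min(a + fib[k] - 1, n)):
        probe(i)
    return probe.result()
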