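"""Closed-form algebra for sums of shifted gamma-type exponential terms.

Bolus input functions and compartmental tissue responses are all sums of
terms ``A * (t - t0)**p * exp(-a*(t - t0))`` for ``t >= t0`` (zero before
the onset ``t0``).  This family is closed under scaling, time shifting,
convolution with a causal exponential ``exp(-k t)`` (hence also with the
unit-mass dispersion kernel ``exp(-t/tau)/tau``), and definite integration
— so the whole PET forward model can be evaluated exactly, with no
numerical ODE solving or discrete convolution.

Degenerate rate collisions (``|k - a|`` below :data:`RATE_TOL`) fall back
to the limiting ``t * exp(-a t)`` form instead of producing a 0/0.

The algebra sits in the innermost loop of the joint fit, so operations use
an unchecked fast constructor internally; validation happens only on
user-built instances.
"""

from __future__ import annotations

from math import factorial
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammainc, gammaln

__all__ = ["ExpSum", "RATE_TOL", "concat"]

#: Two exponential rates closer than this (1/min) are treated as equal.
RATE_TOL = 1e-9


def _phi_cols(a: np.ndarray, p: np.ndarray, x: np.ndarray) -> np.ndarray:
    """``int_0^x s**p exp(-a s) ds`` per term column.

    ``a`` and ``p`` have shape (m,); ``x`` has shape (nb, m) with x >= 0.
    Stable for any ``a*x``: p = 0 uses expm1; higher powers use the
    regularized lower incomplete gamma function.
    """
    out = np.empty(x.shape, dtype=float)
    tiny = a <= RATE_TOL
    plain = ~tiny & (p == 0)
    rest = ~tiny & (p > 0)
    if tiny.any():
        out[:, tiny] = x[:, tiny] ** (p[tiny] + 1.0) / (p[tiny] + 1.0)
    if plain.any():
        out[:, plain] = -np.expm1(-a[plain] * x[:, plain]) / a[plain]
    if rest.any():
        ar, pr = a[rest], p[rest]
        log_pref = gammaln(pr + 1.0) - (pr + 1.0) * np.log(ar)
        out[:, rest] = np.exp(log_pref) * gammainc(pr + 1.0, ar * x[:, rest])
    return out


def _phi(a, p, x) -> np.ndarray:
    """Broadcasting wrapper around :func:`_phi_cols` for scalar/array input."""
    a, p, x = np.broadcast_arrays(
        np.asarray(a, float), np.asarray(p, float), np.asarray(x, float)
    )
    flat_a = a.reshape(-1)
    return _phi_cols(flat_a, p.reshape(-1), x.reshape(1, -1))[0].reshape(x.shape)


class ExpSum:
    """A finite sum of terms ``A (t-t0)^p e^{-a(t-t0)}``, each zero for t < t0.

    Terms are stored as flat arrays (``amp``, ``rate``, ``power``,
    ``onset``); all operations return new instances and never mutate.
    """

    __slots__ = ("amp", "rate", "power", "onset")

    def __init__(
        self,
        amp: Sequence[float],
        rate: Sequence[float],
        power: Sequence[int] | None = None,
        onset: Sequence[float] | None = None,
    ) -> None:
        amp = np.atleast_1d(np.asarray(amp, dtype=float))
        rate = np.atleast_1d(np.asarray(rate, dtype=float))
        n = amp.size
        power = (
            np.zeros(n)
            if power is None
            else np.broadcast_to(np.asarray(power, dtype=float), (n,)).copy()
        )
        onset = (
            np.zeros(n)
            if onset is None
            else np.broadcast_to(np.asarray(onset, dtype=float), (n,)).copy()
        )
        if not (rate.shape == (n,) and power.shape == (n,) and onset.shape == (n,)):
            raise ValueError("amp, rate, power, onset must have equal length")
        if np.any(rate < 0):
            raise ValueError("decay rates must be non-negative")
        if np.any(power < 0) or np.any(power != np.round(power)):
            raise ValueError("powers must be non-negative integers")
        self.amp = amp
        self.rate = rate
        self.power = power
        self.onset = onset

    @classmethod
    def _new(cls, amp, rate, power, onset) -> "ExpSum":
        """Unchecked constructor for internal use (arrays already valid)."""
        obj = cls.__new__(cls)
        obj.amp = amp
        obj.rate = rate
        obj.power = power
        obj.onset = onset
        return obj

    # ------------------------------------------------------------------
    @classmethod
    def zero(cls) -> "ExpSum":
        z = np.empty(0)
        return cls._new(z, z.copy(), z.copy(), z.copy())

    @property
    def n_terms(self) -> int:
        return int(self.amp.size)

    def __call__(self, t: float | np.ndarray) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        tt = np.atleast_1d(t)[:, None] - self.onset[None, :]  # (nt, nterm)
        active = tt >= 0.0
        tt = np.where(active, tt, 0.0)
        vals = (
            self.amp[None, :]
            * tt ** self.power[None, :]
            * np.exp(-self.rate[None, :] * tt)
        )
        out = np.where(active, vals, 0.0).sum(axis=1)
        return float(out[0]) if scalar else out

    # -- linear structure ----------------------------------------------
    def scale(self, c: float) -> "ExpSum":
        return ExpSum._new(self.amp * c, self.rate, self.power, self.onset)

    def shift(self, dt: float) -> "ExpSum":
        """Delay the curve by ``dt`` minutes (negative values advance it)."""
        return ExpSum._new(self.amp, self.rate, self.power, self.onset + dt)

    def __add__(self, other: "ExpSum") -> "ExpSum":
        if not isinstance(other, ExpSum):
            return NotImplemented
        return concat([self, other])

    # -- convolution -----------------------------------------------------
    def convolve_exp(self, k: float) -> "ExpSum":
        """Convolve with the causal (un-normalized) exponential ``e^{-k t}``.

        For ``d = k - a`` away from zero the term ``t^p e^{-a t}`` maps to

            sum_{q<=p} (-1)^{p-q} (p!/q!) / d^{p-q+1} * t^q e^{-a t}
            + (-1)^p p! / d^{p+1} * e^{-k t};

        at a rate collision the limit is ``t^{p+1} e^{-a t} / (p + 1)``.
        """
        if k < 0:
            raise ValueError("convolution rate must be non-negative")
        A, a, p, t0 = self.amp, self.rate, self.power, self.onset
        d = k - a
        deg = np.abs(d) < RATE_TOL
        out_amp: list[np.ndarray] = []
        out_rate: list[np.ndarray] = []
        out_pow: list[np.ndarray] = []
        out_on: list[np.ndarray] = []
        if deg.any():
            out_amp.append(A[deg] / (p[deg] + 1.0))
            out_rate.append(a[deg])
            out_pow.append(p[deg] + 1.0)
            out_on.append(t0[deg])
        nd = ~deg
        if nd.any():
            An, an, pn, tn, dn = A[nd], a[nd], p[nd], t0[nd], d[nd]
            for pv in range(int(pn.max()) + 1):
                m = pn == pv
                if not m.any():
                    continue
                Am, am, tm, dm = An[m], an[m], tn[m], dn[m]
                sign = 1.0
                for q in range(pv, -1, -1):
                    coeff = sign * factorial(pv) / factorial(q)
                    out_amp.append(Am * coeff / dm ** (pv - q + 1))
                    out_rate.append(am)
                    out_pow.append(np.full(Am.size, float(q)))
                    out_on.append(tm)
                    sign = -sign
                coeff = factorial(pv) * (1.0 if pv % 2 == 0 else -1.0)
                out_amp.append(-Am * coeff / dm ** (pv + 1))
                out_rate.append(np.full(Am.size, float(k)))
                out_pow.append(np.zeros(Am.size))
                out_on.append(tm)
        return ExpSum._new(
            np.concatenate(out_amp),
            np.concatenate(out_rate),
            np.concatenate(out_pow),
            np.concatenate(out_on),
        ).compress()

    def disperse(self, tau: float) -> "ExpSum":
        """Convolve with the unit-mass dispersion kernel ``e^{-t/tau}/tau``.

        ``tau <= RATE_TOL`` is the identity (the kernel tends to a delta).
        """
        if tau < 0:
            raise ValueError("dispersion time constant must be non-negative")
        if tau <= RATE_TOL:
            return self
        return self.convolve_exp(1.0 / tau).scale(1.0 / tau)

    # -- integration -----------------------------------------------------
    def cumulative(self, t: float | np.ndarray) -> np.ndarray | float:
        """Integral of the curve from its earliest onset up to ``t``."""
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        x = np.clip(np.atleast_1d(t)[:, None] - self.onset[None, :], 0.0, None)
        vals = self.amp[None, :] * _phi_cols(self.rate, self.power, x)
        out = vals.sum(axis=1)
        return float(out[0]) if scalar else out

    def _averages_contiguous(
        self, bounds_min: np.ndarray, durations_min: np.ndarray
    ) -> np.ndarray:
        """Frame means over contiguous frames given their boundary grid.

        Fast path without validation: ``bounds_min`` holds the n+1 frame
        boundaries of n contiguous frames with lengths ``durations_min``.
        """
        if self.amp.size == 0:
            return np.zeros(durations_min.size)
        x = bounds_min[:, None] - self.onset[None, :]
        np.clip(x, 0.0, None, out=x)
        cum = (self.amp * _phi_cols(self.rate, self.power, x)).sum(axis=1)
        return np.diff(cum) / durations_min

    def integral(self, lo: float, hi: float) -> float:
        """Definite integral over ``[lo, hi]``."""
        return float(self.cumulative(hi) - self.cumulative(lo))

    def frame_averages(self, starts: np.ndarray, durations: np.ndarray) -> np.ndarray:
        """Mean value over each frame ``[start, start + duration]`` (minutes)."""
        starts = np.asarray(starts, dtype=float)
        durations = np.asarray(durations, dtype=float)
        if np.any(durations <= 0):
            raise ValueError("frame durations must be positive")
        if self.n_terms == 0:
            return np.zeros_like(starts)
        ends = starts + durations
        if starts.size > 1 and np.array_equal(starts[1:], ends[:-1]):
            # contiguous frames: integrate once per boundary, then difference
            bounds = np.concatenate([starts, ends[-1:]])
            return self._averages_contiguous(bounds, durations)
        return (self.cumulative(ends) - self.cumulative(starts)) / durations

    # -- housekeeping ----------------------------------------------------
    def compress(self) -> "ExpSum":
        """Merge terms with identical (rate, power, onset); drop zero amps."""
        n = self.amp.size
        if n <= 1:
            return self
        order = np.lexsort((self.onset, self.power, self.rate))
        r, p, o = self.rate[order], self.power[order], self.onset[order]
        new_group = np.empty(n, dtype=bool)
        new_group[0] = True
        new_group[1:] = (r[1:] != r[:-1]) | (p[1:] != p[:-1]) | (o[1:] != o[:-1])
        gid = np.cumsum(new_group) - 1
        n_groups = gid[-1] + 1
        amp = np.zeros(n_groups)
        np.add.at(amp, gid, self.amp[order])
        first = np.flatnonzero(new_group)
        keep = amp != 0.0
        return ExpSum._new(amp[keep], r[first][keep], p[first][keep], o[first][keep])

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ExpSum(n_terms={self.n_terms})"


def concat(curves: Iterable["ExpSum"]) -> ExpSum:
    """Sum several ExpSum curves into one (merging identical terms)."""
    curves = list(curves)
    if not curves:
        return ExpSum.zero()
    return ExpSum._new(
        np.concatenate([c.amp for c in curves]),
        np.concatenate([c.rate for c in curves]),
        np.concatenate([c.power for c in curves]),
        np.concatenate([c.onset for c in curves]),
    ).compress()
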