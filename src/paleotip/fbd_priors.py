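"""Fossilized birth-death prior probabilities of branch durations.

Under a birth-death-sampling process with piecewise-constant origination
lambda(t), extinction mu(t) and fossil-sampling psi(t), the probability
that a lineage alive at age t leaves no sampled descendant and is never
itself sampled, E(t), satisfies (with t increasing into the past)

    dE/dt = mu - (lambda + mu + psi) E + lambda E^2 .

Because every analysed taxon here is a fossil there is no sampling of
extant descendants, so the boundary condition at the young edge of the
rates window is E = 1.  Within each constant-rate interval the Riccati
equation has a closed form, and continuity at interval boundaries stitches
the pieces together.

The prior probability of a branch spanning [younger, older] — no sampled
ancestor along it and no birth on it that leaves sampled descendants — is

    exp( - \int_younger^older [ psi(t) + lambda(t) (1 - E(t)) ] dt ),

which this module evaluates in closed form piece by piece.  A tree's FBD
log-prior (lnP FBD) is the sum over its branches, including the stem from
the basal divergence age when one is supplied.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np

from paleotip.core_io import ModelTree, ValidationError
from paleotip.occurrence_rates import SkylineRates

__all__ = [
    "UnsampledProbabilityFunction",
    "unsampled_probability",
    "branch_log_prior",
    "tree_log_prior",
]

_EPS = 1e-12


@dataclass
class _Segment:
    """One constant-rate piece, ages in [young, old], E(young) known."""

    young: float
    old: float
    lam: float
    mu: float
    psi: float
    e_young: float
    e_old: float = float("nan")


def _solve_e(seg: _Segment, s: float) -> float:
    """E at s Myr above the segment's young edge (0 <= s <= old-young)."""
    lam, mu, psi, e0 = seg.lam, seg.mu, seg.psi, seg.e_young
    if s <= 0.0:
        return e0
    total = lam + mu + psi
    if lam < _EPS:
        if total < _EPS:
            return e0
        eq = mu / (mu + psi)
        return eq + (e0 - eq) * math.exp(-(mu + psi) * s)
    disc = total * total - 4.0 * lam * mu
    if disc < _EPS:  # psi = 0, lam = mu: double root at E = 1
        u0 = e0 - 1.0
        return 1.0 + u0 / (1.0 - lam * u0 * s)
    c = math.sqrt(disc)
    e_minus = (total - c) / (2.0 * lam)
    e_plus = (total + c) / (2.0 * lam)
    if abs(e0 - e_plus) < _EPS:
        return e_plus
    r0 = (e0 - e_minus) / (e0 - e_plus)
    ru = r0 * math.exp(-c * s)
    return (e_minus - e_plus * ru) / (1.0 - ru)


def _integral_e(seg: _Segment, s1: float, s2: float) -> float:
    """Closed-form integral of E(s) ds over [s1, s2] within one segment."""
    lam, mu, psi, e0 = seg.lam, seg.mu, seg.psi, seg.e_young
    ds = s2 - s1
    if ds <= 0.0:
        return 0.0
    total = lam + mu + psi
    if lam < _EPS:
        if total < _EPS:
            return e0 * ds
        k = mu + psi
        eq = mu / k
        return eq * ds + (e0 - eq) / k * (
            math.exp(-k * s1) - math.exp(-k * s2)
        )
    disc = total * total - 4.0 * lam * mu
    if disc < _EPS:  # psi = 0, lam = mu
        u0 = e0 - 1.0
        if abs(u0) < _EPS:
            return ds
        return ds - (
            math.log(1.0 - lam * u0 * s2) - math.log(1.0 - lam * u0 * s1)
        ) / lam
    c = math.sqrt(disc)
    e_minus = (total - c) / (2.0 * lam)
    e_plus = (total + c) / (2.0 * lam)
    if abs(e0 - e_plus) < _EPS:
        return e_plus * ds
    r0 = (e0 - e_minus) / (e0 - e_plus)
    term = (e_minus - e_plus) / c * (
        math.log(1.0 - r0 * math.exp(-c * s2))
        - math.log(1.0 - r0 * math.exp(-c * s1))
    )
    return e_minus * ds + term


class UnsampledProbabilityFunction:
    """E(t) on a rates window, piecewise closed form, continuous at joins.

    ``E(t)`` is the probability that a lineage alive at age ``t`` is never
    sampled and leaves no sampled descendant by the young edge of the
    window.  E = 1 at the young edge (no extant sampling) and E is 1
    everywhere when psi is identically zero.
    """

    def __init__(
        self, rates: SkylineRates, older: float, younger: float
    ) -> None:
        if older <= younger:
            raise ValidationError("window must satisfy older > younger")
        self.older = older
        self.younger = younger
        self.rates = rates
        raw = rates.segments(older, younger)  # ordered old -> young
        self.segments: list[_Segment] = []
        e_current = 1.0  # boundary condition at the young edge
        for a_old, a_young, idx in reversed(raw):
            seg = _Segment(
                young=a_young,
                old=a_old,
                lam=float(rates.origination[idx]),
                mu=float(rates.extinction[idx]),
                psi=float(rates.sampling[idx]),
                e_young=e_current,
            )
            seg.e_old = _solve_e(seg, seg.old - seg.young)
            e_current = seg.e_old
            self.segments.append(seg)  # young -> old order
        # cumulative weight integral at each segment's young edge, so a
        # branch integral is two O(1) lookups instead of a segment sweep
        self._edges = [seg.young for seg in self.segments]
        self._cum = []
        acc = 0.0
        for seg in self.segments:
            self._cum.append(acc)
            span = seg.old - seg.young
            acc += (seg.psi + seg.lam) * span - seg.lam * _integral_e(
                seg, 0.0, span
            )

    def _segment_at(self, t: float) -> _Segment:
        if t < self.younger - 1e-9 or t > self.older + 1e-9:
            raise ValidationError(
                f"age {t} Ma outside rates window "
                f"[{self.older}, {self.younger}]"
            )
        i = bisect_right(self._edges, t) - 1
        return self.segments[min(max(i, 0), len(self.segments) - 1)]

    def __call__(self, t: float) -> float:
        seg = self._segment_at(t)
        s = min(max(t - seg.young, 0.0), seg.old - seg.young)
        return min(1.0, max(0.0, _solve_e(seg, s)))

    def _cum_weight(self, t: float) -> float:
        """Cumulative weight integral from the window's young edge to t."""
        i = bisect_right(self._edges, t) - 1
        i = min(max(i, 0), len(self.segments) - 1)
        seg = self.segments[i]
        s = min(max(t - seg.young, 0.0), seg.old - seg.young)
        return self._cum[i] + (seg.psi + seg.lam) * s - seg.lam * _integral_e(
            seg, 0.0, s
        )

    def integral_weight(self, younger: float, older: float) -> float:
        """Integral of psi(t) + lambda(t) (1 - E(t)) dt over [younger, older]."""
        if older < younger - 1e-12:
            raise ValidationError("reversed ages in branch integral")
        if older <= younger:
            return 0.0
        self._segment_at(younger)
        self._segment_at(older)
        return self._cum_weight(older) - self._cum_weight(younger)


def unsampled_probability(
    rates: SkylineRates,
    older: float | None = None,
    younger: float | None = None,
) -> UnsampledProbabilityFunction:
    """Build E(t) for a rates skyline on a window (default: the timescale)."""
    if older is None:
        older = rates.timescale.older_bound
    if younger is None:
        younger = rates.timescale.younger_bound
    return UnsampledProbabilityFunction(rates, older, younger)


def branch_log_prior(
    older: float,
    younger: float,
    rates: SkylineRates | None = None,
    E: UnsampledProbabilityFunction | None = None,
) -> float:
    """Log prior of a branch spanning [younger, older] Ma.

    The probability of sampling no ancestor along the branch and of no
    birth on the branch leaving sampled descendants.  Zero-duration
    branches (the sampled-ancestor convention) have log prior 0.
    """
    if older < younger - 1e-12:
        raise ValidationError(
            f"reversed branch ages: older={older}, younger={younger}"
        )
    if E is None:
        if rates is None:
            raise ValidationError("either rates or E must be supplied")
        E = unsampled_probability(
            rates,
            older=max(older, rates.timescale.older_bound),
            younger=min(younger, rates.timescale.younger_bound),
        )
    return -E.integral_weight(younger, older)


def tree_log_prior(
    tree: ModelTree,
    rates: SkylineRates,
    origin_age: float | None = None,
    E: UnsampledProbabilityFunction | None = None,
) -> float:
    """lnP FBD of a fully dated tree: the summed branch log-priors.

    Includes the root stem from ``origin_age`` (the basal divergence from
    the clade's sister group) down to the root node when supplied.
    """
    tree.validate_ages()
    ages = [n.age for n in tree.postorder()]
    top = max(ages + ([origin_age] if origin_age is not None else []))
    if origin_age is not None and origin_age < tree.root.age - 1e-9:
        raise ValidationError(
            f"origin age {origin_age} younger than root age {tree.root.age}"
        )
    if E is None:
        E = unsampled_probability(
            rates,
            older=max(top, rates.timescale.older_bound),
            younger=min(min(ages), rates.timescale.younger_bound),
        )
    total = 0.0
    for parent, child in tree.branches():
        total += branch_log_prior(parent.age, child.age, E=E)
    if origin_age is not None:
        total += branch_log_prior(origin_age, tree.root.age, E=E)
    return total
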