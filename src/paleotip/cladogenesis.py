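"""Reconstructed cladogenesis rates on a dated tree.

An internal branch of the dated tree ends in the divergence that defines
it, so the likelihood of a hypothesized cladogenesis rate lambda(t) given
such a branch is the probability of exactly one *sampled* cladogenetic
event over the branch duration times the probability of zero sampled
ancestors from the branch over that time:

    ln L(branch) = ln(Lambda) - Lambda - \int psi(t) dt ,
    Lambda       = \int lambda(t) (1 - E(t)) dt ,

with extinction and sampling held at their occurrence-derived values.  A
terminal branch instead ends at its taxon's first appearance — a sampling
event, not a divergence — so in the whole-tree fit it contributes the
probability of zero sampled cladogenetic events and zero sampled
ancestors, terminated by the tip's own sampling.

The unsampled probability E is computed with the species-level origination
rate set to a multiple (default two, the average species count per genus)
of the hypothesized genus-level cladogenesis rate: a genus-level
divergence is only observed if at least one species of the side clade is
ever sampled.  This multiplication applies only inside this module, never
to the dating priors.

Two rate forms are fitted and compared by a likelihood-ratio test:
constant lambda_0, and exponential decay
lambda(t) = lambda_0 exp(-kappa (t0 - t)) anchored at the clade's basal
divergence age t0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from paleotip.core_io import ModelTree, Timescale, ValidationError
from paleotip.fbd_priors import UnsampledProbabilityFunction
from paleotip.occurrence_rates import SkylineRates

__all__ = [
    "CladoRateModel",
    "CladoFit",
    "LRTResult",
    "branch_clado_loglik",
    "per_branch_mle",
    "fit_clado_model",
    "likelihood_ratio_test",
]

_KAPPA_MAX = 2.0  # per Myr
_DECAY_STEP = 1.0  # Myr discretization of the decaying-rate skyline


@dataclass(frozen=True)
class CladoRateModel:
    """Constant or exponentially declining cladogenesis rate.

    ``lambda0`` is per lineage-Myr; for the exponential form the rate at
    age t is ``lambda0 * exp(-kappa * (t0 - t))`` with ``t0`` the clade's
    basal divergence age (so the rate declines toward the present).
    """

    form: str
    lambda0: float
    kappa: float = 0.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.form not in ("constant", "exponential_decay"):
            raise ValidationError(f"unknown cladogenesis form {self.form!r}")
        if self.lambda0 <= 0:
            raise ValidationError("lambda0 must be positive")
        if self.kappa < 0:
            raise ValidationError("kappa must be >= 0")

    def rate_at(self, age: float) -> float:
        if self.form == "constant" or self.kappa == 0.0:
            return self.lambda0
        return self.lambda0 * math.exp(-self.kappa * (self.t0 - age))


@dataclass
class CladoFit:
    """A fitted cladogenesis-rate model with its maximized log-likelihood."""

    model: CladoRateModel
    loglik: float
    per_branch_rates: dict[str, float] | None = None
    n_branches: int = 0


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    p_value: float


# ---------------------------------------------------------------------------
# Branch likelihoods
# ---------------------------------------------------------------------------


def _doubled_skyline(
    model: CladoRateModel,
    rates: SkylineRates,
    older: float,
    younger: float,
    species_factor: float = 2.0,
) -> SkylineRates:
    """Piecewise skyline with origination = species_factor x the model rate.

    Extinction and sampling stay at their occurrence-derived values; the
    factor (default two species per genus) converts the genus-level
    cladogenesis rate into the species-level origination that governs
    whether a side clade is ever sampled.
    """
    edges = {older, younger}
    for iv in rates.timescale:
        if younger < iv.older < older:
            edges.add(iv.older)
        if younger < iv.younger < older:
            edges.add(iv.younger)
    if model.form == "exponential_decay" and model.kappa > 0:
        t = older - _DECAY_STEP
        while t > younger:
            edges.add(round(t, 9))
            t -= _DECAY_STEP
    sorted_edges = sorted(edges, reverse=True)
    names, lam, mu, psi = [], [], [], []
    for i, (a, b) in enumerate(zip(sorted_edges, sorted_edges[1:])):
        mid = 0.5 * (a + b)
        _, mu_i, psi_i = rates.at(mid)
        names.append((f"seg{i}", a, b))
        lam.append(species_factor * model.rate_at(mid))
        mu.append(mu_i)
        psi.append(psi_i)
    return SkylineRates(
        Timescale(names), np.array(lam), np.array(mu), np.array(psi)
    )


def _build_E(
    model: CladoRateModel,
    rates: SkylineRates,
    older: float,
    species_factor: float = 2.0,
) -> UnsampledProbabilityFunction:
    younger = rates.timescale.younger_bound
    older = max(older, rates.timescale.older_bound)
    sky = _doubled_skyline(model, rates, older, younger, species_factor)
    return UnsampledProbabilityFunction(sky, older, younger)


def _psi_integral(rates: SkylineRates, younger: float, older: float) -> float:
    if older <= younger:
        return 0.0
    total = 0.0
    for a, b, idx in rates.segments(older, younger):
        total += rates.sampling[idx] * (a - b)
    return total


def _sampled_divergence_mean(
    older: float,
    younger: float,
    E: UnsampledProbabilityFunction,
    species_factor: float,
) -> float:
    """Lambda: the sampled-divergence intensity integrated over a branch.

    E's skyline carries origination species_factor * lambda_model and the
    empirical psi, so integral_weight = int psi + int f*lambda*(1-E);
    peeling psi off and dividing by f leaves int lambda_model (1 - E)."""
    w = E.integral_weight(younger, older)
    psi_int = _psi_integral(E.rates, younger, older)
    return max(0.0, w - psi_int) / species_factor


def branch_clado_loglik(
    older: float,
    younger: float,
    model: CladoRateModel,
    rates: SkylineRates,
    E: UnsampledProbabilityFunction | None = None,
    species_factor: float = 2.0,
) -> float:
    """Log-likelihood of a cladogenesis-rate model given one branch.

    Exactly one sampled cladogenetic event (Poisson with mean Lambda, the
    sampled-divergence intensity integrated over the branch) and zero
    sampled ancestors (the pointwise psi integral).  With psi = 0 no side
    clade can ever be sampled, Lambda = 0 and the log-likelihood is -inf.
    """
    if older < younger - 1e-12:
        raise ValidationError(
            f"reversed branch ages: older={older}, younger={younger}"
        )
    if E is None:
        E = _build_E(model, rates, older, species_factor)
    big_lambda = _sampled_divergence_mean(older, younger, E, species_factor)
    psi_int = _psi_integral(rates, younger, older)
    if big_lambda <= 0.0:
        return -math.inf
    return math.log(big_lambda) - big_lambda - psi_int


def _tree_branches(
    tree: ModelTree,
) -> list[tuple[str, float, float, bool]]:
    """(label, older, younger, is_terminal) for positive-duration branches.

    Zero-length sampled-ancestor attachments carry no duration
    information and are excluded."""
    tree.validate_ages()
    out = []
    for i, (parent, child) in enumerate(tree.branches()):
        if parent.age - child.age < 1e-6:
            continue
        label = child.label if child.is_leaf else f"node{i}"
        out.append(
            (label, float(parent.age), float(child.age), child.is_leaf)
        )
    return out


def _tree_loglik(
    branches: list[tuple[str, float, float, bool]],
    model: CladoRateModel,
    rates: SkylineRates,
    species_factor: float = 2.0,
) -> float:
    top = max(older for _, older, _, _ in branches)
    E = _build_E(model, rates, top, species_factor)
    total = 0.0
    for _, older, younger, is_terminal in branches:
        if is_terminal:
            # ends at the tip's own first sampling: no sampled divergence
            # and no sampled ancestor before it (the sampling density
            # itself does not depend on the cladogenesis rate)
            big_lambda = _sampled_divergence_mean(
                older, younger, E, species_factor
            )
            total += -big_lambda - _psi_integral(rates, younger, older)
        else:
            total += branch_clado_loglik(
                older, younger, model, rates, E=E,
                species_factor=species_factor,
            )
        if not math.isfinite(total):
            return -math.inf
    return total


# ---------------------------------------------------------------------------
# Per-branch and whole-tree fits
# ---------------------------------------------------------------------------


def per_branch_mle(
    tree: ModelTree,
    rates: SkylineRates,
    lambda_bounds: tuple[float, float] = (1e-4, 20.0),
    species_factor: float = 2.0,
) -> dict[str, tuple[float, float, float]]:
    """Per-branch origination-rate MLEs for the branch-duration likelihood.

    Returns ``branch label -> (lambda_hat, midpoint age, duration)``; the
    scatter of lambda_hat against branch midpoint age is the per-branch
    rate profile.  Short branches generally favour high rates.
    Deterministic.
    """
    out: dict[str, tuple[float, float, float]] = {}
    lo, hi = math.log(lambda_bounds[0]), math.log(lambda_bounds[1])
    for label, older, younger, _terminal in _tree_branches(tree):
        def neg(log_lam: float, older=older, younger=younger) -> float:
            model = CladoRateModel("constant", math.exp(log_lam))
            ll = branch_clado_loglik(
                older, younger, model, rates, species_factor=species_factor
            )
            return -ll if math.isfinite(ll) else 1e12

        res = minimize_scalar(
            neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-4}
        )
        out[label] = (
            float(math.exp(res.x)),
            0.5 * (older + younger),
            older - younger,
        )
    return out


def fit_clado_model(
    tree: ModelTree,
    rates: SkylineRates,
    form: str,
    t0: float | None = None,
    species_factor: float = 2.0,
) -> CladoFit:
    """Maximize the summed branch log-likelihood over the rate parameters.

    The exponential fit is initialized from the constant fit with
    kappa = 0, so its likelihood can never fall below the constant one.
    """
    branches = _tree_branches(tree)
    if len(branches) < 2:
        raise ValidationError("cladogenesis fit needs at least 2 branches")
    if t0 is None:
        t0 = float(tree.root.age)

    def neg_const(log_lam: float) -> float:
        model = CladoRateModel("constant", math.exp(log_lam))
        ll = _tree_loglik(branches, model, rates, species_factor)
        return -ll if math.isfinite(ll) else 1e12

    res_c = minimize_scalar(
        neg_const,
        bounds=(math.log(1e-4), math.log(20.0)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    lam_c = float(math.exp(res_c.x))
    ll_c = -float(res_c.fun)
    if form == "constant":
        return CladoFit(
            CladoRateModel("constant", lam_c),
            ll_c,
            n_branches=len(branches),
        )
    if form != "exponential_decay":
        raise ValidationError(f"unknown cladogenesis form {form!r}")

    def neg_exp(p: np.ndarray) -> float:
        kappa = float(min(max(p[1], 0.0), _KAPPA_MAX))
        penalty = 1e3 * (abs(p[1] - kappa)) ** 2  # steer back into bounds
        model = CladoRateModel(
            "exponential_decay", math.exp(p[0]), kappa, t0
        )
        ll = _tree_loglik(branches, model, rates, species_factor)
        return (-ll if math.isfinite(ll) else 1e12) + penalty

    res_e = minimize(
        neg_exp,
        np.array([math.log(lam_c), 0.0]),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 500},
    )
    lam0 = float(math.exp(res_e.x[0]))
    kappa = float(min(max(res_e.x[1], 0.0), _KAPPA_MAX))
    ll_e = -float(neg_exp(np.array([math.log(lam0), kappa])))
    if ll_e < ll_c:  # optimizer wandered; the nested model is the floor
        lam0, kappa, ll_e = lam_c, 0.0, ll_c
    return CladoFit(
        CladoRateModel("exponential_decay", lam0, kappa, t0),
        ll_e,
        n_branches=len(branches),
    )


def likelihood_ratio_test(constant: CladoFit, exponential: CladoFit) -> LRTResult:
    """Chi-square(1) test of exponential decay against a constant rate."""
    if constant.n_branches != exponential.n_branches:
        raise ValidationError("fits compare different branch sets")
    statistic = 2.0 * (exponential.loglik - constant.loglik)
    if statistic < -1e-6:
        raise ValidationError(
            f"nesting violated: exponential lnL {exponential.loglik} below "
            f"constant lnL {constant.loglik}"
        )
    statistic = max(0.0, statistic)
    p = float(chi2.sf(statistic, df=1))
    return LRTResult(statistic=statistic, p_value=min(p, 1.0) if statistic > 0 else 1.0)
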