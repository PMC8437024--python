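"""Posterior over divergence times and clock models for a fossil clade.

The posterior decomposes additively in log space (one row per model):

    ln posterior = lnP FAs + lnL alpha + lnP FBD

where lnP FAs is the beta(1, N) prior of the replicate's set of first
appearances, lnL alpha the Mk character likelihood of the clock model, and
lnP FBD the fossilized birth-death prior of the branch durations.  Three
models are compared:

* ``Strict Clock + FA Priors`` — constant rate of change; divergence times
  chosen on character likelihood alone (the FBD term is still reported for
  the resulting tree but takes no part in the optimization or the model's
  posterior surface);
* ``Strict Clock + FA Priors + FBD Priors`` — constant rate with FBD
  branch-duration priors;
* ``Early Burst + FA Priors + FBD Priors`` — rate of change steps down at a
  breakpoint age, with FBD priors.

The search is a deterministic grid over basal divergence ages with nested
optimization (golden-section over clock rates on the log scale, coordinate
ascent over internal-node ages), not MCMC.  First-appearance uncertainty is
integrated by replicate resampling, each replicate weighted by its FA
prior.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp

from paleotip.core_io import (
    AnalysisConfig,
    CharacterMatrix,
    ModelTree,
    ValidationError,
)
from paleotip.fbd_priors import UnsampledProbabilityFunction, unsampled_probability
from paleotip.morph_likelihood import (
    ClockModel,
    PruningEngine,
    RateClasses,
    count_parsimony_steps,
    fit_rate_distribution,
    matrix_log_likelihood,
    quartile_rate_classes,
)
from paleotip.occurrence_rates import SkylineRates

__all__ = [
    "FACandidate",
    "FACandidateSet",
    "FAReplicate",
    "ModelPosterior",
    "PosteriorSurface",
    "ModelScanResult",
    "sample_fa_replicate",
    "fa_log_prior",
    "date_internal_nodes",
    "scan_posterior",
    "credible_interval",
    "bayes_factor",
    "conditional_bayes_factor",
    "read_fa_candidates",
    "write_fa_candidates",
]

MODEL_STRICT_FA = "Strict Clock + FA Priors"
MODEL_STRICT_FBD = "Strict Clock + FA Priors + FBD Priors"
MODEL_EARLY_BURST = "Early Burst + FA Priors + FBD Priors"
ALL_MODELS = (MODEL_STRICT_FA, MODEL_STRICT_FBD, MODEL_EARLY_BURST)


# ---------------------------------------------------------------------------
# First-appearance candidates and replicates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FACandidate:
    collection: str
    older: float  # Ma
    younger: float  # Ma

    def __post_init__(self) -> None:
        if self.older < self.younger:
            raise ValidationError(
                f"collection {self.collection!r}: older bound "
                f"{self.older} < younger bound {self.younger}"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.older + self.younger)


class FACandidateSet:
    """Per-taxon candidate first-appearance collections with age bounds.

    A collection shared by several taxa (the same id in several lists)
    receives a single age draw per replicate, used by all linked taxa.
    ``N`` for a taxon is its number of candidates — the shape2 of its
    beta(1, N) first-appearance prior.
    """

    def __init__(self, candidates: dict[str, list[FACandidate]]) -> None:
        for taxon, cands in candidates.items():
            if not cands:
                raise ValidationError(f"taxon {taxon!r} has no FA candidates")
        self.candidates = {t: list(c) for t, c in candidates.items()}

    @property
    def taxa(self) -> list[str]:
        return sorted(self.candidates)

    def n_candidates(self, taxon: str) -> int:
        return len(self.candidates[taxon])

    def shared_collections(self) -> dict[str, list[str]]:
        """collection id -> taxa whose candidate lists contain it (if > 1)."""
        by_coll: dict[str, list[str]] = {}
        for taxon, cands in self.candidates.items():
            for cand in cands:
                by_coll.setdefault(cand.collection, []).append(taxon)
        return {c: sorted(t) for c, t in by_coll.items() if len(t) > 1}

    def ranked(self, taxon: str) -> list[FACandidate]:
        """Candidates in stratigraphic order, oldest first (deterministic)."""
        return sorted(
            self.candidates[taxon],
            key=lambda c: (-c.midpoint, -c.older, c.collection),
        )


@dataclass
class FAReplicate:
    """One draw of first-appearance ages for every taxon."""

    ages: dict[str, float]  # taxon -> FA age (Ma)
    fa_collection: dict[str, str]  # taxon -> collection providing the FA
    seed: int


def sample_fa_replicate(fc: FACandidateSet, seed: int = 0) -> FAReplicate:
    """Draw one age per candidate collection; a taxon's FA is its oldest draw.

    Collections shared between taxa get a single draw used by all of them.
    """
    rng = np.random.default_rng(seed)
    draws: dict[str, float] = {}
    all_colls: dict[str, FACandidate] = {}
    for taxon in fc.taxa:
        for cand in fc.candidates[taxon]:
            all_colls.setdefault(cand.collection, cand)
    for coll in sorted(all_colls):
        cand = all_colls[coll]
        if cand.older == cand.younger:
            draws[coll] = cand.older
        else:
            draws[coll] = float(rng.uniform(cand.younger, cand.older))
    ages: dict[str, float] = {}
    fa_coll: dict[str, str] = {}
    for taxon in fc.taxa:
        best = max(
            fc.candidates[taxon],
            key=lambda c: (draws[c.collection], c.collection),
        )
        ages[taxon] = draws[best.collection]
        fa_coll[taxon] = best.collection
    return FAReplicate(ages=ages, fa_collection=fa_coll, seed=seed)


def fa_log_prior(rep: FAReplicate, fc: FACandidateSet) -> float:
    """beta(1, N) log prior of the replicate's set of first appearances.

    For a taxon with N candidates in stratigraphic order (oldest first),
    the prior mass of its FA being the j-th candidate is the beta(1, N)
    mass of the j-th of N equal quantile bins,
    ``(1 - (j-1)/N)^N - (1 - j/N)^N``; with N = 1 the prior is uniform and
    contributes nothing.  The total is the sum of log masses over taxa.
    """
    total = 0.0
    for taxon in fc.taxa:
        if taxon not in rep.fa_collection:
            raise ValidationError(f"replicate lacks an FA for taxon {taxon!r}")
        ranked = fc.ranked(taxon)
        n = len(ranked)
        colls = [c.collection for c in ranked]
        chosen = rep.fa_collection[taxon]
        if chosen not in colls:
            raise ValidationError(
                f"FA collection {chosen!r} is not a candidate for {taxon!r}"
            )
        j = colls.index(chosen) + 1
        mass = (1.0 - (j - 1) / n) ** n - (1.0 - j / n) ** n
        total += math.log(mass)
    return total


# ---------------------------------------------------------------------------
# Posterior containers
# ---------------------------------------------------------------------------


@dataclass
class ModelPosterior:
    """The additive log-posterior decomposition for one model's best tree."""

    model: str
    basal_age: float
    lnp_fas: float
    lnl_alpha: float
    lnp_fbd: float
    ln_posterior: float
    credible_older: float | None = None
    credible_younger: float | None = None

    @classmethod
    def from_components(
        cls,
        model: str,
        basal_age: float,
        lnp_fas: float,
        lnl_alpha: float,
        lnp_fbd: float,
        credible_older: float | None = None,
        credible_younger: float | None = None,
    ) -> "ModelPosterior":
        return cls(
            model=model,
            basal_age=basal_age,
            lnp_fas=lnp_fas,
            lnl_alpha=lnl_alpha,
            lnp_fbd=lnp_fbd,
            ln_posterior=lnp_fas + lnl_alpha + lnp_fbd,
            credible_older=credible_older,
            credible_younger=credible_younger,
        )

    def to_row(self) -> dict:
        return {
            "model": self.model,
            "basal_divergence": self.basal_age,
            "ci_older": self.credible_older,
            "ci_younger": self.credible_younger,
            "lnP_FAs": self.lnp_fas,
            "lnL_alpha": self.lnl_alpha,
            "lnP_FBD": self.lnp_fbd,
            "ln_posterior": self.ln_posterior,
        }


@dataclass
class PosteriorSurface:
    """ln posterior over the basal-divergence grid for one model."""

    model: str
    ages: np.ndarray
    ln_posterior: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.ln_posterior = np.asarray(self.ln_posterior, dtype=float)
        if self.ages.shape != self.ln_posterior.shape:
            raise ValidationError("surface grid and values must align")

    def best_age(self) -> float:
        return float(self.ages[int(np.argmax(self.ln_posterior))])

    def log_marginal(self) -> float:
        return float(logsumexp(self.ln_posterior))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.model,
                "basal_age": self.ages,
                "ln_posterior": self.ln_posterior,
            }
        )


@dataclass
class ModelScanResult:
    posterior: ModelPosterior
    surface: PosteriorSurface
    best_tree: ModelTree
    best_clock: ClockModel


# ---------------------------------------------------------------------------
# Node-age optimization
# ---------------------------------------------------------------------------


def _initialize_ages(tree: ModelTree, basal_age: float) -> None:
    """Spread internal ages evenly between the root and tip constraints."""
    depth: dict[int, int] = {id(tree.root): 0}
    maxdepth: dict[int, int] = {}
    for node in tree.preorder():
        if node.parent is not None:
            depth[id(node)] = depth[id(node.parent)] + 1
    for node in tree.postorder():
        if node.is_leaf:
            maxdepth[id(node)] = depth[id(node)]
        else:
            maxdepth[id(node)] = max(maxdepth[id(c)] for c in node.children)
    tree.root.age = basal_age
    for node in tree.preorder():
        if node.parent is None or node.is_leaf:
            continue
        oldest_tip = max(l.age for l in _subtree_leaves(node))
        parent_age = node.parent.age
        # interpolate by remaining node depth toward the oldest tip below
        steps_left = maxdepth[id(node)] - depth[id(node)] + 1
        node.age = oldest_tip + (parent_age - oldest_tip) * (
            steps_left / (steps_left + 1)
        )
        node.age = min(node.age, parent_age)


def _subtree_leaves(node) -> list:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        else:
            stack.extend(n.children)
    return out


def date_internal_nodes(
    tree: ModelTree,
    basal_age: float,
    rep: FAReplicate,
    clock: ClockModel,
    rates: SkylineRates | None = None,
    rc: RateClasses | None = None,
    cm: CharacterMatrix | None = None,
    E: UnsampledProbabilityFunction | None = None,
    tol: float = 0.01,
    max_sweeps: int = 10,
    ascertainment: bool = False,
    warm_tree: ModelTree | None = None,
) -> ModelTree:
    """Set internal node ages to maximize lnL alpha (+ lnP FBD if rates given).

    The root is fixed at ``basal_age`` and tips at the replicate's first
    appearances; the remaining internal nodes are optimized by coordinate
    ascent, each within its feasible window (between its parent's age and
    its oldest descendant), with golden-section search to ``tol`` Myr.
    Deterministic given its inputs.
    """
    if cm is None:
        raise ValidationError("a character matrix is required to date nodes")
    work = tree.copy()
    for leaf in work.leaves():
        if leaf.label not in rep.ages:
            raise ValidationError(f"replicate lacks an FA age for {leaf.label!r}")
        leaf.age = rep.ages[leaf.label]
        if leaf.age > basal_age:
            raise ValidationError(
                f"basal age {basal_age} Ma younger than FA of {leaf.label!r} "
                f"({leaf.age} Ma)"
            )
    _initialize_ages(work, basal_age)
    if warm_tree is not None:
        # reuse a previous solution's internal ages (same topology),
        # clamped into this replicate's feasible windows
        for node, prev in zip(work.postorder(), warm_tree.postorder()):
            if not node.is_leaf and node.parent is not None:
                node.age = prev.age
        work.root.age = basal_age
        for node in work.postorder():  # push up over older descendants
            if not node.is_leaf and node.parent is not None:
                node.age = max(node.age, max(c.age for c in node.children))
        for node in work.preorder():  # then cap below parents
            if node.parent is not None and not node.is_leaf:
                node.age = min(node.age, node.parent.age)
    work.validate_ages()

    if rc is None:
        rc = quartile_rate_classes(clock.sigma)
    if rates is not None and E is None:
        youngest = min(l.age for l in work.leaves())
        E = unsampled_probability(
            rates,
            older=max(basal_age, rates.timescale.older_bound),
            younger=min(youngest, rates.timescale.younger_bound),
        )

    engine = PruningEngine(work, cm, clock, rc, ascertainment=ascertainment)

    def node_fbd(node, age: float) -> float:
        """FBD log-prior contribution of the branches touching ``node``."""
        if E is None:
            return 0.0
        total = -E.integral_weight(age, node.parent.age)
        for child in node.children:
            total -= E.integral_weight(child.age, age)
        return total

    fbd_total = 0.0
    if E is not None:
        for parent, child in work.branches():
            fbd_total -= E.integral_weight(child.age, parent.age)

    free = [
        n for n in work.postorder() if not n.is_leaf and n.parent is not None
    ]
    prev_obj = engine.loglik() + fbd_total
    for sweep in range(max_sweeps):
        # coarse pass first, then refine; alternate sweep direction so
        # changes propagate both root-ward and tip-ward
        xatol = max(tol, 0.2) if sweep == 0 and warm_tree is None else tol
        order = free if sweep % 2 == 0 else list(reversed(free))
        for node in order:
            lo = max(c.age for c in node.children)
            hi = node.parent.age
            if hi - lo <= xatol:
                continue
            old_age = node.age
            fbd_rest = fbd_total - node_fbd(node, old_age)

            def neg(age: float, node=node, fbd_rest=fbd_rest) -> float:
                return -(
                    engine.loglik_if_age(node, age)
                    + fbd_rest
                    + node_fbd(node, age)
                )

            res = minimize_scalar(
                neg,
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": xatol},
            )
            best = float(res.x)
            if -res.fun < -neg(old_age):
                best = old_age  # keep the incumbent on numerical ties
            engine.set_age(node, best)
            fbd_total = fbd_rest + node_fbd(node, best)
        obj = engine.loglik() + fbd_total
        if sweep >= 1 and obj - prev_obj < 2e-2:
            break
        prev_obj = obj
    work.validate_ages()
    return work


def _optimize_clock(
    tree: ModelTree,
    cm: CharacterMatrix,
    mode: str,
    tau: float,
    sigma: float,
    init: ClockModel | None = None,
    ascertainment: bool = False,
) -> ClockModel:
    """Maximize lnL over clock rates on the log scale, ages held fixed."""
    rc = quartile_rate_classes(sigma)

    if mode == "strict":
        def neg(log_alpha: float) -> float:
            clock = ClockModel.strict(math.exp(log_alpha), sigma)
            return -matrix_log_likelihood(
                tree, cm, clock, rc, ascertainment=ascertainment
            )

        x0 = math.log(init.alpha_early) if init else math.log(0.01)
        res = minimize_scalar(
            neg,
            bounds=(x0 - 6.0, x0 + 6.0),
            method="bounded",
            options={"xatol": 1e-4},
        )
        return ClockModel.strict(math.exp(float(res.x)), sigma)

    def neg2(p: np.ndarray) -> float:
        clock = ClockModel.early_burst(
            math.exp(p[0]), math.exp(p[1]), tau, sigma
        )
        return -matrix_log_likelihood(
            tree, cm, clock, rc, ascertainment=ascertainment
        )

    if init is not None:
        x0 = np.array([math.log(init.alpha_early), math.log(init.alpha_late)])
    else:
        x0 = np.array([math.log(0.02), math.log(0.01)])
    res = minimize(
        neg2, x0, method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
    )
    return ClockModel.early_burst(
        math.exp(res.x[0]), math.exp(res.x[1]), tau, sigma
    )


# ---------------------------------------------------------------------------
# The posterior scan
# ---------------------------------------------------------------------------


def scan_posterior(
    tree: ModelTree,
    cm: CharacterMatrix,
    fc: FACandidateSet,
    rates: SkylineRates,
    config: AnalysisConfig,
    models: tuple[str, ...] = ALL_MODELS,
    sigma: float | None = None,
    reoptimize_per_replicate: bool = False,
    outer_iters: int = 2,
) -> dict[str, ModelScanResult]:
    """Grid-scan the basal divergence age for each model.

    For each model and each basal age on the grid the clock rates and
    internal-node ages are optimized (alternating golden-section over rates
    and coordinate ascent over ages), and the resulting posterior mass is
    averaged over FA replicates, each weighted by its beta(1, N) prior.
    The clock is optimized on the first replicate and shared across the
    rest unless ``reoptimize_per_replicate`` is set.

    Returns per model: the best decomposition (additivity of
    lnP FAs + lnL alpha + lnP FBD holds exactly), the posterior surface
    over the grid, the best dated tree and the best clock.
    """
    grid = config.grid()
    if len(grid) == 0:
        raise ValidationError("empty basal-age grid")
    missing = set(tree.taxa) - set(fc.taxa)
    if missing:
        raise ValidationError(f"tree taxa lacking FA candidates: {sorted(missing)}")

    if sigma is None:
        if cm.n_char >= 10:
            steps = count_parsimony_steps(tree, cm)
            try:
                sigma = fit_rate_distribution(steps).lognormal_sigma
            except ValidationError:
                sigma = 0.0
        else:
            sigma = 0.0
    rc = quartile_rate_classes(sigma, config.rate_class_count)

    replicates = []
    for i in range(config.replicates):
        rep = sample_fa_replicate(fc, seed=(config.seed + 104729 * i) % (2**31 - 1))
        replicates.append((rep, fa_log_prior(rep, fc)))

    oldest_fa = max(max(r.ages[t] for t in tree.taxa) for r, _ in replicates)
    E_cache: dict[float, UnsampledProbabilityFunction] = {}

    def get_E(basal: float, youngest: float) -> UnsampledProbabilityFunction:
        key = round(basal, 9)
        if key not in E_cache:
            E_cache[key] = unsampled_probability(
                rates,
                older=max(basal, rates.timescale.older_bound),
                younger=min(youngest, rates.timescale.younger_bound),
            )
        return E_cache[key]

    results: dict[str, ModelScanResult] = {}
    for model in models:
        use_fbd = model != MODEL_STRICT_FA
        mode = "early_burst" if model == MODEL_EARLY_BURST else "strict"
        surface_ln = np.full(len(grid), -np.inf)
        best: tuple[float, float, ModelTree, ClockModel, float, float, float] | None = None
        clock_warm: ClockModel | None = None
        tree_warm: ModelTree | None = None

        for gi, basal in enumerate(grid):
            if basal <= oldest_fa:
                continue
            rep_masses = []
            shared_clock: ClockModel | None = None
            rep0_tree: ModelTree | None = None
            for ri, (rep, lnpfa) in enumerate(replicates):
                youngest = min(rep.ages[t] for t in tree.taxa)
                E = get_E(basal, youngest) if use_fbd else None
                if ri == 0 or reoptimize_per_replicate:
                    clock = clock_warm or _default_clock(mode, config, sigma)
                    dated = None
                    for oi in range(outer_iters):
                        dated = date_internal_nodes(
                            tree, basal, rep, clock,
                            rates=rates if use_fbd else None,
                            rc=rc, cm=cm, E=E,
                            ascertainment=config.ascertainment,
                            warm_tree=dated if dated is not None else tree_warm,
                        )
                        clock = _optimize_clock(
                            dated, cm, mode, config.breakpoint_tau, sigma,
                            init=clock, ascertainment=config.ascertainment,
                        )
                    shared_clock = clock
                    clock_warm = clock
                    if ri == 0:
                        rep0_tree = dated
                        tree_warm = dated
                else:
                    clock = shared_clock
                    dated = date_internal_nodes(
                        tree, basal, rep, clock,
                        rates=rates if use_fbd else None,
                        rc=rc, cm=cm, E=E,
                        ascertainment=config.ascertainment,
                        warm_tree=rep0_tree,
                    )
                lnl = matrix_log_likelihood(
                    dated, cm, clock, rc, ascertainment=config.ascertainment
                )
                E_report = get_E(basal, min(rep.ages[t] for t in tree.taxa))
                lnfbd = 0.0
                for parent, child in dated.branches():
                    lnfbd -= E_report.integral_weight(child.age, parent.age)
                # the model's own objective picks the best tree; the FA-only
                # model still reports the FBD log-prior of that tree
                mass = lnpfa + lnl + (lnfbd if use_fbd else 0.0)
                rep_masses.append(mass)
                if best is None or mass > best[0]:
                    best = (mass, basal, dated, clock, lnpfa, lnl, lnfbd)
            if rep_masses:
                surface_ln[gi] = logsumexp(rep_masses) - math.log(len(rep_masses))

        if best is None:
            raise ValidationError(
                f"no grid age older than the oldest FA ({oldest_fa} Ma)"
            )
        surface = PosteriorSurface(model, grid.copy(), surface_ln)
        ci = credible_interval(surface, 0.95)
        _, basal, dated, clock, lnpfa, lnl, lnfbd = best
        posterior = ModelPosterior.from_components(
            model, basal, lnpfa, lnl, lnfbd,
            credible_older=ci[0], credible_younger=ci[1],
        )
        results[model] = ModelScanResult(posterior, surface, dated, clock)
    return results


def _default_clock(mode: str, config: AnalysisConfig, sigma: float) -> ClockModel:
    if mode == "strict":
        return ClockModel.strict(0.01, sigma)
    return ClockModel.early_burst(0.02, 0.01, config.breakpoint_tau, sigma)


# ---------------------------------------------------------------------------
# Credible intervals and Bayes factors
# ---------------------------------------------------------------------------


def credible_interval(
    surface: PosteriorSurface, level: float = 0.95
) -> tuple[float, float]:
    """Smallest set of grid ages holding >= ``level`` posterior mass.

    Grid points are added highest posterior first (ties resolved toward
    the earlier-sorted, higher-posterior point); the result is reported as
    (oldest, youngest).  A flat surface returns the full window with a
    warning.
    """
    ln = surface.ln_posterior
    finite = np.isfinite(ln)
    if not finite.any():
        raise ValidationError("posterior surface has no finite values")
    if np.allclose(ln[finite], ln[finite][0], rtol=0.0, atol=1e-12):
        warnings.warn(
            "posterior surface is flat; credible interval is the full window",
            stacklevel=2,
        )
        ages = surface.ages[finite]
        return float(ages.max()), float(ages.min())
    probs = np.exp(ln - logsumexp(ln[finite]))
    probs[~finite] = 0.0
    order = np.argsort(-probs, kind="stable")
    chosen: list[int] = []
    mass = 0.0
    for idx in order:
        chosen.append(int(idx))
        mass += probs[idx]
        if mass >= level - 1e-12:
            break
    ages = surface.ages[chosen]
    return float(ages.max()), float(ages.min())


def bayes_factor(a: PosteriorSurface, b: PosteriorSurface) -> float:
    """Ratio of grid-summed (marginal) posterior masses of a over b."""
    if a.ages.shape != b.ages.shape or not np.allclose(a.ages, b.ages):
        raise ValidationError("Bayes factor requires surfaces on the same grid")
    return float(np.exp(a.log_marginal() - b.log_marginal()))


def conditional_bayes_factor(
    reference: PosteriorSurface, age_favoured: float, age_alternative: float
) -> float:
    """Posterior ratio within one model's surface at two basal ages.

    The reference model's posterior at the age it favours divided by its
    posterior at the age favoured by a competing model — a conditional
    variant of model support useful when two models prefer different
    divergence times.
    """
    def at(age: float) -> float:
        idx = int(np.argmin(np.abs(reference.ages - age)))
        return float(reference.ln_posterior[idx])

    return float(np.exp(at(age_favoured) - at(age_alternative)))


# ---------------------------------------------------------------------------
# FA candidate I/O
# ---------------------------------------------------------------------------

FA_COLUMNS = ["taxon", "collection", "max_ma", "min_ma"]


def read_fa_candidates(path: str | Path) -> FACandidateSet:
    """Read FA candidates CSV (taxon, collection, max_ma, min_ma)."""
    df = pd.read_csv(path)
    missing = [c for c in FA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    candidates: dict[str, list[FACandidate]] = {}
    for row in df.itertuples(index=False):
        candidates.setdefault(str(row.taxon), []).append(
            FACandidate(str(row.collection), float(row.max_ma), float(row.min_ma))
        )
    return FACandidateSet(candidates)


def write_fa_candidates(fc: FACandidateSet, path: str | Path) -> None:
    rows = [
        {
            "taxon": taxon,
            "collection": cand.collection,
            "max_ma": cand.older,
            "min_ma": cand.younger,
        }
        for taxon in fc.taxa
        for cand in fc.candidates[taxon]
    ]
    pd.DataFrame(rows, columns=FA_COLUMNS).to_csv(path, index=False)
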