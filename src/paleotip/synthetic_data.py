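"""Forward simulation of the processes the analysis assumes.

The generator produces, from one seeded specification:

* a complete birth-death tree grown forward in time under piecewise-
  constant origination/extinction rates (budding speciation);
* Poisson fossil-sampling events per lineage, with optional lognormal
  among-lineage sampling-rate heterogeneity;
* the reconstructed tree of sampled species, tips placed at first
  appearances (zero-length branches where a first appearance predates the
  true divergence, the sampled-ancestor convention);
* an occurrence table whose events are grouped into collections with
  bounded age uncertainty, plus the per-taxon first-appearance candidate
  sets that fall out of that uncertainty;
* a discrete character matrix evolved along the reconstructed tree under a
  strict or early-burst Mk clock with lognormal among-character rates;
* optionally a genus-level collapse (several species per genus, oldest
  species as exemplar) matching how genus-level analyses use species-level
  occurrence data.

``make_fixture_bundle`` writes a self-consistent directory of NEXUS,
newick, CSV and YAML files runnable end-to-end by the CLI, byte-identical
per seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from paleotip.core_io import (
    AnalysisConfig,
    CharacterMatrix,
    ModelTree,
    OccurrenceTable,
    Timescale,
    TreeNode,
    ValidationError,
    write_character_matrix,
    write_dated_tree,
    write_occurrences,
    write_timescale,
)
import pandas as pd

from paleotip.morph_likelihood import ClockModel, branch_expected_change
from paleotip.occurrence_rates import SkylineRates
from paleotip.tip_dating import FACandidate, FACandidateSet, write_fa_candidates

__all__ = [
    "SimulationSpec",
    "SimulatedClade",
    "simulate_fbd_tree",
    "simulate_occurrence_table",
    "simulate_characters",
    "make_fixture_bundle",
]


def _default_rates() -> SkylineRates:
    # species-level turnover plausible for early Palaeozoic brachiopods, on
    # 3-Myr stage-slices spanning the scan window plus the sampled record;
    # origination is elevated during the clade's initial radiation
    # (470-462 Ma) and declines afterwards
    ts = Timescale.uniform(521.0, 440.0, 27)
    lam = np.array(
        [0.8 if 462.0 <= iv.midpoint <= 470.0 else 0.3 for iv in ts]
    )
    n = len(ts)
    return SkylineRates(ts, lam, np.full(n, 0.35), np.full(n, 0.5))


def _default_clock() -> ClockModel:
    # early burst: pre-462 Ma rates three times the later rates
    return ClockModel.early_burst(0.03, 0.01, tau=462.0, sigma=1.0)


@dataclass
class SimulationSpec:
    """Conditions for one synthetic data set.

    Defaults emulate the genus-level Ordovician radiation setting: a
    521-440 Ma window, species-level origination/extinction/sampling of
    0.4/0.35/0.5 per lineage-Myr, lognormal sampling heterogeneity of
    scale 1, an early-burst clock with a 3x rate drop at 462 Ma and
    lognormal among-character spread 1, 65 characters on about 39 taxa,
    and on average two species per genus.
    """

    rates: SkylineRates = field(default_factory=_default_rates)
    heterogeneity_scale: float = 1.0
    clock: ClockModel = field(default_factory=_default_clock)
    n_characters: int = 65
    state_counts: tuple[int, ...] = (2, 2, 2, 3)
    missing_fraction: float = 0.1
    taxon_cap: int = 400
    origin_age: float | None = 470.0  # clade radiates mid-window
    species_per_genus: float = 2.0
    age_uncertainty: float = 1.0  # +- half-width on collection ages, Myr
    seed: int = 0

    def __post_init__(self) -> None:
        if self.taxon_cap < 2:
            raise ValidationError("taxon cap must be >= 2")
        if self.heterogeneity_scale < 0:
            raise ValidationError("heterogeneity scale must be >= 0")
        if self.n_characters < 1:
            raise ValidationError("need at least one character")

    @property
    def window(self) -> tuple[float, float]:
        ts = self.rates.timescale
        older = self.origin_age if self.origin_age is not None else ts.older_bound
        return older, ts.younger_bound


@dataclass
class _Lineage:
    id: int
    birth_age: float
    end_age: float = math.nan
    extinct: bool = False
    multiplier: float = 1.0
    sample_ages: list[float] = field(default_factory=list)
    births: list[tuple[float, int]] = field(default_factory=list)  # (age, child id)


@dataclass
class SimulatedClade:
    """Output of one forward FBD simulation."""

    complete_tree: ModelTree
    sampled_tree: ModelTree | None
    lineages: dict[int, _Lineage]
    sampled_species: list[str]
    fa_ages: dict[str, float]
    occurrences: dict[str, list[float]]  # species -> true sample ages
    resample_count: int = 0


def _species_label(lineage_id: int) -> str:
    return f"sp{lineage_id:04d}"


def _simulate_once(spec: SimulationSpec, rng: np.random.Generator) -> dict[int, _Lineage]:
    older, younger = spec.window
    rates = spec.rates
    lineages: dict[int, _Lineage] = {}
    counter = 0

    def new_lineage(birth_age: float) -> _Lineage:
        nonlocal counter
        mult = 1.0
        if spec.heterogeneity_scale > 0:
            mult = float(
                rng.lognormal(mean=0.0, sigma=spec.heterogeneity_scale)
            )
        lin = _Lineage(id=counter, birth_age=birth_age, multiplier=mult)
        lineages[counter] = lin
        counter += 1
        return lin

    capped = False
    stack = [new_lineage(older)]
    while stack:
        lin = stack.pop()
        t = lin.birth_age
        while True:
            lam, mu, psi = rates.at(t - 1e-12)
            psi_eff = psi * lin.multiplier
            idx = rates._clamped_index(t - 1e-12)
            edge = max(rates.timescale[idx].younger, younger)
            total = lam + mu + psi_eff
            if total <= 0:
                t = edge
            else:
                t_next = t - float(rng.exponential(1.0 / total))
                if t_next <= edge:
                    t = edge
                else:
                    u = float(rng.uniform())
                    if u < lam / total:
                        if len(lineages) >= spec.taxon_cap:
                            if not capped:
                                warnings.warn(
                                    "taxon cap reached; truncating births",
                                    stacklevel=3,
                                )
                                capped = True
                        else:
                            child = new_lineage(t_next)
                            lin.births.append((t_next, child.id))
                            stack.append(child)
                        t = t_next
                        continue
                    if u < (lam + mu) / total:
                        lin.end_age = t_next
                        lin.extinct = True
                        break
                    lin.sample_ages.append(t_next)
                    t = t_next
                    continue
            if t <= younger + 1e-12:
                lin.end_age = younger
                break
    return lineages


def _complete_tree(lineages: dict[int, _Lineage]) -> ModelTree:
    def build(lin: _Lineage) -> TreeNode:
        # walk the lineage's budding events young -> old, chaining nodes
        node = TreeNode(_species_label(lin.id), age=lin.end_age)
        for age, child_id in sorted(lin.births):
            parent = TreeNode(age=age)
            parent.add_child(node)
            parent.add_child(build(lineages[child_id]))
            node = parent
        return node

    return ModelTree(build(lineages[0]))


def _reconstructed_tree(
    lineages: dict[int, _Lineage], fa_ages: dict[str, float]
) -> ModelTree | None:
    sampled_ids = {
        lid for lid, lin in lineages.items() if lin.sample_ages
    }

    # lineages whose subtree (self or any descendant lineage) is sampled
    contributes: set[int] = set()
    order: list[int] = []
    stack = [0]
    while stack:
        lid = stack.pop()
        order.append(lid)
        stack.extend(child for _, child in lineages[lid].births)
    for lid in reversed(order):
        lin = lineages[lid]
        if lid in sampled_ids or any(
            c in contributes for _, c in lin.births
        ):
            contributes.add(lid)
    if 0 not in contributes:
        return None

    def build(lid: int) -> TreeNode | None:
        lin = lineages[lid]
        events: list[tuple[float, str, int]] = [
            (age, "birth", child_id)
            for age, child_id in lin.births
            if child_id in contributes
        ]
        if lid in sampled_ids:
            # a first appearance older than later buds attaches the tip as
            # a zero-length branch at its FA (sampled-ancestor convention)
            events.append((fa_ages[_species_label(lid)], "sample", lid))
        node: TreeNode | None = None
        for age, kind, ref in sorted(events):
            if kind == "sample":
                side: TreeNode | None = TreeNode(_species_label(ref), age=age)
            else:
                side = build(ref)
            if node is None:
                node = side
                continue
            parent = TreeNode(age=age)
            parent.add_child(node)
            parent.add_child(side)
            node = parent
        return node

    root = build(0)
    if root is None or root.is_leaf:
        return None
    tree = ModelTree(root)
    # clamp first appearances older than their true divergence to the
    # divergence age (zero-length branch: the sampled-ancestor convention)
    for node in tree.preorder():
        for child in node.children:
            if child.age is not None and node.age is not None:
                if child.age > node.age:
                    child.age = node.age
    return tree


def simulate_fbd_tree(
    spec: SimulationSpec,
    seed: int | None = None,
    min_sampled: int = 4,
    max_attempts: int = 500,
) -> SimulatedClade:
    """Forward-simulate a clade under the piecewise birth-death-sampling model.

    Starts one lineage at the window's old edge, draws events with a
    Gillespie walk inside each constant-rate interval, assigns
    Poisson(psi x heterogeneity) fossilization events per lineage, and
    rejection-resamples until at least ``min_sampled`` species carry
    fossils (the resample count is reported on the result).
    """
    base_seed = spec.seed if seed is None else seed
    attempts = 0
    while True:
        rng = np.random.default_rng((base_seed + 7919 * attempts) % (2**31 - 1))
        lineages = _simulate_once(spec, rng)
        sampled = [lid for lid, lin in lineages.items() if lin.sample_ages]
        if len(sampled) >= min_sampled:
            break
        attempts += 1
        if attempts >= max_attempts:
            raise ValidationError(
                f"no simulation with >= {min_sampled} sampled taxa in "
                f"{max_attempts} attempts; sampling rate may be too low"
            )
    species = sorted(_species_label(lid) for lid in sampled)
    fa_ages = {
        _species_label(lid): max(lineages[lid].sample_ages) for lid in sampled
    }
    occurrences = {
        _species_label(lid): sorted(lineages[lid].sample_ages, reverse=True)
        for lid in sampled
    }
    return SimulatedClade(
        complete_tree=_complete_tree(lineages),
        sampled_tree=_reconstructed_tree(lineages, fa_ages),
        lineages=lineages,
        sampled_species=species,
        fa_ages=fa_ages,
        occurrences=occurrences,
        resample_count=attempts,
    )


# ---------------------------------------------------------------------------
# Occurrence tables and FA candidates
# ---------------------------------------------------------------------------


def assign_genera(
    clade: SimulatedClade, mean_species: float = 2.0, seed: int = 0
) -> dict[str, str]:
    """Group sampled species into genera (sizes ~ 1 + Poisson(mean - 1)).

    Species are grouped in tree order so genera are clusters of relatives;
    the mapping is species label -> genus label.
    """
    rng = np.random.default_rng(seed)
    if clade.sampled_tree is not None:
        ordered = [
            l.label for l in clade.sampled_tree.leaves()
            if l.label in clade.fa_ages
        ]
    else:
        ordered = sorted(clade.sampled_species)
    mapping: dict[str, str] = {}
    gi = 0
    i = 0
    while i < len(ordered):
        size = 1 + int(rng.poisson(max(0.0, mean_species - 1.0)))
        for sp in ordered[i : i + size]:
            mapping[sp] = f"gen{gi:03d}"
        gi += 1
        i += size
    return mapping


def simulate_occurrence_table(
    clade: SimulatedClade,
    ts: Timescale,
    seed: int = 0,
    age_uncertainty: float = 1.0,
    genus_map: dict[str, str] | None = None,
    collection_spacing: float = 0.25,
    localities_per_horizon: int = 3,
) -> tuple[OccurrenceTable, FACandidateSet]:
    """Bin fossil events into collections and derive FA candidate sets.

    Events are grouped onto horizons ``collection_spacing`` Myr apart with
    a few localities per horizon, so co-occurring taxa share collection
    ids.  Each collection's age bounds are its horizon age +-
    ``age_uncertainty`` (clipped to the timescale).  A taxon's FA
    candidates are all of its collections whose age bounds overlap its
    oldest collection's bounds; with zero uncertainty every taxon has a
    single candidate.
    """
    rng = np.random.default_rng(seed)
    rows = []
    taxon_colls: dict[str, dict[str, tuple[float, float]]] = {}
    for sp in clade.sampled_species:
        genus = genus_map.get(sp, sp) if genus_map else sp
        for age in clade.occurrences[sp]:
            horizon = round(age / collection_spacing)
            locality = int(rng.integers(localities_per_horizon))
            coll = f"c{horizon:05d}_{locality}"
            h_age = horizon * collection_spacing
            older = min(h_age + age_uncertainty, ts.older_bound)
            younger = max(h_age - age_uncertainty, ts.younger_bound)
            if younger > older:
                older, younger = ts.older_bound, ts.younger_bound
            rows.append(
                {
                    "species": sp,
                    "genus": genus,
                    "collection": coll,
                    "max_ma": older,
                    "min_ma": younger,
                }
            )
            taxon = genus if genus_map else sp
            taxon_colls.setdefault(taxon, {})[coll] = (older, younger)
    occ = OccurrenceTable(pd.DataFrame(rows))

    candidates: dict[str, list[FACandidate]] = {}
    for taxon, colls in taxon_colls.items():
        items = [
            FACandidate(c, older, younger)
            for c, (older, younger) in sorted(colls.items())
        ]
        oldest = max(items, key=lambda c: (c.older, c.younger, c.collection))
        cands = [
            c
            for c in items
            if c is oldest
            or min(c.older, oldest.older) > max(c.younger, oldest.younger)
        ]
        candidates[taxon] = cands
    return occ, FACandidateSet(candidates)


def simulate_background_occurrences(
    ts: Timescale,
    seed: int = 0,
    n_clades: int = 40,
    origination: float = 0.35,
    extinction: float = 0.33,
    sampling: float = 0.5,
    heterogeneity_scale: float = 1.0,
    age_uncertainty: float = 1.0,
    collection_spacing: float = 0.25,
) -> pd.DataFrame:
    """Occurrence rows for a broader background fauna across the window.

    Rate estimation needs occurrences well beyond the focal clade (and
    older than its record), the way a clade-level study leans on the
    encompassing group's database extract.  Independent background clades
    originate at staggered ages across the timescale and evolve under
    constant turnover; their occurrences share the same collection-horizon
    scheme as the focal clade (ids prefixed ``b``).
    """
    rng = np.random.default_rng(seed)
    rates = SkylineRates.constant(
        origination, extinction, sampling,
        ts.older_bound, ts.younger_bound,
    )
    rows = []
    origins = np.linspace(
        ts.older_bound - 1.0, ts.younger_bound + 8.0, n_clades
    )
    for ci, origin in enumerate(origins):
        spec = SimulationSpec(
            rates=rates,
            heterogeneity_scale=heterogeneity_scale,
            taxon_cap=200,
            origin_age=float(origin),
            seed=int(rng.integers(2**31 - 1)),
        )
        try:
            clade = simulate_fbd_tree(spec, min_sampled=1, max_attempts=200)
        except ValidationError:
            continue
        for sp, ages in clade.occurrences.items():
            for age in ages:
                horizon = round(age / collection_spacing)
                locality = int(rng.integers(3))
                h_age = horizon * collection_spacing
                older = min(h_age + age_uncertainty, ts.older_bound)
                younger = max(h_age - age_uncertainty, ts.younger_bound)
                rows.append(
                    {
                        "species": f"bg{ci:02d}_{sp}",
                        "genus": f"bgen{ci:02d}",
                        "collection": f"b{horizon:05d}_{locality}",
                        "max_ma": older,
                        "min_ma": younger,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Character simulation
# ---------------------------------------------------------------------------


def simulate_characters(
    tree: ModelTree,
    clock: ClockModel,
    n_characters: int,
    state_counts: tuple[int, ...] = (2,),
    missing_fraction: float = 0.0,
    seed: int = 0,
) -> CharacterMatrix:
    """Evolve discrete characters along a dated tree under the Mk clock.

    Each character draws a lognormal(0, sigma) rate factor, a state count
    cycled from ``state_counts``, and a uniform root state, then changes
    along each branch with the Mk transition probabilities implied by the
    clock's expected-change integral.  A missing-data mask is applied at
    the requested fraction.
    """
    tree.validate_ages()
    rng = np.random.default_rng(seed)
    leaves = tree.leaves()
    taxa = [l.label for l in leaves]
    states = np.zeros((len(taxa), n_characters), dtype=np.int64)
    k_arr = np.array(
        [state_counts[c % len(state_counts)] for c in range(n_characters)],
        dtype=np.int64,
    )
    factors = (
        rng.lognormal(0.0, clock.sigma, size=n_characters)
        if clock.sigma > 0
        else np.ones(n_characters)
    )
    leaf_index = {id(l): i for i, l in enumerate(leaves)}
    node_states: dict[int, np.ndarray] = {
        id(tree.root): np.array(
            [rng.integers(k) for k in k_arr], dtype=np.int64
        )
    }
    for node in tree.preorder():
        current = node_states[id(node)]
        if node.is_leaf:
            states[leaf_index[id(node)]] = current
            continue
        for child in node.children:
            nu_base = branch_expected_change(node.age, child.age, clock)
            child_states = current.copy()
            for c in range(n_characters):
                k = int(k_arr[c])
                nu = factors[c] * nu_base
                x = math.exp(-k * nu / (k - 1))
                if rng.uniform() >= x:  # jump to the stationary distribution
                    child_states[c] = int(rng.integers(k))
            node_states[id(child)] = child_states
    if missing_fraction > 0:
        mask = rng.uniform(size=states.shape) < missing_fraction
        states[mask] = -1
    return CharacterMatrix(taxa=taxa, states=states, k_per_char=k_arr)


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------


def make_fixture_bundle(
    spec: SimulationSpec,
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    genus_level: bool = True,
) -> dict[str, Path]:
    """Write a self-consistent NEXUS + newick + CSV + YAML bundle.

    The bundle contains the occurrence table, timescale, FA candidate
    sets, character matrix, the model cladogram (topology), the true
    dated tree, the generating parameters, and an analysis configuration;
    it is deterministic per seed and passes all reader validations.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clade = simulate_fbd_tree(spec, min_sampled=10)
    if clade.sampled_tree is None:
        raise ValidationError("simulation yielded no reconstructable tree")
    ts = spec.rates.timescale

    genus_map = None
    if genus_level:
        genus_map = assign_genera(
            clade, spec.species_per_genus, seed=spec.seed + 1
        )
    occ, fc = simulate_occurrence_table(
        clade,
        ts,
        seed=spec.seed + 2,
        age_uncertainty=spec.age_uncertainty,
        genus_map=genus_map,
    )
    # rate estimation leans on the encompassing fauna, not just the clade
    background = simulate_background_occurrences(
        ts,
        seed=spec.seed + 4,
        heterogeneity_scale=spec.heterogeneity_scale,
        age_uncertainty=spec.age_uncertainty,
    )
    occ = OccurrenceTable(
        pd.concat([occ.records, background], ignore_index=True)
    )

    analysed_tree = clade.sampled_tree
    if genus_map:
        analysed_tree = _collapse_to_genera(clade, genus_map)
    cm = simulate_characters(
        analysed_tree,
        spec.clock,
        spec.n_characters,
        spec.state_counts,
        spec.missing_fraction,
        seed=spec.seed + 3,
    )

    if config is None:
        oldest_fa = max(
            clade.fa_ages[sp]
            for sp in clade.sampled_species
        )
        scan_younger = oldest_fa + 1.0
        config = AnalysisConfig(
            scan_older=min(ts.older_bound, scan_younger + 15.0),
            scan_younger=scan_younger,
            grid_step=3.0,
            breakpoint_tau=spec.clock.tau or 462.0,
            replicates=3,
            seed=spec.seed,
        )

    paths = {
        "occurrences": out / "occurrences.csv",
        "timescale": out / "timescale.yaml",
        "fa_candidates": out / "fa_candidates.csv",
        "matrix": out / "matrix.nex",
        "tree": out / "tree.newick",
        "true_tree": out / "true_dated_tree.newick",
        "config": out / "config.yaml",
        "truth": out / "truth.yaml",
    }
    write_occurrences(occ, paths["occurrences"])
    write_timescale(ts, paths["timescale"])
    write_fa_candidates(fc, paths["fa_candidates"])
    write_character_matrix(cm, paths["matrix"])
    paths["tree"].write_text(
        analysed_tree.to_newick(dated=False) + "\n", encoding="utf-8"
    )
    write_dated_tree(analysed_tree, paths["true_tree"])
    config.to_yaml(paths["config"])
    truth = {
        "origination": [float(x) for x in spec.rates.origination],
        "extinction": [float(x) for x in spec.rates.extinction],
        "sampling": [float(x) for x in spec.rates.sampling],
        "heterogeneity_scale": spec.heterogeneity_scale,
        "clock_mode": spec.clock.mode,
        "alpha_early": spec.clock.alpha_early,
        "alpha_late": spec.clock.alpha_late,
        "breakpoint_tau": spec.clock.tau,
        "sigma": spec.clock.sigma,
        "true_root_age": float(analysed_tree.root.age),
        "n_sampled_species": len(clade.sampled_species),
        "n_analysed_taxa": len(analysed_tree.taxa),
        "resample_count": clade.resample_count,
        "seed": spec.seed,
    }
    paths["truth"].write_text(
        yaml.safe_dump(truth, sort_keys=False), encoding="utf-8"
    )
    return paths


def _collapse_to_genera(
    clade: SimulatedClade, genus_map: dict[str, str]
) -> ModelTree:
    """Keep one exemplar species (oldest FA) per genus, relabelled by genus."""
    exemplar: dict[str, str] = {}
    for sp, genus in genus_map.items():
        if genus not in exemplar or clade.fa_ages[sp] > clade.fa_ages[exemplar[genus]]:
            exemplar[genus] = sp
    keep = {sp: g for g, sp in exemplar.items()}
    tree = clade.sampled_tree.copy()

    def prune(node: TreeNode) -> TreeNode | None:
        if node.is_leaf:
            if node.label in keep:
                return TreeNode(keep[node.label], age=node.age)
            return None
        kept = [prune(c) for c in node.children]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        new = TreeNode(age=node.age)
        for c in kept:
            new.add_child(c)
        return new

    root = prune(tree.root)
    if root is None or root.is_leaf:
        raise ValidationError("genus collapse left fewer than two tips")
    out = ModelTree(root)
    for node in out.preorder():
        for child in node.children:
            if child.age > node.age:
                child.age = node.age
    return out
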