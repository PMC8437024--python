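"""Shared fixtures: tiny trees, matrices and rate skylines built in memory."""

import numpy as np
import pytest

from paleotip.core_io import CharacterMatrix, ModelTree, Timescale, TreeNode
from paleotip.occurrence_rates import SkylineRates


def balanced_tree(tip_ages: dict[str, float], node_ages: list[float]) -> ModelTree:
    """A four-tip balanced tree ((A,B),(C,D)) with explicit ages.

    ``node_ages`` is [root, left, right].
    """
    a, b, c, d = (TreeNode(t, age=tip_ages[t]) for t in ("A", "B", "C", "D"))
    left = TreeNode(age=node_ages[1], children=[a, b])
    right = TreeNode(age=node_ages[2], children=[c, d])
    return ModelTree(TreeNode(age=node_ages[0], children=[left, right]))


@pytest.fixture
def four_tip_tree() -> ModelTree:
    return balanced_tree(
        {"A": 460.0, "B": 458.0, "C": 461.0, "D": 455.0},
        [470.0, 465.0, 466.0],
    )


@pytest.fixture
def two_tip_tree() -> ModelTree:
    a = TreeNode("A", age=460.0)
    b = TreeNode("B", age=455.0)
    return ModelTree(TreeNode(age=468.0, children=[a, b]))


@pytest.fixture
def constant_rates() -> SkylineRates:
    return SkylineRates.constant(
        origination=0.4, extinction=0.3, sampling=0.2,
        older=500.0, younger=440.0, n_intervals=1,
    )


@pytest.fixture
def skyline_rates() -> SkylineRates:
    ts = Timescale.uniform(500.0, 440.0, 6)
    return SkylineRates(
        ts,
        np.array([0.2, 0.5, 0.8, 0.4, 0.3, 0.2]),
        np.array([0.1, 0.3, 0.4, 0.5, 0.3, 0.2]),
        np.array([0.1, 0.2, 0.5, 0.6, 0.4, 0.3]),
    )


def small_dating_problem(seed: int = 0, n_char: int = 30):
    """A compact species-level dating problem for scan-level tests.

    Returns (tree, character matrix, FA candidate set, true rates); the
    tree has roughly 8-25 fossil tips with first appearances drawn from
    collections carrying +-1 Myr age uncertainty.
    """
    from paleotip.morph_likelihood import ClockModel
    from paleotip.synthetic_data import (
        SimulationSpec,
        simulate_characters,
        simulate_fbd_tree,
        simulate_occurrence_table,
    )

    rates = SkylineRates.constant(
        origination=0.5, extinction=0.3, sampling=0.6,
        older=500.0, younger=445.0, n_intervals=11,
    )
    clock = ClockModel.early_burst(0.03, 0.01, tau=462.0, sigma=0.5)
    spec = SimulationSpec(
        rates=rates,
        heterogeneity_scale=0.0,
        clock=clock,
        n_characters=n_char,
        taxon_cap=60,
        origin_age=470.0,
        age_uncertainty=1.0,
        seed=seed,
    )
    clade = simulate_fbd_tree(spec, min_sampled=8)
    tree = clade.sampled_tree
    occ, fc = simulate_occurrence_table(
        clade, rates.timescale, seed=seed + 1, age_uncertainty=1.0
    )
    cm = simulate_characters(
        tree, clock, n_char, (2, 2, 3), missing_fraction=0.05, seed=seed + 2
    )
    return tree, cm, fc, rates


def random_character_matrix(
    rng: np.random.Generator,
    taxa: list[str],
    n_char: int,
    k: int = 2,
    missing_fraction: float = 0.0,
) -> CharacterMatrix:
    states = rng.integers(0, k, size=(len(taxa), n_char))
    if missing_fraction > 0:
        mask = rng.uniform(size=states.shape) < missing_fraction
        states[mask] = -1
    return CharacterMatrix(
        taxa=list(taxa), states=states, k_per_char=np.full(n_char, k)
    )
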