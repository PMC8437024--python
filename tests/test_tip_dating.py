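"""FA priors, node dating, posterior scan and model comparison."""

import itertools
import math

import numpy as np
import pytest

from paleotip.core_io import (
    AnalysisConfig,
    CharacterMatrix,
    ModelTree,
    TreeNode,
    ValidationError,
)
from paleotip.fbd_priors import tree_log_prior
from paleotip.morph_likelihood import (
    ClockModel,
    matrix_log_likelihood,
    quartile_rate_classes,
)
from paleotip.occurrence_rates import SkylineRates
from paleotip.tip_dating import (
    MODEL_EARLY_BURST,
    MODEL_STRICT_FA,
    MODEL_STRICT_FBD,
    FACandidate,
    FACandidateSet,
    FAReplicate,
    ModelPosterior,
    PosteriorSurface,
    bayes_factor,
    conditional_bayes_factor,
    credible_interval,
    date_internal_nodes,
    fa_log_prior,
    read_fa_candidates,
    sample_fa_replicate,
    scan_posterior,
    write_fa_candidates,
)
from tests.conftest import random_character_matrix, small_dating_problem


class TestSampleFAReplicate:
    def test_single_candidate_fa_is_that_collection(self):
        fc = FACandidateSet({"tax": [FACandidate("c1", 470.0, 468.0)]})
        rep = sample_fa_replicate(fc, seed=3)
        assert rep.fa_collection["tax"] == "c1"
        assert 468.0 <= rep.ages["tax"] <= 470.0

    def test_shared_collection_single_draw(self):
        shared = FACandidate("shared", 470.0, 465.0)
        fc = FACandidateSet({"t1": [shared], "t2": [shared]})
        for seed in range(10):
            rep = sample_fa_replicate(fc, seed=seed)
            assert rep.ages["t1"] == rep.ages["t2"]

    def test_oldest_candidate_fraction_matches_overlap_geometry(self):
        # candidates A [10, 8] and B [9, 7]: P(A draws older than B)
        a = FACandidate("A", 10.0, 8.0)
        b = FACandidate("B", 9.0, 7.0)
        fc = FACandidateSet({"tax": [a, b]})
        # analytic: P(U[8,10] > U[7,9]) by direct double integration
        grid = np.linspace(0, 1, 2001)
        da = 8 + 2 * grid
        db = 7 + 2 * grid
        p_analytic = np.mean(da[:, None] > db[None, :])
        hits = sum(
            sample_fa_replicate(fc, seed=s).fa_collection["tax"] == "A"
            for s in range(1000)
        )
        p_hat = hits / 1000
        se = math.sqrt(p_analytic * (1 - p_analytic) / 1000)
        assert abs(p_hat - p_analytic) < 3 * se


class TestFALogPrior:
    def test_single_candidate_contributes_zero(self):
        fc = FACandidateSet({"tax": [FACandidate("c1", 470.0, 468.0)]})
        rep = sample_fa_replicate(fc, seed=0)
        assert fa_log_prior(rep, fc) == 0.0

    def test_two_candidates_oldest_has_mass_three_quarters(self):
        fc = FACandidateSet(
            {
                "tax": [
                    FACandidate("old", 472.0, 470.0),
                    FACandidate("young", 469.0, 467.0),
                ]
            }
        )
        rep = FAReplicate(
            ages={"tax": 471.0}, fa_collection={"tax": "old"}, seed=0
        )
        assert fa_log_prior(rep, fc) == pytest.approx(math.log(0.75))

    @pytest.mark.parametrize("n", [1, 2, 3, 7, 20, 50])
    def test_masses_sum_to_one(self, n):
        cands = [
            FACandidate(f"c{j}", 480.0 - j, 479.0 - j) for j in range(n)
        ]
        fc = FACandidateSet({"tax": cands})
        total = 0.0
        for cand in cands:
            rep = FAReplicate(
                ages={"tax": cand.older},
                fa_collection={"tax": cand.collection},
                seed=0,
            )
            total += math.exp(fa_log_prior(rep, fc))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_non_candidate_collection_rejected(self):
        fc = FACandidateSet({"tax": [FACandidate("c1", 470.0, 468.0)]})
        rep = FAReplicate(
            ages={"tax": 469.0}, fa_collection={"tax": "other"}, seed=0
        )
        with pytest.raises(ValidationError, match="not a candidate"):
            fa_log_prior(rep, fc)

    def test_roundtrip_csv(self, tmp_path):
        fc = FACandidateSet(
            {
                "t1": [FACandidate("c1", 470, 468), FACandidate("c2", 469, 467)],
                "t2": [FACandidate("c2", 469, 467)],
            }
        )
        path = tmp_path / "fa.csv"
        write_fa_candidates(fc, path)
        back = read_fa_candidates(path)
        assert back.taxa == ["t1", "t2"]
        assert back.n_candidates("t1") == 2
        assert back.shared_collections() == {"c2": ["t1", "t2"]}


def _rep(ages: dict[str, float]) -> FAReplicate:
    return FAReplicate(
        ages=ages, fa_collection={t: f"c_{t}" for t in ages}, seed=0
    )


class TestDateInternalNodes:
    def test_two_tip_tree_root_fixed(self, constant_rates):
        a = TreeNode("A")
        b = TreeNode("B")
        tree = ModelTree(TreeNode(children=[a, b]))
        cm = CharacterMatrix(
            ["A", "B"], np.array([[0], [1]]), k_per_char=np.array([2])
        )
        rep = _rep({"A": 460.0, "B": 455.0})
        dated = date_internal_nodes(
            tree, 468.0, rep, ClockModel.strict(0.02),
            rates=constant_rates, cm=cm,
        )
        assert dated.root.age == 468.0
        assert {l.label: l.age for l in dated.leaves()} == rep.ages

    def test_basal_younger_than_fa_errors(self, constant_rates):
        a = TreeNode("A")
        b = TreeNode("B")
        tree = ModelTree(TreeNode(children=[a, b]))
        cm = CharacterMatrix(
            ["A", "B"], np.array([[0], [1]]), k_per_char=np.array([2])
        )
        rep = _rep({"A": 470.0, "B": 455.0})
        with pytest.raises(ValidationError, match="younger than FA"):
            date_internal_nodes(
                tree, 468.0, rep, ClockModel.strict(0.02),
                rates=constant_rates, cm=cm,
            )

    def test_matches_exhaustive_grid_four_tips(self, constant_rates):
        rng = np.random.default_rng(21)
        taxa = ["A", "B", "C", "D"]
        cm = random_character_matrix(rng, taxa, 12, k=2)
        clock = ClockModel.strict(0.05)
        rep = _rep({"A": 460.0, "B": 458.0, "C": 461.0, "D": 455.0})
        basal = 470.0

        def build(left_age, right_age):
            a, b, c, d = (TreeNode(t, age=rep.ages[t]) for t in taxa)
            left = TreeNode(age=left_age, children=[a, b])
            right = TreeNode(age=right_age, children=[c, d])
            return ModelTree(TreeNode(age=basal, children=[left, right]))

        best, best_ages = -np.inf, None
        for la in np.linspace(460.0, basal, 101):
            for ra in np.linspace(461.0, basal, 91):
                t = build(la, ra)
                obj = matrix_log_likelihood(t, cm, clock) + tree_log_prior(
                    t, constant_rates
                )
                if obj > best:
                    best, best_ages = obj, (la, ra)

        topo = build(465.0, 466.0)
        dated = date_internal_nodes(
            topo, basal, rep, clock, rates=constant_rates, cm=cm
        )
        got = sorted(
            n.age for n in dated.internal_nodes() if n.parent is not None
        )
        want = sorted(best_ages)
        assert np.allclose(got, want, atol=0.2)

    def test_objective_dominates_coarse_grid_six_tips(self, constant_rates):
        rng = np.random.default_rng(22)
        taxa = [f"t{i}" for i in range(6)]
        cm = random_character_matrix(rng, taxa, 15, k=2)
        clock = ClockModel.strict(0.04)
        ages = {t: float(rng.uniform(452, 462)) for t in taxa}
        rep = _rep(ages)
        basal = 470.0

        def caterpillar():
            node = TreeNode(taxa[0])
            for t in taxa[1:]:
                node = TreeNode(children=[node, TreeNode(t)])
            return ModelTree(node)

        topo = caterpillar()
        dated = date_internal_nodes(
            topo, basal, rep, clock, rates=constant_rates, cm=cm
        )
        obj_ours = matrix_log_likelihood(dated, cm, clock) + tree_log_prior(
            dated, constant_rates
        )
        # random feasible configurations never beat the coordinate ascent
        free = [
            n for n in dated.internal_nodes() if n.parent is not None
        ]
        best_random = -np.inf
        for _ in range(300):
            probe = dated.copy()
            for node in probe.postorder():
                if node.is_leaf or node.parent is None:
                    continue
                lo = max(c.age for c in node.children)
                node.age = float(rng.uniform(lo, basal))
            for node in probe.preorder():
                if node.parent is not None and not node.is_leaf:
                    node.age = min(node.age, node.parent.age)
            obj = matrix_log_likelihood(probe, cm, clock) + tree_log_prior(
                probe, constant_rates
            )
            best_random = max(best_random, obj)
        assert obj_ours >= best_random - 0.05

    def test_prior_dominated_limit_pushes_nodes_young(self):
        # near-flat likelihood and heavy sampling: short unsampled
        # branches are favored, so nodes sit near their youngest bound
        rates = SkylineRates.constant(0.4, 0.3, 3.0, 500, 440)
        rng = np.random.default_rng(23)
        taxa = ["A", "B", "C", "D"]
        cm = random_character_matrix(rng, taxa, 5, k=2)
        rep = _rep({"A": 460.0, "B": 458.0, "C": 461.0, "D": 455.0})
        a, b, c, d = (TreeNode(t) for t in taxa)
        left = TreeNode(children=[a, b])
        right = TreeNode(children=[c, d])
        tree = ModelTree(TreeNode(children=[left, right]))
        dated = date_internal_nodes(
            tree, 470.0, rep, ClockModel.strict(1e-5), rates=rates, cm=cm
        )
        for node in dated.internal_nodes():
            if node.parent is None:
                continue
            lo = max(ch.age for ch in node.children)
            assert node.age - lo < 0.5


class TestScanPosterior:
    def test_assembly_identity_single_point(self):
        tree, cm, fc, rates = small_dating_problem(seed=5)
        oldest = max(c.older for t in tree.taxa for c in fc.candidates[t])
        config = AnalysisConfig(
            scan_older=oldest + 3.0,
            scan_younger=oldest + 2.0,
            grid_step=5.0,  # single grid point
            replicates=1,
            seed=11,
        )
        results = scan_posterior(
            tree, cm, fc, rates, config,
            models=(MODEL_STRICT_FBD,), sigma=0.0,
        )
        r = results[MODEL_STRICT_FBD]
        p = r.posterior
        rep = sample_fa_replicate(fc, seed=config.seed)
        assert p.lnp_fas == pytest.approx(fa_log_prior(rep, fc), abs=1e-9)
        rc = quartile_rate_classes(0.0)
        assert p.lnl_alpha == pytest.approx(
            matrix_log_likelihood(r.best_tree, cm, r.best_clock, rc), abs=1e-9
        )
        assert p.lnp_fbd == pytest.approx(
            tree_log_prior(r.best_tree, rates), abs=1e-9
        )
        assert p.ln_posterior == pytest.approx(
            p.lnp_fas + p.lnl_alpha + p.lnp_fbd, abs=1e-9
        )

    def test_n_equal_one_removes_fa_prior_and_variance(self):
        tree, cm, fc, rates = small_dating_problem(seed=6)
        single = FACandidateSet(
            {t: [fc.ranked(t)[0]] for t in fc.taxa}
        )
        reps = [sample_fa_replicate(single, seed=s) for s in (1, 2, 3)]
        for rep in reps:
            assert fa_log_prior(rep, single) == 0.0
        spans = {
            t: reps[0].ages[t] == reps[1].ages[t] == reps[2].ages[t]
            for t in single.taxa
            if single.candidates[t][0].older == single.candidates[t][0].younger
        }
        assert all(spans.values())

    def test_early_burst_with_equal_rates_matches_strict_dating(
        self, constant_rates
    ):
        rng = np.random.default_rng(30)
        taxa = ["A", "B", "C", "D"]
        cm = random_character_matrix(rng, taxa, 10, k=2)
        rep = _rep({"A": 460.0, "B": 458.0, "C": 461.0, "D": 455.0})
        a, b, c, d = (TreeNode(t) for t in taxa)
        tree = ModelTree(
            TreeNode(
                children=[
                    TreeNode(children=[a, b]),
                    TreeNode(children=[c, d]),
                ]
            )
        )
        strict = date_internal_nodes(
            tree, 470.0, rep, ClockModel.strict(0.03, 0.5),
            rates=constant_rates, cm=cm,
        )
        burst = date_internal_nodes(
            tree, 470.0, rep,
            ClockModel.early_burst(0.03, 0.03, tau=463.0, sigma=0.5),
            rates=constant_rates, cm=cm,
        )
        for ns, nb in zip(strict.postorder(), burst.postorder()):
            assert ns.age == nb.age


class TestCredibleInterval:
    def test_point_mass(self):
        surface = PosteriorSurface(
            "m", np.array([470.0, 471, 472]), np.array([-5.0, -500.0, -500.0])
        )
        assert credible_interval(surface) == (470.0, 470.0)

    def test_symmetric_two_point_tie_takes_single_point(self):
        surface = PosteriorSurface(
            "m", np.array([470.0, 471.0]), np.array([-2.0, -2.0 - 1e-6])
        )
        older, younger = credible_interval(surface, level=0.5)
        assert older == younger == 470.0

    def test_gaussian_surface_matches_cumulative_mass(self):
        ages = np.arange(460.0, 480.0, 0.5)
        ln = -0.5 * ((ages - 470.0) / 2.0) ** 2
        surface = PosteriorSurface("m", ages, ln)
        older, younger = credible_interval(surface, 0.95)
        probs = np.exp(ln - ln.max())
        probs /= probs.sum()
        order = np.argsort(-probs, kind="stable")
        mass, chosen = 0.0, []
        for i in order:
            chosen.append(i)
            mass += probs[i]
            if mass >= 0.95:
                break
        assert older == pytest.approx(ages[chosen].max())
        assert younger == pytest.approx(ages[chosen].min())
        assert younger <= 470.0 <= older

    def test_flat_surface_warns_full_window(self):
        surface = PosteriorSurface(
            "m", np.array([470.0, 471, 472]), np.full(3, -3.0)
        )
        with pytest.warns(UserWarning, match="flat"):
            older, younger = credible_interval(surface)
        assert (older, younger) == (472.0, 470.0)


class TestBayesFactor:
    def test_identical_surfaces_unity(self):
        s = PosteriorSurface("a", np.arange(3.0), np.array([-1.0, -2.0, -3.0]))
        t = PosteriorSurface("b", np.arange(3.0), np.array([-1.0, -2.0, -3.0]))
        assert bayes_factor(s, t) == pytest.approx(1.0)

    def test_uniform_log_offset(self):
        ages = np.arange(4.0)
        a = PosteriorSurface("a", ages, np.array([-1.0, -2.0, -0.5, -3.0]))
        b = PosteriorSurface("b", ages, a.ln_posterior - 1.0)
        assert bayes_factor(a, b) == pytest.approx(math.e)

    def test_closed_form_mass_ratio(self):
        ages = np.arange(3.0)
        a = PosteriorSurface("a", ages, np.log([0.2, 0.5, 0.3]))
        b = PosteriorSurface("b", ages, np.log([0.05, 0.1, 0.05]))
        assert bayes_factor(a, b) == pytest.approx(1.0 / 0.2)

    def test_mismatched_grids_error(self):
        a = PosteriorSurface("a", np.arange(3.0), np.zeros(3))
        b = PosteriorSurface("b", np.arange(4.0), np.zeros(4))
        with pytest.raises(ValidationError, match="same grid"):
            bayes_factor(a, b)

    def test_conditional_variant(self):
        ages = np.array([470.0, 475.0, 480.0])
        ref = PosteriorSurface("ref", ages, np.log([0.6, 0.3, 0.1]))
        bf = conditional_bayes_factor(ref, 470.0, 480.0)
        assert bf == pytest.approx(6.0)


class TestModelPosterior:
    def test_from_components_sums(self):
        p = ModelPosterior.from_components(
            "m", 470.0, lnp_fas=-10.0, lnl_alpha=-100.0, lnp_fbd=-5.0
        )
        assert p.ln_posterior == pytest.approx(-115.0)
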