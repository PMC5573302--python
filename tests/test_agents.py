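"""Agent semantics: action sets, site selection, phenotype application,
angiogenesis and initialisation."""

import numpy as np
import pytest

from oncolattice.actions import allowed_actions
from oncolattice.agents import (CellAgent, World, apply_phenotype,
                                candidate_condition, environmental_transitions,
                                initialize_world, select_target_site,
                                selection_probabilities, update_perfusion)
from oncolattice.config import load_config
from oncolattice.lattice import (ARTERIOLE, PARENT_ARTERY, PARENT_VEIN,
                                 VENULE, moore_neighbors)


def make_world(nx=7, seed=0, **overrides):
    cfg = load_config(None, {
        "geometry": {"nx": nx, "ny": nx, "nz": nx}, "seed": seed, **overrides})
    return initialize_world(cfg)


def empty_world(nx=7, seed=0):
    """A world with vessels and fields but no tissue cells."""
    return make_world(nx=nx, seed=seed, agents={"init_prob": 0.0})


class TestAllowedActions:
    @pytest.mark.parametrize("ctype,expected", [
        ("cancerous", {"hypoxia", "necrosis", "migration", "proliferation",
                       "quiescence"}),
        ("healthy", {"apoptosis", "migration", "proliferation", "quiescence"}),
        ("stalk", {"quiescence", "branch", "sprout"}),
        ("tip", {"quiescence", "branch", "expansion"}),
    ])
    def test_per_type_action_sets(self, ctype, expected):
        assert allowed_actions(ctype) == expected

    def test_healthy_cells_cannot_starve_actively(self):
        assert "necrosis" not in allowed_actions("healthy")
        assert "hypoxia" not in allowed_actions("healthy")

    def test_unknown_type_raises(self):
        with pytest.raises(ValueError):
            allowed_actions("osteoblast")


class TestSiteSelection:
    def test_flat_neighborhood_fails_condition(self):
        w = empty_world()
        w.fields["oxygen"].C[:] = 0.4
        w.fields["glucose"].C[:] = 0.4
        w.refresh_neighbor_stats()
        assert not candidate_condition((3, 3, 3), w, "cancerous")

    def test_condition_matches_direct_arithmetic(self):
        w = empty_world()
        w.fields["oxygen"].C[:] = 1.0
        w.fields["glucose"].C[:] = 0.0
        w.fields["oxygen"].C[2, 3, 3] = 10.0  # one hot neighbour
        w.refresh_neighbor_stats()
        vals = np.array([w.fields["oxygen"].C[q]
                         for q in moore_neighbors((3, 3, 3), w.lattice)])
        expected = vals.max() - vals.mean() > 3 * vals.std()
        assert candidate_condition((3, 3, 3), w, "cancerous") == expected
        assert expected  # the constructed outlier does trip the 3-sigma rule

    def test_vessel_cells_read_vegf_not_nutrients(self):
        w = empty_world()
        w.fields["oxygen"].C[2, 3, 3] = 50.0   # large oxygen outlier
        w.refresh_neighbor_stats()
        assert candidate_condition((3, 3, 3), w, "cancerous")
        assert not candidate_condition((3, 3, 3), w, "tip")
        w.fields["vegf"].C[2, 3, 3] = 1.0
        w.refresh_neighbor_stats()
        assert candidate_condition((3, 3, 3), w, "tip")

    def test_selection_probabilities_follow_weights(self):
        w = empty_world()
        # neighbourhood means around the two candidates in ratio 3:1
        w.fields["oxygen"].C[:] = 0.0
        w.fields["glucose"].C[:] = 0.0
        w.fields["oxygen"].C[0:3, 0:3, 0:3] = 3.0
        w.fields["oxygen"].C[4:7, 4:7, 4:7] = 1.0
        w.refresh_neighbor_stats()
        probs = selection_probabilities([(1, 1, 1), (5, 5, 5)], w, "cancerous")
        assert probs == pytest.approx([0.75, 0.25])
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_candidate_is_certain(self):
        w = empty_world()
        w.fields["oxygen"].C[:] = 0.3
        w.refresh_neighbor_stats()
        assert selection_probabilities([(2, 2, 2)], w, "healthy") == \
            pytest.approx([1.0])

    def test_permutation_equivariance(self):
        w = empty_world()
        w.fields["glucose"].C[1, 1, 1] = 2.0
        w.refresh_neighbor_stats()
        cands = [(1, 1, 1), (3, 3, 3), (5, 5, 5)]
        p1 = selection_probabilities(cands, w, "healthy")
        p2 = selection_probabilities(cands[::-1], w, "healthy")
        assert p1.tolist() == p2[::-1].tolist()

    def test_all_zero_weights_fall_back_to_uniform(self):
        w = empty_world()
        probs = selection_probabilities([(1, 1, 1), (2, 2, 2)], w, "tip")
        assert probs == pytest.approx([0.5, 0.5])


class TestApplyPhenotype:
    def test_apoptosis_frees_the_site(self):
        w = empty_world()
        a = w.spawn_tissue("healthy", (3, 3, 3))
        apply_phenotype(w, a, "apoptosis")
        assert w.lattice.occupant[3, 3, 3] == 0
        assert a.id not in w.lattice.index
        assert a.id not in w.agents

    def test_necrosis_marks_site_permanently(self):
        w = empty_world()
        a = w.spawn_tissue("cancerous", (3, 3, 3))
        apply_phenotype(w, a, "necrosis")
        assert not w.lattice.can_occupy((3, 3, 3), "cancerous")
        assert a.id not in w.agents

    def test_blocked_proliferation_becomes_absorbing_quiescence(self):
        w = empty_world()
        w.fields["oxygen"].C[:] = 1.0
        w.refresh_neighbor_stats()
        mother = w.spawn_tissue("cancerous", (3, 3, 3))
        for q in moore_neighbors((3, 3, 3), w.lattice):
            w.spawn_tissue("healthy", q)
        realised = apply_phenotype(w, mother, "proliferation")
        assert realised == "quiescence"
        assert mother.frozen

    def test_proliferation_places_one_daughter(self):
        w = empty_world()
        w.fields["oxygen"].C[:] = 1.0
        w.refresh_neighbor_stats()
        mother = w.spawn_tissue("healthy", (3, 3, 3))
        realised = apply_phenotype(w, mother, "proliferation")
        assert realised == "proliferation"
        assert mother.division_counter == 1
        assert len(w.live_tissue()) == 2
        daughter = [a for a in w.live_tissue() if a.id != mother.id][0]
        assert max(abs(a - b) for a, b in zip(daughter.site, mother.site)) == 1

    def test_low_oxygen_postpones_division(self):
        w = empty_world()
        w.fields["oxygen"].C[:] = 0.0
        w.refresh_neighbor_stats()
        mother = w.spawn_tissue("cancerous", (3, 3, 3))
        apply_phenotype(w, mother, "proliferation")
        assert mother.prolif_delay == 1.0
        assert len(w.live_tissue()) == 1

    def test_migration_moves_the_cell(self):
        w = empty_world()
        w.fields["oxygen"].C[:] = 0.5
        w.refresh_neighbor_stats()
        a = w.spawn_tissue("cancerous", (3, 3, 3))
        apply_phenotype(w, a, "migration")
        assert a.site != (3, 3, 3)
        assert w.lattice.index[a.id] == a.site

    def test_chosen_quiescence_is_absorbing_for_tissue(self):
        w = empty_world()
        a = w.spawn_tissue("healthy", (3, 3, 3))
        apply_phenotype(w, a, "quiescence")
        assert a.frozen

    def test_disallowed_action_raises(self):
        w = empty_world()
        a = w.spawn_tissue("healthy", (3, 3, 3))
        with pytest.raises(ValueError):
            apply_phenotype(w, a, "necrosis")

    def test_tip_expansion_leaves_stalk_behind(self):
        w = empty_world()
        w.fields["vegf"].C[:] = 0.2
        w.refresh_neighbor_stats()
        tip = w.spawn_endothelial("tip", (3, 3, 3), None, "artery", ARTERIOLE)
        age0 = tip.tip_age
        realised = apply_phenotype(w, tip, "expansion")
        assert realised == "expansion"
        assert tip.tip_age == age0 + 1.0
        assert tip.site != (3, 3, 3)
        stalks = [a for a in w.agents.values()
                  if a.ctype == "stalk" and a.site == (3, 3, 3)]
        assert len(stalks) == 1
        # lineage splice: tip's parent is the new stalk
        assert tip.parent == stalks[0].id

    def test_branch_delivers_two_offspring(self):
        w = empty_world()
        w.fields["vegf"].C[:] = 0.2
        w.refresh_neighbor_stats()
        tip = w.spawn_endothelial("tip", (3, 3, 3), None, "artery", ARTERIOLE)
        n0 = len(w.agents)
        assert apply_phenotype(w, tip, "branch") == "branch"
        assert len(w.agents) == n0 + 2

    def test_sprout_creates_a_tip_daughter(self):
        w = empty_world()
        w.fields["vegf"].C[:] = 0.2
        w.refresh_neighbor_stats()
        stalk = w.spawn_endothelial("stalk", (3, 3, 3), None, "vein",
                                    PARENT_VEIN)
        assert apply_phenotype(w, stalk, "sprout") == "sprout"
        tips = [a for a in w.agents.values() if a.ctype == "tip"]
        assert len(tips) == 1
        assert tips[0].parent == stalk.id
        assert tips[0].vclass == VENULE  # class inherited from the vein side


class TestPerfusion:
    def _chain(self, w, sites, side="artery"):
        parent = None
        agents = []
        for i, s in enumerate(sites):
            ct = "tip" if i == len(sites) - 1 else "stalk"
            a = w.spawn_endothelial(ct, s, parent, side, ARTERIOLE)
            parent = a.id
            agents.append(a)
        return agents

    def test_artery_to_vein_connection_perfuses_whole_path(self):
        w = empty_world(nx=9)
        # artery line sits at x = 4 (mid-face y = 0); grow a sprout from it
        # toward the vein edge at (0, 0)
        chain = self._chain(w, [(3, 1, 4), (2, 1, 4), (1, 1, 4)])
        update_perfusion(w)
        assert all(w.lattice.perfused[a.site] for a in chain)
        assert w.vessel_tree.perfused_ids >= {a.id for a in chain}

    def test_isolated_sprout_stays_unperfused(self):
        w = empty_world(nx=9)
        chain = self._chain(w, [(4, 4, 4), (5, 4, 4)])
        update_perfusion(w)
        assert not any(w.lattice.perfused[a.site] for a in chain)

    def test_removing_connecting_tip_reverts_perfusion(self):
        # graph-connectivity oracle: perfusion is exactly reachability
        w = empty_world(nx=9)
        chain = self._chain(w, [(3, 1, 4), (2, 1, 4), (1, 1, 4)])
        update_perfusion(w)
        assert w.lattice.perfused[chain[0].site]
        w.remove_agent(chain[-1].id)
        update_perfusion(w)
        assert not w.lattice.perfused[chain[0].site]
        assert not w.lattice.perfused[chain[1].site]


class TestEnvironmentalTransitions:
    def test_hypoxia_counter_tracks_oxygen_deprivation(self):
        w = empty_world()
        a = w.spawn_tissue("cancerous", (3, 3, 3))
        w.fields["oxygen"].C[:] = 0.0
        for _ in range(3):
            environmental_transitions(w)
        assert a.hypoxia_counter == 3.0
        w.fields["oxygen"].C[:] = 1.0
        environmental_transitions(w)
        assert a.hypoxia_counter == 0.0

    def test_prolonged_hypoxia_forces_necrosis_and_apoptosis(self):
        w = empty_world()
        c = w.spawn_tissue("cancerous", (3, 3, 3))
        h = w.spawn_tissue("healthy", (5, 5, 5))
        w.fields["oxygen"].C[:] = 0.0
        limit = w.config.agents.hypoxia_duration_limit
        for _ in range(int(limit) + 1):
            environmental_transitions(w)
        assert c.id not in w.agents
        assert h.id not in w.agents
        assert w.lattice.occupant[3, 3, 3] == 3   # necrotic debris
        assert w.lattice.occupant[5, 5, 5] == 0   # apoptosis frees the site

    def test_quiescent_cells_are_not_immune(self):
        w = empty_world()
        a = w.spawn_tissue("cancerous", (3, 3, 3))
        apply_phenotype(w, a, "quiescence")
        assert a.frozen
        w.fields["oxygen"].C[:] = 0.0
        for _ in range(int(w.config.agents.hypoxia_duration_limit) + 1):
            environmental_transitions(w)
        assert a.id not in w.agents


class TestInitializeWorld:
    def test_exactly_eight_parent_vessel_lines(self):
        w = make_world(nx=10, seed=3)
        art = (w.lattice.vessel == PARENT_ARTERY)
        vein = (w.lattice.vessel == PARENT_VEIN)
        # parent vessels are vertical lines: count distinct (x, y) columns
        assert art.any(axis=2).sum() == 4
        assert vein.any(axis=2).sum() == 4
        assert art.sum() == 4 * 10 and vein.sum() == 4 * 10
        assert w.lattice.perfused[art].all() and w.lattice.perfused[vein].all()

    def test_seed_sphere_occupancy_fraction(self):
        # Monte-Carlo frequency oracle over 40 seeds: the cancer seed sphere
        # fills at the configured 70% probability
        fracs = []
        for seed in range(40):
            w = make_world(nx=9, seed=seed)
            center = np.array([(d - 1) / 2 for d in w.lattice.dims])
            r = w.config.agents.seed_radius_um / w.config.geometry.ds_um
            n_in, n_occ = 0, 0
            for x in range(9):
                for y in range(9):
                    for z in range(9):
                        if np.linalg.norm(np.array([x, y, z]) - center) <= r:
                            if w.lattice.vessel[x, y, z] == 0:
                                n_in += 1
                                n_occ += int(w.lattice.occupant[x, y, z] == 2)
            fracs.append(n_occ / n_in)
        assert abs(np.mean(fracs) - 0.70) < 0.04

    def test_zero_probability_gives_vessels_only(self):
        w = empty_world()
        assert len(w.live_tissue()) == 0
        assert sum(a.ctype == "stalk" for a in w.agents.values()) > 0

    def test_nutrients_peak_at_parent_vessels(self):
        w = make_world(nx=11, seed=1)
        o2 = w.fields["oxygen"].C
        vessel_mean = o2[w.lattice.vessel > 0].mean()
        rest_mean = o2[w.lattice.vessel == 0].mean()
        assert vessel_mean > rest_mean
        for sp in ("vegf", "tgf_alpha", "tnf_alpha"):
            assert w.fields[sp].total() == 0.0

    def test_initialization_is_seed_reproducible(self):
        w1 = make_world(nx=8, seed=11)
        w2 = make_world(nx=8, seed=11)
        assert (w1.lattice.occupant == w2.lattice.occupant).all()
        w3 = make_world(nx=8, seed=12)
        assert (w1.lattice.occupant != w3.lattice.occupant).any()
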