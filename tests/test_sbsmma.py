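"""Mode–residue couplings, free energies, responses and modulation measures."""

import numpy as np
import pytest

from allomap import (
    DOWN,
    UP,
    ModeSet,
    Perturbation,
    ResidueId,
    RunConfig,
    Site,
    allosteric_response,
    build_network,
    free_energy_profile,
    hessian,
    mode_couplings,
    modulation_range,
    normal_modes,
    response_profile,
    site_signal,
)
from allomap.sbsmma import CouplingMatrix, pair_modes, unperturbed_state
from allomap.structures import CaResidue, CaStructure


def _two_node():
    residues = [
        CaResidue(ResidueId("A", 1), "ALA", (0.0, 0.0, 0.0)),
        CaResidue(ResidueId("A", 2), "ALA", (5.0, 0.0, 0.0)),
    ]
    return CaStructure(residues, source="two-node")


class TestModeCouplings:
    def test_pure_translation_mode_couples_to_nothing(self, coil30):
        net = build_network(coil30)
        n = len(coil30)
        v = np.zeros((1, 3 * n))
        v[0, 0::3] = 1.0 / np.sqrt(n)
        modes = ModeSet(eigenvalues=np.array([1.0]), vectors=v, n_rigid=0)
        c = mode_couplings(modes, net)
        assert np.abs(c.eps).max() == 0.0

    def test_two_node_stretch_mode_coupling_is_two(self):
        net = build_network(_two_node(), cutoff=10)
        modes = normal_modes(hessian(net), n_modes=1)
        c = mode_couplings(modes, net)
        # e = (x̂, −x̂)/√2 → |e_1 − e_2|² = 2 for each node
        assert np.allclose(c.eps, 2.0)

    @pytest.mark.parametrize("neighbors", [True, False])
    def test_matches_independent_double_loop(self, coil30, neighbors):
        net = build_network(coil30)
        modes = normal_modes(hessian(net), n_modes=10)
        c = mode_couplings(modes, net, neighbors=neighbors)
        e = modes.vectors3
        nbrs = net.neighbor_lists()
        n = len(coil30)
        expected = np.zeros((10, n))
        for mu in range(10):
            for i in range(n):
                js = nbrs[i] if neighbors else [j for j in range(n) if j != i]
                expected[mu, i] = sum(
                    float(np.sum((e[mu, i] - e[mu, j]) ** 2)) for j in js
                )
        assert np.allclose(c.eps, expected, atol=1e-12)

    def test_residue_count_mismatch_rejected(self, coil30, coil20):
        net = build_network(coil30)
        modes = normal_modes(hessian(build_network(coil20)), n_modes=10)
        with pytest.raises(ValueError, match="residues"):
            mode_couplings(modes, net)


class TestFreeEnergyProfile:
    def test_unit_couplings_give_zero(self, coil30):
        c = CouplingMatrix(eps=np.ones((10, len(coil30))), structure=coil30)
        assert np.allclose(free_energy_profile(c), 0.0)

    def test_single_mode_closed_form(self, coil30):
        c = CouplingMatrix(eps=np.full((1, len(coil30)), np.e ** 2), structure=coil30)
        assert np.allclose(free_energy_profile(c), 1.0)

    def test_equals_half_sum_of_logs(self, coil30, rng):
        eps = rng.uniform(0.1, 5.0, size=(5, len(coil30)))
        c = CouplingMatrix(eps=eps, structure=coil30)
        assert np.allclose(free_energy_profile(c), 0.5 * np.log(eps).sum(axis=0))

    def test_zero_coupling_clamped_not_infinite(self, coil30):
        eps = np.ones((3, len(coil30)))
        eps[0, 0] = 0.0
        c = CouplingMatrix(eps=eps, structure=coil30)
        g = free_energy_profile(c)
        assert np.all(np.isfinite(g))


class TestResponseProfile:
    def test_identity_perturbation_gives_exact_zero(self, coil30, config):
        profile = allosteric_response(coil30, Perturbation(), config)
        assert np.all(profile.dg == 0.0)
        assert np.all(profile.dh == 0.0)

    def test_chain_mean_of_dh_is_zero(self, coil30, config):
        rid = coil30.residue_ids[4]
        profile = allosteric_response(coil30, Perturbation.mutation(rid, UP, 2.0), config)
        assert abs(profile.dh.mean()) < 1e-10

    def test_mode_count_mismatch_rejected(self, coil30):
        c5 = CouplingMatrix(eps=np.ones((5, len(coil30))), structure=coil30)
        c6 = CouplingMatrix(eps=np.ones((6, len(coil30))), structure=coil30)
        with pytest.raises(ValueError, match="mismatch"):
            response_profile(c5, c6)

    def test_equals_independent_recomputation(self, dumbbell60, config):
        rid = dumbbell60.residue_ids[10]  # lobe A
        p = Perturbation.mutation(rid, UP, config.theta_up)
        profile = allosteric_response(dumbbell60, p, config)
        # from-scratch rerun: fresh network, fresh eigendecompositions
        from allomap import perturb_network

        net0 = build_network(dumbbell60, cutoff=config.cutoff_A, k=config.k)
        m0 = normal_modes(hessian(net0), n_modes=config.n_modes)
        netP = perturb_network(net0, p, site_pairs=config.site_pairs)
        mP = normal_modes(hessian(netP), n_modes=config.n_modes)
        c0 = mode_couplings(m0, net0)
        cP = mode_couplings(mP, netP)
        dg = 0.5 * np.sum(np.log(np.maximum(cP.eps, 1e-12) / np.maximum(c0.eps, 1e-12)), axis=0)
        assert np.allclose(profile.dg, dg, atol=1e-12)
        assert np.allclose(profile.dh, dg - dg.mean(), atol=1e-12)

    def test_spring_scale_invariance(self, coil30):
        rid = coil30.residue_ids[8]
        p = Perturbation.mutation(rid, UP, 2.0)
        dh1 = allosteric_response(coil30, p, RunConfig(k=1.0)).dh
        dh10 = allosteric_response(coil30, p, RunConfig(k=10.0)).dh
        assert np.abs(dh1 - dh10).max() < 1e-8

    def test_per_chain_centering(self, sym_dimer30):
        config = RunConfig(center="per_chain")
        rid = sym_dimer30.residue_ids[3]
        profile = allosteric_response(sym_dimer30, Perturbation.mutation(rid, UP, 2.0), config)
        for chain in sym_dimer30.chains:
            idx = sym_dimer30.chain_indices(chain)
            assert abs(profile.dh[idx].mean()) < 1e-10

    def test_sym_dimer_equivariance(self, sym_dimer30, config):
        half = len(sym_dimer30) // 2
        rid_a = sym_dimer30.residue_ids[3]
        rid_b = sym_dimer30.residue_ids[3 + half]
        dh_a = allosteric_response(
            sym_dimer30, Perturbation.mutation(rid_a, UP, 2.0), config
        ).dh
        dh_b = allosteric_response(
            sym_dimer30, Perturbation.mutation(rid_b, UP, 2.0), config
        ).dh
        swapped = np.concatenate([dh_b[half:], dh_b[:half]])
        assert np.abs(dh_a - swapped).max() < 1e-6

    def test_tsv_and_json_writers(self, coil30, config, tmp_path):
        rid = coil30.residue_ids[0]
        profile = allosteric_response(coil30, Perturbation.mutation(rid, UP, 2.0), config)
        out = tmp_path / "profile.tsv"
        profile.to_tsv(out)
        header = out.read_text().splitlines()[0].split("\t")
        assert header == ["residue_id", "chain", "resseq", "dg_kbt", "dh_kbt"]
        d = profile.to_json_dict()
        assert d["perturbation"]["mutations"][0]["residue"] == "A.1"
        assert len(d["dh_kbt"]) == len(coil30)


class TestModulationRange:
    def _profiles(self, structure, rid, config):
        up = allosteric_response(structure, Perturbation.mutation(rid, UP, config.theta_up), config)
        down = allosteric_response(
            structure, Perturbation.mutation(rid, DOWN, config.theta_down), config
        )
        return up, down

    def test_equal_profiles_cancel(self, helix20, config):
        up, _ = self._profiles(helix20, helix20.residue_ids[9], config)
        assert np.allclose(modulation_range(up, up.__class__(
            dg=up.dg, dh=up.dh, structure=up.structure, perturbation=up.perturbation
        )), 0.0)

    def test_elementwise_subtraction(self, helix20, config):
        up, down = self._profiles(helix20, helix20.residue_ids[9], config)
        assert np.array_equal(modulation_range(up, down), up.dh - down.dh)

    def test_profiles_of_different_residues_rejected(self, helix20, config):
        up, _ = self._profiles(helix20, helix20.residue_ids[9], config)
        _, down = self._profiles(helix20, helix20.residue_ids[3], config)
        with pytest.raises(ValueError, match="same residue"):
            modulation_range(up, down)

    def test_linearity_chain(self, helix20, config):
        rid = helix20.residue_ids[9]
        a = allosteric_response(helix20, Perturbation.mutation(rid, UP, 3.0), config)
        b = allosteric_response(helix20, Perturbation.mutation(rid, UP, 2.0), config)
        c = allosteric_response(helix20, Perturbation.mutation(rid, DOWN, 0.5), config)
        ab = a.dh - b.dh
        bc = b.dh - c.dh
        ac = a.dh - c.dh
        assert np.allclose(ab + bc, ac, atol=1e-12)


class TestSiteSignal:
    def test_single_residue_site(self, coil30, config):
        rid = coil30.residue_ids[2]
        profile = allosteric_response(coil30, Perturbation.mutation(rid, UP, 2.0), config)
        site = Site(label="one", members=frozenset([coil30.residue_ids[20]]))
        assert site_signal(profile, site) == pytest.approx(profile.dh[20])

    def test_whole_chain_site_is_zero(self, coil30, config):
        rid = coil30.residue_ids[2]
        profile = allosteric_response(coil30, Perturbation.mutation(rid, UP, 2.0), config)
        site = Site(label="all", members=frozenset(coil30.residue_ids))
        assert site_signal(profile, site) == pytest.approx(0.0, abs=1e-10)

    def test_mean_over_members(self, dumbbell60, config):
        rid = dumbbell60.residue_ids[5]
        profile = allosteric_response(dumbbell60, Perturbation.mutation(rid, UP, 2.0), config)
        members = dumbbell60.residue_ids[40:44]
        site = Site(label="four", members=frozenset(members))
        expected = np.mean([profile.dh[dumbbell60.index(r)] for r in members])
        assert site_signal(profile, site) == pytest.approx(expected)

    def test_foreign_site_rejected(self, coil30, config):
        profile = allosteric_response(coil30, Perturbation(), config)
        with pytest.raises(KeyError):
            site_signal(profile, Site(label="x", members=frozenset([ResidueId("Z", 1)])))


class TestModeMatching:
    def test_rank_pairing_is_identity(self, coil30, config):
        state = unperturbed_state(coil30, config)
        assert np.array_equal(pair_modes(state.modes, state.modes), np.arange(10))

    def test_overlap_pairing_recovers_permutation(self, coil30, config):
        state = unperturbed_state(coil30, config)
        perm = np.array([2, 0, 1, 3, 4, 5, 6, 7, 8, 9])
        shuffled = ModeSet(
            eigenvalues=state.modes.eigenvalues[perm],
            vectors=state.modes.vectors[perm],
            n_rigid=6,
        )
        matched = pair_modes(state.modes, shuffled, method="overlap")
        assert np.array_equal(perm[matched], np.arange(10))

    def test_overlap_matching_runs_through_pipeline(self, coil30):
        config = RunConfig(mode_matching="overlap")
        rid = coil30.residue_ids[10]
        profile = allosteric_response(coil30, Perturbation.mutation(rid, UP, 2.0), config)
        assert np.all(np.isfinite(profile.dh))
        assert abs(profile.dh.mean()) < 1e-10
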