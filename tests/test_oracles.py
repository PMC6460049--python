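import numpy as np
import pytest

from nksig.engine import Model, ReactionSpec, SpeciesSpec
from nksig.lattice import LatticeGeometry, build_lattice
from nksig.oracles import (
    OracleReport,
    StateSpaceTooLarge,
    binding_occupancy_scan,
    collapse_to_well_mixed,
    empirical_state_distribution,
    master_equation_oracle,
    msd_diffusion_check,
    total_variation,
    well_mixed_ode,
)
from nksig.units import bimolecular_to_stochastic, kd_to_rate_pair, um3_to_litres


def _one_chamber_binding(n_r, n_l, kon, koff, edge=0.02):
    lat = build_lattice(LatticeGeometry(edge, edge, edge))
    species = [SpeciesSpec("R"), SpeciesSpec("L"), SpeciesSpec("C")]
    rx = [ReactionSpec("bind", (("R", 1), ("L", 1)), (("C", 1),), rate=kon),
          ReactionSpec("unbind", (("C", 1),), (("R", 1), ("L", 1)), rate=koff)]
    init = np.zeros((1, 3), dtype=np.int64)
    init[0, 0], init[0, 1] = n_r, n_l
    return Model(lattice=lat, species=species, reactions=rx, initial_counts=init)


class TestWellMixedOde:
    def test_occupancy_half_at_kd_with_ligand_excess(self):
        # ligand dosed at K_D in a 1 um^3 chamber, 40-fold receptor excess
        from nksig.units import concentration_to_count
        kd, kon = 0.8, 1.0
        v = um3_to_litres(1.0)
        n_l = concentration_to_count(kd, v)
        m = _one_chamber_binding(n_l // 40, n_l, kon, kd * kon, edge=1.0)
        ss = well_mixed_ode(m)
        occ = ss["C"] / (ss["C"] + ss["R"])
        assert occ == pytest.approx(0.5, abs=0.02)

    def test_activating_cascade_fixed_point(self, desk_params):
        """Activating-arm-only steady state agrees with an independently
        iterated fixed point of the push-pull cascade."""
        from nksig.model import PeptideDose, Variant, build_model
        model = build_model(Variant.MODEL2, PeptideDose.single(0.0),
                            params=desk_params.values, seed=0)
        wm = collapse_to_well_mixed(model)
        ss = well_mixed_ode(wm, t_end=20_000.0)
        # independent fixed point: iterate species-wise equilibria
        from nksig.engine import CompiledModel
        cm = CompiledModel(wm)
        names = cm.names
        y = cm.initial_counts()[0].astype(float)
        rx = {r.name: (cm.r_rate[i], i) for i, r in enumerate(wm.reactions)}
        p = desk_params
        v = um3_to_litres(wm.lattice.geometry.chamber_edge_um ** 3)
        b = lambda key: bimolecular_to_stochastic(p.get(key), v)
        AR_tot, L_tot = y[names.index("AR")], y[names.index("LIG_ACT")]
        SFK_tot = y[names.index("SFK")] + y[names.index("SFK_cl")]
        ZAP_tot, VAV_tot = y[names.index("ZAP70")], y[names.index("pVAV1")] + y[names.index("VAV1")]
        kon, koff = b("binding.activating.kon_per_uM_s"), p.get("binding.activating.KR_uM") * p.get("binding.activating.kon_per_uM_s")
        kp = b("rates.sfk_itam_phos_per_uM_s") * SFK_tot
        bd = p.get("rates.basal_itam_dephos_per_s")
        zon, zoff = b("rates.zap70_on_per_uM_s"), p.get("rates.zap70_off_per_s")
        vp, bpv = b("rates.vav1_phos_per_uM_s"), p.get("rates.basal_pvav1_decay_per_s")
        ARL = pbound = Z = 0.0
        for _ in range(500):
            ARL = AR_tot * kon * (L_tot - ARL) / (kon * (L_tot - ARL) + koff)
            pfrac = kp / (kp + bd)
            pbound_sites = ARL * pfrac
            Zfree = ZAP_tot - Z
            Z = pbound_sites * zon * Zfree / (zon * Zfree + zoff)
        a = vp * Z
        pv = VAV_tot * a / (a + bpv)
        assert ss["pVAV1"] == pytest.approx(pv, rel=0.15)

    def test_multichamber_model_rejected(self, desk_params):
        from nksig.model import PeptideDose, Variant, build_model
        model = build_model(Variant.MODEL2, PeptideDose.single(0.0),
                            params=desk_params.values)
        with pytest.raises(ValueError):
            well_mixed_ode(model)


class TestMasterEquation:
    def test_one_molecule_uniform_over_chambers(self):
        lat = build_lattice(LatticeGeometry(0.04, 0.02, 0.02))
        init = np.zeros((4, 1), dtype=np.int64)
        init[2, 0] = 1
        m = Model(lattice=lat, species=[SpeciesSpec("X", diffusion_um2_s=0.01)],
                  reactions=[], initial_counts=init)
        dist, _ = master_equation_oracle(m)
        assert len(dist) == 4
        for pv in dist.values():
            assert pv == pytest.approx(0.25, abs=1e-9)

    def test_two_state_binding_detailed_balance(self):
        m = _one_chamber_binding(1, 1, kon=0.001, koff=1.0)
        dist, _ = master_equation_oracle(m)
        ks = bimolecular_to_stochastic(0.001, um3_to_litres(0.02**3))
        odds = ks / 1.0
        bound = {k: v for k, v in dist.items() if k[2] == 1}
        unbound = {k: v for k, v in dist.items() if k[2] == 0}
        assert sum(bound.values()) / sum(unbound.values()) == pytest.approx(odds, rel=1e-6)

    def test_state_space_guard(self):
        m = _one_chamber_binding(40, 40, kon=0.001, koff=1.0)
        with pytest.raises(StateSpaceTooLarge):
            master_equation_oracle(m, max_states=10)


class TestDiffusionAndBinding:
    def test_immobile_species_has_zero_msd(self):
        assert msd_diffusion_check(0.0) == 0.0

    def test_msd_recovers_membrane_coefficient_coarsely(self):
        d = msd_diffusion_check(0.01, n_traj=300, horizon_s=2.0, seed=11)
        assert d == pytest.approx(0.01, rel=0.2)

    def test_very_tight_binder_saturates(self):
        bp = kd_to_rate_pair(0.01, 1.0)
        _, occ = binding_occupancy_scan(bp, doses_uM=np.array([0.5, 1.0, 2.0]),
                                        seed=5, replicates=2, t_end=300.0)
        assert (occ > 0.95).all()

    def test_insufficient_ligand_excess_rejected(self):
        bp = kd_to_rate_pair(0.8, 1.0)
        with pytest.raises(ValueError):
            binding_occupancy_scan(bp, doses_uM=np.array([0.001]), n_receptor=50)


def test_oracle_report_thresholding():
    r = OracleReport.make("demo", statistic=0.05, threshold=0.1, inputs=(1, 2))
    assert r.passed
    r2 = OracleReport.make("demo", statistic=0.2, threshold=0.1, inputs=(1, 2))
    assert not r2.passed


def test_total_variation_bounds():
    p = {"a": 0.5, "b": 0.5}
    q = {"a": 1.0}
    assert total_variation(p, p) == 0.0
    assert total_variation(p, q) == pytest.approx(0.5)
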