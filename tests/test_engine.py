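import numpy as np
import pytest

from nksig.engine import (
    ChamberState,
    CompiledModel,
    InvariantViolation,
    Model,
    ReactionSpec,
    SpeciesSpec,
    propensity,
    reference_simulate,
    simulate,
    ssa_step,
)
from nksig.lattice import LatticeGeometry, build_lattice
from nksig.oracles import well_mixed_ode
from nksig.units import bimolecular_to_stochastic, um3_to_litres


def _one_chamber(edge=0.02):
    return build_lattice(LatticeGeometry(edge, edge, edge))


def _binding_model(n_a=50, n_b=60, kon=1.0, koff=5.0, edge=0.02):
    lat = _one_chamber(edge)
    species = [SpeciesSpec("A"), SpeciesSpec("B"), SpeciesSpec("C")]
    rx = [ReactionSpec("bind", (("A", 1), ("B", 1)), (("C", 1),), rate=kon),
          ReactionSpec("unbind", (("C", 1),), (("A", 1), ("B", 1)), rate=koff)]
    init = np.zeros((1, 3), dtype=np.int64)
    init[0, 0], init[0, 1] = n_a, n_b
    return Model(lattice=lat, species=species, reactions=rx, initial_counts=init)


class TestPropensity:
    def test_unimolecular_scales_linearly(self):
        rx = ReactionSpec("d", (("A", 1),), (("B", 1),), rate=0.8)
        assert propensity([10, 0], rx, 0.8, ["A", "B"]) == pytest.approx(8.0)

    def test_bimolecular_pair_count(self):
        # 1 uM^-1 s^-1 converted at the 0.02 um chamber volume
        k = bimolecular_to_stochastic(1.0, um3_to_litres(0.02**3))
        rx = ReactionSpec("b", (("A", 1), ("B", 1)), (("C", 1),), rate=1.0)
        assert propensity([2, 3, 0], rx, k, ["A", "B", "C"]) == pytest.approx(1245.6, rel=1e-3)

    def test_homodimeric_uses_n_choose_2(self):
        rx = ReactionSpec("dim", (("A", 2),), (("B", 1),), rate=1.0)
        assert propensity([4, 0], rx, 2.0, ["A", "B"]) == pytest.approx(2.0 * 6)

    def test_zero_when_any_reactant_absent(self):
        rx = ReactionSpec("b", (("A", 1), ("B", 1)), (("C", 1),), rate=1.0)
        assert propensity([5, 0, 0], rx, 10.0, ["A", "B", "C"]) == 0.0

    def test_negative_counts_signal_engine_bug(self):
        rx = ReactionSpec("d", (("A", 1),), (("B", 1),), rate=1.0)
        with pytest.raises(InvariantViolation):
            propensity([-1, 0], rx, 1.0, ["A", "B"])


class TestReactionSpecValidation:
    def test_termolecular_rejected(self):
        with pytest.raises(ValueError):
            ReactionSpec("bad", (("A", 2), ("B", 1)), (("C", 1),), rate=1.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            ReactionSpec("bad", (("A", 1),), (("B", 1),), rate=-1.0)

    def test_neighbor_locality_requires_catalytic_enzyme(self):
        from nksig.engine import Locality
        with pytest.raises(ValueError):
            ReactionSpec("bad", (("E", 1), ("S", 1)), (("P", 1),), rate=1.0,
                         locality=Locality.NEIGHBOR_CHAMBER)


class TestSsaStep:
    def test_single_decay_then_absorbing(self):
        lat = _one_chamber()
        m = Model(lattice=lat, species=[SpeciesSpec("A")],
                  reactions=[ReactionSpec("decay", (("A", 1),), (), rate=2.0)],
                  initial_counts=np.array([[1]], dtype=np.int64))
        cm = CompiledModel(m)
        rng = np.random.default_rng(0)
        state = ChamberState(counts=cm.initial_counts())
        state, dt, absorbing = ssa_step(state, cm, rng)
        assert not absorbing and dt > 0
        assert state.counts[0, 0] == 0
        _, dt2, absorbing2 = ssa_step(state, cm, rng)
        assert absorbing2 and dt2 == 0.0

    def test_decay_waiting_time_is_exponential(self):
        lat = _one_chamber()
        m = Model(lattice=lat, species=[SpeciesSpec("A")],
                  reactions=[ReactionSpec("decay", (("A", 1),), (), rate=2.0)],
                  initial_counts=np.array([[1]], dtype=np.int64))
        cm = CompiledModel(m)
        rng = np.random.default_rng(42)
        waits = []
        for _ in range(2000):
            state = ChamberState(counts=cm.initial_counts())
            _, dt, _ = ssa_step(state, cm, rng)
            waits.append(dt)
        assert np.mean(waits) == pytest.approx(0.5, rel=0.1)


class TestSimulate:
    def test_empty_reaction_set_conserves_totals(self):
        lat = build_lattice(LatticeGeometry(0.08, 0.02, 0.02))
        init = np.full((lat.n_chambers, 1), 3, dtype=np.int64)
        m = Model(lattice=lat, species=[SpeciesSpec("X", diffusion_um2_s=0.01)],
                  reactions=[], initial_counts=init)
        traj = simulate(m, t_end=20.0, sample_interval=1.0, seed=4)
        assert (traj.totals[:, 0] == init.sum()).all()

    def test_seed_determinism_and_sensitivity(self):
        m = _binding_model()
        a = simulate(m, 30.0, 0.5, seed=9)
        b = simulate(m, 30.0, 0.5, seed=9)
        c = simulate(m, 30.0, 0.5, seed=10)
        assert np.array_equal(a.totals, b.totals)
        assert not np.array_equal(a.totals, c.totals)

    def test_absorbing_run_fills_remaining_samples(self):
        lat = _one_chamber()
        m = Model(lattice=lat, species=[SpeciesSpec("A")],
                  reactions=[ReactionSpec("decay", (("A", 1),), (), rate=5.0)],
                  initial_counts=np.array([[3]], dtype=np.int64))
        traj = simulate(m, t_end=50.0, sample_interval=1.0, seed=1)
        assert traj.absorbed
        assert traj.totals[-1, 0] == 0
        assert (np.diff(traj.totals[:, 0]) <= 0).all()

    def test_diffusion_stationary_distribution_uniform(self):
        # single tracer on a 2x2 periodic lattice: occupancy ~ uniform
        from nksig.lattice import Boundary
        lat = build_lattice(LatticeGeometry(0.04, 0.02, 0.02,
                                            boundary=Boundary.PERIODIC))
        init = np.zeros((4, 1), dtype=np.int64)
        init[0, 0] = 1
        m = Model(lattice=lat, species=[SpeciesSpec("X", diffusion_um2_s=0.01)],
                  reactions=[], initial_counts=init)
        traj = simulate(m, t_end=12_000.0, sample_interval=1.0, seed=3,
                        record_chambers=True)
        occ = traj.chamber_samples[200:, :, 0].mean(axis=0)
        from scipy.stats import chisquare
        counts = traj.chamber_samples[200:, :, 0].sum(axis=0)
        assert chisquare(counts).pvalue > 0.01
        assert occ.sum() == pytest.approx(1.0)

    def test_reversible_binding_matches_ode_oracle(self):
        m = _binding_model(n_a=200, n_b=260, kon=0.02, koff=5.0)
        ode = well_mixed_ode(m)
        runs = [simulate(m, 60.0, 0.5, seed=s).total("C")[40:].mean()
                for s in range(5)]
        se = np.std(runs, ddof=1) / np.sqrt(len(runs))
        assert abs(np.mean(runs) - ode["C"]) < 3 * max(se, 0.5)

    def test_tree_and_reference_samplers_agree_in_law(self):
        m = _binding_model(n_a=2, n_b=2, kon=0.005, koff=2.0)
        t_fast = simulate(m, 4000.0, 0.25, seed=21)
        t_ref = reference_simulate(m, 400.0, 0.25, seed=22)
        # stationary occupancy of the complex from both samplers
        f_fast = t_fast.total("C")[20:].mean()
        f_ref = t_ref.total("C")[20:].mean()
        assert f_fast == pytest.approx(f_ref, abs=0.1)

    def test_invalid_arguments_rejected(self):
        m = _binding_model()
        with pytest.raises(ValueError):
            simulate(m, t_end=0.0)
        with pytest.raises(ValueError):
            simulate(m, t_end=10.0, sample_interval=0.0)


class TestTrajectoryIO:
    def test_tidy_writer_columns(self, tmp_path):
        m = _binding_model()
        m.metadata = {"variant": "model2", "mode": "single",
                      "dose_L7R_uM": 12.5, "dose_L7D_uM": 0.0}
        traj = simulate(m, 5.0, 1.0, seed=0)
        path = tmp_path / "traj.csv"
        traj.write_csv(path)
        import pandas as pd
        df = pd.read_csv(path)
        for col in ("time_s", "species_state", "total_count", "seed",
                    "variant", "mode", "dose_L7R_uM", "dose_L7D_uM"):
            assert col in df.columns
        assert set(df["species_state"]) == {"A", "B", "C"}

    def test_chamber_snapshot_frame(self):
        from nksig.engine import chamber_snapshot_frame
        m = _binding_model()
        df = chamber_snapshot_frame(m, m.initial_counts, 0.0)
        assert list(df.columns) == ["chamber_i", "chamber_j", "species_state",
                                    "count", "time_s"]
        assert df["count"].sum() == 110
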