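"""Independent oracles that certify the stochastic engine.

Each oracle avoids the engine's propensity/stepping code on purpose: the
well-mixed oracle integrates mass-action rate equations with scipy, the
master-equation oracle enumerates the reachable state space and solves
the stationary linear system directly, the diffusion check estimates D
from mean-squared displacement of a tracer, and the binding scan fits a
hyperbolic occupancy curve to a titration.  Agreement with the engine is
evidence, not tautology.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

from .engine import (
    TYPE_BI,
    TYPE_HOMO,
    TYPE_TRANS,
    TYPE_UNI,
    CompiledModel,
    Model,
    ReactionSpec,
    SpeciesSpec,
    simulate,
)
from .lattice import Boundary, LatticeGeometry, build_lattice, diffusion_hop_rate
from .units import BindingParams, concentration_to_count, um3_to_litres


@dataclass(frozen=True)
class OracleReport:
    """Outcome of one oracle comparison; thresholds live in the test suite."""

    oracle: str
    statistic: float
    threshold: float
    passed: bool
    inputs_hash: str

    @staticmethod
    def make(oracle: str, statistic: float, threshold: float, inputs) -> "OracleReport":
        h = hashlib.sha256(repr(inputs).encode()).hexdigest()[:12]
        return OracleReport(oracle=oracle, statistic=float(statistic),
                            threshold=float(threshold),
                            passed=bool(statistic < threshold), inputs_hash=h)


# ---------------------------------------------------------------------------
# well-mixed mass-action ODE
# ---------------------------------------------------------------------------

def collapse_to_well_mixed(model: Model) -> Model:
    """Collapse a lattice model to a single cubic chamber of the full box
    volume (same species, reactions and totals; spatial structure erased)."""
    g = model.lattice.geometry
    v_box_um3 = g.box_edge_um**2 * g.box_thickness_um
    edge = v_box_um3 ** (1.0 / 3.0)
    lat = build_lattice(LatticeGeometry(box_edge_um=edge, box_thickness_um=edge,
                                        chamber_edge_um=edge))
    totals = model.initial_counts.sum(axis=0, keepdims=True).astype(np.int64)
    return Model(lattice=lat, species=list(model.species),
                 reactions=list(model.reactions), initial_counts=totals,
                 confinement={}, trans_radius=model.trans_radius,
                 metadata=dict(model.metadata), observables=dict(model.observables))


def well_mixed_ode(model: Model | CompiledModel, t_end: float = 3000.0,
                   rtol: float = 1e-8, atol: float = 1e-8) -> dict[str, float]:
    """Deterministic steady state of the mass-action system in count units.

    The model must be single-chamber (collapse it first); the rate
    equations are assembled here from the reaction list, independently of
    the SSA propensity code.
    """
    cm = model if isinstance(model, CompiledModel) else CompiledModel(model)
    if cm.C != 1:
        raise ValueError("collapse the model to one chamber first")
    R, S = cm.R, cm.S
    y0 = cm.initial_counts()[0].astype(float)

    r_rate = cm.r_rate
    r_type = cm.r_type
    r_s1, r_s2 = cm.r_s1, cm.r_s2
    r_nch, r_chsp, r_chd = cm.r_nch, cm.r_chsp, cm.r_chd

    def rhs(_t, y):
        dy = np.zeros(S)
        for r in range(R):
            t = r_type[r]
            if t == TYPE_UNI:
                flux = r_rate[r] * y[r_s1[r]]
            elif t == TYPE_HOMO:
                flux = r_rate[r] * y[r_s1[r]] * y[r_s1[r]] * 0.5
            else:  # bi and trans coincide in a single chamber
                flux = r_rate[r] * y[r_s1[r]] * y[r_s2[r]]
            for m in range(r_nch[r]):
                dy[r_chsp[r, m]] += r_chd[r, m] * flux
        return dy

    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return dict(zip(cm.names, sol.y[:, -1]))


# ---------------------------------------------------------------------------
# exact stationary distribution for tiny models
# ---------------------------------------------------------------------------

class StateSpaceTooLarge(ValueError):
    pass


def _transition_list(cm: CompiledModel, counts: np.ndarray):
    """(rate, new_state) pairs out of a state; formulas written out here,
    independent of the kernel."""
    C, S = counts.shape
    out = []
    for c in range(C):
        for r in range(cm.R):
            t = cm.r_type[r]
            n1 = counts[c, cm.r_s1[r]]
            if t == TYPE_UNI:
                a = cm.r_rate[r] * n1
            elif t == TYPE_BI:
                a = cm.r_rate[r] * n1 * counts[c, cm.r_s2[r]]
            elif t == TYPE_HOMO:
                a = cm.r_rate[r] * n1 * (n1 - 1) / 2.0
            else:  # TYPE_TRANS: target here or in a lateral neighbour
                targets = [(c, counts[c, cm.r_s2[r]])]
                for m in range(cm.n_neighbors[c]):
                    b = cm.neighbors[c, m]
                    targets.append((b, counts[b, cm.r_s2[r]]))
                for b, nt in targets:
                    if nt <= 0 or n1 <= 0:
                        continue
                    a = cm.r_rate[r] * n1 * nt
                    new = counts.copy()
                    for m in range(cm.r_nch[r]):
                        new[b, cm.r_chsp[r, m]] += cm.r_chd[r, m]
                    out.append((a, new))
                continue
            if a <= 0:
                continue
            new = counts.copy()
            for m in range(cm.r_nch[r]):
                new[c, cm.r_chsp[r, m]] += cm.r_chd[r, m]
            out.append((a, new))
        for s in range(S):
            if counts[c, s] <= 0 or cm.hop_rate[s] <= 0:
                continue
            for m in range(cm.n_neighbors[c]):
                b = cm.neighbors[c, m]
                if not cm.mask[s, b]:
                    continue
                new = counts.copy()
                new[c, s] -= 1
                new[b, s] += 1
                out.append((cm.hop_rate[s], new))
    return out


def master_equation_oracle(model: Model | CompiledModel,
                           max_states: int = 10_000):
    """Exact stationary distribution of a tiny model by enumerating the
    reachable state space and solving pi Q = 0.

    Returns (distribution, index) where ``distribution`` maps flattened
    count tuples to stationary probabilities.
    """
    cm = model if isinstance(model, CompiledModel) else CompiledModel(model)
    init = cm.initial_counts()
    key = lambda arr: tuple(arr.reshape(-1))
    index: dict[tuple, int] = {key(init): 0}
    frontier = [init]
    edges: list[tuple[int, int, float]] = []
    while frontier:
        state = frontier.pop()
        i = index[key(state)]
        for rate, new in _transition_list(cm, state):
            k = key(new)
            if k not in index:
                if len(index) >= max_states:
                    raise StateSpaceTooLarge(
                        f"more than {max_states} reachable states")
                index[k] = len(index)
                frontier.append(new.copy())
            edges.append((i, index[k], rate))
    n = len(index)
    Q = np.zeros((n, n))
    for i, j, rate in edges:
        Q[i, j] += rate
        Q[i, i] -= rate
    # stationary distribution: pi Q = 0, sum(pi) = 1
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    dist = {k: pi[i] for k, i in index.items()}
    return dist, index


def empirical_state_distribution(model: Model | CompiledModel, t_end: float,
                                 sample_interval: float, seed: int,
                                 burn_in: float = 0.0) -> dict[tuple, float]:
    """Empirical stationary distribution from regularly sampled chamber
    snapshots of one long engine run."""
    traj = simulate(model, t_end=t_end, sample_interval=sample_interval,
                    seed=seed, record_chambers=True)
    sel = traj.sample_times >= burn_in
    snaps = traj.chamber_samples[sel]
    freq: dict[tuple, float] = {}
    for snap in snaps:
        k = tuple(snap.reshape(-1))
        freq[k] = freq.get(k, 0.0) + 1.0
    n = sum(freq.values())
    return {k: v / n for k, v in freq.items()}


def total_variation(p: dict, q: dict) -> float:
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)


# ---------------------------------------------------------------------------
# diffusion (MSD) check
# ---------------------------------------------------------------------------

def msd_diffusion_check(D_um2_s: float, chamber_edge_um: float = 0.02,
                        n_traj: int = 1000, horizon_s: float = 2.0,
                        seed: int = 0, box_chambers: int = 40,
                        n_samples: int = 50) -> float:
    """Estimate the effective lateral diffusion coefficient of a single
    tracer from the slope of MSD(t)/4 (least squares through the origin).

    Runs on a periodic box so boundaries are never touched; displacements
    are unwrapped by nearest image (valid because hops per sampling
    interval are few compared to half the box).
    """
    if D_um2_s == 0.0:
        return 0.0
    l = chamber_edge_um
    geo = LatticeGeometry(box_edge_um=box_chambers * l, box_thickness_um=l,
                          chamber_edge_um=l, boundary=Boundary.PERIODIC)
    lat = build_lattice(geo)
    species = [SpeciesSpec("tracer", diffusion_um2_s=D_um2_s)]
    # keep the reaction list non-empty but inert
    rx = [ReactionSpec("noop", (("tracer", 1),), (("tracer", 1),), rate=0.0)]
    init = np.zeros((lat.n_chambers, 1), dtype=np.int64)
    start = lat.flat_index(box_chambers // 2, box_chambers // 2)
    init[start, 0] = 1
    model = Model(lattice=lat, species=species, reactions=rx,
                  initial_counts=init)
    dt = horizon_s / n_samples
    n = box_chambers
    msd = None
    times = None
    for k in range(n_traj):
        traj = simulate(model, t_end=horizon_s, sample_interval=dt,
                        seed=seed + k, record_chambers=True)
        pos = np.argmax(traj.chamber_samples[:, :, 0], axis=1)
        ij = np.stack([pos // n, pos % n], axis=1).astype(float)
        step = np.diff(ij, axis=0)
        step = (step + n / 2) % n - n / 2  # nearest image
        ij_unwrapped = np.vstack([ij[:1], ij[:1] + np.cumsum(step, axis=0)])
        disp = (ij_unwrapped - ij_unwrapped[0]) * l
        sq = (disp**2).sum(axis=1)
        msd = sq if msd is None else msd + sq
        times = traj.sample_times
    msd = msd / n_traj
    t, y = times[1:], msd[1:]
    slope = float((t * y).sum() / (t * t).sum())
    return slope / 4.0


# ---------------------------------------------------------------------------
# binding titration
# ---------------------------------------------------------------------------

def binding_occupancy_scan(binding: BindingParams,
                           doses_uM: np.ndarray | None = None,
                           n_receptor: int = 5,
                           chamber_edge_um: float = 1.0,
                           t_end: float = 600.0, burn_in: float = 100.0,
                           seed: int = 0, replicates: int = 4) -> tuple[float, np.ndarray]:
    """Half-max (fitted K_D) of an SSA binding titration R + L <-> C.

    The ligand is dosed in large excess of the receptor; mean fractional
    occupancy across the dose grid is fitted with d/(d + K).  Returns
    (K_fit, occupancy array).
    """
    K = binding.K_D
    if doses_uM is None:
        doses_uM = K * np.array([0.25, 0.5, 1.0, 2.0, 4.0])
    l = chamber_edge_um
    geo = LatticeGeometry(box_edge_um=l, box_thickness_um=l, chamber_edge_um=l)
    lat = build_lattice(geo)
    v = um3_to_litres(l**3)
    species = [SpeciesSpec("R"), SpeciesSpec("L"), SpeciesSpec("C")]
    rx = [ReactionSpec("bind", (("R", 1), ("L", 1)), (("C", 1),), rate=binding.k_on),
          ReactionSpec("unbind", (("C", 1),), (("R", 1), ("L", 1)), rate=binding.k_off)]
    occ = np.zeros(len(doses_uM))
    for i, d in enumerate(doses_uM):
        n_l = concentration_to_count(float(d), v)
        if n_l < 20 * n_receptor:
            raise ValueError(f"dose {d} uM gives only {n_l} ligands; "
                             "not in sufficient excess")
        vals = []
        for rep in range(replicates):
            init = np.zeros((1, 3), dtype=np.int64)
            init[0, 0] = n_receptor
            init[0, 1] = n_l
            model = Model(lattice=lat, species=species, reactions=rx,
                          initial_counts=init)
            traj = simulate(model, t_end=t_end, sample_interval=1.0,
                            seed=seed + 1000 * i + rep)
            sel = traj.sample_times >= burn_in
            vals.append(traj.total("C")[sel].mean() / n_receptor)
        occ[i] = np.mean(vals)
    popt, _ = curve_fit(lambda d, k: d / (d + k), doses_uM, occ, p0=[K])
    return float(popt[0]), occ
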