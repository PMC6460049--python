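"""Exact stochastic simulation of reaction-diffusion on a subvolume lattice.

Chemistry follows the law of mass action within each chamber; diffusion is
treated as a set of first-order hop reactions between neighbouring
chambers at rate D/l^2 per neighbour.  Two samplers are provided:

* :func:`simulate` — production path, a chamber-indexed direct method
  (binary sum tree over chamber propensities) compiled with numba.
* :func:`reference_simulate` / :func:`ssa_step` — a plain direct method in
  pure Python kept deliberately independent of the compiled kernel, used
  as the in-law reference in the validation suite.

Both are exact realisations of the same spatial chemical master equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .lattice import Lattice, diffusion_hop_rate
from .units import bimolecular_to_stochastic, um3_to_litres


class Compartment(str, Enum):
    MEMBRANE = "membrane"
    CYTOSOL = "cytosol"


class Locality(str, Enum):
    SAME_CHAMBER = "same_chamber"
    NEIGHBOR_CHAMBER = "neighbor_chamber"


class InvariantViolation(RuntimeError):
    """Signals an engine bug (negative count / negative propensity)."""


@dataclass(frozen=True)
class SpeciesSpec:
    """One species-state tracked by the engine."""

    name: str
    compartment: Compartment = Compartment.MEMBRANE
    diffusion_um2_s: float = 0.0
    initial_distribution: str = "uniform"  # uniform | cluster | absent

    def __post_init__(self):
        if self.diffusion_um2_s < 0:
            raise ValueError(f"negative diffusion coefficient for {self.name}")


@dataclass(frozen=True)
class ReactionSpec:
    """Mass-action reaction with at most two reactant molecules.

    ``rate`` is in 1/s for unimolecular channels and 1/(uM s) for
    bimolecular ones; the conversion to per-pair stochastic rates happens
    at compile time using the chamber volume.  ``neighbor_chamber``
    locality marks a catalytic pair reaction whose second reactant may sit
    in the same chamber or any lateral neighbour (the trans-acting
    phosphatase channel); the first reactant must then be unchanged by the
    reaction.
    """

    name: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate: float
    locality: Locality = Locality.SAME_CHAMBER

    def order(self) -> int:
        return sum(n for _, n in self.reactants)

    def __post_init__(self):
        if self.rate < 0 or not np.isfinite(self.rate):
            raise ValueError(f"reaction {self.name}: non-finite or negative rate")
        if self.order() > 2:
            raise ValueError(f"reaction {self.name}: more than 2 reactant molecules")
        if self.order() == 0:
            raise ValueError(f"reaction {self.name}: needs at least one reactant")
        if self.locality == Locality.NEIGHBOR_CHAMBER:
            if len(self.reactants) != 2:
                raise ValueError(f"reaction {self.name}: neighbor locality needs 2 reactants")
            enz = self.reactants[0][0]
            delta = _delta_map(self.reactants, self.products)
            if delta.get(enz, 0) != 0:
                raise ValueError(
                    f"reaction {self.name}: first reactant must be catalytic for "
                    "neighbor_chamber locality"
                )


def _delta_map(reactants, products) -> dict[str, int]:
    d: dict[str, int] = {}
    for sp, n in reactants:
        d[sp] = d.get(sp, 0) - n
    for sp, n in products:
        d[sp] = d.get(sp, 0) + n
    return {k: v for k, v in d.items() if v != 0}


@dataclass
class Model:
    """Complete declarative description of one simulation.

    ``initial_counts`` has shape (n_chambers, n_species); ``confinement``
    optionally maps species names to boolean chamber masks outside of
    which the species cannot hop (a preformed, maintained microcluster).
    ``metadata`` carries run labels (variant, stimulation mode, doses).
    """

    lattice: Lattice
    species: list[SpeciesSpec]
    reactions: list[ReactionSpec]
    initial_counts: np.ndarray
    confinement: dict[str, np.ndarray] = field(default_factory=dict)
    trans_radius: int = 1
    metadata: dict = field(default_factory=dict)
    observables: dict[str, list[str]] = field(default_factory=dict)

    def species_index(self, name: str) -> int:
        for i, sp in enumerate(self.species):
            if sp.name == name:
                return i
        raise KeyError(name)

    def validate(self) -> None:
        C = self.lattice.n_chambers
        S = len(self.species)
        if self.initial_counts.shape != (C, S):
            raise ValueError(
                f"initial_counts shape {self.initial_counts.shape} != ({C}, {S})"
            )
        if (self.initial_counts < 0).any():
            raise InvariantViolation("negative initial counts")
        names = {sp.name for sp in self.species}
        for rx in self.reactions:
            for sp, _ in rx.reactants + rx.products:
                if sp not in names:
                    raise ValueError(f"reaction {rx.name}: unknown species {sp}")


@dataclass
class ChamberState:
    """Per-chamber integer counts for every species plus the clock."""

    counts: np.ndarray  # (C, S) int64
    time: float = 0.0

    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass
class Trajectory:
    """Sampled lattice-total time series from one seeded run."""

    sample_times: np.ndarray  # (T,) seconds
    totals: np.ndarray  # (T, S) lattice sums
    species_names: list[str]
    seed: int
    metadata: dict = field(default_factory=dict)
    chamber_samples: np.ndarray | None = None  # (T, C, S) when requested
    n_events: int = 0
    absorbed: bool = False

    def total(self, name: str) -> np.ndarray:
        return self.totals[:, self.species_names.index(name)]

    def group_total(self, names: list[str]) -> np.ndarray:
        idx = [self.species_names.index(n) for n in names]
        return self.totals[:, idx].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: time_s, species_state, total_count, seed + labels."""
        T, S = self.totals.shape
        df = pd.DataFrame(
            {
                "time_s": np.repeat(self.sample_times, S),
                "species_state": np.tile(np.asarray(self.species_names), T),
                "total_count": self.totals.reshape(-1),
            }
        )
        df["seed"] = self.seed
        for key in ("variant", "mode", "dose_L7R_uM", "dose_L7D_uM"):
            if key in self.metadata:
                df[key] = self.metadata[key]
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def chamber_snapshot_frame(model: Model, counts: np.ndarray, time_s: float) -> pd.DataFrame:
    """Per-chamber snapshot as a tidy table (chamber_i, chamber_j, species_state, count)."""
    rows = []
    for c in range(model.lattice.n_chambers):
        i, j, _k = model.lattice.coords(c)
        for s, sp in enumerate(model.species):
            if counts[c, s]:
                rows.append((i, j, sp.name, int(counts[c, s]), time_s))
    return pd.DataFrame(rows, columns=["chamber_i", "chamber_j", "species_state", "count", "time_s"])


# ---------------------------------------------------------------------------
# compilation to flat arrays
# ---------------------------------------------------------------------------

TYPE_UNI = 1
TYPE_BI = 2
TYPE_HOMO = 3
TYPE_TRANS = 4


class CompiledModel:
    """Flat-array form of a :class:`Model` consumed by the samplers."""

    def __init__(self, model: Model):
        model.validate()
        lat = model.lattice
        g = lat.geometry
        self.model = model
        self.C = lat.n_chambers
        self.S = len(model.species)
        self.names = [sp.name for sp in model.species]
        name_to_idx = {n: i for i, n in enumerate(self.names)}
        self.neighbors = lat.neighbors.astype(np.int32)
        self.n_neighbors = lat.n_neighbors.astype(np.int32)

        v_chamber = um3_to_litres(g.chamber_edge_um**3)

        # species: allowed-chamber masks and hop-rate factors
        self.mask = np.ones((self.S, self.C), dtype=np.uint8)
        for name, m in model.confinement.items():
            self.mask[name_to_idx[name]] = np.asarray(m, dtype=np.uint8)
        self.hopfac = np.zeros((self.S, self.C), dtype=np.float64)
        self.hop_rate = np.zeros(self.S, dtype=np.float64)  # D/l^2 per neighbour
        for s, sp in enumerate(model.species):
            rate = diffusion_hop_rate(sp.diffusion_um2_s, g.chamber_edge_um)
            self.hop_rate[s] = rate
            if rate == 0.0:
                continue
            for c in range(self.C):
                if not self.mask[s, c]:
                    continue
                na = 0
                for m in range(self.n_neighbors[c]):
                    b = self.neighbors[c, m]
                    if self.mask[s, b]:
                        na += 1
                self.hopfac[s, c] = rate * na

        # reactions
        R = len(model.reactions)
        self.R = R
        self.r_type = np.zeros(R, dtype=np.int32)
        self.r_rate = np.zeros(R, dtype=np.float64)
        self.r_s1 = np.full(R, -1, dtype=np.int32)
        self.r_s2 = np.full(R, -1, dtype=np.int32)
        self.r_nch = np.zeros(R, dtype=np.int32)
        self.r_chsp = np.full((R, 4), -1, dtype=np.int32)
        self.r_chd = np.zeros((R, 4), dtype=np.int64)
        for r, rx in enumerate(model.reactions):
            delta = _delta_map(rx.reactants, rx.products)
            if len(delta) > 4:
                raise ValueError(f"reaction {rx.name}: too many state changes")
            if rx.locality == Locality.NEIGHBOR_CHAMBER and model.trans_radius > 0:
                self.r_type[r] = TYPE_TRANS
                self.r_s1[r] = name_to_idx[rx.reactants[0][0]]
                self.r_s2[r] = name_to_idx[rx.reactants[1][0]]
                self.r_rate[r] = bimolecular_to_stochastic(rx.rate, v_chamber)
            elif rx.order() == 1:
                self.r_type[r] = TYPE_UNI
                self.r_s1[r] = name_to_idx[rx.reactants[0][0]]
                self.r_rate[r] = rx.rate
            elif len(rx.reactants) == 1:  # homodimeric A + A
                self.r_type[r] = TYPE_HOMO
                self.r_s1[r] = name_to_idx[rx.reactants[0][0]]
                self.r_rate[r] = bimolecular_to_stochastic(rx.rate, v_chamber)
            else:
                self.r_type[r] = TYPE_BI
                self.r_s1[r] = name_to_idx[rx.reactants[0][0]]
                self.r_s2[r] = name_to_idx[rx.reactants[1][0]]
                self.r_rate[r] = bimolecular_to_stochastic(rx.rate, v_chamber)
            for m, (sp, d) in enumerate(sorted(delta.items())):
                self.r_chsp[r, m] = name_to_idx[sp]
                self.r_chd[r, m] = d
            self.r_nch[r] = len(delta)

        # species -> channel adjacency, specialised for the inline kernel:
        # entries (channel, kind, rate, partner); kind 0 uni / 1 bi /
        # 2 homodimer / 3 trans-channel enzyme.  Trans targets get their
        # own list because a target change touches the channel in the
        # chamber and all its lateral neighbours.
        per_sp: list[list[tuple]] = [[] for _ in range(self.S)]
        per_sp_trans: list[list[tuple]] = [[] for _ in range(self.S)]
        for r in range(R):
            t, rate = self.r_type[r], self.r_rate[r]
            s1, s2 = self.r_s1[r], self.r_s2[r]
            if t == TYPE_UNI:
                per_sp[s1].append((r, 0, rate, 0))
            elif t == TYPE_BI:
                per_sp[s1].append((r, 1, rate, s2))
                per_sp[s2].append((r, 1, rate, s1))
            elif t == TYPE_HOMO:
                per_sp[s1].append((r, 2, rate, 0))
            else:  # TYPE_TRANS
                per_sp[s1].append((r, 3, rate, s2))
                per_sp_trans[s2].append((r, rate, s1, s2))
        self.adj_idx, flat = _csr(per_sp)
        self.adj_r = np.asarray([f[0] for f in flat], dtype=np.int32)
        self.adj_kind = np.asarray([f[1] for f in flat], dtype=np.int32)
        self.adj_rate = np.asarray([f[2] for f in flat], dtype=np.float64)
        self.adj_partner = np.asarray([f[3] for f in flat], dtype=np.int32)
        self.tr_idx, flat = _csr(per_sp_trans)
        self.tr_r = np.asarray([f[0] for f in flat], dtype=np.int32)
        self.tr_rate = np.asarray([f[1] for f in flat], dtype=np.float64)
        self.tr_s1 = np.asarray([f[2] for f in flat], dtype=np.int32)
        self.tr_s2 = np.asarray([f[3] for f in flat], dtype=np.int32)
        self.has_trans = bool((self.r_type == TYPE_TRANS).any())

    def initial_counts(self) -> np.ndarray:
        return self.model.initial_counts.astype(np.int64).copy()


def _csr(lists: list[list]) -> tuple[np.ndarray, list]:
    idx = np.zeros(len(lists) + 1, dtype=np.int32)
    flat: list = []
    for i, lst in enumerate(lists):
        flat.extend(lst)
        idx[i + 1] = len(flat)
    return idx, flat


# ---------------------------------------------------------------------------
# reference direct method (independent of the compiled kernel)
# ---------------------------------------------------------------------------

def _all_propensities(cm: CompiledModel, counts: np.ndarray) -> np.ndarray:
    """Dense (C, R + S) propensity table, recomputed from scratch."""
    if (counts < 0).any():
        raise InvariantViolation("negative counts")
    C, S, R = cm.C, cm.S, cm.R
    P = np.zeros((C, R + S))
    for c in range(C):
        for r in range(R):
            P[c, r] = propensity_channel(cm, counts, c, r)
        for s in range(S):
            P[c, R + s] = cm.hopfac[s, c] * counts[c, s]
    return P


def propensity_channel(cm: CompiledModel, counts: np.ndarray, c: int, r: int) -> float:
    t = cm.r_type[r]
    if t == TYPE_UNI:
        return cm.r_rate[r] * counts[c, cm.r_s1[r]]
    if t == TYPE_BI:
        return cm.r_rate[r] * counts[c, cm.r_s1[r]] * counts[c, cm.r_s2[r]]
    if t == TYPE_HOMO:
        n = counts[c, cm.r_s1[r]]
        return cm.r_rate[r] * n * (n - 1) / 2.0
    # trans: enzyme here, target here or in a lateral neighbour
    tgt = counts[c, cm.r_s2[r]]
    for m in range(cm.n_neighbors[c]):
        tgt += counts[cm.neighbors[c, m], cm.r_s2[r]]
    return cm.r_rate[r] * counts[c, cm.r_s1[r]] * tgt


def propensity(chamber_counts: np.ndarray, reaction: ReactionSpec, stochastic_rate: float,
               species_names: list[str]) -> float:
    """Law-of-mass-action propensity of one reaction in one chamber.

    ``stochastic_rate`` must already be in per-chamber units (1/s per
    molecule or per pair).  Homodimeric channels use n(n-1)/2 pairs.
    """
    if (np.asarray(chamber_counts) < 0).any():
        raise InvariantViolation("negative counts")
    idx = {n: i for i, n in enumerate(species_names)}
    a = stochastic_rate
    if reaction.order() == 1:
        return a * chamber_counts[idx[reaction.reactants[0][0]]]
    if len(reaction.reactants) == 1:
        n = chamber_counts[idx[reaction.reactants[0][0]]]
        return a * n * (n - 1) / 2.0
    n1 = chamber_counts[idx[reaction.reactants[0][0]]]
    n2 = chamber_counts[idx[reaction.reactants[1][0]]]
    return a * n1 * n2


def ssa_step(state: ChamberState, cm: CompiledModel, rng: np.random.Generator
             ) -> tuple[ChamberState, float, bool]:
    """One exact direct-method event.  Returns (state, elapsed, absorbing).

    When the total propensity is zero the state is returned unchanged with
    the absorbing flag set.
    """
    P = _all_propensities(cm, state.counts)
    total = P.sum()
    if total <= 0.0:
        return state, 0.0, True
    dt = rng.exponential(1.0 / total)
    flat = P.reshape(-1)
    pick = np.searchsorted(np.cumsum(flat), rng.random() * total, side="right")
    pick = min(pick, flat.size - 1)
    c, ch = divmod(pick, cm.R + cm.S)
    counts = state.counts
    if ch < cm.R:
        _execute_reaction(cm, counts, c, ch, rng)
    else:
        s = ch - cm.R
        # choose a uniformly random allowed neighbour
        allowed = [cm.neighbors[c, m] for m in range(cm.n_neighbors[c])
                   if cm.mask[s, cm.neighbors[c, m]]]
        b = allowed[rng.integers(len(allowed))]
        counts[c, s] -= 1
        counts[b, s] += 1
    state.time += dt
    return state, dt, False


def _execute_reaction(cm: CompiledModel, counts: np.ndarray, c: int, r: int,
                      rng: np.random.Generator) -> None:
    target = c
    if cm.r_type[r] == TYPE_TRANS:
        s2 = cm.r_s2[r]
        w = [counts[c, s2]] + [counts[cm.neighbors[c, m], s2] for m in range(cm.n_neighbors[c])]
        chambers = [c] + [cm.neighbors[c, m] for m in range(cm.n_neighbors[c])]
        wsum = float(sum(w))
        u = rng.random() * wsum
        acc = 0.0
        for ch_b, wt in zip(chambers, w):
            acc += wt
            if u <= acc:
                target = ch_b
                break
    for m in range(cm.r_nch[r]):
        counts[target, cm.r_chsp[r, m]] += cm.r_chd[r, m]
        if counts[target, cm.r_chsp[r, m]] < 0:
            raise InvariantViolation(
                f"negative count for {cm.names[cm.r_chsp[r, m]]} after reaction "
                f"{cm.model.reactions[r].name}"
            )


def reference_simulate(model: Model, t_end: float, sample_interval: float, seed: int,
                       record_chambers: bool = False) -> Trajectory:
    """Plain direct-method simulation (slow; validation reference)."""
    cm = model if isinstance(model, CompiledModel) else CompiledModel(model)
    rng = np.random.default_rng(seed)
    state = ChamberState(counts=cm.initial_counts(), time=0.0)
    times = np.arange(0.0, t_end + 0.5 * sample_interval, sample_interval)
    totals = np.zeros((len(times), cm.S), dtype=np.int64)
    chambers = np.zeros((len(times), cm.C, cm.S), dtype=np.int64) if record_chambers else None
    i_samp = 0
    n_events = 0
    absorbed = False
    while i_samp < len(times):
        while i_samp < len(times) and state.time >= times[i_samp] - 1e-12:
            totals[i_samp] = state.counts.sum(axis=0)
            if record_chambers:
                chambers[i_samp] = state.counts
            i_samp += 1
        if i_samp >= len(times):
            break
        state, _dt, absorbing = ssa_step(state, cm, rng)
        if absorbing:
            absorbed = True
            for j in range(i_samp, len(times)):
                totals[j] = state.counts.sum(axis=0)
                if record_chambers:
                    chambers[j] = state.counts
            break
        n_events += 1
    meta = dict(cm.model.metadata) if isinstance(cm, CompiledModel) else {}
    return Trajectory(sample_times=times, totals=totals,
                      species_names=list(cm.names), seed=seed, metadata=meta,
                      chamber_samples=chambers, n_events=n_events, absorbed=absorbed)


# ---------------------------------------------------------------------------
# production path
# ---------------------------------------------------------------------------

def simulate(model: Model, t_end: float, sample_interval: float = 1.0, seed: int = 0,
             record_chambers: bool = False, method: str = "tree") -> Trajectory:
    """Simulate ``model`` to ``t_end`` seconds, sampling lattice totals.

    ``method='tree'`` runs the compiled chamber-indexed direct method;
    ``method='reference'`` runs the pure-Python reference sampler.  Both
    draw from the same law; trajectories are reproducible from ``seed``.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if sample_interval <= 0:
        raise ValueError("sample_interval must be positive")
    if method == "reference":
        return reference_simulate(model, t_end, sample_interval, seed,
                                  record_chambers=record_chambers)
    from ._kernel import run_kernel

    cm = model if isinstance(model, CompiledModel) else CompiledModel(model)
    counts = cm.initial_counts()
    times = np.arange(0.0, t_end + 0.5 * sample_interval, sample_interval)
    totals = np.zeros((len(times), cm.S), dtype=np.int64)
    if record_chambers:
        chamber_out = np.zeros((len(times), cm.C, cm.S), dtype=np.int64)
    else:
        chamber_out = np.zeros((1, 1, 1), dtype=np.int64)
    n_events, absorbed, bad = run_kernel(
        counts, cm.neighbors, cm.n_neighbors, cm.hopfac, cm.mask,
        cm.r_type, cm.r_rate, cm.r_s1, cm.r_s2, cm.r_nch, cm.r_chsp, cm.r_chd,
        cm.adj_idx, cm.adj_r, cm.adj_kind, cm.adj_rate, cm.adj_partner,
        cm.tr_idx, cm.tr_r, cm.tr_rate, cm.tr_s1, cm.tr_s2,
        np.float64(t_end), times, totals,
        np.int64(1 if record_chambers else 0), chamber_out,
        np.int64(seed),
    )
    if bad >= 0:
        raise InvariantViolation(
            f"negative count or non-finite propensity around reaction "
            f"{cm.model.reactions[bad].name if bad < cm.R else 'diffusion'}"
        )
    return Trajectory(
        sample_times=times, totals=totals, species_names=list(cm.names),
        seed=seed, metadata=dict(cm.model.metadata),
        chamber_samples=chamber_out if record_chambers else None,
        n_events=int(n_events), absorbed=bool(absorbed),
    )
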