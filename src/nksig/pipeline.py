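"""Dose-response experiment pipeline.

Reproduces the in-silico protocol: sweep the inhibitory-peptide dose from
0 to 12.5 uM either alone (``single``) or mixed with the antagonist so the
total stays at 12.5 uM (``mixed``), run seeded replicate simulations per
dose, read out the steady-state pVav1 (time average between 5 and 15 min)
and the amount of SHP-1 bound to ITIMs, and detect peptide antagonism as
a range of doses where the mixed-mode pVav1 significantly exceeds the
single-mode pVav1 at matched inhibitory dose.

Replicates of matching (dose index, replicate) share seeds across modes
and variants, so mode comparisons are paired (common random numbers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .engine import Trajectory, simulate
from .model import (
    OBSERVABLES,
    ClusterScalingRule,
    ModelVariant,
    PeptideDose,
    StimulationMode,
    Variant,
    build_model,
    rule_from_params,
)

DEFAULT_DOSES_UM = (0.0, 1.25, 2.5, 5.0, 7.5, 10.0, 12.5)


@dataclass(frozen=True)
class DoseGrid:
    """Inhibitory-peptide dose grid plus replicate/seed policy."""

    l7r_doses_uM: tuple[float, ...] = DEFAULT_DOSES_UM
    mode: StimulationMode = StimulationMode.SINGLE
    replicates: int = 10
    seed_base: int = 0
    total_uM: float = 12.5

    def __post_init__(self):
        d = np.asarray(self.l7r_doses_uM, dtype=float)
        if d.size == 0 or (np.diff(d) <= 0).any():
            raise ValueError("doses must be strictly ascending and non-empty")
        if d[0] < 0 or d[-1] > self.total_uM + 1e-9:
            raise ValueError(f"doses must lie in [0, {self.total_uM}]")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    def dose(self, i: int) -> PeptideDose:
        x = self.l7r_doses_uM[i]
        if self.mode == StimulationMode.SINGLE:
            return PeptideDose.single(x)
        return PeptideDose.mixed(x, total_uM=self.total_uM)

    def seed(self, i_dose: int, replicate: int) -> int:
        """Replicate r of dose i runs with seed base + 131*i + r (shared
        across modes/variants so comparisons are paired)."""
        return int(self.seed_base + 131 * i_dose + replicate)


@dataclass(frozen=True)
class SteadyStateSummary:
    """Window time-average of one species for one condition."""

    species: str
    window: tuple[float, float]
    mean: float
    sd: float
    n_replicates: int


def steady_state_mean(trajectory: Trajectory, species: str | list[str],
                      window: tuple[float, float] = (300.0, 900.0)) -> SteadyStateSummary:
    """Time average (and sd over samples) of a species or observable group
    inside ``window``.  ``species`` may be an observable name from the
    model catalogue, a species-state name, or an explicit list of states.
    """
    lo, hi = window
    if not (lo < hi):
        raise ValueError(f"malformed window {window}")
    t = trajectory.sample_times
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise ValueError(f"window {window} outside trajectory [{t[0]}, {t[-1]}]")
    y = _resolve_series(trajectory, species)
    sel = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    y = y[sel]
    label = species if isinstance(species, str) else "+".join(species)
    return SteadyStateSummary(species=label, window=(lo, hi),
                              mean=float(y.mean()), sd=float(y.std(ddof=1)),
                              n_replicates=1)


def _resolve_series(trajectory: Trajectory, species) -> np.ndarray:
    if isinstance(species, (list, tuple)):
        return trajectory.group_total(list(species)).astype(float)
    if species in trajectory.species_names:
        return trajectory.total(species).astype(float)
    if species in OBSERVABLES:
        return trajectory.group_total(OBSERVABLES[species]).astype(float)
    raise KeyError(f"unknown species or observable {species!r}")


NOT_SETTLED = float("inf")


def time_to_steady_state(trajectory: Trajectory, species: str | list[str],
                         tolerance: float = 0.10,
                         window: tuple[float, float] = (300.0, 900.0),
                         running_s: float = 60.0) -> float:
    """Earliest time after which a centred ``running_s`` running mean stays
    within ``tolerance`` of the steady-state window mean.

    Returns ``inf`` (sentinel: not settled) when the running mean still
    leaves the band inside the averaging window itself.
    """
    ref = steady_state_mean(trajectory, species, window).mean
    t = trajectory.sample_times
    y = _resolve_series(trajectory, species)
    half = running_s / 2.0
    run = np.empty_like(y)
    for i, ti in enumerate(t):
        sel = (t >= ti - half) & (t <= ti + half)
        run[i] = y[sel].mean()
    band = tolerance * ref
    outside = np.abs(run - ref) > band
    if not outside.any():
        return 0.0
    last = int(np.flatnonzero(outside)[-1])
    if last + 1 >= len(t):
        return NOT_SETTLED
    settle = float(t[last + 1])
    return settle if settle <= window[1] else NOT_SETTLED


@dataclass
class DoseResponseCurve:
    """Per-dose replicate steady-state means for one (variant, mode)."""

    variant: str
    mode: str
    doses_uM: np.ndarray
    values: dict[str, np.ndarray]  # observable -> (n_doses, n_replicates)
    window: tuple[float, float]
    seeds: np.ndarray  # (n_doses, n_replicates)
    settle_s: np.ndarray  # (n_doses, n_replicates)
    cluster_edges_um: np.ndarray = field(default=None)

    def mean(self, species: str = "pVav1") -> np.ndarray:
        return self.values[species].mean(axis=1)

    def sd(self, species: str = "pVav1") -> np.ndarray:
        return self.values[species].std(axis=1, ddof=1)

    @property
    def n_replicates(self) -> int:
        return self.values["pVav1"].shape[1]

    @property
    def all_settled(self) -> bool:
        return bool(np.isfinite(self.settle_s).all())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        n_d, n_r = self.seeds.shape
        for i in range(n_d):
            for r in range(n_r):
                row = {
                    "variant": self.variant, "mode": self.mode,
                    "dose_L7R_uM": self.doses_uM[i],
                    "replicate": r, "seed": self.seeds[i, r],
                    "settle_s": self.settle_s[i, r],
                }
                for sp, v in self.values.items():
                    row[sp] = v[i, r]
                rows.append(row)
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_dose_series(variant: ModelVariant | Variant, mode: StimulationMode | str,
                    grid: DoseGrid, params: dict,
                    rule: ClusterScalingRule | None = None,
                    species: tuple[str, ...] = ("pVav1", "itim_shp1"),
                    t_end: float | None = None,
                    window: tuple[float, float] | None = None,
                    sample_interval: float = 1.0,
                    reuse_top_dose_from: DoseResponseCurve | None = None
                    ) -> DoseResponseCurve:
    """One seeded simulation per (dose, replicate); curve of steady-state
    pVav1 and ITIM-bound SHP-1 (plus any extra observables requested).

    When sweeping mixed mode with the grid topping out at the mixture
    total, the top dose carries no antagonist and is exactly the
    single-mode condition with the same seeds; pass that variant's
    single-mode curve as ``reuse_top_dose_from`` to splice its top row in
    instead of recomputing it.
    """
    if isinstance(variant, Variant):
        variant = ModelVariant(variant)
    mode = StimulationMode(mode)
    grid = DoseGrid(l7r_doses_uM=grid.l7r_doses_uM, mode=mode,
                    replicates=grid.replicates, seed_base=grid.seed_base,
                    total_uM=grid.total_uM)
    if rule is None:
        rule = rule_from_params(params)
    sim = params.get("simulation", {})
    t_end = float(t_end if t_end is not None else sim.get("t_end_s", 900.0))
    window = window or (sim.get("window_lo_s", 300.0), sim.get("window_hi_s", 900.0))

    n_d, n_r = len(grid.l7r_doses_uM), grid.replicates
    values = {sp: np.zeros((n_d, n_r)) for sp in species}
    seeds = np.zeros((n_d, n_r), dtype=np.int64)
    settle = np.zeros((n_d, n_r))
    edges = np.zeros(n_d)
    splice_top = False
    if reuse_top_dose_from is not None:
        src = reuse_top_dose_from
        if (mode == StimulationMode.MIXED
                and grid.l7r_doses_uM[-1] == grid.total_uM
                and np.allclose(src.doses_uM, grid.l7r_doses_uM)
                and src.n_replicates == n_r
                and src.seeds[-1, 0] == grid.seed(n_d - 1, 0)):
            splice_top = True
        else:
            raise ValueError("reuse_top_dose_from does not match this sweep")
    for i in range(n_d):
        if splice_top and i == n_d - 1:
            for sp in species:
                values[sp][i] = src.values[sp][i]
            seeds[i] = src.seeds[i]
            settle[i] = src.settle_s[i]
            edges[i] = src.cluster_edges_um[i]
            continue
        dose = grid.dose(i)
        for r in range(n_r):
            seed = grid.seed(i, r)
            model = build_model(variant, dose, rule=rule, params=params, seed=seed)
            traj = simulate(model, t_end=t_end, sample_interval=sample_interval,
                            seed=seed)
            for sp in species:
                values[sp][i, r] = steady_state_mean(traj, sp, window).mean
            settle[i, r] = time_to_steady_state(traj, "pVav1", window=window)
            seeds[i, r] = seed
        edges[i] = model.metadata["cluster_edge_um"]
    return DoseResponseCurve(
        variant=variant.variant.value, mode=mode.value,
        doses_uM=np.asarray(grid.l7r_doses_uM, dtype=float),
        values=values, window=tuple(window), seeds=seeds, settle_s=settle,
        cluster_edges_um=edges,
    )


@dataclass(frozen=True)
class AntagonismResult:
    """Per-dose mixed-vs-single comparison of steady-state pVav1."""

    doses_uM: np.ndarray
    effect: np.ndarray  # mean(mixed - single) per dose
    p_one_sided: np.ndarray  # H1: mixed > single
    ci_low: np.ndarray  # lower end of one-sided (1 - alpha) CI of the effect
    significant: np.ndarray  # bool per dose
    detected: bool  # >= 2 consecutive significant doses
    alpha: float

    @property
    def antagonistic_doses(self) -> np.ndarray:
        return self.doses_uM[self.significant]


def antagonism_range(single: DoseResponseCurve, mixed: DoseResponseCurve,
                     alpha: float = 0.05, species: str = "pVav1") -> AntagonismResult:
    """Doses where mixed-mode pVav1 exceeds single-mode pVav1 (one-sided
    CI excluding zero); antagonism is called when the significant set
    contains at least two consecutive grid doses."""
    if not np.allclose(single.doses_uM, mixed.doses_uM):
        raise ValueError("curves do not share the dose grid")
    if single.n_replicates != mixed.n_replicates:
        raise ValueError("curves do not share the replicate count")
    paired = np.array_equal(single.seeds, mixed.seeds)
    a, b = single.values[species], mixed.values[species]
    n_d, n_r = a.shape
    eff = np.zeros(n_d)
    pvals = np.ones(n_d)
    ci_low = np.zeros(n_d)
    for i in range(n_d):
        diff = b[i] - a[i]
        eff[i] = diff.mean()
        if paired:
            se = diff.std(ddof=1) / np.sqrt(n_r)
            df = n_r - 1
        else:
            se = np.sqrt(a[i].var(ddof=1) / n_r + b[i].var(ddof=1) / n_r)
            df = 2 * (n_r - 1)
        if se == 0:
            pvals[i] = 0.0 if eff[i] > 0 else 1.0
            ci_low[i] = eff[i]
            continue
        tstat = eff[i] / se
        pvals[i] = float(stats.t.sf(tstat, df))
        ci_low[i] = eff[i] - stats.t.ppf(1 - alpha, df) * se
    sig = (pvals < alpha) & (ci_low > 0)
    detected = bool((sig[:-1] & sig[1:]).any())
    return AntagonismResult(doses_uM=single.doses_uM, effect=eff,
                            p_one_sided=pvals, ci_low=ci_low,
                            significant=sig, detected=detected, alpha=alpha)


def paired_onesided_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided paired t test p-value for H1: mean(y) > mean(x); arrays
    are flattened (doses x replicates pooled)."""
    diff = (np.asarray(y, float) - np.asarray(x, float)).ravel()
    if diff.std(ddof=1) == 0:
        return 0.0 if diff.mean() > 0 else 1.0
    t = diff.mean() / (diff.std(ddof=1) / np.sqrt(diff.size))
    return float(stats.t.sf(t, diff.size - 1))
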