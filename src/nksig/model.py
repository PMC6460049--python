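"""NK-cell membrane-proximal signaling models (variants 1 and 2).

Both variants share a canonical signal-integration network: inhibitory
KIR2DL2/3 receptors bind HLA-C presenting either a strong inhibitory
peptide (L7R, K_D = 0.8 uM) or a weak antagonist peptide (L7D, K_D =
4.4 uM); Src-family kinases (SFK) phosphorylate the ITIM of ligated KIR;
phospho-ITIMs recruit the cytosolic phosphatase SHP-1, which
dephosphorylates pVav1.  An uncharacterised activating receptor (AR)
binds its ligand (affinity K_R), is ITAM-phosphorylated by SFK, docks
Zap-70, and ITAM-bound Zap-70 phosphorylates Vav1.  pVav1 abundance is
the activation readout.

The variants differ in exactly two respects:

* Model 1 adds a trans-acting phosphatase reaction — SHP-1 carried by
  antagonist-ligated KIR dephosphorylates phospho-ITIMs of ligated KIR in
  the same or neighbouring chambers — and leaves SFK spatially uniform.
* Model 2 omits that reaction and instead co-clusters SFK with KIR inside
  the imposed microcluster.

KIR sit in a preformed square microcluster at the box centre whose edge
grows with antagonist dose at constant copy number (density dilution);
the cluster size is independent of the inhibitory-peptide dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .engine import (
    Compartment,
    Locality,
    Model,
    ReactionSpec,
    SpeciesSpec,
)
from .lattice import Boundary, GeometryError, Lattice, LatticeGeometry, build_lattice, region_chambers
from .units import VolumeContext, concentration_to_count, kd_to_rate_pair, um3_to_litres


class Variant(str, Enum):
    MODEL1 = "model1"
    MODEL2 = "model2"


@dataclass(frozen=True)
class ModelVariant:
    """Feature switches implied by the variant choice.

    Model 1: SFK not co-clustered, trans-dephosphorylation present.
    Model 2: SFK co-clustered, trans-dephosphorylation absent.
    Explicit flags are accepted but must match the variant; a mismatch
    (e.g. requesting the trans channel in Model 2) is rejected.
    """

    variant: Variant
    sfk_coclustered: bool | None = None
    trans_dephos_reaction: bool | None = None

    def __post_init__(self):
        want_cocluster = self.variant == Variant.MODEL2
        want_trans = self.variant == Variant.MODEL1
        if self.sfk_coclustered is None:
            object.__setattr__(self, "sfk_coclustered", want_cocluster)
        if self.trans_dephos_reaction is None:
            object.__setattr__(self, "trans_dephos_reaction", want_trans)
        if self.sfk_coclustered != want_cocluster or self.trans_dephos_reaction != want_trans:
            raise ValueError(
                f"{self.variant.value} requires sfk_coclustered={want_cocluster}, "
                f"trans_dephos_reaction={want_trans}"
            )


class StimulationMode(str, Enum):
    SINGLE = "single"
    MIXED = "mixed"


@dataclass(frozen=True)
class PeptideDose:
    """Doses of the inhibitory (L7R) and antagonist (L7D) HLA-peptide ligands."""

    L7R_uM: float
    L7D_uM: float
    mode: StimulationMode = StimulationMode.SINGLE
    total_uM: float = 12.5

    def __post_init__(self):
        if self.L7R_uM < 0 or self.L7D_uM < 0:
            raise ValueError("doses must be non-negative")
        if self.mode == StimulationMode.MIXED:
            if not math.isclose(self.L7R_uM + self.L7D_uM, self.total_uM, rel_tol=1e-9, abs_tol=1e-9):
                raise ValueError(
                    f"mixed-mode doses must sum to {self.total_uM} uM "
                    f"(got {self.L7R_uM} + {self.L7D_uM})"
                )
        elif self.L7D_uM != 0.0:
            raise ValueError("single-peptide mode carries no antagonist dose")

    @classmethod
    def single(cls, L7R_uM: float) -> "PeptideDose":
        return cls(L7R_uM=L7R_uM, L7D_uM=0.0, mode=StimulationMode.SINGLE)

    @classmethod
    def mixed(cls, L7R_uM: float, total_uM: float = 12.5) -> "PeptideDose":
        return cls(L7R_uM=L7R_uM, L7D_uM=total_uM - L7R_uM,
                   mode=StimulationMode.MIXED, total_uM=total_uM)


@dataclass(frozen=True)
class ClusterScalingRule:
    """Antagonist dose -> KIR (and, in Model 2, SFK) cluster edge length.

    The edge interpolates monotonically from ``edge_at_zero_um`` (no
    antagonist) to ``edge_at_max_um`` at ``max_dose_uM``, holding total
    clustered copy numbers fixed; setting the two edges equal gives the
    fixed-cluster control.  ``linear_edge`` interpolates the edge length,
    ``linear_area`` the cluster area.
    """

    edge_at_zero_um: float = 0.2
    edge_at_max_um: float = 1.0
    max_dose_uM: float = 12.5
    interpolation: str = "linear_edge"

    def __post_init__(self):
        if not (0 < self.edge_at_zero_um <= self.edge_at_max_um):
            raise ValueError("need 0 < edge_at_zero <= edge_at_max")
        if self.max_dose_uM <= 0:
            raise ValueError("max_dose must be positive")
        if self.interpolation not in ("linear_edge", "linear_area"):
            raise ValueError(f"unknown interpolation {self.interpolation}")

    @classmethod
    def fixed(cls, edge_um: float = 0.2) -> "ClusterScalingRule":
        return cls(edge_at_zero_um=edge_um, edge_at_max_um=edge_um)


def cluster_edge_for_dose(L7D_uM: float, rule: ClusterScalingRule,
                          chamber_edge_um: float) -> float:
    """Cluster edge (um) at an antagonist dose, snapped to whole chambers.

    Snapping is to the nearest positive multiple of the chamber edge, so
    the region always tiles the lattice exactly.
    """
    if L7D_uM < 0 or L7D_uM > rule.max_dose_uM * (1 + 1e-9):
        raise ValueError(f"antagonist dose {L7D_uM} outside [0, {rule.max_dose_uM}]")
    f = L7D_uM / rule.max_dose_uM
    if rule.interpolation == "linear_edge":
        edge = rule.edge_at_zero_um + f * (rule.edge_at_max_um - rule.edge_at_zero_um)
    else:
        area = rule.edge_at_zero_um**2 + f * (rule.edge_at_max_um**2 - rule.edge_at_zero_um**2)
        edge = math.sqrt(area)
    n = max(1, int(math.floor(edge / chamber_edge_um + 0.5)))
    return n * chamber_edge_um


# ---------------------------------------------------------------------------
# species catalogue
# ---------------------------------------------------------------------------

#: free ligands and kinase; in Model 2 a fraction of the SFK pool is
#: co-clustered with KIR (species SFK_cl, confined to the cluster region)
#: and the remainder diffuses freely — both pools share identical chemistry
HLA_R, HLA_D, LIG_A, SFK = "HLA_L7R", "HLA_L7D", "LIG_ACT", "SFK"
SFK_CL = "SFK_cl"
#: KIR states: ligand in {none, R, D} x ITIM in {u, p} x SHP-1 bound
KIR, KIR_P, KIR_PS = "KIR", "KIR_p", "KIR_pS"
KIR_R, KIR_RP, KIR_RPS = "KIR_L7R", "KIR_L7R_p", "KIR_L7R_pS"
KIR_D, KIR_DP, KIR_DPS = "KIR_L7D", "KIR_L7D_p", "KIR_L7D_pS"
#: activating receptor states: ligand in {none, L} x ITAM in {u, p} x Zap-70
AR, AR_P, AR_PZ = "AR", "AR_p", "AR_pZ"
AR_L, AR_LP, AR_LPZ = "AR_L", "AR_L_p", "AR_L_pZ"
#: cytosolic pools
SHP1, ZAP70, VAV1, PVAV1 = "SHP1", "ZAP70", "VAV1", "pVAV1"

KIR_STATES = [KIR, KIR_P, KIR_PS, KIR_R, KIR_RP, KIR_RPS, KIR_D, KIR_DP, KIR_DPS]
AR_STATES = [AR, AR_P, AR_PZ, AR_L, AR_LP, AR_LPZ]
MEMBRANE_FREE = [HLA_R, HLA_D, LIG_A, SFK, SFK_CL]
CYTOSOL_SPECIES = [SHP1, ZAP70, VAV1, PVAV1]

OBSERVABLES: dict[str, list[str]] = {
    "pVav1": [PVAV1],
    "Vav1": [VAV1],
    "itim_shp1": [KIR_PS, KIR_RPS, KIR_DPS],
    "pITIM": [KIR_P, KIR_PS, KIR_RP, KIR_RPS, KIR_DP, KIR_DPS],
    "pITAM": [AR_P, AR_PZ, AR_LP, AR_LPZ],
    "itam_zap70": [AR_PZ, AR_LPZ],
    "ligated_KIR": [KIR_R, KIR_RP, KIR_RPS, KIR_D, KIR_DP, KIR_DPS],
}

#: conserved groups (free + bound forms); totals constant over any run
CONSERVED_GROUPS: dict[str, list[str]] = {
    "KIR_total": KIR_STATES,
    "AR_total": AR_STATES,
    "SFK_total": [SFK, SFK_CL],
    "SHP1_total": [SHP1, KIR_PS, KIR_RPS, KIR_DPS],
    "ZAP70_total": [ZAP70, AR_PZ, AR_LPZ],
    "VAV1_total": [VAV1, PVAV1],
    "HLA_L7R_total": [HLA_R, KIR_R, KIR_RP, KIR_RPS],
    "HLA_L7D_total": [HLA_D, KIR_D, KIR_DP, KIR_DPS],
    "LIG_ACT_total": [LIG_A, AR_L, AR_LP, AR_LPZ],
}

REQUIRED_PARAM_KEYS = [
    "geometry.box_edge_um", "geometry.thickness_um", "geometry.chamber_edge_um",
    "geometry.boundary",
    "diffusion.membrane_um2_s", "diffusion.cytosol_um2_s",
    "binding.L7R.KD_uM", "binding.L7R.kon_per_uM_s",
    "binding.L7D.KD_uM", "binding.L7D.kon_per_uM_s",
    "binding.activating.KR_uM", "binding.activating.kon_per_uM_s",
    "rates.sfk_itim_phos_per_uM_s", "rates.sfk_itam_phos_per_uM_s",
    "rates.shp1_on_per_uM_s", "rates.shp1_off_per_s",
    "rates.zap70_on_per_uM_s", "rates.zap70_off_per_s",
    "rates.vav1_phos_per_uM_s", "rates.vav1_dephos_per_uM_s",
    "rates.trans_dephos_per_uM_s", "rates.trans_dephos_radius",
    "rates.basal_itim_dephos_per_s", "rates.basal_itam_dephos_per_s",
    "rates.basal_pvav1_decay_per_s",
    "copy_numbers.KIR", "copy_numbers.SFK", "copy_numbers.AR",
    "copy_numbers.SHP1", "copy_numbers.ZAP70", "copy_numbers.VAV1",
    "doses.activating_ligand_uM", "doses.mixture_total_uM",
    "cluster.edge_at_zero_um", "cluster.edge_at_max_um", "cluster.max_dose_uM",
    "cluster.interpolation", "cluster.confined", "cluster.sfk_cluster_fraction",
]


class MissingParameterError(KeyError):
    def __init__(self, keys):
        self.keys = list(keys)
        super().__init__(f"missing parameter keys: {', '.join(self.keys)}")


def _get(params: dict, dotted: str):
    node = params
    for part in dotted.split("."):
        if not isinstance(node, dict) or part not in node:
            raise MissingParameterError([dotted])
        node = node[part]
    return node


def validate_params(params: dict) -> None:
    missing = []
    for key in REQUIRED_PARAM_KEYS:
        try:
            _get(params, key)
        except MissingParameterError:
            missing.append(key)
    if missing:
        raise MissingParameterError(missing)


def species_catalog(params: dict) -> list[SpeciesSpec]:
    d_mem = _get(params, "diffusion.membrane_um2_s")
    d_cyt = _get(params, "diffusion.cytosol_um2_s")
    out = []
    # cytosolic pools first: their hops dominate the event stream and the
    # kernel's within-chamber scan terminates earliest for low indices
    for name in CYTOSOL_SPECIES:
        out.append(SpeciesSpec(name=name, compartment=Compartment.CYTOSOL,
                               diffusion_um2_s=d_cyt))
    for name in MEMBRANE_FREE + KIR_STATES + AR_STATES:
        out.append(SpeciesSpec(name=name, compartment=Compartment.MEMBRANE,
                               diffusion_um2_s=d_mem))
    return out


def reaction_network(variant: ModelVariant | Variant, params: dict) -> list[ReactionSpec]:
    """The full mass-action network; Model 1 appends the trans channel.

    Every channel other than the trans-acting dephosphorylation is strictly
    same-chamber.  Reactions 1-9 of the canonical network are identical
    between the variants.
    """
    if isinstance(variant, Variant):
        variant = ModelVariant(variant)
    validate_params(params)
    kR = kd_to_rate_pair(_get(params, "binding.L7R.KD_uM"),
                         _get(params, "binding.L7R.kon_per_uM_s"))
    kD = kd_to_rate_pair(_get(params, "binding.L7D.KD_uM"),
                         _get(params, "binding.L7D.kon_per_uM_s"))
    kA = kd_to_rate_pair(_get(params, "binding.activating.KR_uM"),
                         _get(params, "binding.activating.kon_per_uM_s"))
    r = params["rates"]

    rx: list[ReactionSpec] = []

    def add(name, reactants, products, rate, locality=Locality.SAME_CHAMBER):
        rx.append(ReactionSpec(name=name,
                               reactants=tuple((s, 1) for s in reactants),
                               products=tuple((s, 1) for s in products),
                               rate=rate, locality=locality))

    # (1)-(2) KIR ligation by HLA:L7R / HLA:L7D, any ITIM/SHP-1 state
    for lig, kb, states in (
        (HLA_R, kR, [(KIR, KIR_R), (KIR_P, KIR_RP), (KIR_PS, KIR_RPS)]),
        (HLA_D, kD, [(KIR, KIR_D), (KIR_P, KIR_DP), (KIR_PS, KIR_DPS)]),
    ):
        for free, bound in states:
            add(f"bind:{lig}+{free}", [free, lig], [bound], kb.k_on)
            add(f"unbind:{bound}", [bound], [free, lig], kb.k_off)
    # (3) SFK phosphorylates the ITIM of ligated KIR (both kinase pools)
    for kin in (SFK, SFK_CL):
        add(f"phos:ITIM(L7R):{kin}", [kin, KIR_R], [kin, KIR_RP], r["sfk_itim_phos_per_uM_s"])
        add(f"phos:ITIM(L7D):{kin}", [kin, KIR_D], [kin, KIR_DP], r["sfk_itim_phos_per_uM_s"])
    # basal pITIM dephosphorylation (SHP-1-free states only)
    for p, u in ((KIR_P, KIR), (KIR_RP, KIR_R), (KIR_DP, KIR_D)):
        add(f"basal_dephos:{p}", [p], [u], r["basal_itim_dephos_per_s"])
    # (4) SHP-1 recruitment to phospho-ITIMs
    for p, ps in ((KIR_P, KIR_PS), (KIR_RP, KIR_RPS), (KIR_DP, KIR_DPS)):
        add(f"shp1_on:{p}", [SHP1, p], [ps], r["shp1_on_per_uM_s"])
        add(f"shp1_off:{ps}", [ps], [SHP1, p], r["shp1_off_per_s"])
    # (5) ITIM-bound SHP-1 dephosphorylates pVav1
    for ps in (KIR_PS, KIR_RPS, KIR_DPS):
        add(f"vav_dephos:{ps}", [ps, PVAV1], [ps, VAV1], r["vav1_dephos_per_uM_s"])
    # (10) Model 1 only: antagonist-complex SHP-1 dephosphorylates
    # neighbouring phospho-ITIMs of ligated KIR
    if variant.trans_dephos_reaction:
        for p, u in ((KIR_RP, KIR_R), (KIR_DP, KIR_D)):
            add(f"trans_dephos:{p}", [KIR_DPS, p], [KIR_DPS, u],
                r["trans_dephos_per_uM_s"], locality=Locality.NEIGHBOR_CHAMBER)
    # (6) activating receptor ligation (affinity K_R)
    for free, bound in ((AR, AR_L), (AR_P, AR_LP), (AR_PZ, AR_LPZ)):
        add(f"bind:{LIG_A}+{free}", [free, LIG_A], [bound], kA.k_on)
        add(f"unbind:{bound}", [bound], [free, LIG_A], kA.k_off)
    # (7) SFK phosphorylates the ITAM of ligated AR (both kinase pools)
    for kin in (SFK, SFK_CL):
        add(f"phos:ITAM:{kin}", [kin, AR_L], [kin, AR_LP], r["sfk_itam_phos_per_uM_s"])
    for p, u in ((AR_P, AR), (AR_LP, AR_L)):
        add(f"basal_dephos:{p}", [p], [u], r["basal_itam_dephos_per_s"])
    # (8) Zap-70 docking on phospho-ITAMs
    for p, pz in ((AR_LP, AR_LPZ), (AR_P, AR_PZ)):
        add(f"zap_on:{p}", [ZAP70, p], [pz], r["zap70_on_per_uM_s"])
        add(f"zap_off:{pz}", [pz], [ZAP70, p], r["zap70_off_per_s"])
    # (9) ITAM-bound Zap-70 phosphorylates Vav1
    for pz in (AR_LPZ, AR_PZ):
        add(f"vav_phos:{pz}", [pz, VAV1], [pz, PVAV1], r["vav1_phos_per_uM_s"])
    # basal pVav1 decay
    add("basal_decay:pVav1", [PVAV1], [VAV1], r["basal_pvav1_decay_per_s"])
    return rx


# ---------------------------------------------------------------------------
# initial state
# ---------------------------------------------------------------------------

def _distribute(n: int, chambers: np.ndarray, counts: np.ndarray, s: int,
                rng: np.random.Generator) -> None:
    """Spread n molecules evenly over ``chambers``; the remainder goes to a
    seeded uniform draw of chambers without replacement."""
    m = len(chambers)
    base, rem = divmod(int(n), m)
    if base:
        counts[chambers, s] += base
    if rem:
        extra = rng.choice(chambers, size=rem, replace=False)
        counts[extra, s] += 1


def geometry_from_params(params: dict) -> LatticeGeometry:
    return LatticeGeometry(
        box_edge_um=_get(params, "geometry.box_edge_um"),
        box_thickness_um=_get(params, "geometry.thickness_um"),
        chamber_edge_um=_get(params, "geometry.chamber_edge_um"),
        boundary=Boundary(_get(params, "geometry.boundary")),
    )


def rule_from_params(params: dict) -> ClusterScalingRule:
    return ClusterScalingRule(
        edge_at_zero_um=_get(params, "cluster.edge_at_zero_um"),
        edge_at_max_um=_get(params, "cluster.edge_at_max_um"),
        max_dose_uM=_get(params, "cluster.max_dose_uM"),
        interpolation=_get(params, "cluster.interpolation"),
    )


def initial_state(variant: ModelVariant | Variant, doses: PeptideDose,
                  rule: ClusterScalingRule, lattice: Lattice, params: dict,
                  seed: int = 0) -> tuple[np.ndarray, dict[str, np.ndarray], float]:
    """Initial per-chamber counts, confinement masks and the cluster edge.

    KIR (total count constant across doses) are spread uniformly over the
    cluster region set by the antagonist dose; in Model 2 the SFK pool is
    placed in (and confined to) the same region, in Model 1 it is uniform
    over the lattice.  Ligands, the activating receptor and the cytosolic
    pools are uniform; pVav1 starts at zero.
    """
    if isinstance(variant, Variant):
        variant = ModelVariant(variant)
    validate_params(params)
    g = lattice.geometry
    C = lattice.n_chambers
    species = species_catalog(params)
    names = [sp.name for sp in species]
    idx = {n: i for i, n in enumerate(names)}
    counts = np.zeros((C, len(names)), dtype=np.int64)
    # independent stream per species so remainder placement of one pool
    # does not depend on how the others were drawn
    rng_for = lambda name: np.random.default_rng((seed, idx[name]))

    vol = VolumeContext.from_geometry(g.chamber_edge_um, C)
    edge = cluster_edge_for_dose(doses.L7D_uM, rule, g.chamber_edge_um)
    region = region_chambers(lattice, edge)
    all_chambers = np.arange(C)

    n_R = concentration_to_count(doses.L7R_uM, vol.box_volume_l)
    n_D = concentration_to_count(doses.L7D_uM, vol.box_volume_l)
    n_A = concentration_to_count(_get(params, "doses.activating_ligand_uM"), vol.box_volume_l)
    _distribute(n_R, all_chambers, counts, idx[HLA_R], rng_for(HLA_R))
    _distribute(n_D, all_chambers, counts, idx[HLA_D], rng_for(HLA_D))
    _distribute(n_A, all_chambers, counts, idx[LIG_A], rng_for(LIG_A))

    cn = params["copy_numbers"]
    _distribute(cn["KIR"], region, counts, idx[KIR], rng_for(KIR))
    if variant.sfk_coclustered:
        frac = _get(params, "cluster.sfk_cluster_fraction")
        n_cl = int(math.floor(frac * cn["SFK"] + 0.5))
        _distribute(n_cl, region, counts, idx[SFK_CL], rng_for(SFK_CL))
        _distribute(cn["SFK"] - n_cl, all_chambers, counts, idx[SFK], rng_for(SFK))
    else:
        _distribute(cn["SFK"], all_chambers, counts, idx[SFK], rng_for(SFK))
    _distribute(cn["AR"], all_chambers, counts, idx[AR], rng_for(AR))
    for name in (SHP1, ZAP70, VAV1):
        _distribute(cn[name], all_chambers, counts, idx[name], rng_for(name))
    # pVav1 starts at 0

    confinement: dict[str, np.ndarray] = {}
    if _get(params, "cluster.confined"):
        mask = np.zeros(C, dtype=bool)
        mask[region] = True
        for name in KIR_STATES:
            confinement[name] = mask
        if variant.sfk_coclustered:
            confinement[SFK_CL] = mask
    return counts, confinement, edge


def build_model(variant: ModelVariant | Variant, doses: PeptideDose,
                rule: ClusterScalingRule | None = None,
                params: dict | None = None, seed: int = 0) -> Model:
    """Assemble the complete, validated :class:`~nksig.engine.Model`."""
    if params is None:
        raise MissingParameterError(REQUIRED_PARAM_KEYS)
    if isinstance(variant, Variant):
        variant = ModelVariant(variant)
    validate_params(params)
    if rule is None:
        rule = rule_from_params(params)
    lattice = build_lattice(geometry_from_params(params))
    counts, confinement, edge = initial_state(variant, doses, rule, lattice, params, seed)
    model = Model(
        lattice=lattice,
        species=species_catalog(params),
        reactions=reaction_network(variant, params),
        initial_counts=counts,
        confinement=confinement,
        trans_radius=int(_get(params, "rates.trans_dephos_radius")),
        metadata={
            "variant": variant.variant.value,
            "mode": doses.mode.value,
            "dose_L7R_uM": doses.L7R_uM,
            "dose_L7D_uM": doses.L7D_uM,
            "cluster_edge_um": edge,
        },
        observables=dict(OBSERVABLES),
    )
    model.validate()
    return model
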