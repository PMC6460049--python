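# Methods

`nksig` simulates membrane-proximal signaling of an NK cell whose
inhibitory KIR2DL2/3 receptors are stimulated by HLA-C presenting either
a strongly inhibitory peptide (L7R) or a weak antagonist peptide (L7D),
alongside a constitutively engaged, unspecified activating receptor.
The package exists to ask one question in silico: when the two peptides
are mixed, does inhibition collapse ("peptide antagonism"), and is the
collapse driven by a biochemical feedback or by the dilution of tight
receptor/kinase co-clusters?

## Reaction network

Both model variants share a canonical signal-integration core (all
mass-action):

1. `KIR + HLA:L7R <-> KIR.L7R` with K_D = 0.8 uM, and
   `KIR + HLA:L7D <-> KIR.L7D` with K_D = 4.4 uM (both printed values;
   absolute on-rates are not published, so k_on = 1 /uM/s for both and
   k_off = K_D * k_on).
2. Src-family kinases (SFK) phosphorylate the ITIM of *ligated* KIR.
   ITIMs are strictly two-state (unphosphorylated / phosphorylated).
3. Phospho-ITIMs reversibly recruit cytosolic SHP-1; ITIM-bound SHP-1
   dephosphorylates pVav1.
4. The activating receptor (AR) binds its ligand with K_R = 5 uM; SFK
   phosphorylate the ITAM of ligated AR; phospho-ITAMs dock Zap-70;
   ITAM-bound Zap-70 phosphorylates Vav1.  Lattice-total pVav1 is the
   activation readout.
5. Slow basal dephosphorylation of pITIM and pITAM and basal pVav1 decay
   close the cycles; without them the phosphorylation arms would have
   absorbing states and "steady state" would be degenerate.

The variants differ in exactly two respects:

* **Model 1** adds a trans-acting channel — SHP-1 riding on
  *antagonist*-ligated KIR dephosphorylates phospho-ITIMs of ligated KIR
  in the same chamber or (at fine resolution) its four lateral
  neighbours — and leaves SFK spatially uniform.
* **Model 2** omits that channel and instead co-clusters SFK with KIR
  inside the imposed microcluster.

## Spatial representation

The synapse contact patch is a single-layer subvolume lattice (box
L x L x h = 2 x 2 x 0.02 um at the reference geometry, cubic chambers of
edge l).  Membrane and cytosolic molecules co-reside in each chamber and
differ only in their diffusion coefficient (0.01 vs 10 um^2/s at the
reference scale).  Diffusion is a first-order hop to each lateral
neighbour at rate D/l^2; boundaries reflect (the box is a finite contact
patch; periodic boundaries are a config option).  Chemistry is exact
Gillespie within chambers.

KIR sit in a preformed square microcluster at the box centre
(0.2 x 0.2 um^2 when no antagonist is present).  As the antagonist dose
rises, the cluster edge grows linearly to 1.0 um at 12.5 uM while total
copy numbers stay fixed, so density falls; the cluster is insensitive to
the inhibitory-peptide dose.  Setting the two edges equal gives the
fixed-cluster control.  Edges snap to whole chambers.

**Cluster maintenance.** The microcluster is imposed, not emergent, and
it must persist for the 15-minute run: free membrane diffusion would
erase any initial placement within ~L^2/4D = 100 s, long before the 5-15
min readout window, leaving the two variants indistinguishable at steady
state.  Clustered species (all KIR states and, in Model 2, the
co-clustered SFK pool) therefore diffuse freely *within* the cluster
region but do not leave it — a "preformed, maintained" cluster whose
size is set per dose by the scaling rule.  No molecular mechanism for
the maintenance is modeled.

**Partial SFK co-clustering.** Model 2 co-clusters a fraction (default
0.6) of the SFK pool with KIR and leaves the rest uniform.  Complete
sequestration would leave zero kinase outside a cluster occupying ~1% of
the contact area, collapsing ITAM phosphorylation of the uniformly
distributed activating receptors and with it the activation readout;
with partial co-clustering the uniform pool sustains a
variant-insensitive activating arm (zero-dose pVav1 agrees between
variants to within a few percent) while the clustered pool still
dominates the local kinase density at the KIR cluster (38x bulk when
tight), which is the dilution-sensitive quantity that drives antagonism
in Model 2.

## Parameters

Printed, fixed inputs: box geometry; chamber edge; D_membrane = 0.01 and
D_cytosol = 10 um^2/s; K_D = 0.8 uM (L7R) and 4.4 uM (L7D); K_R = 5 uM;
tight-cluster edge 0.2 um; mixture total 12.5 uM; 15-min runs with the
5-15 min steady-state window.

All remaining constants (copy numbers, catalytic and binding rates,
basal rates, activating-ligand dose, maximum cluster edge) are
documented stand-ins, tagged `default-unpublished` in the parameter
file.  They were chosen, using a deterministic two-compartment
(cluster/bulk) mass-action sketch followed by small stochastic pilots,
to place the model in the regime the biology describes:

* single-peptide IC50 inside the 0-12.5 uM grid (occupancy alone puts
  most of the response below ~2.5 uM given K_D = 0.8 uM);
* the activating arm alone holds ~240 pVav1 molecules of 300 total Vav1
  (well above shot noise; the most inhibited condition keeps >100);
* ITIM phosphorylation near saturation in the tight Model 2 cluster and
  a factor ~14 below it at full dilution, so cluster growth moves the
  system across the responsive part of the curve;
* the trans-dephosphorylation constant (0.015 /uM/s) large enough that a
  frozen tight cluster lets Model 1 antagonize, yet small enough that
  the growing-cluster default keeps Model 1's mixed-mode curve at or
  below its single-mode curve;
* pVav1 phosphorylation/dephosphorylation turnover fast enough
  (relaxation ~3 s) that the trajectory settles within ~40 s and a 60 s
  running mean fluctuates by well under the +/-10% settling band.

Defaults live in `nksig.config.default_parameters()`; every key carries
a provenance tag and any YAML override flips the tag to `user`.

## Desk-scale profile

The reference geometry (10,000 chambers, cytosolic hop rate 25,000 /s
per molecule) is far too expensive for routine desk use, so all shipped
experiments run on a documented coarse profile
(`nksig.config.desk_scale()`): chamber edge 0.25 um (8 x 8 x 1
chambers), which preserves the cluster-to-box area ratios (tight cluster
= 1 chamber ~ 1.6% of the box; maximal cluster = 25%, as at fine
scale).  Three consequences are handled explicitly:

* Coarsening the chamber inflates the box volume (thickness = chamber
  edge).  Dosed ligand copy numbers scale with the volume, which leaves
  their count-space binding fluxes invariant; bimolecular constants
  *between copy-number pools* are instead rescaled by the volume ratio
  so that count-level fluxes match the reference condition.
* The trans-acting channel becomes same-chamber only: one coarse chamber
  already spans more than the fine-scale neighbourhood.
* Cytosolic diffusion is reduced to 0.75 um^2/s — still 75x the
  membrane coefficient, with box-scale cytosolic mixing (~1.3 s) far
  faster than every reaction timescale — to bound the event rate.

What the profile does not preserve: sub-cluster spatial detail, and
local-depletion corrections where a concentrated sink competes with
hop-in supply (the tight cluster depletes chamber-local pVav1 by ~30%
at the default rates; this is the main reason the shipped defaults keep
the Vav cycle moderate rather than very fast).  The acceptance
diffusion and affinity checks run at the printed fine-scale coefficients
and are unaffected by the profile.

Problem sizes used by the shipped experiments: 64 chambers, ~11,500
molecules (dose-dependent), 900 simulated seconds per run, 7-point dose
grid, 10 replicates per dose, ~2 x 10^7 events per run.

## Stochastic engine

The production sampler is a chamber-indexed direct method: one exact
event loop over the whole lattice with chamber totals in a binary sum
tree (O(log C) selection/update) and per-chamber channel propensities
maintained incrementally through a precomputed species-to-channel
adjacency, compiled with numba.  A plain pure-Python direct method is
retained as an in-law reference; both are exact samplers of the same
spatial chemical master equation and their agreement is asserted on
tiny instances against an enumerated master-equation solution.
Propensities are recomputed from counts at every update (cached values
are replaced, not accumulated), and the tree is rebuilt every 4 x 10^6
events to stop float drift; a mismatch between cached and freshly
scanned propensities triggers an immediate rebuild instead of an event.
Trajectories are bit-reproducible from the seed; replicate r of dose i
uses seed base + 131 i + r, shared across stimulation modes and
variants so mode contrasts are paired (common random numbers).

## Validation oracles

All oracles avoid the engine's propensity/stepping code:

* mass-action ODE of the collapsed (single-chamber) model via scipy
  LSODA — used for high-copy-number mean checks and the binding
  occupancy analytics;
* exact stationary distributions of tiny models by enumerating the
  reachable state space and solving pi Q = 0 — compared to sampled
  engine distributions by total variation distance;
* tracer mean-squared displacement on a periodic box, D_eff = slope/4
  by least squares through the origin — recovers both printed diffusion
  coefficients within 10%;
* SSA binding titrations fitted with d/(d+K) — recover both printed
  K_Ds within 10% (the hyperbolic fit avoids the bias of reading the
  half-maximum off a saturating grid).

## Readouts and statistics

Steady state is the time average over 5-15 simulated minutes (fixed
regardless of lattice scale).  The settling time is the earliest time
after which a centred 60 s running mean stays within +/-10% of that
average; a path that still leaves the band inside the window reports a
"not settled" sentinel, which the dose-response curve retains as
replicate metadata.  Per dose, the replicate *median* settling time is
the estimator of the system's relaxation — the median is robust to the
occasional single-path noise excursion late in the window, which the
running-mean detector otherwise misreads as late settling.

Antagonism is declared when mixed-mode steady-state pVav1 exceeds the
single-mode value at matched inhibitory dose with a one-sided paired-t
confidence interval excluding zero at two or more consecutive grid
doses.  The SHP-1 recruitment contrasts are pooled one-sided paired
tests at 1.25-5 uM — the doses where the antagonist occupies an
appreciable fraction of KIR, which is where the recruitment signature
lives (at high inhibitory dose the antagonist share of the mixture
vanishes by construction).

## Synthetic fixtures

`nksig.config.synthetic_trajectory` generates constant, exponential-
relaxation and ramp trajectories with seeded Gaussian sampling noise and
known window means and settling times, so the summary statistics are
testable against closed forms without the engine.  These fixtures mimic
only the *shape* of trajectories; they carry no chemistry.

## Limitations

* Every unpublished constant is a stand-in; the experiment's phenotypes
  are qualitative contrasts, not quantitative predictions, and the
  package's tests certify exactly those contrasts under the documented
  defaults (they were verified to survive a small perturbation probe of
  the trans-dephosphorylation constant, the dominant free knob).
* Cluster geometry is imposed and maintained by fiat; no mechanism of
  cluster formation, growth or peptide-dependent remodeling is modeled.
* Concentrations use the thin 3-D box volume; no 2-D/3-D affinity
  (confinement) corrections are applied.
* Peptide loading and decay on HLA-C, receptor identity of the
  activating arm, and any downstream signaling beyond pVav1 are out of
  scope.
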