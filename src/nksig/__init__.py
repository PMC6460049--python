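"""nksig: spatial stochastic simulation of NK-cell inhibitory KIR signaling.

Exact Gillespie reaction-diffusion on a subvolume lattice, the two
competing KIR/SFK microcluster model variants, and the dose-response
pipeline that probes peptide antagonism (mixed inhibitory + antagonist
stimulation versus single inhibitory stimulation, read out as steady-state
pVav1).
"""

from .engine import (
    ChamberState,
    CompiledModel,
    InvariantViolation,
    Model,
    ReactionSpec,
    SpeciesSpec,
    Trajectory,
    propensity,
    reference_simulate,
    simulate,
    ssa_step,
)
from .lattice import (
    Boundary,
    GeometryError,
    Lattice,
    LatticeGeometry,
    build_lattice,
    diffusion_hop_rate,
    region_chambers,
)
from .model import (
    ClusterScalingRule,
    ModelVariant,
    PeptideDose,
    StimulationMode,
    Variant,
    build_model,
    cluster_edge_for_dose,
    initial_state,
    reaction_network,
)
from .units import (
    AVOGADRO,
    BindingParams,
    VolumeContext,
    bimolecular_to_stochastic,
    concentration_to_count,
    count_to_concentration,
    kd_to_rate_pair,
)

__version__ = "0.1.0"


def __getattr__(name):
    # pipeline/config/oracles pull in scipy and yaml; import lazily so the
    # core engine stays light to import
    import importlib

    for mod in ("pipeline", "config", "oracles"):
        module = importlib.import_module(f".{mod}", __name__)
        if hasattr(module, name):
            return getattr(module, name)
    raise AttributeError(name)
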