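import numpy as np
import pytest

from nksig.config import default_parameters, desk_scale
from nksig.model import ClusterScalingRule, Variant
from nksig.pipeline import DoseGrid, run_dose_series


@pytest.fixture(scope="session")
def reference_params():
    """Defaults at the published fine box geometry (not simulated at this scale)."""
    return default_parameters()


@pytest.fixture(scope="session")
def desk_params():
    """Desk-scale simulation profile used for all production runs."""
    return desk_scale()


@pytest.fixture(scope="session")
def sweep_cache(desk_params):
    """The full in-silico experiment, shared by every phenotype assertion:

    single- and mixed-mode dose-response curves for both model variants at
    the default (growing-cluster) rule, plus the Model 1 mixed-mode curve
    with the cluster frozen at its tight size.  10 replicates per dose with
    seeds shared across conditions, so mode contrasts are paired.
    """
    p = desk_params.values
    curves = {}
    for variant in (Variant.MODEL1, Variant.MODEL2):
        grid = DoseGrid(mode="single", replicates=10, seed_base=0)
        single = run_dose_series(variant, "single", grid, p)
        curves[(variant.value, "single")] = single
        grid = DoseGrid(mode="mixed", replicates=10, seed_base=0)
        curves[(variant.value, "mixed")] = run_dose_series(
            variant, "mixed", grid, p, reuse_top_dose_from=single)
    grid = DoseGrid(mode="mixed", replicates=10, seed_base=0)
    curves[("model1", "mixed", "fixed")] = run_dose_series(
        Variant.MODEL1, "mixed", grid, p, rule=ClusterScalingRule.fixed(0.2),
        reuse_top_dose_from=curves[("model1", "single")])
    try:  # diagnostic dump; harmless if the tree is read-only
        import pathlib
        d = pathlib.Path(__file__).resolve().parent.parent / "scratch" / "sweeps"
        d.mkdir(parents=True, exist_ok=True)
        for key, curve in curves.items():
            curve.write_csv(d / ("_".join(key) + ".csv"))
    except OSError:
        pass
    return curves
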