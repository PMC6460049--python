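"""Unit conversions between experimental and per-chamber stochastic quantities.

All bulk quantities in the model are expressed in experimental units
(micromolar concentrations, second-order rate constants in 1/(uM*s)),
while the stochastic engine works with integer molecule counts per
subvolume ("chamber") and per-pair event rates in 1/s.  The conversions
here are the single authoritative bridge between the two descriptions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

AVOGADRO = 6.02214076e23  # 1/mol (CODATA 2018 exact)

#: litres per cubic micrometre
LITRE_PER_UM3 = 1e-15


def um3_to_litres(v_um3: float) -> float:
    """Convert a volume in um^3 to litres."""
    return v_um3 * LITRE_PER_UM3


@dataclass(frozen=True)
class VolumeContext:
    """Volumes needed to convert concentrations and bimolecular rates.

    Attributes
    ----------
    chamber_volume_l : float
        Volume of one cubic chamber, litres (= l^3 converted).
    box_volume_l : float
        Total simulation-box volume, litres.
    """

    chamber_volume_l: float
    box_volume_l: float
    avogadro: float = AVOGADRO

    @classmethod
    def from_geometry(cls, chamber_edge_um: float, n_chambers: int) -> "VolumeContext":
        v_ch = um3_to_litres(chamber_edge_um**3)
        return cls(chamber_volume_l=v_ch, box_volume_l=v_ch * n_chambers)


@dataclass(frozen=True)
class BindingParams:
    """Reversible binding parameters with the invariant K_D = k_off / k_on."""

    k_on: float  # 1/(uM s)
    k_off: float  # 1/s

    @property
    def K_D(self) -> float:
        return self.k_off / self.k_on


def concentration_to_count(c_uM: float, volume_l: float) -> int:
    """Convert a concentration (uM) to an integer molecule count in ``volume_l``.

    Rounding is round-half-up (0.5 always rounds away from zero), applied
    once at initialisation; this is the documented quantisation rule for
    all dose -> copy-number conversions.
    """
    if c_uM < 0:
        raise ValueError(f"negative concentration: {c_uM}")
    if volume_l <= 0:
        raise ValueError(f"non-positive volume: {volume_l}")
    exact = c_uM * 1e-6 * AVOGADRO * volume_l
    return int(math.floor(exact + 0.5))


def count_to_concentration(n: int, volume_l: float) -> float:
    """Inverse of :func:`concentration_to_count` up to one-molecule quantisation."""
    if n < 0:
        raise ValueError(f"negative count: {n}")
    if volume_l <= 0:
        raise ValueError(f"non-positive volume: {volume_l}")
    return n / (1e-6 * AVOGADRO * volume_l)


def bimolecular_to_stochastic(k2_per_uM_s: float, chamber_volume_l: float) -> float:
    """Convert a second-order rate constant to a per-reactant-pair rate (1/s).

    For a chamber of volume V the stochastic rate is k2 * 1e6 / (N_A * V),
    such that rate * n_A * n_B reproduces the mass-action flux at the
    chamber's local concentrations.
    """
    if k2_per_uM_s < 0:
        raise ValueError(f"negative rate constant: {k2_per_uM_s}")
    if chamber_volume_l <= 0:
        raise ValueError(f"non-positive chamber volume: {chamber_volume_l}")
    return k2_per_uM_s * 1e6 / (AVOGADRO * chamber_volume_l)


def kd_to_rate_pair(K_D_uM: float, k_on_per_uM_s: float) -> BindingParams:
    """Resolve (K_D, k_on) into a :class:`BindingParams` with k_off = K_D * k_on."""
    if K_D_uM <= 0:
        raise ValueError(f"non-positive K_D: {K_D_uM}")
    if k_on_per_uM_s <= 0:
        raise ValueError(f"non-positive k_on: {k_on_per_uM_s}")
    return BindingParams(k_on=k_on_per_uM_s, k_off=K_D_uM * k_on_per_uM_s)
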