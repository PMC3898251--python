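"""Torsional energy function for candidate disulfide bonds.

The score is a geometry-conformity measure, not a free energy: it ranks
how closely a modelled bridge matches the torsion angles and bond angles
observed in native disulfides. The chi3 term has its minima at the two
peaks of the native chi3 distribution, -87 and about +97 degrees; the
chi1 term is a threefold cosine with minima at the staggered rotamers
(-60, +60, 180 degrees); the CB-SG-SG' bond angles carry a harmonic
strain term. All terms are non-negative, so a perfect native-like
geometry scores exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

__all__ = ["EnergyParams", "e_chi3", "e_chi1", "e_angle", "total_energy", "energy_breakdown"]


@dataclass(frozen=True)
class EnergyParams:
    """Constants of the disulfide energy function.

    Attributes
    ----------
    a3 : amplitude of the chi3 torsion term (kcal/mol).
    k3 : periodicity factor of the chi3 term (dimensionless); with the
        default 1.957 the two minima per turn fall at -87 and +96.96 deg.
    phi3 : phase offset of the chi3 term (deg).
    a1 : amplitude of the threefold chi1 rotamer term (kcal/mol).
    k_theta : harmonic force constant on the CB-SG-SG' angles
        (kcal/mol/deg^2).
    theta0 : ideal CB-SG-SG' angle (deg).
    """

    a3: float = 4.0
    k3: float = 1.957
    phi3: float = 87.0
    a1: float = 1.4
    k_theta: float = 0.015
    theta0: float = 104.9

    def __post_init__(self) -> None:
        if self.a3 < 0 or self.a1 < 0 or self.k_theta < 0:
            raise ValueError("energy amplitudes must be non-negative")


def e_chi3(chi3, params: EnergyParams = EnergyParams()):
    """Chi3 torsion energy: a3 * (1 - cos(k3 * (chi3 + phi3))), degrees in."""
    chi3 = np.asarray(chi3, dtype=float)
    e = params.a3 * (1.0 - np.cos(np.radians(params.k3 * (chi3 + params.phi3))))
    return float(e) if e.ndim == 0 else e


def e_chi1(chi1, params: EnergyParams = EnergyParams()):
    """Threefold chi1 rotamer energy: a1 * (1 + cos(3 * chi1)); zero at +/-60, 180."""
    chi1 = np.asarray(chi1, dtype=float)
    e = params.a1 * (1.0 + np.cos(np.radians(3.0 * chi1)))
    return float(e) if e.ndim == 0 else e


def e_angle(theta, params: EnergyParams = EnergyParams()):
    """Harmonic CB-SG-SG' angle strain: k_theta * (theta - theta0)^2."""
    theta = np.asarray(theta, dtype=float)
    e = params.k_theta * (theta - params.theta0) ** 2
    return float(e) if e.ndim == 0 else e


def total_energy(
    chi1_a, chi1_b, chi3, theta_a, theta_b, params: EnergyParams = EnergyParams()
):
    """Sum of the chi1, chi1', chi3 and both angle-strain terms."""
    return (
        e_chi1(chi1_a, params)
        + e_chi1(chi1_b, params)
        + e_chi3(chi3, params)
        + e_angle(theta_a, params)
        + e_angle(theta_b, params)
    )


def energy_breakdown(
    chi1_a: float,
    chi1_b: float,
    chi3: float,
    theta_a: float,
    theta_b: float,
    params: EnergyParams = EnergyParams(),
) -> Dict[str, float]:
    """Per-term energies plus their total, as a plain dict."""
    terms = {
        "e_chi1_a": e_chi1(chi1_a, params),
        "e_chi1_b": e_chi1(chi1_b, params),
        "e_chi3": e_chi3(chi3, params),
        "e_angle_a": e_angle(theta_a, params),
        "e_angle_b": e_angle(theta_b, params),
    }
    terms["total"] = sum(terms.values())
    return terms
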