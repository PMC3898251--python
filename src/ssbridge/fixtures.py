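"""Deterministic synthetic test structures with exact geometric ground truth.

A bridge fixture is built by inverse kinematics: the disulfide core
(SG-SG, both CB, both CA/N) is laid down so that the requested chi1,
chi1' and chi3 torsions, the ideal S-S bond length and the ideal
CB-SG-SG' angles hold exactly, then short extended-conformation alanine
stubs are grown from both cysteines so that C-beta reconstruction and
B-factor averaging see realistic neighbours. These are geometric ground
truth objects, not physically realistic decoys.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .geometry import IdealParams, construct_cbeta, dihedral, place_atom
from .pdbio import AtomRecord, Residue, StructureModel, write_pdb

__all__ = ["BridgeSpec", "build_ideal_bridge", "build_multimodel",
           "build_survey_set"]

# standard backbone covalent geometry
D_N_CA = 1.458
D_CA_C = 1.525
D_C_N = 1.329
D_C_O = 1.231
ANG_N_CA_C = 111.0
ANG_CA_C_N = 116.2
ANG_C_N_CA = 121.7
ANG_CA_C_O = 120.5

PHI_EXT = -140.0
PSI_EXT = 135.0
OMEGA = 180.0


@dataclass(frozen=True)
class BridgeSpec:
    """Ground-truth parameters of one planted disulfide bridge."""

    chi3: float = -87.0
    chi1_a: float = -60.0
    chi1_b: float = -60.0
    chi2_a: float = -60.0
    chi2_b: float = -60.0
    flank_len: int = 3
    noise_sigma: float = 0.0
    seed: int = 0
    bfactor_plan: str = "constant"  # constant | gradient
    resolution: float = 1.5

    def __post_init__(self) -> None:
        if self.flank_len < 0:
            raise ValueError("flank_len must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.bfactor_plan not in ("constant", "gradient"):
            raise ValueError("bfactor_plan must be 'constant' or 'gradient'")


def _place_carbonyl_c(sg, cb, ca, n, chi1: float) -> np.ndarray:
    """Place the backbone C so that CB sits on the L-amino-acid side."""
    for delta in (122.5, -122.5):
        c = place_atom(sg, cb, ca, D_CA_C, IdealParams().ang_n_ca_cb, chi1 + delta)
        if dihedral(n, ca, c, cb) > 0:
            return c
    raise RuntimeError("could not satisfy L-chirality")  # pragma: no cover


def _extend_forward(n, ca, c, phi: float, psi_next: float):
    """Grow the next residue's backbone; returns (N', CA', C') and its O."""
    n1 = place_atom(n, ca, c, D_C_N, ANG_CA_C_N, psi_next)
    ca1 = place_atom(ca, c, n1, D_N_CA, ANG_C_N_CA, OMEGA)
    c1 = place_atom(c, n1, ca1, D_CA_C, ANG_N_CA_C, phi)
    return n1, ca1, c1


def _extend_backward(n, ca, c, phi: float, psi_prev: float):
    """Grow the previous residue's backbone; returns (N0, CA0, C0)."""
    c0 = place_atom(c, ca, n, D_C_N, ANG_C_N_CA, phi)
    ca0 = place_atom(ca, n, c0, D_CA_C, ANG_CA_C_N, OMEGA)
    n0 = place_atom(n, c0, ca0, D_N_CA, ANG_N_CA_C, psi_prev)
    return n0, ca0, c0


def _carbonyl_o(n, ca, c, psi: float) -> np.ndarray:
    return place_atom(n, ca, c, D_C_O, ANG_CA_C_O, psi + 180.0)


def _ala_residue(chain: str, seq: int, n, ca, c, o, ideal: IdealParams) -> Residue:
    cb = construct_cbeta(n, ca, c, ideal)
    atoms = [
        AtomRecord("N", "N", np.asarray(n, float), 10.0, 1.0),
        AtomRecord("CA", "C", np.asarray(ca, float), 10.0, 1.0),
        AtomRecord("C", "C", np.asarray(c, float), 10.0, 1.0),
        AtomRecord("O", "O", np.asarray(o, float), 10.0, 1.0),
        AtomRecord("CB", "C", cb, 10.0, 1.0),
    ]
    return Residue(chain, seq, "", "ALA", atoms)


def _grow_segment(chain: str, cys_seq: int, n, ca, c, cb, sg,
                  flank_len: int, ideal: IdealParams) -> List[Residue]:
    """One chain segment: flank_len ALA, the CYS, flank_len ALA."""
    residues: List[Residue] = []
    # forward flank (seq increasing)
    cur = (n, ca, c)
    fwd: List[Residue] = []
    for k in range(flank_len):
        n1, ca1, c1 = _extend_forward(*cur, phi=PHI_EXT, psi_next=PSI_EXT)
        o1 = _carbonyl_o(n1, ca1, c1, PSI_EXT)
        fwd.append(_ala_residue(chain, cys_seq + 1 + k, n1, ca1, c1, o1, ideal))
        cur = (n1, ca1, c1)
    # backward flank (seq decreasing)
    cur = (n, ca, c)
    bwd: List[Residue] = []
    for k in range(flank_len):
        n0, ca0, c0 = _extend_backward(*cur, phi=PHI_EXT, psi_prev=PSI_EXT)
        o0 = _carbonyl_o(n0, ca0, c0, PSI_EXT)
        bwd.append(_ala_residue(chain, cys_seq - 1 - k, n0, ca0, c0, o0, ideal))
        cur = (n0, ca0, c0)
    o_cys = _carbonyl_o(n, ca, c, PSI_EXT)
    cys = Residue(chain, cys_seq, "", "CYS", [
        AtomRecord("N", "N", np.asarray(n, float), 10.0, 1.0),
        AtomRecord("CA", "C", np.asarray(ca, float), 10.0, 1.0),
        AtomRecord("C", "C", np.asarray(c, float), 10.0, 1.0),
        AtomRecord("O", "O", np.asarray(o_cys, float), 10.0, 1.0),
        AtomRecord("CB", "C", np.asarray(cb, float), 10.0, 1.0),
        AtomRecord("SG", "S", np.asarray(sg, float), 10.0, 1.0),
    ])
    residues.extend(reversed(bwd))
    residues.append(cys)
    residues.extend(fwd)
    return residues


def build_ideal_bridge(
    spec: BridgeSpec = BridgeSpec(),
    ideal: IdealParams = IdealParams(),
) -> Tuple[StructureModel, Dict]:
    """Construct a two-cysteine model realizing the spec's torsions exactly.

    Returns the model and a ground-truth record with the planted angles and
    SG coordinates (pre-noise).
    """
    ang_s = np.radians(ideal.ang_cb_s_s)
    sg_a = np.zeros(3)
    sg_b = np.array([ideal.d_ss, 0.0, 0.0])
    cb_a = sg_a + ideal.d_cb_sg * np.array([np.cos(ang_s), np.sin(ang_s), 0.0])
    cb_b = place_atom(cb_a, sg_a, sg_b, ideal.d_cb_sg, ideal.ang_cb_s_s, spec.chi3)

    def cys_frame(sg, cb, sg_other, chi1, chi2):
        ca = place_atom(sg_other, sg, cb, ideal.d_ca_cb, ideal.ang_ca_cb_sg, chi2)
        n = place_atom(sg, cb, ca, D_N_CA, ideal.ang_n_ca_cb, chi1)
        c = _place_carbonyl_c(sg, cb, ca, n, chi1)
        return n, ca, c

    n_a, ca_a, c_a = cys_frame(sg_a, cb_a, sg_b, spec.chi1_a, spec.chi2_a)
    n_b, ca_b, c_b = cys_frame(sg_b, cb_b, sg_a, spec.chi1_b, spec.chi2_b)

    seq_a, seq_b = 10, 30
    residues = (
        _grow_segment("A", seq_a, n_a, ca_a, c_a, cb_a, sg_a, spec.flank_len, ideal)
        + _grow_segment("A", seq_b, n_b, ca_b, c_b, cb_b, sg_b, spec.flank_len, ideal)
    )

    if spec.bfactor_plan == "gradient":
        n_res = len(residues)
        for i, res in enumerate(residues):
            b = 5.0 + 45.0 * (i / max(1, n_res - 1))
            for a in res.atoms:
                a.b_factor = b

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        for res in residues:
            for a in res.atoms:
                a.coord = a.coord + rng.normal(0.0, spec.noise_sigma, 3)

    key_a, key_b = ("A", seq_a, ""), ("A", seq_b, "")
    model = StructureModel(
        model_id=1,
        residues=residues,
        ssbonds=[(key_a, key_b)],
        source_id=f"synthetic-bridge-chi3{spec.chi3:+.1f}",
        resolution=spec.resolution,
    )
    truth = {
        "res_a": key_a,
        "res_b": key_b,
        "chi1_a": spec.chi1_a,
        "chi1_b": spec.chi1_b,
        "chi3": spec.chi3,
        "theta_a": ideal.ang_cb_s_s,
        "theta_b": ideal.ang_cb_s_s,
        "sg_a": sg_a,
        "sg_b": sg_b,
        "cb_a": cb_a,
        "cb_b": cb_b,
    }
    return model, truth


def build_multimodel(n_models: int, spec: BridgeSpec = BridgeSpec(),
                     ideal: IdealParams = IdealParams()) -> str:
    """PDB text with n_models MODEL blocks, each an independently noised copy."""
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    models = []
    for i in range(n_models):
        m, _ = build_ideal_bridge(
            BridgeSpec(
                chi3=spec.chi3, chi1_a=spec.chi1_a, chi1_b=spec.chi1_b,
                chi2_a=spec.chi2_a, chi2_b=spec.chi2_b,
                flank_len=spec.flank_len, noise_sigma=spec.noise_sigma,
                seed=spec.seed + i, bfactor_plan=spec.bfactor_plan,
                resolution=spec.resolution,
            ),
            ideal,
        )
        m.model_id = i + 1
        models.append(m)
    if n_models == 1:
        return write_pdb(models[0])
    return write_pdb(models)


def build_survey_set(n: int, seed: int = 0,
                     ideal: IdealParams = IdealParams()
                     ) -> List[Tuple[StructureModel, Dict]]:
    """n noise-free bridges with chi3 near the native peaks and rotameric chi1.

    chi3 is drawn uniformly from [-92, -82] U [+92, +102] and each chi1
    from the staggered rotamers {-60, +60, 180} (seeded, reproducible).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        if rng.integers(2) == 0:
            chi3 = float(rng.uniform(-92.0, -82.0))
        else:
            chi3 = float(rng.uniform(92.0, 102.0))
        chi1_a, chi1_b = rng.choice([-60.0, 60.0, 180.0], size=2)
        spec = BridgeSpec(chi3=chi3, chi1_a=float(chi1_a), chi1_b=float(chi1_b),
                          seed=int(rng.integers(2 ** 31)))
        model, truth = build_ideal_bridge(spec, ideal)
        model.source_id = f"synthetic-survey-{k:03d}"
        out.append((model, truth))
    return out
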