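"""Disulfide-bridge candidate scan.

For every residue pair the scanner rebuilds C-beta from the backbone,
sweeps a chi1 x chi1' grid of idealized S-gamma placements on both
residues, and keeps poses in which the two sulfurs can meet at the
disulfide bond length with native-like chi3 torsion and CB-SG-SG' bond
angles. Surviving poses are scored with the torsional energy function
and the pair's mobility is summarized as the sum of the two residues'
mean backbone+CB B-factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .energy import EnergyParams, energy_breakdown
from .geometry import IdealParams, bond_angle, dihedral
from .pdbio import BFACTOR_ATOMS, Residue, StructureModel

logger = logging.getLogger("ssbridge")

__all__ = [
    "ScanConfig",
    "DisulfidePrediction",
    "NothingToScanError",
    "pair_sum_bfactor",
    "residue_mean_bfactor",
    "scan",
]


class NothingToScanError(ValueError):
    """Fewer than two residues with a complete backbone."""


@dataclass(frozen=True)
class ScanConfig:
    """Geometric stringency settings for the candidate scan.

    chi3_windows : accepted (center, half-width) chi3 intervals in degrees;
        the defaults bracket the two peaks of the native chi3 distribution.
    ss_bond_tolerance : allowed deviation of the modelled S-S distance from
        the ideal disulfide bond length (A).
    angle_tolerance : allowed deviation of the two CB-SG-SG' angles from
        their ideal value (deg).
    cb_cb_range : CB-CB distance prefilter (A).
    chi1_grid_step : grid resolution of the chi1 sweep (deg); must divide 360.
    refine : locally refine candidate grid poses by coordinate descent.
    min_seq_separation : minimum |seq_a - seq_b| within a chain; inter-chain
        pairs are always allowed.
    include_native_cys : scan residues that are already cysteine.
    energy_cutoff : optional upper bound on the pair energy (kcal/mol).
    """

    chi3_windows: Tuple[Tuple[float, float], ...] = ((-87.0, 10.0), (97.0, 10.0))
    ss_bond_tolerance: float = 0.2
    angle_tolerance: float = 10.0
    cb_cb_range: Tuple[float, float] = (3.0, 5.5)
    chi1_grid_step: float = 5.0
    refine: bool = True
    min_seq_separation: int = 2
    include_native_cys: bool = True
    energy_cutoff: Optional[float] = None
    use_file_cb: bool = False

    def __post_init__(self) -> None:
        if self.ss_bond_tolerance < 0 or self.angle_tolerance < 0:
            raise ValueError("tolerances must be non-negative")
        if not (360.0 / self.chi1_grid_step).is_integer():
            raise ValueError("chi1_grid_step must divide 360")
        lo, hi = self.cb_cb_range
        if not lo < hi:
            raise ValueError("cb_cb_range must be an increasing interval")
        for _, tol in self.chi3_windows:
            if tol < 0:
                raise ValueError("chi3 window tolerance must be non-negative")


@dataclass
class DisulfidePrediction:
    """A scored candidate disulfide bridge between two residues."""

    res_a: Tuple[str, int, str]
    res_b: Tuple[str, int, str]
    aa_a: str
    aa_b: str
    chi1_a: float
    chi1_b: float
    chi3: float
    theta_a: float
    theta_b: float
    ss_distance: float
    energy: float
    energy_terms: Dict[str, float] = field(default_factory=dict)
    sum_bfactor: float = 0.0
    sg_a: np.ndarray = None
    sg_b: np.ndarray = None
    is_native: bool = False


def residue_mean_bfactor(res: Residue) -> float:
    """Mean B-factor over the present backbone + CB atoms (N, CA, C, O, CB)."""
    values = [a.b_factor for a in res.atoms if a.name in BFACTOR_ATOMS]
    if not values:
        raise ValueError(
            f"residue {res.key} has none of the atoms {BFACTOR_ATOMS}; "
            "B-factor undefined"
        )
    return float(np.mean(values))


def pair_sum_bfactor(res_a: Residue, res_b: Residue) -> float:
    """Sum of the two residues' mean backbone+CB B-factors (the sigma-B metric)."""
    return residue_mean_bfactor(res_a) + residue_mean_bfactor(res_b)


def _wrap_angle(a):
    """Map angles to (-180, 180]."""
    a = np.asarray(a, dtype=float)
    w = -(np.mod(-a + 180.0, 360.0) - 180.0)
    w = np.where(w == -180.0, 180.0, w)
    return float(w) if w.ndim == 0 else w


def _circular_diff(a: float, b: float) -> float:
    return abs(_wrap_angle(a - b))


def _in_windows(chi3: float, windows) -> bool:
    return any(_circular_diff(chi3, c) <= t for c, t in windows)


def _window_distance(chi3: float, windows) -> float:
    return min(_circular_diff(chi3, c) for c, _ in windows)


class _SidechainFrame:
    """Per-residue frame mapping chi1 to an idealized SG position."""

    def __init__(self, n: np.ndarray, ca: np.ndarray, cb: np.ndarray,
                 ideal: IdealParams):
        bc = cb - ca
        bc /= np.linalg.norm(bc)
        ab = ca - n
        axis_n = np.cross(ab, bc)
        axis_n /= np.linalg.norm(axis_n)
        m = np.cross(axis_n, bc)
        ang = np.radians(ideal.ang_ca_cb_sg)
        self._origin = cb - ideal.d_cb_sg * np.cos(ang) * bc
        self._u = ideal.d_cb_sg * np.sin(ang) * m
        self._v = ideal.d_cb_sg * np.sin(ang) * axis_n

    def sg(self, chi1) -> np.ndarray:
        chi = np.radians(np.asarray(chi1, dtype=float))
        c, s = np.cos(chi), np.sin(chi)
        return self._origin + np.multiply.outer(c, self._u) + np.multiply.outer(s, self._v)


@dataclass
class _ScanResidue:
    residue: Residue
    cb: np.ndarray
    frame: _SidechainFrame
    sg_grid: np.ndarray  # (K, 3)


def _prepare_residue(res: Residue, chis: np.ndarray, ideal: IdealParams,
                     use_file_cb: bool) -> Optional[_ScanResidue]:
    from .geometry import construct_cbeta

    if not res.has_backbone():
        logger.warning("residue %s lacks complete backbone; skipped", res.key)
        return None
    n, ca, c = res.coord("N"), res.coord("CA"), res.coord("C")
    if use_file_cb and res.coord("CB") is not None:
        cb = res.coord("CB")
    else:
        cb = construct_cbeta(n, ca, c, ideal)
    frame = _SidechainFrame(n, ca, cb, ideal)
    return _ScanResidue(residue=res, cb=cb, frame=frame, sg_grid=frame.sg(chis))


def _refine_pose(chi_a: float, chi_b: float, frame_a: _SidechainFrame,
                 frame_b: _SidechainFrame, d_ss: float, step0: float) -> Tuple[float, float]:
    """Coordinate descent on |d(SG, SG') - d_ss| to step < 0.01 degrees."""

    def dev(ca: float, cb: float) -> float:
        return abs(np.linalg.norm(frame_a.sg(ca) - frame_b.sg(cb)) - d_ss)

    cur = dev(chi_a, chi_b)
    step = step0
    while step >= 0.01:
        moved = True
        while moved:
            moved = False
            for da, db in ((step, 0.0), (-step, 0.0), (0.0, step), (0.0, -step)):
                v = dev(chi_a + da, chi_b + db)
                if v < cur - 1e-14:
                    chi_a, chi_b, cur = chi_a + da, chi_b + db, v
                    moved = True
        step *= 0.5
    return chi_a, chi_b


def _batch_dihedral(p1, p2, p3, p4):
    """Signed torsions for (M, 3) point arrays, degrees in (-180, 180]."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    c12 = np.cross(b1, b2)
    c23 = np.cross(b2, b3)
    y = np.einsum("ij,ij->i", np.cross(c12, c23), b2) / np.linalg.norm(b2, axis=1)
    x = np.einsum("ij,ij->i", c12, c23)
    ang = np.degrees(np.arctan2(y, x))
    return np.where(ang <= -180.0, ang + 360.0, ang)


def _batch_angle(p1, p2, p3):
    """Bond angles at p2 for (M, 3) point arrays, degrees."""
    a = p1 - p2
    b = p3 - p2
    cosang = np.einsum("ij,ij->i", a, b) / (
        np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _evaluate_poses(chi_a: np.ndarray, chi_b: np.ndarray, ra: "_ScanResidue",
                    rb: "_ScanResidue", config: ScanConfig, energy: EnergyParams,
                    ideal: IdealParams):
    """Vectorized validation of (chi1, chi1') pose arrays.

    Returns the best (lowest-energy, tie-broken) pose among those passing
    the S-S distance, chi3 window and bond-angle gates, or None.
    """
    from .energy import e_angle, e_chi1, e_chi3

    sg_a = np.atleast_2d(ra.frame.sg(chi_a))
    sg_b = np.atleast_2d(rb.frame.sg(chi_b))
    d = np.linalg.norm(sg_a - sg_b, axis=1)
    ok = np.abs(d - ideal.d_ss) <= config.ss_bond_tolerance
    if not ok.any():
        return None
    chi_a, chi_b = np.asarray(chi_a)[ok], np.asarray(chi_b)[ok]
    sg_a, sg_b, d = sg_a[ok], sg_b[ok], d[ok]

    cb_a = np.broadcast_to(ra.cb, sg_a.shape)
    cb_b = np.broadcast_to(rb.cb, sg_b.shape)
    chi3 = _batch_dihedral(cb_a, sg_a, sg_b, cb_b)
    wdist = np.min(
        [np.abs(_wrap_angle(chi3 - c)) for c, _ in config.chi3_windows], axis=0)
    in_window = np.zeros(len(chi3), dtype=bool)
    for c, t in config.chi3_windows:
        in_window |= np.abs(_wrap_angle(chi3 - c)) <= t
    theta_a = _batch_angle(cb_a, sg_a, sg_b)
    theta_b = _batch_angle(cb_b, sg_b, sg_a)
    ok = (in_window
          & (np.abs(theta_a - energy.theta0) <= config.angle_tolerance)
          & (np.abs(theta_b - energy.theta0) <= config.angle_tolerance))
    if not ok.any():
        return None
    chi1_a = np.atleast_1d(_wrap_angle(chi_a[ok]))
    chi1_b = np.atleast_1d(_wrap_angle(chi_b[ok]))
    chi3, theta_a, theta_b = chi3[ok], theta_a[ok], theta_b[ok]
    sg_a, sg_b, d, wdist = sg_a[ok], sg_b[ok], d[ok], wdist[ok]
    total = (e_chi1(chi1_a, energy) + e_chi1(chi1_b, energy)
             + e_chi3(chi3, energy) + e_angle(theta_a, energy)
             + e_angle(theta_b, energy))
    i = int(np.lexsort((chi1_a, wdist, total))[0])
    terms = energy_breakdown(float(chi1_a[i]), float(chi1_b[i]), float(chi3[i]),
                             float(theta_a[i]), float(theta_b[i]), energy)
    rank = (float(total[i]), float(wdist[i]), float(chi1_a[i]))
    return (rank, float(chi1_a[i]), float(chi1_b[i]), float(chi3[i]),
            float(theta_a[i]), float(theta_b[i]), float(d[i]), terms,
            sg_a[i], sg_b[i])


def _best_pose(ra: _ScanResidue, rb: _ScanResidue, chis: np.ndarray,
               config: ScanConfig, energy: EnergyParams, ideal: IdealParams):
    """Search the chi1 x chi1' grid for the lowest-energy valid bridge pose.

    With refinement on, grid cells whose S-S deviation is within reach of
    the tolerance (a chord-length margin accounts for the sulfur's maximum
    travel over half a grid step) are explored on a 1-degree sub-lattice,
    and the winning pose is polished by coordinate descent on the S-S
    deviation. The polished pose replaces the lattice winner only when it
    stays valid and does not materially change the energy, so the reported
    score remains comparable to an exhaustive fine-grid search.
    """
    dist = np.linalg.norm(ra.sg_grid[:, None, :] - rb.sg_grid[None, :, :], axis=2)
    dev = np.abs(dist - ideal.d_ss)

    step = config.chi1_grid_step
    if config.refine and step > 1.0:
        half = step / 2.0
        r_eff = ideal.d_cb_sg * np.sin(np.radians(ideal.ang_ca_cb_sg))
        margin = 2.0 * (2.0 * r_eff * np.sin(np.radians(half) / 2.0))
        cells = np.argwhere(dev <= config.ss_bond_tolerance + margin)
        if cells.size == 0:
            cells = np.array([np.unravel_index(np.argmin(dev), dev.shape)])
        offsets = np.arange(-np.floor(half), np.floor(half) + 0.5, 1.0)
        candidates = {
            (chis[i] + da, chis[j] + db)
            for i, j in cells for da in offsets for db in offsets
        }
    else:
        idx = np.argwhere(dev <= config.ss_bond_tolerance)
        candidates = {(chis[i], chis[j]) for i, j in idx}
        if config.refine:
            i0, j0 = np.unravel_index(np.argmin(dev), dev.shape)
            candidates.add((chis[i0], chis[j0]))

    if not candidates:
        return None
    cand = np.array(sorted(candidates))
    best = _evaluate_poses(cand[:, 0], cand[:, 1], ra, rb, config, energy, ideal)
    if best is None:
        return None

    if config.refine:
        chi_a, chi_b = _refine_pose(best[1], best[2], ra.frame, rb.frame,
                                    ideal.d_ss, step / 2.0)
        polished = _evaluate_poses(np.array([chi_a]), np.array([chi_b]),
                                   ra, rb, config, energy, ideal)
        if polished is not None and abs(polished[0][0] - best[0][0]) <= 0.02:
            best = polished
    return best


def scan(
    model: StructureModel,
    config: ScanConfig = ScanConfig(),
    energy: EnergyParams = EnergyParams(),
    ideal: IdealParams = IdealParams(),
    progress: Optional[Callable[[float], None]] = None,
) -> List[DisulfidePrediction]:
    """Enumerate residue pairs and return scored disulfide predictions.

    The output is ordered by (chain, seq, icode) of the first then second
    residue of each pair. ``progress``, when given, is called with the
    percent complete at every 1% of pairs.
    """
    chis = np.arange(-180.0 + config.chi1_grid_step, 180.0 + 1e-9,
                     config.chi1_grid_step)
    prepared: List[_ScanResidue] = []
    for res in model.residues:
        if not config.include_native_cys and res.res_name == "CYS":
            continue
        sr = _prepare_residue(res, chis, ideal, config.use_file_cb)
        if sr is not None:
            prepared.append(sr)
    if len(prepared) < 2:
        raise NothingToScanError("nothing to scan: fewer than 2 residues with a "
                                 "complete backbone")

    native_pairs = {frozenset((a, b)) for a, b in model.ssbonds}

    def sort_key(sr: _ScanResidue):
        k = sr.residue.key
        return (k[0], k[1], k[2])

    ordered = sorted(prepared, key=sort_key)
    pairs = []
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            ra, rb = ordered[i].residue, ordered[j].residue
            if ra.chain_id == rb.chain_id and \
                    abs(ra.seq_num - rb.seq_num) < config.min_seq_separation:
                continue
            pairs.append((ordered[i], ordered[j]))

    n_pairs = len(pairs)
    next_report = 0.01
    predictions: List[DisulfidePrediction] = []
    for idx, (ra, rb) in enumerate(pairs):
        if progress is not None and n_pairs and (idx + 1) / n_pairs >= next_report:
            pct = 100.0 * (idx + 1) / n_pairs
            progress(pct)
            next_report = np.floor((idx + 1) / n_pairs * 100.0) / 100.0 + 0.01
        d_cb = float(np.linalg.norm(ra.cb - rb.cb))
        if not config.cb_cb_range[0] <= d_cb <= config.cb_cb_range[1]:
            continue
        best = _best_pose(ra, rb, chis, config, energy, ideal)
        if best is None:
            continue
        _, chi1_a, chi1_b, chi3, theta_a, theta_b, d, terms, sg_a, sg_b = best
        if config.energy_cutoff is not None and terms["total"] > config.energy_cutoff:
            continue
        pred = DisulfidePrediction(
            res_a=ra.residue.key,
            res_b=rb.residue.key,
            aa_a=ra.residue.res_name,
            aa_b=rb.residue.res_name,
            chi1_a=chi1_a,
            chi1_b=chi1_b,
            chi3=chi3,
            theta_a=theta_a,
            theta_b=theta_b,
            ss_distance=d,
            energy=terms["total"],
            energy_terms=terms,
            sum_bfactor=pair_sum_bfactor(ra.residue, rb.residue),
            sg_a=sg_a,
            sg_b=sg_b,
            is_native=frozenset((ra.residue.key, rb.residue.key)) in native_pairs,
        )
        predictions.append(pred)
    return predictions
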