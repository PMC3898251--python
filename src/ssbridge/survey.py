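"""Native-disulfide survey and blind-validation harness.

Native bridges are read off the input structures (SSBOND records plus any
cysteine pair whose file SG-SG distance is bonded). The blind validation
then hides the side chains — the scan only ever uses backbone coordinates
and a rebuilt C-beta — and asks how many native bridges the scan recovers,
whether the predicted chi3 has the native handedness, how tightly predicted
chi3 tracks native chi3, and how far the modelled sulfurs sit from the
deposited ones. Native-geometry energies are summarized alongside.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .energy import EnergyParams, total_energy
from .geometry import IdealParams, bond_angle, dihedral
from .pdbio import StructureModel
from .scan import ScanConfig, scan

logger = logging.getLogger("ssbridge")

__all__ = ["NativeBridge", "SurveyReport", "extract_native", "blind_validate",
           "select_survey_set"]

ResidueKey = Tuple[str, int, str]

SS_BOND_DETECT_CUTOFF = 2.5  # A; file SG-SG distances below this count as bonded


@dataclass
class NativeBridge:
    res_a: ResidueKey
    res_b: ResidueKey
    chi3: float
    sg_a: np.ndarray
    sg_b: np.ndarray
    chi1_a: float
    chi1_b: float
    theta_a: float
    theta_b: float


@dataclass
class SurveyReport:
    n_structures: int
    n_native: int
    n_recovered: int
    recovery_pct: float
    n_chirality_correct: int
    chirality_pct: float
    r_squared: float
    median_sg_dist: float
    chi3_histogram: Dict[str, List[float]] = field(default_factory=dict)
    energy_histogram: Dict[str, List[float]] = field(default_factory=dict)
    energy_mean: float = 0.0
    energy_p90: float = 0.0

    def to_dict(self) -> dict:
        return {
            "n_structures": self.n_structures,
            "n_native": self.n_native,
            "n_recovered": self.n_recovered,
            "recovery_pct": self.recovery_pct,
            "n_chirality_correct": self.n_chirality_correct,
            "chirality_pct": self.chirality_pct,
            "r_squared": self.r_squared,
            "median_sg_dist": self.median_sg_dist,
            "chi3_histogram": self.chi3_histogram,
            "energy_histogram": self.energy_histogram,
            "energy_mean": self.energy_mean,
            "energy_p90": self.energy_p90,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def extract_native(model: StructureModel) -> List[NativeBridge]:
    """Native disulfides: SSBOND pairs plus CYS pairs with bonded file SG-SG.

    Duplicates are merged; bridges whose residues lack CB or SG coordinates
    cannot be measured and are dropped with a warning.
    """
    rmap = model.residue_map()
    pair_set = {frozenset((a, b)) for a, b in model.ssbonds}
    cys = [r for r in model.residues if r.res_name == "CYS" and r.coord("SG") is not None]
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            d = np.linalg.norm(cys[i].coord("SG") - cys[j].coord("SG"))
            if d < SS_BOND_DETECT_CUTOFF:
                pair_set.add(frozenset((cys[i].key, cys[j].key)))

    bridges: List[NativeBridge] = []
    for pair in pair_set:
        key_a, key_b = sorted(pair)
        ra, rb = rmap.get(key_a), rmap.get(key_b)
        if ra is None or rb is None:
            continue
        coords = {}
        ok = True
        for tag, r in (("a", ra), ("b", rb)):
            for name in ("N", "CA", "CB", "SG"):
                c = r.coord(name)
                if c is None:
                    logger.warning("native bridge %s-%s: missing %s on %s; dropped",
                                   key_a, key_b, name, r.key)
                    ok = False
                coords[f"{name}_{tag}"] = c
        if not ok:
            continue
        bridges.append(
            NativeBridge(
                res_a=key_a,
                res_b=key_b,
                chi3=dihedral(coords["CB_a"], coords["SG_a"], coords["SG_b"],
                              coords["CB_b"]),
                sg_a=coords["SG_a"],
                sg_b=coords["SG_b"],
                chi1_a=dihedral(coords["N_a"], coords["CA_a"], coords["CB_a"],
                                coords["SG_a"]),
                chi1_b=dihedral(coords["N_b"], coords["CA_b"], coords["CB_b"],
                                coords["SG_b"]),
                theta_a=bond_angle(coords["CB_a"], coords["SG_a"], coords["SG_b"]),
                theta_b=bond_angle(coords["CB_b"], coords["SG_b"], coords["SG_a"]),
            )
        )
    bridges.sort(key=lambda b: (b.res_a, b.res_b))
    return bridges


def _r_squared(native: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination of the OLS fit of predicted on native chi3."""
    if len(native) == 0:
        return float("nan")
    if len(native) == 1 or np.ptp(native) < 1e-9:
        return 1.0 if np.max(np.abs(predicted - native)) < 1e-9 else 0.0
    coeffs = np.polyfit(native, predicted, 1)
    fitted = np.polyval(coeffs, native)
    ss_res = float(np.sum((predicted - fitted) ** 2))
    ss_tot = float(np.sum((predicted - np.mean(predicted)) ** 2))
    if ss_tot <= 1e-12:
        return 1.0 if ss_res <= 1e-12 else 0.0
    return max(0.0, min(1.0, 1.0 - ss_res / ss_tot))


def blind_validate(
    models: Sequence[StructureModel],
    config: ScanConfig = ScanConfig(),
    energy: EnergyParams = EnergyParams(),
    ideal: IdealParams = IdealParams(),
) -> SurveyReport:
    """Scan each structure blind and score recovery of its native bridges."""
    n_native = 0
    n_recovered = 0
    chirality_pairs: List[Tuple[float, float]] = []  # (native, predicted) chi3
    sg_dists: List[float] = []
    native_energies: List[float] = []
    native_chi3: List[float] = []

    any_native = False
    for model in models:
        natives = extract_native(model)
        if not natives:
            continue
        any_native = True
        predictions = scan(model, config, energy, ideal)
        pred_map = {frozenset((p.res_a, p.res_b)): p for p in predictions}
        for nb in natives:
            n_native += 1
            native_chi3.append(nb.chi3)
            native_energies.append(
                total_energy(nb.chi1_a, nb.chi1_b, nb.chi3, nb.theta_a, nb.theta_b,
                             energy)
            )
            pred = pred_map.get(frozenset((nb.res_a, nb.res_b)))
            if pred is None:
                continue
            n_recovered += 1
            # match modelled sulfurs to file sulfurs by residue
            if pred.res_a == nb.res_a:
                pa, pb = pred.sg_a, pred.sg_b
            else:
                pa, pb = pred.sg_b, pred.sg_a
            sg_dists.append(float(np.linalg.norm(pa - nb.sg_a)))
            sg_dists.append(float(np.linalg.norm(pb - nb.sg_b)))
            if np.sign(pred.chi3) == np.sign(nb.chi3):
                chirality_pairs.append((nb.chi3, pred.chi3))

    if not any_native:
        raise ValueError("no native bridges found in the input structures")

    nat = np.array([p[0] for p in chirality_pairs])
    prd = np.array([p[1] for p in chirality_pairs])
    energies = np.array(native_energies)

    chi3_edges = np.arange(-180.0, 180.0 + 5.0, 5.0)
    chi3_counts, _ = np.histogram(native_chi3, bins=chi3_edges)
    e_hi = max(0.25, float(np.ceil(energies.max() / 0.25) * 0.25)) if len(energies) else 0.25
    e_edges = np.arange(0.0, e_hi + 0.25, 0.25)
    e_counts, _ = np.histogram(energies, bins=e_edges)

    return SurveyReport(
        n_structures=len(models),
        n_native=n_native,
        n_recovered=n_recovered,
        recovery_pct=100.0 * n_recovered / n_native,
        n_chirality_correct=len(chirality_pairs),
        chirality_pct=(100.0 * len(chirality_pairs) / n_recovered
                       if n_recovered else 0.0),
        r_squared=_r_squared(nat, prd),
        median_sg_dist=float(np.median(sg_dists)) if sg_dists else float("nan"),
        chi3_histogram={"edges": chi3_edges.tolist(),
                        "counts": chi3_counts.tolist()},
        energy_histogram={"edges": e_edges.tolist(), "counts": e_counts.tolist()},
        energy_mean=float(np.mean(energies)) if len(energies) else float("nan"),
        energy_p90=float(np.percentile(energies, 90)) if len(energies) else float("nan"),
    )


def select_survey_set(models: Sequence[StructureModel],
                      max_resolution: float = 2.0) -> List[StructureModel]:
    """Keep structures with at least one native bridge and resolution <= cutoff.

    Sequence-redundancy filtering is the caller's responsibility (pass a
    non-redundant list). Structures without a recorded resolution are
    excluded and logged.
    """
    kept = []
    for model in models:
        if model.resolution is None:
            logger.warning("structure %s has no recorded resolution; excluded",
                           model.source_id or model.model_id)
            continue
        if model.resolution > max_resolution:
            continue
        if not extract_native(model):
            continue
        kept.append(model)
    return kept
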