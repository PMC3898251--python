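"""Whole-chain B-factor summary and colorimetric normalization.

Per-residue mobility is the mean B-factor over the backbone + CB atoms,
the same quantity the pair scan sums into the sigma-B metric. For display
the per-residue values are normalized to 512 discrete steps between the
structure's minimum and maximum: the lower 256 steps map to a blue scale,
the upper 256 to a red scale (red = high mobility).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Tuple

import pandas as pd

from .pdbio import StructureModel
from .scan import residue_mean_bfactor

__all__ = ["BFactorProfile", "profile", "colorize"]

ResidueKey = Tuple[str, int, str]


@dataclass
class BFactorProfile:
    per_residue: List[Tuple[ResidueKey, float]]
    b_min: float
    b_max: float
    b_mean: float

    def value(self, key: ResidueKey) -> float:
        for k, b in self.per_residue:
            if k == key:
                return b
        raise KeyError(f"residue {key} not in profile")


def profile(model: StructureModel) -> BFactorProfile:
    """Per-residue mean backbone+CB B-factors with their range and mean."""
    per_residue = []
    for res in model.residues:
        try:
            per_residue.append((res.key, residue_mean_bfactor(res)))
        except ValueError:
            continue
    if not per_residue:
        raise ValueError("no residue with usable backbone/CB atoms")
    values = [b for _, b in per_residue]
    return BFactorProfile(
        per_residue=per_residue,
        b_min=min(values),
        b_max=max(values),
        b_mean=sum(values) / len(values),
    )


def colorize(prof: BFactorProfile, residue_key: ResidueKey) -> Tuple[int, str]:
    """Map a residue's B-factor to (index 0..511, 'blue'|'red').

    index = round((b - b_min) / (b_max - b_min) * 511), rounding half-up;
    indices 0-255 are blue, 256-511 red. A flat profile maps everything to
    (0, 'blue').
    """
    b = prof.value(residue_key)
    span = prof.b_max - prof.b_min
    if span <= 0:
        return 0, "blue"
    index = int(math.floor((b - prof.b_min) / span * 511.0 + 0.5))
    index = max(0, min(511, index))
    return index, ("blue" if index <= 255 else "red")


def profile_csv(prof: BFactorProfile) -> str:
    """Profile as CSV: residue key, mean B, color index and channel."""
    rows = []
    for key, b in prof.per_residue:
        idx, channel = colorize(prof, key)
        rows.append({
            "chain": key[0],
            "seq_num": key[1],
            "icode": key[2],
            "mean_b": f"{b:.2f}",
            "index": idx,
            "channel": channel,
        })
    return pd.DataFrame(rows).to_csv(index=False)
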