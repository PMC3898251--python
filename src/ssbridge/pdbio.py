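"""PDB-format structure input/output.

Reading is backed by gemmi and post-processed into light dataclasses:
alternate locations are collapsed to the highest-occupancy conformer,
hydrogens are dropped, HETATM records are skipped except selenomethionine
(MSE, parsed as MET), and SSBOND records are attached to every model.
Writing emits fixed-column ATOM/SSBOND text, including mutant export in
which selected residue pairs are truncated to CYS with a modelled SG.
"""

from __future__ import annotations

import logging
import re
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import IdealParams, construct_cbeta

logger = logging.getLogger("ssbridge")

__all__ = [
    "AtomRecord",
    "Residue",
    "StructureModel",
    "PDBParseError",
    "NoCoordinatesError",
    "PDBFetchError",
    "read_pdb",
    "read_pdb_file",
    "fetch_pdb",
    "write_pdb",
    "write_mutant_pdb",
    "write_csv",
    "CSV_COLUMNS",
]

ResidueKey = Tuple[str, int, str]

BACKBONE_ATOMS = ("N", "CA", "C", "O")
BFACTOR_ATOMS = ("N", "CA", "C", "O", "CB")

CSV_COLUMNS = [
    "chain1",
    "res1",
    "aa1",
    "chain2",
    "res2",
    "aa2",
    "chi3_deg",
    "energy_kcal_mol",
    "sum_bfactor",
]


class PDBParseError(ValueError):
    """Malformed PDB content; the message names the offending line."""


class NoCoordinatesError(PDBParseError):
    """Input stream contains no ATOM coordinates."""


class PDBFetchError(RuntimeError):
    """PDB entry could not be retrieved."""


@dataclass
class AtomRecord:
    name: str
    element: str
    coord: np.ndarray
    b_factor: float
    occupancy: float
    alt_loc: str = ""


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    icode: str
    res_name: str
    atoms: List[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_num, self.icode)

    def atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> Optional[np.ndarray]:
        a = self.atom(name)
        return None if a is None else a.coord

    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in ("N", "CA", "C"))


@dataclass
class StructureModel:
    model_id: int
    residues: List[Residue] = field(default_factory=list)
    ssbonds: List[Tuple[ResidueKey, ResidueKey]] = field(default_factory=list)
    source_id: str = ""
    resolution: Optional[float] = None

    def residue_map(self) -> dict:
        return {r.key: r for r in self.residues}

    def get_residue(self, key: ResidueKey) -> Optional[Residue]:
        for r in self.residues:
            if r.key == key:
                return r
        return None


# ---------------------------------------------------------------------------
# reading

_FLOAT_FIELDS = ((30, 38), (38, 46), (46, 54), (54, 60), (60, 66))


def _validate_fixed_columns(text: str) -> int:
    """Check numeric fields of ATOM/HETATM lines; return the ATOM count.

    gemmi tolerates trailing garbage in numeric fields, so this runs first
    to give a parse error that names the line.
    """
    n_atom = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec not in ("ATOM  ", "HETATM"):
            continue
        if rec == "ATOM  ":
            n_atom += 1
        for lo, hi in _FLOAT_FIELDS:
            fld = line[lo:hi].strip()
            if fld == "" and lo >= 54:  # occupancy/B may be absent
                continue
            try:
                float(fld)
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed numeric field {fld!r} in columns "
                    f"{lo + 1}-{hi}"
                ) from None
        seq = line[22:26].strip()
        try:
            int(seq)
        except ValueError:
            raise PDBParseError(
                f"line {lineno}: malformed residue sequence number {seq!r}"
            ) from None
    return n_atom


def _resolve_altlocs(atoms: List[AtomRecord]) -> List[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, tie -> first alt_loc."""
    by_name: dict = {}
    order: List[str] = []
    for a in atoms:
        if a.name not in by_name:
            by_name[a.name] = []
            order.append(a.name)
        by_name[a.name].append(a)
    out = []
    for name in order:
        group = by_name[name]
        best = min(group, key=lambda a: (-a.occupancy, a.alt_loc))
        out.append(best)
    return out


def read_pdb(text: str, source_id: str = "") -> List[StructureModel]:
    """Parse a PDB-format character stream into one StructureModel per model.

    A file without MODEL records yields exactly one model with model_id 1.
    """
    import gemmi

    n_atom = _validate_fixed_columns(text)
    if n_atom == 0:
        raise NoCoordinatesError("no coordinates: input contains no ATOM records")
    st = gemmi.read_pdb_string(text)
    resolution = st.resolution if st.resolution and st.resolution > 0 else None

    ssbond_keys: List[Tuple[ResidueKey, ResidueKey]] = []
    for con in st.connections:
        p1, p2 = con.partner1, con.partner2
        k1 = (p1.chain_name, p1.res_id.seqid.num, (p1.res_id.seqid.icode or " ").strip())
        k2 = (p2.chain_name, p2.res_id.seqid.num, (p2.res_id.seqid.icode or " ").strip())
        if p1.res_id.name == "CYS" and p2.res_id.name == "CYS":
            ssbond_keys.append((k1, k2))

    models: List[StructureModel] = []
    for m in st:
        residues: List[Residue] = []
        for chain in m:
            for res in chain:
                het = res.het_flag == "H"
                res_name = res.name
                if het:
                    if res_name != "MSE":
                        continue
                    res_name = "MET"
                atoms: List[AtomRecord] = []
                for a in res:
                    if a.element.is_hydrogen:
                        continue
                    name = a.name
                    if het and name == "SE":  # selenium stands in for SD
                        name = "SD"
                    alt = a.altloc if a.altloc not in ("\x00", " ") else ""
                    if a.b_iso < 0:
                        logger.warning(
                            "negative B-factor %.2f on atom %s of %s %s%d",
                            a.b_iso, name, res.name, chain.name, res.seqid.num,
                        )
                    atoms.append(
                        AtomRecord(
                            name=name,
                            element=a.element.name,
                            coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
                            b_factor=float(a.b_iso),
                            occupancy=float(a.occ),
                            alt_loc=alt,
                        )
                    )
                if not atoms:
                    continue
                residues.append(
                    Residue(
                        chain_id=chain.name,
                        seq_num=res.seqid.num,
                        icode=(res.seqid.icode or " ").strip(),
                        res_name=res_name,
                        atoms=_resolve_altlocs(atoms),
                    )
                )
        model = StructureModel(
            model_id=m.num,
            residues=residues,
            source_id=source_id,
            resolution=resolution,
        )
        rmap = model.residue_map()
        for k1, k2 in ssbond_keys:
            r1, r2 = rmap.get(k1), rmap.get(k2)
            if r1 is None or r2 is None:
                logger.warning("SSBOND references a residue absent from model %d: %s %s",
                               m.num, k1, k2)
                continue
            if r1.res_name != "CYS" or r2.res_name != "CYS":
                logger.warning("SSBOND partner is not CYS in model %d: %s %s", m.num, k1, k2)
                continue
            model.ssbonds.append((k1, k2))
        models.append(model)
    if not models:
        raise NoCoordinatesError("no coordinates: no usable residues parsed")
    return models


def read_pdb_file(path) -> List[StructureModel]:
    p = Path(path)
    return read_pdb(p.read_text(), source_id=p.name)


# ---------------------------------------------------------------------------
# fetching

_PDB_ID_RE = re.compile(r"^[0-9][A-Za-z0-9]{3}$")
_PDB_URL = "https://files.rcsb.org/download/{id}.pdb"


def default_cache_dir() -> Path:
    return Path.home() / ".cache" / "ssbridge"


def fetch_pdb(pdb_id: str, cache_dir=None, timeout: float = 30.0) -> str:
    """Return the PDB-format text for a 4-character PDB identifier.

    Results are cached on disk so repeated calls work offline.
    """
    if not _PDB_ID_RE.match(pdb_id or ""):
        raise ValueError(f"invalid PDB identifier {pdb_id!r}: expected 4 characters, "
                         "digit first")
    pdb_id = pdb_id.lower()
    cache = Path(cache_dir) if cache_dir is not None else default_cache_dir()
    cached = cache / f"{pdb_id}.pdb"
    if cached.exists():
        return cached.read_text()
    url = _PDB_URL.format(id=pdb_id.upper())
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            text = resp.read().decode("utf-8", errors="replace")
    except Exception as exc:  # noqa: BLE001 - network errors are environment-specific
        raise PDBFetchError(f"could not retrieve PDB entry {pdb_id!r}: {exc}") from exc
    cache.mkdir(parents=True, exist_ok=True)
    cached.write_text(text)
    return text


# ---------------------------------------------------------------------------
# writing

def _format_atom_name(name: str, element: str) -> str:
    # one-letter elements start in column 14, two-letter (e.g. SE) in 13
    if len(name) >= 4 or len(element) >= 2:
        return f"{name:<4.4s}"
    return f" {name:<3s}"


def _atom_line(serial: int, atom: AtomRecord, res: Residue) -> str:
    x, y, z = atom.coord
    return (
        f"ATOM  {serial:5d} {_format_atom_name(atom.name, atom.element)}"
        f"{atom.alt_loc or ' '}"
        f"{res.res_name:>3s} {res.chain_id:1s}{res.seq_num:4d}{res.icode or ' '}"
        f"   {x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
        f"          {atom.element:>2s}"
    )


def _ssbond_line(serial: int, k1: ResidueKey, k2: ResidueKey) -> str:
    c1, s1, i1 = k1
    c2, s2, i2 = k2
    return (
        f"SSBOND {serial:3d} CYS {c1:1s} {s1:4d}{i1 or ' '}"
        f"   CYS {c2:1s} {s2:4d}{i2 or ' '}"
    )


def write_pdb(models) -> str:
    """Serialize one StructureModel or a list of them to PDB-format text.

    A single model is written without MODEL/ENDMDL wrappers; a list is
    written as numbered MODEL blocks. SSBOND records (taken from the first
    model) precede the coordinates.
    """
    if isinstance(models, StructureModel):
        model_list = [models]
        wrap = False
    else:
        model_list = list(models)
        wrap = len(model_list) != 1
        if not model_list:
            raise ValueError("no models to write")

    lines: List[str] = []
    if model_list[0].resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {model_list[0].resolution:7.2f} ANGSTROMS.")
    for i, (k1, k2) in enumerate(model_list[0].ssbonds, start=1):
        lines.append(_ssbond_line(i, k1, k2))
    for model in model_list:
        if wrap:
            lines.append(f"MODEL     {model.model_id:4d}")
        serial = 0
        for res in model.residues:
            for atom in res.atoms:
                serial += 1
                lines.append(_atom_line(serial, atom, res))
        if wrap:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_mutant_pdb(
    model: StructureModel,
    predictions: Sequence,
    ideal: IdealParams = IdealParams(),
) -> str:
    """Write the model with predicted pairs mutated to disulfide-bonded CYS.

    Each mutated residue becomes CYS truncated at CB (CB is rebuilt from
    the backbone when the native residue lacks one, e.g. glycine), with SG
    placed at the prediction's modelled coordinates, occupancy 1.00 and
    B-factor copied from the residue's CA. One SSBOND record is emitted
    per predicted pair; untouched residues are written verbatim.
    """
    rmap = model.residue_map()
    sg_coords: dict = {}
    pairs: List[Tuple[ResidueKey, ResidueKey]] = []
    for pred in predictions:
        for key, sg in ((pred.res_a, pred.sg_a), (pred.res_b, pred.sg_b)):
            if key not in rmap:
                raise ValueError(f"prediction references a residue missing from the "
                                 f"model: {key}")
            sg_coords[key] = np.asarray(sg, dtype=float)
        pairs.append((pred.res_a, pred.res_b))

    kept_native = [
        (k1, k2) for k1, k2 in model.ssbonds
        if k1 not in sg_coords and k2 not in sg_coords
    ]
    out = StructureModel(
        model_id=model.model_id,
        source_id=model.source_id,
        resolution=model.resolution,
        ssbonds=kept_native + list(pairs),
    )
    for res in model.residues:
        if res.key not in sg_coords:
            out.residues.append(res)
            continue
        if res.res_name == "CYS":
            logger.warning("native CYS %s re-posed: SG moved to the modelled position",
                           res.key)
        kept = [a for a in res.atoms if a.name in BACKBONE_ATOMS + ("CB", "OXT")]
        mutant = Residue(res.chain_id, res.seq_num, res.icode, "CYS",
                         atoms=[AtomRecord(a.name, a.element, a.coord.copy(),
                                           a.b_factor, a.occupancy, a.alt_loc)
                                for a in kept])
        ca = mutant.atom("CA")
        ca_b = ca.b_factor if ca is not None else 0.0
        if mutant.atom("CB") is None:
            n, ca_c, c = res.coord("N"), res.coord("CA"), res.coord("C")
            if n is None or ca_c is None or c is None:
                raise ValueError(f"cannot build CB for {res.key}: incomplete backbone")
            cb = construct_cbeta(n, ca_c, c, ideal)
            mutant.atoms.append(AtomRecord("CB", "C", cb, ca_b, 1.0))
        mutant.atoms.append(
            AtomRecord("SG", "S", sg_coords[res.key], ca_b, 1.0)
        )
        out.residues.append(mutant)
    return write_pdb(out)


# ---------------------------------------------------------------------------
# CSV export

def _res_label(seq_num: int, icode: str) -> str:
    return f"{seq_num}{icode}" if icode else str(seq_num)


def predictions_frame(predictions: Sequence) -> pd.DataFrame:
    """Tabulate predictions with the canonical CSV columns (unformatted)."""
    rows = []
    for p in predictions:
        rows.append(
            {
                "chain1": p.res_a[0],
                "res1": _res_label(p.res_a[1], p.res_a[2]),
                "aa1": p.aa_a,
                "chain2": p.res_b[0],
                "res2": _res_label(p.res_b[1], p.res_b[2]),
                "aa2": p.aa_b,
                "chi3_deg": p.chi3,
                "energy_kcal_mol": p.energy,
                "sum_bfactor": p.sum_bfactor,
            }
        )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_csv(predictions: Sequence, sort_key: str = "chain1",
              descending: bool = False) -> str:
    """Render predictions as CSV text sorted on one column (stable order)."""
    if sort_key not in CSV_COLUMNS:
        raise ValueError(f"unknown sort key {sort_key!r}; expected one of "
                         f"{', '.join(CSV_COLUMNS)}")
    df = predictions_frame(predictions)
    if len(df):
        df = df.sort_values(sort_key, ascending=not descending, kind="stable")
        for col in ("chi3_deg", "energy_kcal_mol", "sum_bfactor"):
            df[col] = df[col].map(lambda v: f"{v:.2f}")
    return df.to_csv(index=False)
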