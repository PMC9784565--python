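"""Structure input: PDB/mmCIF parsing, hydrophobicity scales and fragment
tables, and reduction of each residue to a single *effective atom*.

The effective atom of a residue is the unweighted mean position of its
non-hydrogen atoms; it carries the residue's intrinsic hydrophobicity taken
from a scale mapping the 20 standard amino acids onto [0, 1]. The ordered
collection of effective atoms (:class:`EffectiveAtomCloud`) is the universe
over which every hydrophobicity profile downstream is indexed.

Author (PDB) residue numbering is used throughout, so fragment ranges match
the numbering printed in structure papers; ranges are inclusive on both ends.
"""

from __future__ import annotations

import urllib.error
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "STANDARD_AA",
    "DEFAULT_ALIASES",
    "ResidueRecord",
    "HydrophobicityScale",
    "FragmentSpec",
    "EffectiveAtomCloud",
    "parse_structure",
    "extract_het_coords",
    "fetch_pdb",
    "compute_effective_atoms",
    "load_scale",
    "load_fragments",
    "default_scale",
]

#: The 20 standard amino-acid three-letter codes.
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Modified residues mapped onto a standard parent for scale lookup.
DEFAULT_ALIASES: Mapping[str, str] = {"MSE": "MET", "SEC": "CYS", "PYL": "LYS"}

_BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: ``(chain_id, auth_seq, icode)`` triple identifying a residue.
ResId = tuple[str, int, str]


@dataclass
class ResidueRecord:
    """One standard residue: identity plus its retained heavy atoms."""

    chain_id: str
    auth_seq: int
    icode: str
    res_name: str
    #: list of ``(element, x, y, z, occupancy, altloc)``
    atoms: list[tuple[str, float, float, float, float, str]]
    #: PDB atom names parallel to ``atoms`` (e.g. "CA", "CB")
    atom_names: list[str] = field(default_factory=list)

    @property
    def res_id(self) -> ResId:
        return (self.chain_id, self.auth_seq, self.icode)


@dataclass(frozen=True)
class HydrophobicityScale:
    """Mapping from three-letter residue name to intrinsic hydrophobicity
    H^r in [0, 1]."""

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = sorted(STANDARD_AA - set(self.values))
        if missing:
            raise InputError(f"scale is missing amino acids: {', '.join(missing)}")
        bad = {k: v for k, v in self.values.items() if not (0.0 <= v <= 1.0)}
        if bad:
            raise InputError(f"scale values outside [0, 1]: {bad}")

    def __getitem__(self, res_name: str) -> float:
        return self.values[res_name]

    def __contains__(self, res_name: str) -> bool:
        return res_name in self.values


@dataclass(frozen=True)
class FragmentSpec:
    """A labelled inclusive author-numbering range, e.g. a TM helix."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(
                f"fragment {self.label!r}: start {self.start} > end {self.end}"
            )


@dataclass
class EffectiveAtomCloud:
    """Ordered per-residue point cloud with intrinsic hydrophobicities.

    ``positions`` is an (N, 3) array in Å; ``h`` holds H^r in [0, 1];
    ``res_ids`` and ``res_names`` run in sequence order.
    """

    res_ids: list[ResId]
    res_names: list[str]
    positions: np.ndarray
    h: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        n = len(self.res_ids)
        if n < 2:
            raise InputError(f"cloud needs at least 2 residues, got {n}")
        if self.positions.shape != (n, 3) or self.h.shape != (n,):
            raise InputError("cloud field lengths are inconsistent")
        if not np.all(np.isfinite(self.positions)):
            raise InputError("cloud contains non-finite coordinates")

    def __len__(self) -> int:
        return len(self.res_ids)

    def replace_positions(self, positions: np.ndarray) -> "EffectiveAtomCloud":
        return EffectiveAtomCloud(
            list(self.res_ids), list(self.res_names), np.asarray(positions), self.h.copy()
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write the cloud as tab-separated text; floats use shortest
        round-trip representation so a read-back is bit-identical."""
        lines = ["chain\tauth_seq\ticode\tres_name\tx\ty\tz\th"]
        for (ch, seq, ic), name, (x, y, z), h in zip(
            self.res_ids, self.res_names, self.positions, self.h
        ):
            lines.append(
                f"{ch}\t{seq}\t{ic}\t{name}\t{float(x)!r}\t{float(y)!r}"
                f"\t{float(z)!r}\t{float(h)!r}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EffectiveAtomCloud":
        text = Path(path).read_text().rstrip("\n").split("\n")
        header = text[0].split("\t")
        if header != ["chain", "auth_seq", "icode", "res_name", "x", "y", "z", "h"]:
            raise InputError(f"{path}: not a cloud TSV (unexpected header)")
        ids, names, pos, h = [], [], [], []
        for line in text[1:]:
            ch, seq, ic, name, x, y, z, hv = line.split("\t")
            ids.append((ch, int(seq), ic))
            names.append(name)
            pos.append((float(x), float(y), float(z)))
            h.append(float(hv))
        return cls(ids, names, np.array(pos), np.array(h))


def _pick_altloc(
    atoms: Iterable[tuple[str, float, float, float, float, str]],
) -> tuple[str, float, float, float, float, str]:
    # highest occupancy wins; ties go to altloc 'A', then first seen
    best = None
    for a in atoms:
        if best is None:
            best = a
            continue
        if a[4] > best[4] or (a[4] == best[4] and a[5] == "A" != best[5]):
            best = a
    return best


def _read_structure(text: str) -> gemmi.Structure:
    if text.lstrip().startswith("data_"):
        doc = gemmi.cif.read_string(text)
        return gemmi.make_structure_from_block(doc.sole_block())
    return gemmi.read_pdb_string(text)


def parse_structure(
    pdb_text: str,
    chain_id: str,
    model_index: int = 0,
    aliases: Mapping[str, str] = DEFAULT_ALIASES,
) -> list[ResidueRecord]:
    """Extract the standard amino-acid residues of one chain.

    HETATM ligands and waters are excluded, except modified residues listed
    in ``aliases`` (e.g. selenomethionine). Hydrogens are dropped. Where a
    residue has alternate locations for an atom, the highest-occupancy
    conformer is kept (ties: altloc 'A', then first).
    """
    structure = _read_structure(pdb_text)
    if len(structure) == 0:
        raise InputError("structure contains no models")
    if model_index >= len(structure):
        raise InputError(f"model index {model_index} out of range")
    model = structure[model_index]
    chain = model.find_chain(chain_id)
    if chain is None:
        available = ", ".join(c.name for c in model)
        raise InputError(f"chain {chain_id!r} not found (available: {available})")

    records: list[ResidueRecord] = []
    for res in chain:
        name = res.name
        if name not in STANDARD_AA and name not in aliases:
            continue
        by_name: dict[str, list] = {}
        for atom in res:
            if atom.is_hydrogen():
                continue
            by_name.setdefault(atom.name, []).append(
                (atom.element.name, atom.pos.x, atom.pos.y, atom.pos.z,
                 atom.occ, atom.altloc or "")
            )
        if not by_name:
            continue
        atom_names = list(by_name)
        atoms = [_pick_altloc(by_name[k]) for k in atom_names]
        records.append(
            ResidueRecord(
                chain_id=chain_id,
                auth_seq=res.seqid.num,
                icode=(res.seqid.icode or "").strip(),
                res_name=name,
                atoms=atoms,
                atom_names=atom_names,
            )
        )
    if not records:
        raise InputError(f"chain {chain_id!r} has no standard amino-acid residues")
    records.sort(key=lambda r: (r.auth_seq, r.icode))
    return records


def extract_het_coords(
    pdb_text: str, het_name: str, model_index: int = 0
) -> np.ndarray:
    """Coordinates (K, 3) of all atoms of HET residues named ``het_name``
    (e.g. ``"FE"``, ``"K"``) anywhere in the model."""
    structure = _read_structure(pdb_text)
    model = structure[model_index]
    coords = [
        (atom.pos.x, atom.pos.y, atom.pos.z)
        for chain in model
        for res in chain
        if res.name == het_name.upper()
        for atom in res
    ]
    if not coords:
        raise InputError(f"no HET residue named {het_name!r} in the structure")
    return np.array(coords)


def fetch_pdb(
    pdb_id: str, cache_dir: str | Path, offline: bool = False
) -> str:
    """Return PDB-format text for ``pdb_id``, caching downloads on disk.

    With ``offline=True`` only the cache is consulted.
    """
    pdb_id = pdb_id.strip().upper()
    if len(pdb_id) != 4 or not pdb_id.isalnum():
        raise InputError(f"not a valid PDB accession: {pdb_id!r}")
    cache_dir = Path(cache_dir)
    cache_file = cache_dir / f"{pdb_id}.pdb"
    if cache_file.exists():
        return cache_file.read_text()
    if offline:
        raise InputError(f"{pdb_id}: not in cache {cache_dir} and offline mode is on")
    url = f"https://files.rcsb.org/download/{pdb_id}.pdb"
    try:
        with urllib.request.urlopen(url, timeout=60) as resp:
            text = resp.read().decode("utf-8", errors="replace")
    except (urllib.error.URLError, OSError) as exc:
        raise InputError(f"could not fetch PDB entry {pdb_id}: {exc}") from exc
    cache_dir.mkdir(parents=True, exist_ok=True)
    cache_file.write_text(text)
    return text


def compute_effective_atoms(
    residues: Sequence[ResidueRecord],
    scale: HydrophobicityScale,
    aliases: Mapping[str, str] = DEFAULT_ALIASES,
    side_chain_only: bool = False,
) -> EffectiveAtomCloud:
    """Collapse each residue to the mean of its heavy-atom coordinates.

    ``side_chain_only=True`` averages side-chain atoms only (falling back to
    all atoms for glycine); the default averages backbone and side chain, the
    convention used for whole-residue hydrophobicity fields.
    """
    ids, names, pos, h = [], [], [], []
    unmapped = []
    for res in residues:
        name = aliases.get(res.res_name, res.res_name)
        if name not in scale:
            unmapped.append(f"{res.res_name} {res.chain_id}{res.auth_seq}")
            continue
        atoms = res.atoms
        if side_chain_only and res.res_name != "GLY" and res.atom_names:
            side = [
                a for a, an in zip(atoms, res.atom_names)
                if an not in _BACKBONE_ATOMS
            ]
            if side:
                atoms = side
        xyz = np.array([[a[1], a[2], a[3]] for a in atoms])
        ids.append(res.res_id)
        names.append(res.res_name)
        pos.append(xyz.mean(axis=0))
        h.append(scale[name])
    if unmapped:
        raise InputError(
            "residues not covered by the hydrophobicity scale: " + ", ".join(unmapped)
        )
    return EffectiveAtomCloud(ids, names, np.array(pos), np.array(h))


def load_scale(path: str | Path) -> HydrophobicityScale:
    """Read a two-column tab-separated scale table (header: res_name, h)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise InputError(f"{path}: expected two tab-separated columns")
    names = df.iloc[:, 0].astype(str).str.upper()
    try:
        vals = df.iloc[:, 1].astype(float)
    except ValueError as exc:
        raise InputError(f"{path}: non-numeric scale value: {exc}") from exc
    return HydrophobicityScale(dict(zip(names, vals)))


def load_fragments(path: str | Path) -> list[FragmentSpec]:
    """Read a three-column tab-separated fragment table (label, start, end)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise InputError(f"{path}: expected three tab-separated columns")
    frags: list[FragmentSpec] = []
    seen = set()
    for _, row in df.iterrows():
        label = str(row.iloc[0])
        if label in seen:
            raise InputError(f"{path}: duplicate fragment label {label!r}")
        seen.add(label)
        frags.append(FragmentSpec(label, int(row.iloc[1]), int(row.iloc[2])))
    return frags


def default_scale() -> HydrophobicityScale:
    """The packaged default scale: a standard residue hydrophobicity scale
    min–max normalized onto [0, 1] (most hydrophilic 0, most hydrophobic 1)."""
    return load_scale(Path(__file__).parent / "data" / "default_scale.tsv")
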