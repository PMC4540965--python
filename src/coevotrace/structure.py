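"""Structure-derived quantities for covariation benchmarking.

Residue-residue distances (shortest distance between non-hydrogen atoms),
contact maps at a threshold distance, relative solvent accessibility (read
from Naccess-style .rsa files or computed with a Shrake-Rupley rollout),
burial classes, and residue-volume-weighted pair accessibility.

An :class:`StructureContext` ties a protein structure to an alignment
through an explicit column -> residue mapping (1-based alignment columns,
author residue numbering preserved).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np

__all__ = [
    "ResidueKey",
    "StructureContext",
    "RESIDUE_VOLUMES",
    "MAX_ASA",
    "read_pdb",
    "read_rsa",
    "read_mapping",
    "write_mapping",
    "compute_sasa",
    "min_heavy_atom_distance",
    "contact_map",
    "weighted_mean_accessibility",
    "burial_class",
]

# Mean amino-acid residue volumes (A^3), Zamyatnin (1972).
RESIDUE_VOLUMES: dict[str, float] = {
    "ALA": 88.6, "ARG": 173.4, "ASN": 114.1, "ASP": 111.1, "CYS": 108.5,
    "GLN": 143.8, "GLU": 138.4, "GLY": 60.1, "HIS": 153.2, "ILE": 166.7,
    "LEU": 166.7, "LYS": 168.6, "MET": 162.9, "PHE": 189.9, "PRO": 112.7,
    "SER": 89.0, "THR": 116.1, "TRP": 227.8, "TYR": 193.6, "VAL": 140.0,
}

# Theoretical maximum accessible surface areas (A^2), Tien et al. (2013),
# used to normalize absolute SASA to a relative percentage.
MAX_ASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


class ResidueKey(NamedTuple):
    """PDB author identification of a residue."""

    chain: str
    resnum: int
    icode: str = ""


class MissingStructureError(KeyError):
    """An alignment column maps to no residue with coordinates."""


class MissingVolumeError(KeyError):
    """No volume entry for a residue type."""


@dataclass
class StructureContext:
    """Structure, accessibility, and alignment mapping for one protein.

    Attributes
    ----------
    coords
        Residue -> ``(n_heavy_atoms, 3)`` coordinate array (Angstrom).
    restypes
        Residue -> three-letter residue type.
    col_to_res
        1-based alignment column -> residue key.
    rel_acc
        Residue -> relative all-atom solvent accessibility (percent of the
        residue type's reference maximum; values slightly above 100 occur).
    volumes
        Residue-type -> volume (A^3); defaults to a published mean-volume
        table.
    """

    coords: dict[ResidueKey, np.ndarray]
    restypes: dict[ResidueKey, str]
    col_to_res: dict[int, ResidueKey] = field(default_factory=dict)
    rel_acc: dict[ResidueKey, float] = field(default_factory=dict)
    volumes: dict[str, float] = field(default_factory=lambda: dict(RESIDUE_VOLUMES))

    def __post_init__(self) -> None:
        for key, xyz in self.coords.items():
            xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
            if xyz.shape[0] < 1:
                raise ValueError(f"residue {key} has no heavy atoms")
            self.coords[key] = xyz

    def residue_for_column(self, column: int) -> ResidueKey:
        try:
            return self.col_to_res[column]
        except KeyError:
            raise MissingStructureError(f"column {column} is not mapped to a residue")

    def mapped_columns(self) -> list[int]:
        return sorted(self.col_to_res)

    def volume(self, key: ResidueKey) -> float:
        restype = self.restypes.get(key, "")
        try:
            return self.volumes[restype]
        except KeyError:
            raise MissingVolumeError(f"no volume for residue type {restype!r} at {key}")


def read_pdb(path: str | Path, chain: str | None = None) -> StructureContext:
    """Read heavy-atom coordinates from a PDB file.

    First model only; for alternate locations, blank or 'A' altloc atoms are
    kept.  Hydrogens and waters are discarded.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import is_aa

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    coords: dict[ResidueKey, np.ndarray] = {}
    restypes: dict[ResidueKey, str] = {}
    for ch in model:
        if chain is not None and ch.id != chain:
            continue
        for res in ch:
            hetflag, resnum, icode = res.id
            if hetflag.strip():
                continue
            xyz = [
                atom.coord
                for atom in res
                if atom.element != "H" and atom.get_altloc() in (" ", "A")
            ]
            if not xyz:
                continue
            key = ResidueKey(ch.id, int(resnum), icode.strip())
            coords[key] = np.asarray(xyz, dtype=float)
            restypes[key] = res.get_resname()
    if not coords:
        raise ValueError(f"no protein residues with heavy atoms found in {path}")
    return StructureContext(coords=coords, restypes=restypes)


def read_rsa(path: str | Path, column: str = "all_atoms_rel") -> dict[ResidueKey, float]:
    """Parse per-residue relative accessibility from a Naccess-style .rsa file.

    Each ``RES`` record carries absolute and relative accessibility for
    all-atoms, side-chain, main-chain, non-polar and polar subsets; by
    default the relative all-atom column is returned.  Records without a
    chain identifier are keyed with an empty chain and matched by residue
    number downstream when unambiguous.
    """
    col_index = {
        "all_atoms_abs": 0, "all_atoms_rel": 1,
        "side_chain_abs": 2, "side_chain_rel": 3,
        "main_chain_abs": 4, "main_chain_rel": 5,
    }[column]
    out: dict[ResidueKey, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.startswith("RES"):
            continue
        # fixed-ish columns: RES <type> <chain><resnum><icode> <numbers...>
        try:
            restype = line[4:7].strip()
            chain = line[8].strip() if len(line) > 8 else ""
            resnum_field = line[9:14].strip()
            if resnum_field and resnum_field[-1].isalpha():
                icode, resnum = resnum_field[-1], int(resnum_field[:-1])
            else:
                icode, resnum = "", int(resnum_field)
            numbers = [float(x) for x in line[14:].split()]
            value = numbers[col_index]
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed RES record: {line!r}") from exc
        key = ResidueKey(chain, resnum, icode)
        if key in out:
            raise ValueError(f"{path}:{lineno}: duplicate residue key {key}")
        out[key] = value
        _ = restype  # type retained in the structure context, not here
    if not out:
        raise ValueError(f"no RES records found in {path}")
    return out


def attach_rsa(context: StructureContext, rsa: Mapping[ResidueKey, float]) -> None:
    """Attach .rsa accessibilities to a context, matching chainless records
    by residue number when unambiguous."""
    by_number: dict[tuple[int, str], list[ResidueKey]] = {}
    for key in context.coords:
        by_number.setdefault((key.resnum, key.icode), []).append(key)
    for key, value in rsa.items():
        if key in context.coords:
            context.rel_acc[key] = value
        elif key.chain == "":
            candidates = by_number.get((key.resnum, key.icode), [])
            if len(candidates) == 1:
                context.rel_acc[candidates[0]] = value
            elif len(candidates) > 1:
                raise ValueError(
                    f"ambiguous chainless residue {key.resnum}{key.icode}: {candidates}"
                )


def compute_sasa(
    context: StructureContext, probe_radius: float = 1.4, n_points: int = 100
) -> dict[ResidueKey, float]:
    """Relative per-residue solvent accessibility via Shrake-Rupley.

    Accessible surface area is accumulated per atom on a fixed spherical
    point mesh and summed per residue, then normalized by a per-residue-type
    reference maximum to a percentage.  Deterministic for a fixed point
    count.  This is an internal approximation used when no .rsa file is
    supplied; it is not a re-implementation of Naccess's exact algorithm.
    """
    # golden-spiral sphere points: deterministic, even coverage
    k = np.arange(n_points) + 0.5
    phi = np.arccos(1 - 2 * k / n_points)
    theta = np.pi * (1 + 5**0.5) * k
    sphere = np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1
    )

    keys = list(context.coords)
    atoms = np.concatenate([context.coords[k2] for k2 in keys])
    owner = np.concatenate(
        [np.full(len(context.coords[k2]), idx) for idx, k2 in enumerate(keys)]
    )
    radii = np.full(len(atoms), 1.7)  # carbon-like heavy-atom radius
    radii_ext = radii + probe_radius

    area_per_res = np.zeros(len(keys))
    for a in range(len(atoms)):
        pts = atoms[a] + radii_ext[a] * sphere
        d2 = ((pts[:, None, :] - atoms[None, :, :]) ** 2).sum(-1)
        d2[:, a] = np.inf
        exposed = (d2 >= (radii_ext[None, :]) ** 2).all(axis=1)
        area = exposed.mean() * 4 * np.pi * radii_ext[a] ** 2
        area_per_res[owner[a]] += area

    out: dict[ResidueKey, float] = {}
    for idx, key in enumerate(keys):
        ref = MAX_ASA.get(context.restypes.get(key, ""), None)
        if ref is None:
            # fall back to the mean reference area for unknown residue types
            ref = float(np.mean(list(MAX_ASA.values())))
        out[key] = 100.0 * area_per_res[idx] / ref
    return out


def min_heavy_atom_distance(
    context: StructureContext, resA: ResidueKey, resB: ResidueKey
) -> float:
    """Shortest distance (A) between heavy atoms of two residues."""
    for key in (resA, resB):
        if key not in context.coords:
            raise MissingStructureError(f"residue {key} has no coordinates")
    a, b = context.coords[resA], context.coords[resB]
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.min()))


def contact_map(
    context: StructureContext,
    threshold: float = 10.0,
    min_separation: int = 0,
) -> dict[tuple[int, int], bool]:
    """Contact labels for every mapped alignment column pair.

    A pair ``(i, j)`` (1-based columns, ``i < j``) is a contact iff the
    minimum heavy-atom distance of the mapped residues is below
    ``threshold`` and ``j - i >= min_separation``.  Pairs failing the
    separation filter are excluded from the map entirely.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    cols = context.mapped_columns()
    labels: dict[tuple[int, int], bool] = {}
    for x in range(len(cols)):
        for y in range(x + 1, len(cols)):
            i, j = cols[x], cols[y]
            if j - i < min_separation:
                continue
            d = min_heavy_atom_distance(
                context, context.col_to_res[i], context.col_to_res[j]
            )
            labels[(i, j)] = d < threshold
    return labels


def weighted_mean_accessibility(
    pair: tuple[int, int], context: StructureContext
) -> float:
    """Residue-volume-weighted mean relative accessibility of a column pair:
    ``(vol_i * acc_i + vol_j * acc_j) / (vol_i + vol_j)``."""
    keys = [context.residue_for_column(c) for c in pair]
    accs, vols = [], []
    for key in keys:
        if key not in context.rel_acc:
            raise MissingStructureError(f"residue {key} has no accessibility value")
        accs.append(context.rel_acc[key])
        vols.append(context.volume(key))
    return float(np.average(accs, weights=vols))


def burial_class(
    residue: ResidueKey, context: StructureContext, core_threshold: float = 10.0
) -> str:
    """Classify a residue by relative accessibility.

    ``completely_buried``: 0% accessible (within 1e-9); ``core``: below the
    core threshold (default 10%); ``exposed`` otherwise.
    """
    if residue not in context.rel_acc:
        raise MissingStructureError(f"residue {residue} has no accessibility value")
    acc = context.rel_acc[residue]
    if abs(acc) <= 1e-9:
        return "completely_buried"
    if acc < core_threshold:
        return "core"
    return "exposed"


def read_mapping(path: str | Path) -> dict[int, ResidueKey]:
    """Read a column -> residue mapping TSV with header ``column chain resnum``
    (optional fourth column: insertion code)."""
    mapping: dict[int, ResidueKey] = {}
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if lineno == 1 and fields[0].strip().lower() == "column":
            continue
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
        col = int(fields[0])
        icode = fields[3].strip() if len(fields) > 3 else ""
        if col in mapping:
            raise ValueError(f"{path}:{lineno}: duplicate column {col}")
        mapping[col] = ResidueKey(fields[1].strip(), int(fields[2]), icode)
    return mapping


def write_mapping(mapping: Mapping[int, ResidueKey], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("column\tchain\tresnum\ticode\n")
        for col in sorted(mapping):
            key = mapping[col]
            fh.write(f"{col}\t{key.chain}\t{key.resnum}\t{key.icode}\n")


def map_columns_by_sequence(
    reference_row: Iterable[str], context: StructureContext, chain: str
) -> dict[int, ResidueKey]:
    """Derive a column -> residue mapping by walking the ungapped reference
    sequence along the chain's residues in order, requiring exact one-letter
    matches.  Intended for the common case where the alignment's reference
    row is the structure's sequence."""
    from Bio.PDB.Polypeptide import protein_letters_3to1

    residues = sorted(
        (k for k in context.coords if k.chain == chain),
        key=lambda k: (k.resnum, k.icode),
    )
    mapping: dict[int, ResidueKey] = {}
    r = 0
    for col, symbol in enumerate(reference_row, start=1):
        if symbol == "-":
            continue
        if r >= len(residues):
            break
        key = residues[r]
        letter = protein_letters_3to1.get(context.restypes.get(key, ""), "X")
        if letter != symbol.upper():
            raise ValueError(
                f"reference/structure mismatch at column {col}: "
                f"alignment {symbol!r} vs residue {key} ({letter!r})"
            )
        mapping[col] = key
        r += 1
    return mapping
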