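"""Nine-pocket model of the HLA-DR binding groove.

The peptide-binding groove of an HLA-DR molecule accommodates a 9-residue
binding core; each core position faces a sub-cavity ("pocket") lined by a
fixed set of beta-chain residues.  Pockets 1, 4, 6, 7 and 9 are the anchor
pockets that dominate binding specificity.  A pocket's *pseudosequence* is
the string of beta-chain residues lining it, read in ascending residue-number
order; alleles sharing a pocket pseudosequence share that pocket's
quantitative binding profile.

This module defines the canonical pocket model (which beta-chain positions
line which pocket), and extraction of pocket pseudosequences from a
residue-numbered beta chain and of pocket residue coordinates from PDB
structures.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio.Data.IUPACData import protein_letters_3to1
from Bio.PDB import PDBParser

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
"""The 20 canonical amino acids in NCBI substitution-matrix order."""

ANCHOR_POCKETS = (1, 4, 6, 7, 9)


class PocketModelError(ValueError):
    """Base class for pocket-model failures."""


class MissingPositionError(PocketModelError):
    """A beta-chain position required by a pocket is absent."""


class MissingChainError(PocketModelError):
    """The requested chain is not present in the structure."""


class MissingResidueError(PocketModelError):
    """A residue number required by a pocket is absent from the chain."""


class MissingAtomError(PocketModelError):
    """The representative atom is absent from a pocket residue."""


class InsertionCodeError(PocketModelError):
    """A pocket residue carries an insertion code, which is not supported."""


@dataclass(frozen=True)
class PocketDefinition:
    """One pocket of the groove: its index, lining positions and anchor flag."""

    pocket_index: int
    beta_positions: tuple[int, ...]
    is_anchor: bool

    def __post_init__(self) -> None:
        if self.pocket_index not in range(1, 10):
            raise PocketModelError(f"pocket index must be 1..9, got {self.pocket_index}")
        if not self.beta_positions:
            raise PocketModelError("beta_positions must be non-empty")
        if any(b >= a for a, b in zip(self.beta_positions[1:], self.beta_positions)):
            raise PocketModelError("beta_positions must be strictly increasing")
        if self.is_anchor != (self.pocket_index in ANCHOR_POCKETS):
            raise PocketModelError(
                f"pocket {self.pocket_index}: is_anchor must be "
                f"{self.pocket_index in ANCHOR_POCKETS}"
            )

    @property
    def size(self) -> int:
        return len(self.beta_positions)


@dataclass(frozen=True)
class PocketPseudosequence:
    """Residues lining one pocket, in ascending beta-chain position order."""

    pocket_index: int
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise PocketModelError("pseudosequence must be non-empty")
        bad = [c for c in self.residues if c not in AMINO_ACIDS and c != "X"]
        if bad:
            raise PocketModelError(f"invalid residue letters: {bad!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, eq=False)
class PocketStructure:
    """3D coordinates (Angstrom) of one pocket's lining residues."""

    pocket_index: int
    coordinates: np.ndarray  # (n, 3)
    source_id: str = "unknown"

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
            raise PocketModelError("coordinates must be a non-empty (n, 3) array")
        if not np.all(np.isfinite(coords)):
            raise PocketModelError("coordinates must be finite")
        object.__setattr__(self, "coordinates", coords)

    def __len__(self) -> int:
        return self.coordinates.shape[0]


def _data_path(name: str):
    return resources.files("drbcore.data").joinpath(name)


def default_pocket_definitions() -> dict[int, PocketDefinition]:
    """The canonical pocket model, read from the packaged pocket table."""
    defs: dict[int, PocketDefinition] = {}
    with _data_path("pockets.tsv").open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("pocket\t"):
                continue
            idx_s, positions_s, anchor_s = line.split("\t")
            idx = int(idx_s)
            defs[idx] = PocketDefinition(
                pocket_index=idx,
                beta_positions=tuple(int(p) for p in positions_s.split()),
                is_anchor=anchor_s.strip() == "1",
            )
    if sorted(defs) != list(range(1, 10)):
        raise PocketModelError("packaged pocket table must define pockets 1..9")
    return defs


def extract_pseudosequence(
    beta_chain: Mapping[int, str], pocket: PocketDefinition
) -> PocketPseudosequence:
    """Read the pocket's lining residues off a residue-numbered beta chain.

    ``beta_chain`` maps beta-chain residue numbers to one-letter codes
    (non-canonical residues may appear as ``'X'``).  Residues are returned in
    ascending position order.  A position absent from the chain raises
    :class:`MissingPositionError` naming the position.
    """
    letters = []
    for pos in pocket.beta_positions:
        if pos not in beta_chain:
            raise MissingPositionError(
                f"position {pos} absent from chain (pocket {pocket.pocket_index})"
            )
        letter = beta_chain[pos].upper()
        if len(letter) != 1:
            raise PocketModelError(f"position {pos}: expected one-letter code, got {letter!r}")
        if letter not in AMINO_ACIDS:
            letter = "X"
        letters.append(letter)
    return PocketPseudosequence(pocket.pocket_index, "".join(letters))


_3TO1 = {k.upper(): v for k, v in protein_letters_3to1.items()}


def _residue_one_letter(resname: str) -> str:
    return _3TO1.get(resname.strip().upper(), "X")


def _load_structure(structure, source_id: str | None):
    if isinstance(structure, (str, Path)):
        path = Path(structure)
        parser = PDBParser(QUIET=True)
        return parser.get_structure(path.stem, str(path)), source_id or path.stem
    return structure, source_id or getattr(structure, "id", "unknown")


def _get_chain(structure, chain_id: str):
    model = next(structure.get_models())
    if chain_id not in model:
        raise MissingChainError(f"chain {chain_id!r} not found in structure")
    return model[chain_id]


def _find_residue(chain, pos: int):
    hits = [res for res in chain if res.id[1] == pos]
    if not hits:
        raise MissingResidueError(f"residue {pos} absent from chain {chain.id!r}")
    with_icode = [res for res in hits if res.id[2].strip()]
    plain = [res for res in hits if not res.id[2].strip()]
    if with_icode and not plain:
        raise InsertionCodeError(
            f"residue {pos} in chain {chain.id!r} carries an insertion code"
        )
    return plain[0]


def _atom_coord(atom) -> np.ndarray:
    # Disordered atom: take the first altloc in file order.
    if atom.is_disordered():
        first = next(iter(atom.child_dict.values()))
        return np.asarray(first.get_coord(), dtype=float)
    return np.asarray(atom.get_coord(), dtype=float)


def _representative_coord(residue, representative: str) -> np.ndarray:
    if representative == "CA":
        if "CA" not in residue:
            raise MissingAtomError(
                f"residue {residue.id[1]} has no CA atom"
            )
        return _atom_coord(residue["CA"])
    if representative == "centroid":
        # unpacked list expands disordered atoms; keep one altloc per atom name
        seen: dict[str, np.ndarray] = {}
        for atom in residue.get_unpacked_list():
            if atom.element == "H":
                continue
            if atom.get_name() not in seen:
                seen[atom.get_name()] = np.asarray(atom.get_coord(), dtype=float)
        coords = list(seen.values())
        if not coords:
            raise MissingAtomError(f"residue {residue.id[1]} has no heavy atoms")
        return np.mean(coords, axis=0)
    raise PocketModelError(f"unknown representative {representative!r}")


def extract_pocket_coordinates(
    structure,
    chain_id: str,
    pocket: PocketDefinition,
    representative: str = "CA",
    source_id: str | None = None,
) -> PocketStructure:
    """One representative coordinate per pocket position from a PDB structure.

    ``structure`` is a path to a PDB file or an already parsed ``Bio.PDB``
    structure.  ``representative`` selects the atom standing in for a residue:
    ``"CA"`` (default) or ``"centroid"`` (mean of heavy atoms).  Missing
    chains, residues and atoms raise distinct errors; residues with insertion
    codes are rejected.
    """
    structure, source = _load_structure(structure, source_id)
    chain = _get_chain(structure, chain_id)
    coords = []
    for pos in pocket.beta_positions:
        residue = _find_residue(chain, pos)
        coords.append(_representative_coord(residue, representative))
    return PocketStructure(pocket.pocket_index, np.asarray(coords), source_id=source)


def beta_chain_from_structure(structure, chain_id: str) -> dict[int, str]:
    """Residue-number -> one-letter-code mapping for a chain of a PDB structure.

    Non-standard residues map to ``'X'``; waters are skipped; insertion-coded
    residues are rejected.
    """
    structure, _ = _load_structure(structure, None)
    chain = _get_chain(structure, chain_id)
    mapping: dict[int, str] = {}
    for residue in chain:
        hetflag, pos, icode = residue.id
        if residue.get_resname().strip() == "HOH":
            continue
        if icode.strip():
            raise InsertionCodeError(
                f"residue {pos} in chain {chain_id!r} carries an insertion code"
            )
        if pos not in mapping:
            mapping[pos] = _residue_one_letter(residue.get_resname())
    return mapping


def load_structure_registry(
    manifest_path: str | Path,
    pdb_dir: str | Path,
    pockets: Iterable[PocketDefinition],
    representative: str = "CA",
) -> dict[tuple[str, int], PocketStructure]:
    """Pocket coordinates for every allele of a structure manifest.

    The manifest is a TSV with columns ``allele``, ``pdb_id``, ``chain_id``;
    PDB files are looked up as ``<pdb_dir>/<pdb_id>.pdb``.  Returns a mapping
    (allele, pocket_index) -> :class:`PocketStructure`; pockets whose
    residues a structure lacks are skipped silently (structural data is an
    optional channel).
    """
    pdb_dir = Path(pdb_dir)
    out: dict[tuple[str, int], PocketStructure] = {}
    with open(manifest_path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                for col in ("allele", "pdb_id", "chain_id"):
                    if col not in header:
                        raise PocketModelError(f"manifest lacks column {col!r}")
                continue
            row = dict(zip(header, fields))
            path = pdb_dir / f"{row['pdb_id']}.pdb"
            parser = PDBParser(QUIET=True)
            structure = parser.get_structure(row["pdb_id"], str(path))
            for pocket in pockets:
                try:
                    out[(row["allele"], pocket.pocket_index)] = extract_pocket_coordinates(
                        structure,
                        row["chain_id"],
                        pocket,
                        representative=representative,
                        source_id=row["pdb_id"],
                    )
                except PocketModelError:
                    continue
    return out


_ANNOTATION = re.compile(r"(\d+)([A-Z])")


def parse_residue_annotations(cell: str) -> list[tuple[int, str]]:
    """Parse a "82N 85V 86G" pocket-composition cell into (position, letter) pairs."""
    cell = cell.strip()
    if not cell:
        return []
    pairs = []
    for token in cell.split():
        m = _ANNOTATION.fullmatch(token)
        if not m:
            raise PocketModelError(f"malformed residue annotation {token!r}")
        pairs.append((int(m.group(1)), m.group(2)))
    return pairs
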