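"""Sequence- and structure-based similarity between MHC II pocket pseudosequences.

Two pockets are compared through two channels:

* **sequence** — each pseudosequence residue is replaced by its 20-value row of
  a substitution matrix (BLOSUM62 by default), giving a 20n-dimensional
  encoding; the similarity is a Gaussian radial-basis function (RBF) of the
  Euclidean distance between encodings,
  ``k_seq = exp(-d^2 / (2 b^2))``.
* **structure** — the pocket residues' 3D coordinates are optimally superposed
  (least-squares rigid motion, proper rotation only) and the RBF of the
  resulting RMSD gives ``k_spa``.

Both channels therefore lie in (0, 1] with 1 meaning identity.  Three
combination rules are supported: ``"rms"`` (quadratic mean of the two
channels), ``"mean"`` (arithmetic mean) and ``"sum"``.  Downstream weighting
uses only the *ranking* of combined similarities, so ``"mean"`` and ``"sum"``
are rank-equivalent by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from .pocket_model import AMINO_ACIDS, PocketPseudosequence, PocketStructure

MODES = ("rms", "mean", "sum")


class SimilarityError(ValueError):
    """Base class for similarity-channel failures."""


class EncodingError(SimilarityError):
    """A pseudosequence cannot be encoded (unknown or 'X' residue)."""


class DegenerateStructureError(SimilarityError):
    """Point set unsuitable for superposition (too few / collinear points)."""


class SubstitutionMatrix:
    """A symmetric amino-acid substitution matrix restricted to the 20 canonical letters.

    Wraps a Biopython substitution-matrix array; ``row(letter)`` returns the
    letter's 20 scores in canonical (NCBI) amino-acid order.
    """

    def __init__(self, array) -> None:
        alphabet = "".join(array.alphabet)
        missing = [a for a in AMINO_ACIDS if a not in alphabet]
        if missing:
            raise SimilarityError(f"matrix lacks letters {missing!r}")
        idx = [alphabet.index(a) for a in AMINO_ACIDS]
        dense = np.asarray(array, dtype=float)[np.ix_(idx, idx)]
        if not np.allclose(dense, dense.T):
            raise SimilarityError("substitution matrix must be symmetric")
        self.values = dense
        self._index = {a: i for i, a in enumerate(AMINO_ACIDS)}

    @classmethod
    def from_file(cls, path: str | Path) -> "SubstitutionMatrix":
        """Read an NCBI-format substitution matrix text file."""
        return cls(substitution_matrices.read(str(path)))

    @classmethod
    def default(cls) -> "SubstitutionMatrix":
        """The bundled BLOSUM62 matrix."""
        with resources.as_file(
            resources.files("drbcore.data").joinpath("blosum62.txt")
        ) as path:
            return cls.from_file(path)

    def row(self, letter: str) -> np.ndarray:
        if letter not in self._index:
            raise EncodingError(f"cannot encode residue {letter!r}")
        return self.values[self._index[letter]]

    def score(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])


@dataclass(frozen=True, eq=False)
class EncodedPseudosequence:
    """Substitution-matrix-row encoding of a pseudosequence: a 20n real vector."""

    vector: np.ndarray
    n: int

    def __post_init__(self) -> None:
        vec = np.asarray(self.vector, dtype=float)
        if vec.shape != (20 * self.n,):
            raise SimilarityError(
                f"encoding must have dimension 20*n = {20 * self.n}, got {vec.shape}"
            )
        object.__setattr__(self, "vector", vec)


def encode(
    pseudo: PocketPseudosequence | str, matrix: SubstitutionMatrix | None = None
) -> EncodedPseudosequence:
    """Concatenate, residue by residue, the substitution-matrix rows of a pseudosequence."""
    matrix = matrix or SubstitutionMatrix.default()
    residues = pseudo.residues if isinstance(pseudo, PocketPseudosequence) else pseudo
    rows = [matrix.row(r) for r in residues]
    return EncodedPseudosequence(np.concatenate(rows), len(residues))


def raw_alignment_score(
    a: str | PocketPseudosequence,
    b: str | PocketPseudosequence,
    matrix: SubstitutionMatrix | None = None,
) -> float:
    """Plain positionwise substitution score sum(M[a_j, b_j]).

    Alternative sequence channel; unlike the RBF channel it is unbounded and
    may not be mixed with the structural channel.
    """
    matrix = matrix or SubstitutionMatrix.default()
    ra = a.residues if isinstance(a, PocketPseudosequence) else a
    rb = b.residues if isinstance(b, PocketPseudosequence) else b
    if len(ra) != len(rb):
        raise SimilarityError("pseudosequences must have equal length")
    return float(sum(matrix.score(x, y) for x, y in zip(ra, rb)))


def seq_similarity(
    va: EncodedPseudosequence, vi: EncodedPseudosequence, bandwidth: float
) -> float:
    """Gaussian RBF similarity of two encoded pseudosequences, in (0, 1]."""
    if bandwidth <= 0:
        raise SimilarityError("bandwidth must be positive")
    if va.vector.shape != vi.vector.shape:
        raise SimilarityError("encoded dimensions differ")
    d2 = float(np.sum((va.vector - vi.vector) ** 2))
    return math.exp(-d2 / (2.0 * bandwidth**2))


def _as_points(x) -> np.ndarray:
    if isinstance(x, PocketStructure):
        return x.coordinates
    pts = np.asarray(x, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise SimilarityError("expected an (n, 3) point array")
    return pts


def superpose_rmsd(a, b) -> float:
    """Minimal RMSD (Angstrom) of b onto a over all proper rigid motions.

    Points are in correspondence by order.  Solved in closed form (Kabsch,
    via SVD-based least-squares rotation fitting with determinant +1).
    Requires >= 3 points per set; collinear point sets are rejected because
    the optimal rotation is then not unique.
    """
    pa, pb = _as_points(a), _as_points(b)
    if pa.shape[0] != pb.shape[0]:
        raise SimilarityError(
            f"point counts differ: {pa.shape[0]} vs {pb.shape[0]}"
        )
    n = pa.shape[0]
    if n < 3:
        raise DegenerateStructureError("superposition needs at least 3 points")
    ca, cb = pa - pa.mean(axis=0), pb - pb.mean(axis=0)
    for c in (ca, cb):
        sv = np.linalg.svd(c, compute_uv=False)
        scale = sv[0] if sv[0] > 0 else 1.0
        if sv[1] <= 1e-9 * scale:
            raise DegenerateStructureError("collinear point set")
    rot, _ = Rotation.align_vectors(ca, cb)
    # residuals computed explicitly: the closed-form rssd loses precision
    # near zero through catastrophic cancellation
    resid = ca - rot.apply(cb)
    return math.sqrt(float(np.sum(resid**2)) / n)


def spa_similarity(rmsd: float, bandwidth: float) -> float:
    """Gaussian RBF similarity of a superposition RMSD, in (0, 1]."""
    if bandwidth <= 0:
        raise SimilarityError("bandwidth must be positive")
    if not np.isfinite(rmsd) or rmsd < 0:
        raise SimilarityError(f"rmsd must be finite and non-negative, got {rmsd}")
    return math.exp(-(rmsd**2) / (2.0 * bandwidth**2))


def combine(kseq: float, kspa: float, mode: str) -> float:
    """Combine the two similarity channels.

    ``"rms"`` = sqrt((kseq^2 + kspa^2)/2), ``"mean"`` = (kseq + kspa)/2,
    ``"sum"`` = kseq + kspa.  Both inputs must lie in [0, 1].
    """
    for name, v in (("kseq", kseq), ("kspa", kspa)):
        if not 0.0 <= v <= 1.0:
            raise SimilarityError(f"{name} must be in [0, 1], got {v}")
    if mode == "rms":
        return math.sqrt((kseq**2 + kspa**2) / 2.0)
    if mode == "mean":
        return (kseq + kspa) / 2.0
    if mode == "sum":
        return kseq + kspa
    raise SimilarityError(f"unknown mode {mode!r}; choose from {MODES}")


@dataclass(frozen=True)
class PairSimilarity:
    """Similarity of a query pocket against one registry entry."""

    kseq: float
    combined: float
    mode: str
    kspa: float | None = None
    rmsd: float | None = None

    @property
    def sequence_only(self) -> bool:
        return self.kspa is None


@dataclass(frozen=True)
class SimilarityVector:
    """Similarities of one query pocket against every registry entry."""

    query_id: str
    entries: tuple[tuple[int, PairSimilarity], ...]
    descending: bool = False

    def __len__(self) -> int:
        return len(self.entries)

    def sorted_descending(self) -> "SimilarityVector":
        """Stable sort by combined similarity, most similar first (ties keep registry order)."""
        ordered = tuple(
            sorted(self.entries, key=lambda item: -item[1].combined)
        )
        return SimilarityVector(self.query_id, ordered, descending=True)

    @property
    def combined_values(self) -> np.ndarray:
        return np.array([p.combined for _, p in self.entries])


def median_pairwise_seq_bandwidth(
    pseudosequences: Sequence[str], matrix: SubstitutionMatrix | None = None
) -> float:
    """Median Euclidean distance among encoded registry pseudosequences (fallback 1.0)."""
    matrix = matrix or SubstitutionMatrix.default()
    if len(pseudosequences) < 2:
        return 1.0
    vecs = np.stack([encode(p, matrix).vector for p in pseudosequences])
    med = float(np.median(pdist(vecs)))
    return med if med > 0 else 1.0


def median_pairwise_spa_bandwidth(structures: Sequence[PocketStructure]) -> float:
    """Median pairwise superposition RMSD among registry structures (fallback 1.0)."""
    structs = [s for s in structures if s is not None]
    if len(structs) < 2:
        return 1.0
    vals = [
        superpose_rmsd(structs[i], structs[j])
        for i in range(len(structs))
        for j in range(i + 1, len(structs))
    ]
    med = float(np.median(vals))
    return med if med > 0 else 1.0


def similarity_vector(
    query_pseudo: PocketPseudosequence | str,
    registry,
    mode: str = "rms",
    query_structure: PocketStructure | None = None,
    matrix: SubstitutionMatrix | None = None,
    seq_bandwidth: float | None = None,
    spa_bandwidth: float | None = None,
    query_id: str = "query",
) -> SimilarityVector:
    """Similarity of a query pocket against every entry of a raw-profile registry.

    ``registry`` is anything with an ``entries`` sequence whose items expose
    ``pseudosequence`` (str) and ``structure`` (PocketStructure or None).
    Entries lacking structural data — or a query without structure — fall back
    to the sequence channel alone (``combined = kseq``), flagged per entry.
    Default bandwidths are the median pairwise distances among registry
    entries in the respective channel.
    """
    if mode not in MODES:
        raise SimilarityError(f"unknown mode {mode!r}; choose from {MODES}")
    entries = list(registry.entries) if hasattr(registry, "entries") else list(registry)
    if not entries:
        raise SimilarityError("registry is empty")
    matrix = matrix or SubstitutionMatrix.default()
    pseudos = [e.pseudosequence for e in entries]
    if seq_bandwidth is None:
        seq_bandwidth = median_pairwise_seq_bandwidth(pseudos, matrix)
    if spa_bandwidth is None:
        spa_bandwidth = median_pairwise_spa_bandwidth(
            [getattr(e, "structure", None) for e in entries]
        )
    vq = encode(query_pseudo, matrix)
    out = []
    for i, entry in enumerate(entries):
        kseq = seq_similarity(vq, encode(entry.pseudosequence, matrix), seq_bandwidth)
        structure = getattr(entry, "structure", None)
        if query_structure is not None and structure is not None:
            rmsd = superpose_rmsd(query_structure, structure)
            kspa = spa_similarity(rmsd, spa_bandwidth)
            pair = PairSimilarity(
                kseq=kseq,
                kspa=kspa,
                rmsd=rmsd,
                combined=combine(kseq, kspa, mode),
                mode=mode,
            )
        else:
            pair = PairSimilarity(kseq=kseq, combined=kseq, mode=mode)
        out.append((i, pair))
    return SimilarityVector(query_id, tuple(out))
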