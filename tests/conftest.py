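"""Shared fixtures: substitution matrices, synthetic PDB text, rotation-grid oracle."""

from __future__ import annotations

import math
from itertools import product

import numpy as np
import pytest

from drbcore.similarity import SubstitutionMatrix


@pytest.fixture(scope="session")
def blosum62() -> SubstitutionMatrix:
    return SubstitutionMatrix.default()


@pytest.fixture(scope="session")
def biopython_blosum62():
    """Biopython's own BLOSUM62 copy — independent oracle for encoding tests."""
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


def atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    x: float,
    y: float,
    z: float,
    altloc: str = " ",
    occupancy: float = 1.0,
    icode: str = " ",
    element: str = "C",
) -> str:
    return (
        f"ATOM  {serial:5d}  {name:<3s}{altloc}{resname:>3s} {chain}"
        f"{resseq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}"
        f"{0.0:6.2f}          {element:>2s}"
    )


@pytest.fixture
def make_pdb(tmp_path):
    """Write synthetic PDB text to a temp file and return its path."""

    def _make(lines: list[str], name: str = "synthetic.pdb"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\nEND\n")
        return path

    return _make


# ---------------------------------------------------------------------------
# Brute-force rotational minimizer: independent oracle for superposition RMSD.
# ---------------------------------------------------------------------------


def _euler_matrices(az: np.ndarray, ay: np.ndarray, ax: np.ndarray) -> np.ndarray:
    """Rz(az) @ Ry(ay) @ Rx(ax) for every angle combination, shape (len(grid), 3, 3)."""
    combos = np.array(list(product(az, ay, ax)))
    a, b, c = np.deg2rad(combos[:, 0]), np.deg2rad(combos[:, 1]), np.deg2rad(combos[:, 2])
    ca_, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    R = np.empty((len(combos), 3, 3))
    R[:, 0, 0] = ca_ * cb
    R[:, 0, 1] = ca_ * sb * sc - sa * cc
    R[:, 0, 2] = ca_ * sb * cc + sa * sc
    R[:, 1, 0] = sa * cb
    R[:, 1, 1] = sa * sb * sc + ca_ * cc
    R[:, 1, 2] = sa * sb * cc - ca_ * sc
    R[:, 2, 0] = -sb
    R[:, 2, 1] = cb * sc
    R[:, 2, 2] = cb * cc
    return R, combos


def _grid_rss(ca: np.ndarray, cb: np.ndarray, az, ay, ax):
    R, combos = _euler_matrices(np.atleast_1d(az), np.atleast_1d(ay), np.atleast_1d(ax))
    rotated = np.einsum("mij,nj->mni", R, cb)
    rss = np.sum((rotated - ca[None]) ** 2, axis=(1, 2))
    return rss, combos


def grid_superposition_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimal RMSD via centroid alignment and Euler-angle grid refinement.

    A global 15-degree scan over proper rotations; the ten best coarse cells
    are each refined by four shrinking local scans (final resolution 0.024
    degrees, well inside a 1-degree grid).  Several coarse candidates are
    refined because distinct local basins can compete.  Shares no code with
    the closed-form estimator under test.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ca, cb = a - a.mean(0), b - b.mean(0)
    coarse = 15.0
    rss, combos = _grid_rss(
        ca, cb, np.arange(0, 360, coarse), np.arange(-90, 90.1, coarse), np.arange(0, 360, coarse)
    )
    best_rmsd = math.inf
    for idx in np.argsort(rss)[:10]:
        angles = combos[idx]
        rmsd = math.sqrt(rss[idx] / ca.shape[0])
        step = coarse
        for _ in range(4):
            step /= 5.0
            offsets = np.arange(-4, 4.1) * step
            local_rss, local_combos = _grid_rss(
                ca, cb, angles[0] + offsets, angles[1] + offsets, angles[2] + offsets
            )
            local_best = int(np.argmin(local_rss))
            local_rmsd = math.sqrt(local_rss[local_best] / ca.shape[0])
            if local_rmsd < rmsd:
                rmsd, angles = local_rmsd, local_combos[local_best]
        best_rmsd = min(best_rmsd, rmsd)
    return best_rmsd


@pytest.fixture(scope="session")
def grid_rmsd_oracle():
    return grid_superposition_rmsd
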