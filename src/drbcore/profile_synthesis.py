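"""Gamma-rank weighting and synthesis of pocket profiles for uncharacterized alleles.

A pocket *profile* is a 20-value vector scoring each amino acid's affinity for
one groove pocket.  For an allele with no experimentally characterized
profiles, a new profile is synthesized per anchor pocket (4, 6, 7, 9) as a
convex combination of known ("raw") profiles: registry entries are ranked by
descending similarity to the query pocket, the discretized gamma density

    G(i) = i^(k-1) * exp(-i / theta) / (theta^k * Gamma(k)),   i = 1..m

is evaluated at the ranks, sharpened by an exponent ``alpha`` and normalized,

    w_i = G(i)^alpha / sum_j G(j)^alpha,

and the reordered raw profiles are averaged with these weights.  With the
default shape k = 1 the discretized density is strictly decreasing in rank,
so more similar entries always receive larger weights, and ``alpha``
concentrates mass on the top-ranked entries (``alpha -> inf`` recovers the
most similar entry's profile; ``alpha -> 0`` with k = 1, theta -> m tends to
the plain average).

Pocket 1 is treated as shared across HLA-DR alleles, so its profile is not
synthesized: a single configured pocket-1 profile is attached unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import softmax
from scipy.stats import gamma as gamma_dist

from .pocket_model import AMINO_ACIDS, PocketStructure
from .similarity import (
    SimilarityVector,
    SubstitutionMatrix,
    similarity_vector,
)

SYNTHESIZED_POCKETS = (4, 6, 7, 9)


class ProfileSynthesisError(ValueError):
    """Base class for profile-synthesis failures."""


class UnknownAlleleError(ProfileSynthesisError):
    """The requested allele has no query pseudosequences configured."""


@dataclass(frozen=True, eq=False)
class RegistryEntry:
    """One raw (pseudosequence, profile) pair, optionally with pocket coordinates."""

    pseudosequence: str
    profile: np.ndarray  # (20,) in canonical amino-acid order
    structure: PocketStructure | None = None
    allele: str | None = None

    def __post_init__(self) -> None:
        prof = np.asarray(self.profile, dtype=float)
        if prof.shape != (20,):
            raise ProfileSynthesisError(
                f"profile must have exactly 20 values, got shape {prof.shape}"
            )
        if not np.all(np.isfinite(prof)):
            raise ProfileSynthesisError("profile values must be finite")
        object.__setattr__(self, "profile", prof)


@dataclass(frozen=True, eq=False)
class RawProfileRegistry:
    """All distinct raw pocket pseudosequences and their profiles for one anchor pocket."""

    pocket_index: int
    entries: tuple[RegistryEntry, ...]

    def __post_init__(self) -> None:
        if self.pocket_index not in SYNTHESIZED_POCKETS:
            raise ProfileSynthesisError(
                f"raw-profile registries exist for pockets {SYNTHESIZED_POCKETS}, "
                f"got {self.pocket_index}"
            )
        if not self.entries:
            raise ProfileSynthesisError("registry must be non-empty")
        object.__setattr__(self, "entries", tuple(self.entries))
        seqs = [e.pseudosequence for e in self.entries]
        if len(set(seqs)) != len(seqs):
            raise ProfileSynthesisError("registry pseudosequences must be unique")
        if len({len(s) for s in seqs}) != 1:
            raise ProfileSynthesisError("registry pseudosequences must share one length")

    @property
    def m(self) -> int:
        return len(self.entries)

    @property
    def n(self) -> int:
        return len(self.entries[0].pseudosequence)


@dataclass(frozen=True, eq=False)
class WeightVector:
    """Normalized rank weights from the discretized, sharpened gamma density."""

    weights: np.ndarray
    shape: float
    scale: float
    alpha: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ProfileSynthesisError("weights must be a non-empty vector")
        if np.any(w < 0) or abs(float(w.sum()) - 1.0) > 1e-12:
            raise ProfileSynthesisError("weights must be non-negative and sum to 1")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.weights.size


def gamma_weights(m: int, k: float = 1.0, theta: float = 1.0, alpha: float = 3.0) -> WeightVector:
    """Rank weights w_i = G(i)^alpha / sum_j G(j)^alpha for ranks i = 1..m.

    G is the gamma(k, theta) density evaluated at the integer ranks.  Computed
    in log space so large ``alpha`` cannot underflow.
    """
    if not (isinstance(m, (int, np.integer)) and m >= 1):
        raise ProfileSynthesisError(f"m must be a positive integer, got {m}")
    if k <= 0 or theta <= 0 or alpha <= 0:
        raise ProfileSynthesisError("k, theta and alpha must be positive")
    ranks = np.arange(1, m + 1, dtype=float)
    log_g = gamma_dist.logpdf(ranks, a=k, scale=theta)
    weights = softmax(alpha * log_g)
    return WeightVector(weights=weights, shape=float(k), scale=float(theta), alpha=float(alpha))


@dataclass(frozen=True, eq=False)
class SynthesizedProfile:
    """A synthesized 20-value pocket profile with full provenance."""

    pocket_index: int
    scores: np.ndarray
    mode: str | None = None
    alpha: float | None = None
    shape: float | None = None
    scale: float | None = None
    contributions: tuple[tuple[int, float], ...] = ()
    """(registry index, weight) pairs in descending-similarity order."""

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (20,):
            raise ProfileSynthesisError("scores must have exactly 20 values")
        object.__setattr__(self, "scores", scores)


def synthesize_profile(
    simvec: SimilarityVector,
    registry: RawProfileRegistry,
    weights: WeightVector,
) -> SynthesizedProfile:
    """Weighted average of raw profiles in descending-similarity order.

    The i-th weight attaches to the i-th most similar registry entry (stable
    ties keep registry order), so any strictly monotone transform of the
    similarity values yields the identical profile.
    """
    if len(simvec) != registry.m or len(weights) != registry.m:
        raise ProfileSynthesisError(
            f"length mismatch: simvec {len(simvec)}, registry {registry.m}, "
            f"weights {len(weights)}"
        )
    ordered = simvec if simvec.descending else simvec.sorted_descending()
    indices = [idx for idx, _ in ordered.entries]
    if sorted(indices) != list(range(registry.m)):
        raise ProfileSynthesisError("similarity vector must cover every registry entry")
    stacked = np.stack([registry.entries[idx].profile for idx in indices])
    scores = weights.weights @ stacked
    return SynthesizedProfile(
        pocket_index=registry.pocket_index,
        scores=scores,
        alpha=weights.alpha,
        shape=weights.shape,
        scale=weights.scale,
        contributions=tuple(zip(indices, (float(w) for w in weights.weights))),
    )


@dataclass
class AlleleQuery:
    """Per-pocket pseudosequences (and optional pocket coordinates) of a query allele."""

    allele: str
    pseudosequences: dict[int, str]
    structures: dict[int, PocketStructure] = field(default_factory=dict)


def synthesize_allele(
    query: AlleleQuery,
    registries: Mapping[int, RawProfileRegistry],
    pocket1_profile: np.ndarray | None,
    mode: str = "rms",
    alpha: float = 3.0,
    k: float = 1.0,
    theta: float = 1.0,
    matrix: SubstitutionMatrix | None = None,
    seq_bandwidth: float | None = None,
    spa_bandwidth: float | None = None,
    include_pocket1: bool = True,
) -> dict[int, SynthesizedProfile]:
    """Synthesize anchor-pocket profiles 4/6/7/9 for one allele.

    Returns a pocket -> profile map.  When ``include_pocket1`` is set, the
    configured shared pocket-1 profile is attached unchanged under key 1 (it
    is an error to request pocket 1 without configuring its profile).
    """
    matrix = matrix or SubstitutionMatrix.default()
    profiles: dict[int, SynthesizedProfile] = {}
    if include_pocket1:
        if pocket1_profile is None:
            raise ProfileSynthesisError("pocket-1 profile required but not configured")
        p1 = np.asarray(pocket1_profile, dtype=float)
        if p1.shape != (20,):
            raise ProfileSynthesisError("pocket-1 profile must have exactly 20 values")
        profiles[1] = SynthesizedProfile(pocket_index=1, scores=p1)
    for pocket in SYNTHESIZED_POCKETS:
        if pocket not in registries:
            raise ProfileSynthesisError(f"no registry for anchor pocket {pocket}")
        registry = registries[pocket]
        if pocket not in query.pseudosequences:
            raise ProfileSynthesisError(
                f"query {query.allele!r} lacks a pocket-{pocket} pseudosequence"
            )
        simvec = similarity_vector(
            query.pseudosequences[pocket],
            registry,
            mode=mode,
            query_structure=query.structures.get(pocket),
            matrix=matrix,
            seq_bandwidth=seq_bandwidth,
            spa_bandwidth=spa_bandwidth,
            query_id=query.allele,
        )
        weights = gamma_weights(registry.m, k=k, theta=theta, alpha=alpha)
        prof = synthesize_profile(simvec, registry, weights)
        profiles[pocket] = SynthesizedProfile(
            pocket_index=pocket,
            scores=prof.scores,
            mode=mode,
            alpha=prof.alpha,
            shape=prof.shape,
            scale=prof.scale,
            contributions=prof.contributions,
        )
    return profiles


class PanAllelePredictor:
    """allele name -> anchor-pocket profiles, via similarity-weighted synthesis.

    Wraps per-pocket raw-profile registries, a shared pocket-1 profile and the
    query pseudosequences of the alleles to predict.  Calling the predictor
    with an allele name returns its pocket -> score-array map (cached).
    """

    def __init__(
        self,
        registries: Mapping[int, RawProfileRegistry],
        queries: Mapping[str, AlleleQuery],
        pocket1_profile: np.ndarray | None = None,
        mode: str = "rms",
        alpha: float = 3.0,
        k: float = 1.0,
        theta: float = 1.0,
        matrix: SubstitutionMatrix | None = None,
        seq_bandwidth: float | None = None,
        spa_bandwidth: float | None = None,
        include_pocket1: bool = True,
    ) -> None:
        self.registries = dict(registries)
        self.queries = dict(queries)
        self.pocket1_profile = pocket1_profile
        self.mode = mode
        self.alpha = alpha
        self.k = k
        self.theta = theta
        self.matrix = matrix or SubstitutionMatrix.default()
        self.seq_bandwidth = seq_bandwidth
        self.spa_bandwidth = spa_bandwidth
        self.include_pocket1 = include_pocket1
        self._cache: dict[str, dict[int, np.ndarray]] = {}

    def __call__(self, allele: str) -> dict[int, np.ndarray]:
        if allele not in self._cache:
            if allele not in self.queries:
                raise UnknownAlleleError(f"no query pseudosequences for allele {allele!r}")
            synth = synthesize_allele(
                self.queries[allele],
                self.registries,
                self.pocket1_profile,
                mode=self.mode,
                alpha=self.alpha,
                k=self.k,
                theta=self.theta,
                matrix=self.matrix,
                seq_bandwidth=self.seq_bandwidth,
                spa_bandwidth=self.spa_bandwidth,
                include_pocket1=self.include_pocket1,
            )
            self._cache[allele] = {p: s.scores for p, s in synth.items()}
        return self._cache[allele]


# ---------------------------------------------------------------------------
# TSV interface (TEPITOPE-style): allele, pocket, pseudosequence, 20 score columns
# ---------------------------------------------------------------------------

PROFILE_COLUMNS = ["allele", "pocket", "pseudosequence", *AMINO_ACIDS]


def read_profile_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"allele": str})
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ProfileSynthesisError(
            f"{path}: profile table lacks required columns {missing}"
        )
    return df


def read_profile_registries(
    path: str | Path,
    structures: Mapping[tuple[str, int], PocketStructure] | None = None,
) -> dict[int, RawProfileRegistry]:
    """Load per-pocket raw-profile registries from a profile TSV.

    ``structures`` optionally attaches pocket coordinates keyed by
    (allele, pocket).  Duplicate pseudosequences within a pocket keep the
    first occurrence (alleles sharing a pocket pseudosequence share its
    profile by assumption).
    """
    df = read_profile_table(path)
    structures = structures or {}
    registries: dict[int, RawProfileRegistry] = {}
    for pocket, group in df.groupby("pocket", sort=True):
        pocket = int(pocket)
        if pocket not in SYNTHESIZED_POCKETS:
            continue
        entries = []
        seen: set[str] = set()
        for _, row in group.iterrows():
            pseudo = str(row["pseudosequence"])
            if pseudo in seen:
                continue
            seen.add(pseudo)
            entries.append(
                RegistryEntry(
                    pseudosequence=pseudo,
                    profile=row[list(AMINO_ACIDS)].to_numpy(dtype=float),
                    structure=structures.get((row["allele"], pocket)),
                    allele=row["allele"],
                )
            )
        registries[pocket] = RawProfileRegistry(pocket_index=pocket, entries=tuple(entries))
    return registries


def read_pocket1_profile(path: str | Path) -> np.ndarray:
    """Read the shared pocket-1 profile (the pocket == 1 row of a profile TSV)."""
    df = read_profile_table(path)
    rows = df[df["pocket"] == 1]
    if rows.empty:
        raise ProfileSynthesisError(f"{path}: no pocket-1 row found")
    return rows.iloc[0][list(AMINO_ACIDS)].to_numpy(dtype=float)


def read_allele_queries(path: str | Path) -> dict[str, AlleleQuery]:
    """Read query pseudosequences: TSV with columns allele, pocket, pseudosequence."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"allele": str, "pseudosequence": str})
    missing = [c for c in ("allele", "pocket", "pseudosequence") if c not in df.columns]
    if missing:
        raise ProfileSynthesisError(f"{path}: query table lacks columns {missing}")
    queries: dict[str, AlleleQuery] = {}
    for (allele,), group in df.groupby(["allele"], sort=False):
        queries[allele] = AlleleQuery(
            allele=allele,
            pseudosequences={
                int(row["pocket"]): str(row["pseudosequence"]) for _, row in group.iterrows()
            },
        )
    return queries


def write_profile_table(
    path: str | Path,
    rows: Iterable[tuple[str, int, str, np.ndarray]],
    header_comments: Sequence[str] = (),
) -> None:
    """Write (allele, pocket, pseudosequence, scores) rows in the profile TSV dialect."""
    records = [
        {
            "allele": allele,
            "pocket": pocket,
            "pseudosequence": pseudo,
            **{aa: float(s) for aa, s in zip(AMINO_ACIDS, np.asarray(scores, dtype=float))},
        }
        for allele, pocket, pseudo, scores in rows
    ]
    df = pd.DataFrame.from_records(records, columns=PROFILE_COLUMNS)
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
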