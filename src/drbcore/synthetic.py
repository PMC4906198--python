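"""Synthetic registries, planted-core peptides and the packaged benchmark tables.

Everything every other module needs for end-to-end testing is generated here
from a seed, with guarantees that are re-verified at generation time:

* random raw-profile registries whose entry coordinates are a fixed template
  plus a perturbation growing with the entry index, so the structural
  similarity ordering is known by construction;
* "planted-core" peptides: profiles are drawn and then boosted so that one
  designated 9-mer window out-scores every other window by at least a chosen
  contrast — the planting is verified exhaustively before the peptide is
  returned;
* full synthetic evaluation scenarios (registries + query alleles + annotated
  records) for pipeline-level tests, including a decoy-registry scenario in
  which per-record correctness is provably monotone in the weight exponent
  ``alpha``;
* the packaged transcriptions of the benchmark tables: 39 crystal complexes
  with annotated cores (30 test + 9 held-out), the canonical pocket model,
  per-complex observed pocket compositions, the published reference
  predictions of this and three competitor methods, and the eleven reference
  allele names.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_prediction import ComplexRecord, predict_core, score_window
from .pocket_model import (
    AMINO_ACIDS,
    PocketDefinition,
    PocketStructure,
    default_pocket_definitions,
    parse_residue_annotations,
)
from .profile_synthesis import (
    AlleleQuery,
    RawProfileRegistry,
    RegistryEntry,
)

SCORED_POCKETS = (1, 4, 6, 7, 9)


class FixtureError(ValueError):
    """Base class for fixture-generation failures."""


class PlantingError(FixtureError):
    """The requested contrast cannot be achieved with the given profiles."""


class TableLoadError(FixtureError):
    """A packaged data file is missing or malformed."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of synthetic data generation.

    ``coordinate_noise`` is the per-rank structural perturbation in Angstrom;
    ``profile_contrast`` the score gap guaranteed between the planted window
    and every other window.
    """

    seed: int = 0
    m: int = 5
    n: int = 6
    coordinate_noise: float = 0.5
    profile_contrast: float = 6.0
    peptide_length: int = 15

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise FixtureError("registry size m and pseudosequence length n must be positive")
        if self.m > 20**self.n:
            raise FixtureError(
                f"cannot draw {self.m} distinct length-{self.n} pseudosequences"
            )
        if self.coordinate_noise < 0:
            raise FixtureError("coordinate_noise must be non-negative")
        if self.profile_contrast <= 0:
            raise FixtureError("profile_contrast must be positive")
        if self.peptide_length < 9:
            raise FixtureError("peptide_length must be at least 9")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _random_pseudosequences(rng: np.random.Generator, m: int, n: int) -> list[str]:
    letters = np.array(list(AMINO_ACIDS))
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < m:
        s = "".join(rng.choice(letters, size=n))
        if s not in seen:
            seen.add(s)
            seqs.append(s)
    return seqs


def make_planted_profiles(
    rng: np.random.Generator,
    contrast: float,
    pockets: Sequence[int] = SCORED_POCKETS,
) -> tuple[dict[int, np.ndarray], dict[int, str]]:
    """Random anchor profiles with one boosted residue per pocket.

    Base scores are uniform in [-2, 2] (TEPITOPE-style signed scores); each
    pocket's boosted residue — distinct across pockets — gains ``contrast``.
    Returns (pocket -> profile, pocket -> boosted letter).
    """
    if contrast <= 0:
        raise PlantingError("contrast must be positive")
    boosted_idx = rng.choice(20, size=len(pockets), replace=False)
    profiles: dict[int, np.ndarray] = {}
    boosted: dict[int, str] = {}
    for pocket, idx in zip(pockets, boosted_idx):
        prof = rng.uniform(-2.0, 2.0, size=20)
        prof[idx] += contrast
        profiles[pocket] = prof
        boosted[pocket] = AMINO_ACIDS[idx]
    return profiles, boosted


def _filler_letter(profiles: Mapping[int, np.ndarray], exclude: set[str]) -> str:
    """Letter with the smallest worst-case anchor score, avoiding excluded letters."""
    best, best_val = None, np.inf
    for i, letter in enumerate(AMINO_ACIDS):
        if letter in exclude:
            continue
        val = max(float(np.asarray(p)[i]) for p in profiles.values())
        if val < best_val:
            best, best_val = letter, val
    if best is None:
        raise PlantingError("no filler letter available")
    return best


def plant_core_peptide(
    profiles: Mapping[int, np.ndarray],
    spec: FixtureSpec,
    rng: np.random.Generator | None = None,
    offset: int | None = None,
    include_pocket1: bool = True,
) -> tuple[str, int]:
    """Build a peptide whose designated window out-scores all others by the contrast.

    The designated window places each pocket's best-scoring residue at the
    position facing that pocket; all remaining positions take a low-scoring
    filler letter.  The guarantee — designated window score at least
    ``spec.profile_contrast`` above every other window — is verified
    exhaustively before returning; failure raises :class:`PlantingError`.
    """
    rng = rng or spec.rng()
    length = spec.peptide_length
    n_windows = length - 8
    if offset is None:
        offset = int(rng.integers(0, n_windows))
    if not 0 <= offset < n_windows:
        raise PlantingError(f"offset {offset} out of range for length {length}")
    pockets = SCORED_POCKETS if include_pocket1 else (4, 6, 7, 9)
    for p in pockets:
        if p not in profiles:
            raise PlantingError(f"profiles must cover anchor pocket {p}")
    best_letters = {
        p: AMINO_ACIDS[int(np.argmax(np.asarray(profiles[p])))] for p in pockets
    }
    filler = _filler_letter(
        {p: profiles[p] for p in pockets}, exclude=set(best_letters.values())
    )
    residues = [filler] * length
    for p in pockets:
        residues[offset + p - 1] = best_letters[p]
    peptide = "".join(residues)

    scores = [
        score_window(peptide[o : o + 9], profiles, include_pocket1)
        for o in range(n_windows)
    ]
    margin = scores[offset] - max(
        (s for o, s in enumerate(scores) if o != offset), default=-np.inf
    )
    if n_windows > 1 and margin < spec.profile_contrast:
        raise PlantingError(
            f"achieved margin {margin:.3f} below required contrast "
            f"{spec.profile_contrast:.3f}"
        )
    return peptide, offset


def _perturbation_direction(rng: np.random.Generator, n: int) -> np.ndarray:
    d = rng.normal(size=(n, 3))
    return d / np.linalg.norm(d) * np.sqrt(n)


def generate_registry(
    spec: FixtureSpec,
    pocket_index: int = 4,
    rng: np.random.Generator | None = None,
    first_entry: tuple[str, np.ndarray] | None = None,
) -> tuple[RawProfileRegistry, PocketStructure | None]:
    """Random raw-profile registry with rank-ordered structural perturbations.

    Entry i's coordinates are a fixed template plus a shared perturbation
    direction scaled by ``i * coordinate_noise`` (1-based), so superposition
    RMSD against the template strictly increases with the entry index; the
    ordering is re-verified at generation time.  ``first_entry`` optionally
    pins entry 0 to a given (pseudosequence, profile) pair.  Returns the
    registry and the template structure (the natural query structure);
    structures are omitted when the pseudosequence is too short to superpose.

    Same spec, same output — generation is fully seed-deterministic.
    """
    from .similarity import superpose_rmsd  # local import to avoid cycle at import time

    rng = rng or spec.rng()
    seqs = _random_pseudosequences(rng, spec.m + 1, spec.n)
    if first_entry is not None:
        pinned_seq, pinned_prof = first_entry
        seqs = [pinned_seq] + [s for s in seqs if s != pinned_seq][: spec.m - 1]
    else:
        seqs = seqs[: spec.m]
    profiles = [rng.uniform(-2.0, 2.0, size=20) for _ in range(spec.m)]
    if first_entry is not None:
        profiles[0] = np.asarray(pinned_prof, dtype=float)

    template: PocketStructure | None = None
    structures: list[PocketStructure | None] = [None] * spec.m
    if spec.n >= 3:
        template_coords = rng.normal(scale=2.0, size=(spec.n, 3))
        template = PocketStructure(pocket_index, template_coords, source_id="template")
        for _attempt in range(20):
            direction = _perturbation_direction(rng, spec.n)
            structures = [
                PocketStructure(
                    pocket_index,
                    template_coords + (i + 1) * spec.coordinate_noise * direction,
                    source_id=f"synthetic-{i}",
                )
                for i in range(spec.m)
            ]
            if spec.coordinate_noise == 0:
                break
            rmsds = [superpose_rmsd(template, s) for s in structures]
            if all(b > a for a, b in zip(rmsds, rmsds[1:])):
                break
        else:
            raise FixtureError("could not realise a strictly ordered perturbation")

    entries = tuple(
        RegistryEntry(
            pseudosequence=seqs[i],
            profile=profiles[i],
            structure=structures[i],
            allele=f"SYN-{pocket_index}-{i}",
        )
        for i in range(spec.m)
    )
    return RawProfileRegistry(pocket_index=pocket_index, entries=entries), template


@dataclass
class SyntheticScenario:
    """A self-contained synthetic evaluation problem."""

    registries: dict[int, RawProfileRegistry]
    queries: dict[str, AlleleQuery]
    pocket1_profile: np.ndarray
    records: list[ComplexRecord]
    true_offsets: dict[str, int]
    planted_profiles: dict[int, np.ndarray]


def generate_scenario(spec: FixtureSpec, n_peptides: int = 1) -> SyntheticScenario:
    """Planted-core scenario: the query matches registry entry 0 in every pocket.

    Entry 0 of each anchor-pocket registry carries the planted profiles, and
    the query allele's pseudosequences (and structures: the registry
    templates) coincide with it, so profile synthesis should recover the
    planted profiles as the weights concentrate and the annotated cores
    should be recovered.
    """
    rng = spec.rng()
    profiles, _ = make_planted_profiles(rng, spec.profile_contrast)
    registries: dict[int, RawProfileRegistry] = {}
    structures: dict[int, PocketStructure] = {}
    pseudos: dict[int, str] = {}
    for pocket in (4, 6, 7, 9):
        seq = "".join(np.random.default_rng(spec.seed + pocket).choice(list(AMINO_ACIDS), spec.n))
        registry, template = generate_registry(
            spec, pocket_index=pocket, rng=rng, first_entry=(seq, profiles[pocket])
        )
        registries[pocket] = registry
        pseudos[pocket] = seq
        if template is not None:
            structures[pocket] = template
    allele = f"SYNT-{spec.seed}"
    queries = {allele: AlleleQuery(allele, pseudos, structures)}

    records = []
    true_offsets: dict[str, int] = {}
    for j in range(n_peptides):
        peptide, offset = plant_core_peptide(profiles, spec, rng)
        pdb_id = f"SYN{spec.seed:04d}-{j}"
        records.append(
            ComplexRecord(
                pdb_id=pdb_id,
                allele=allele,
                peptide=peptide,
                core=peptide[offset : offset + 9],
                split="synthetic",
            )
        )
        true_offsets[pdb_id] = offset
    return SyntheticScenario(
        registries=registries,
        queries=queries,
        pocket1_profile=profiles[1],
        records=records,
        true_offsets=true_offsets,
        planted_profiles=profiles,
    )


def generate_decoy_scenario(
    spec: FixtureSpec, decoy_boost: float = 25.0, n_peptides: int = 3
) -> SyntheticScenario:
    """Scenario whose per-record correctness is provably monotone in ``alpha``.

    Registry entry 0 carries the true planted profiles; every other entry
    carries a *decoy* profile sharing the same base scores but boosting the
    residues of a different window (by ``decoy_boost``, larger than the true
    contrast).  Each peptide presents both the true window and the decoy
    window.  Window margins under the synthesized profile are then affine and
    increasing in the top-rank weight, which itself increases with ``alpha``
    (shape k = 1), so errors can only decrease as ``alpha`` grows.
    """
    if spec.peptide_length < 21:
        raise FixtureError("decoy scenario needs peptide_length >= 21 for disjoint windows")
    rng = spec.rng()
    # Distinct boosted letters for true and decoy sets, plus a filler letter.
    letters = rng.permutation(list(AMINO_ACIDS))
    true_letters = {p: letters[i] for i, p in enumerate(SCORED_POCKETS)}
    decoy_letters = {p: letters[5 + i] for i, p in enumerate(SCORED_POCKETS)}
    filler = str(letters[10])

    base = {p: rng.uniform(-2.0, 2.0, size=20) for p in SCORED_POCKETS}
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    true_profiles, decoy_profiles = {}, {}
    for p in SCORED_POCKETS:
        tp, dp = base[p].copy(), base[p].copy()
        tp[idx[true_letters[p]]] += spec.profile_contrast
        dp[idx[decoy_letters[p]]] += decoy_boost
        true_profiles[p] = tp
        decoy_profiles[p] = dp

    # Registry entry 0 matches the query exactly; others are mutated copies.
    registries: dict[int, RawProfileRegistry] = {}
    pseudos: dict[int, str] = {}
    for pocket in (4, 6, 7, 9):
        qseq = "".join(rng.choice(list(AMINO_ACIDS), spec.n))
        seqs, seen = [qseq], {qseq}
        while len(seqs) < spec.m:
            mut = list(qseq)
            for pos in range(min(len(seqs), spec.n)):
                choices = [a for a in AMINO_ACIDS if a != qseq[pos]]
                mut[pos] = rng.choice(choices)
            s = "".join(mut)
            if s not in seen:
                seen.add(s)
                seqs.append(s)
        entries = tuple(
            RegistryEntry(
                pseudosequence=s,
                profile=(true_profiles if i == 0 else decoy_profiles)[pocket],
                allele=f"DEC-{pocket}-{i}",
            )
            for i, s in enumerate(seqs)
        )
        registries[pocket] = RawProfileRegistry(pocket_index=pocket, entries=entries)
        pseudos[pocket] = qseq

    allele = f"DECOY-{spec.seed}"
    queries = {allele: AlleleQuery(allele, pseudos)}

    records, true_offsets = [], {}
    n_windows = spec.peptide_length - 8
    for j in range(n_peptides):
        # both windows disjoint: restrict the true offset to positions that
        # leave room for a decoy window at least 9 positions away
        valid = [t for t in range(n_windows) if any(abs(o - t) >= 9 for o in range(n_windows))]
        if not valid:
            raise FixtureError("no disjoint decoy window available")
        true_off = int(rng.choice(valid))
        candidates = [o for o in range(n_windows) if abs(o - true_off) >= 9]
        decoy_off = int(rng.choice(candidates))
        residues = [filler] * spec.peptide_length
        for p in SCORED_POCKETS:
            residues[true_off + p - 1] = true_letters[p]
            residues[decoy_off + p - 1] = decoy_letters[p]
        peptide = "".join(residues)
        scores = [
            score_window(peptide[o : o + 9], true_profiles) for o in range(n_windows)
        ]
        margin = scores[true_off] - max(
            s for o, s in enumerate(scores) if o != true_off
        )
        if margin < spec.profile_contrast:
            raise PlantingError(
                f"decoy peptide margin {margin:.3f} below contrast under true profiles"
            )
        pdb_id = f"DEC{spec.seed:04d}-{j}"
        records.append(
            ComplexRecord(
                pdb_id=pdb_id,
                allele=allele,
                peptide=peptide,
                core=peptide[true_off : true_off + 9],
                split="synthetic",
            )
        )
        true_offsets[pdb_id] = true_off
    return SyntheticScenario(
        registries=registries,
        queries=queries,
        pocket1_profile=true_profiles[1],
        records=records,
        true_offsets=true_offsets,
        planted_profiles=true_profiles,
    )


def recovery_under_profile_noise(
    base_seed: int,
    noise_levels: Sequence[float],
    n_instances: int = 50,
    spec_kwargs: Mapping | None = None,
) -> dict[float, float]:
    """Planted-core recovery rate when scoring profiles are perturbed.

    For each instance a planted peptide is generated, one Gaussian
    perturbation is drawn, and prediction runs with profiles perturbed by
    ``level * perturbation`` for every level.  Window-score margins are affine
    in the level, so each instance's correctness region is an interval
    containing zero: per-instance recovery — hence the rate — is
    nonincreasing in the noise level by construction.
    """
    spec_kwargs = dict(spec_kwargs or {})
    hits = {level: 0 for level in noise_levels}
    for i in range(n_instances):
        spec = FixtureSpec(seed=base_seed + i, **spec_kwargs)
        rng = spec.rng()
        profiles, _ = make_planted_profiles(rng, spec.profile_contrast)
        peptide, offset = plant_core_peptide(profiles, spec, rng)
        noise = {p: rng.normal(size=20) for p in SCORED_POCKETS}
        for level in noise_levels:
            noisy = {p: profiles[p] + level * noise[p] for p in SCORED_POCKETS}
            pred = predict_core(peptide, noisy)
            if pred.predicted_core == peptide[offset : offset + 9]:
                hits[level] += 1
    return {level: hits[level] / n_instances for level in noise_levels}


# ---------------------------------------------------------------------------
# Packaged benchmark tables
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkTables:
    """The packaged benchmark dataset and reference material."""

    records: list[ComplexRecord]
    pocket_definitions: dict[int, PocketDefinition]
    complex_pockets: dict[str, dict[int, list[tuple[int, str]]]]
    reference_predictions: pd.DataFrame
    reference_alleles: list[str]
    alt_peptides: dict[str, str]

    @property
    def test_records(self) -> list[ComplexRecord]:
        return [r for r in self.records if r.split == "test30"]

    @property
    def heldout_records(self) -> list[ComplexRecord]:
        return [r for r in self.records if r.split == "heldout9"]


def _read_packaged_tsv(name: str, **kwargs) -> pd.DataFrame:
    path = resources.files("drbcore.data").joinpath(name)
    try:
        with path.open() as fh:
            return pd.read_csv(fh, sep="\t", comment="#", **kwargs)
    except FileNotFoundError as exc:
        raise TableLoadError(f"packaged data file {name} is missing") from exc
    except (pd.errors.ParserError, ValueError) as exc:
        raise TableLoadError(f"packaged data file {name} is malformed: {exc}") from exc


def load_benchmark_tables() -> BenchmarkTables:
    """Load and validate the packaged benchmark tables.

    Schema violations (wrong record count, non-9-mer cores, cores absent from
    their peptides, missing columns) raise :class:`TableLoadError` naming the
    offending file.
    """
    complexes = _read_packaged_tsv("complexes.tsv", dtype=str)
    required = {"pdb_id", "allele", "peptide", "core", "split"}
    if not required.issubset(complexes.columns):
        raise TableLoadError("complexes.tsv: missing required columns")
    records, alt_peptides = [], {}
    for _, row in complexes.iterrows():
        try:
            records.append(
                ComplexRecord(
                    pdb_id=row["pdb_id"],
                    allele=row["allele"],
                    peptide=row["peptide"],
                    core=row["core"],
                    split=row["split"],
                )
            )
        except ValueError as exc:
            raise TableLoadError(f"complexes.tsv: {exc}") from exc
        alt = row.get("alt_peptide")
        if isinstance(alt, str) and alt:
            alt_peptides[row["pdb_id"]] = alt
    splits = {r.split for r in records}
    if len(records) != 39 or splits != {"test30", "heldout9"}:
        raise TableLoadError("complexes.tsv: expected 39 records in splits test30/heldout9")
    if sum(r.split == "test30" for r in records) != 30:
        raise TableLoadError("complexes.tsv: expected 30 test records")

    pockets = default_pocket_definitions()

    comp = _read_packaged_tsv("complex_pockets.tsv", dtype=str).fillna("")
    complex_pockets: dict[str, dict[int, list[tuple[int, str]]]] = {}
    for _, row in comp.iterrows():
        complex_pockets[row["pdb_id"]] = {
            p: parse_residue_annotations(row[f"pocket{p}"]) for p in range(1, 10)
        }

    refs = _read_packaged_tsv("reference_predictions.tsv", dtype=str)
    if "ours" not in refs.columns or len(refs) != 39:
        raise TableLoadError("reference_predictions.tsv: expected 39 rows with an 'ours' column")

    alleles_df = _read_packaged_tsv("alleles.tsv", dtype=str)
    reference_alleles = list(alleles_df["allele"])
    if len(reference_alleles) != 11:
        raise TableLoadError("alleles.tsv: expected 11 reference alleles")

    return BenchmarkTables(
        records=records,
        pocket_definitions=pockets,
        complex_pockets=complex_pockets,
        reference_predictions=refs,
        reference_alleles=reference_alleles,
        alt_peptides=alt_peptides,
    )


def reference_error_counts(tables: BenchmarkTables | None = None) -> dict[str, int]:
    """Error counts of the published reference predictions vs the annotated cores.

    Recomputed from the bundled static columns by exact 9-mer comparison:
    keys like ``"ours_test30"`` or ``"tepitope_test30"``.
    """
    tables = tables or load_benchmark_tables()
    cores = {r.pdb_id: r.core for r in tables.records}
    splits = {r.pdb_id: r.split for r in tables.records}
    counts: dict[str, int] = {}
    for method in ("ours", "tepitope", "multirta", "netmhciipan20"):
        if method not in tables.reference_predictions.columns:
            continue
        for _, row in tables.reference_predictions.iterrows():
            pred = row[method]
            if not isinstance(pred, str) or not pred:
                continue
            key = f"{method}_{splits[row['pdb_id']]}"
            counts.setdefault(key, 0)
            if pred != cores[row["pdb_id"]]:
                counts[key] += 1
    return counts
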