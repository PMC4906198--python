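"""Sliding-window binding-core prediction and its evaluation.

Every contiguous 9-mer window of a peptide is scored by summing, over the
anchor pockets, the pocket profile's score for the residue facing that
pocket (window position p faces pocket p).  Non-anchor pockets contribute
zero, following the TEPITOPE convention; an ``'X'`` residue contributes zero
at its position.  The window with the maximal score is the predicted binding
core; ties go to the leftmost window.

Evaluation compares predicted and annotated cores as exact 9-mer strings
(identical 9-mers at different offsets are indistinguishable in the
benchmark tables) and counts mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pocket_model import AMINO_ACIDS
from .profile_synthesis import UnknownAlleleError

CORE_LENGTH = 9
ANCHOR_POCKETS_SCORED = (1, 4, 6, 7, 9)

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


class PredictionError(ValueError):
    """Base class for core-prediction failures."""


class MissingProfileError(PredictionError):
    """An anchor pocket has no profile configured."""


@dataclass(frozen=True)
class ComplexRecord:
    """One MHC II / peptide complex with an annotated 9-mer binding core."""

    pdb_id: str
    allele: str
    peptide: str
    core: str
    split: str = "test30"

    def __post_init__(self) -> None:
        if len(self.core) != CORE_LENGTH:
            raise PredictionError(
                f"{self.pdb_id}: core must have length {CORE_LENGTH}, got {len(self.core)}"
            )
        if len(self.peptide) < CORE_LENGTH:
            raise PredictionError(f"{self.pdb_id}: peptide shorter than a core")
        if self.core not in self.peptide:
            raise PredictionError(f"{self.pdb_id}: core does not occur in peptide")


@dataclass(frozen=True, eq=False)
class CorePrediction:
    """Predicted binding core of one peptide, with all window scores."""

    peptide: str
    predicted_core: str
    offset: int
    window_scores: np.ndarray


def _profile_scores(profiles, pocket: int) -> np.ndarray:
    if pocket not in profiles:
        raise MissingProfileError(f"no profile for anchor pocket {pocket}")
    prof = profiles[pocket]
    return np.asarray(getattr(prof, "scores", prof), dtype=float)


def _scored_pockets(include_pocket1: bool) -> tuple[int, ...]:
    return ANCHOR_POCKETS_SCORED if include_pocket1 else (4, 6, 7, 9)


def _residue_score(profile: np.ndarray, letter: str) -> float:
    if letter == "X":
        return 0.0
    if letter not in _AA_INDEX:
        raise PredictionError(f"cannot score residue {letter!r}")
    return float(profile[_AA_INDEX[letter]])


def score_window(window: str, profiles: Mapping[int, object], include_pocket1: bool = True) -> float:
    """Anchor-pocket score of a single 9-mer window."""
    if len(window) != CORE_LENGTH:
        raise PredictionError(f"window must have length {CORE_LENGTH}, got {len(window)}")
    total = 0.0
    for pocket in _scored_pockets(include_pocket1):
        total += _residue_score(_profile_scores(profiles, pocket), window[pocket - 1])
    return total


def predict_core(
    peptide: str, profiles: Mapping[int, object], include_pocket1: bool = True
) -> CorePrediction:
    """Score every 9-mer window of the peptide and return the argmax (leftmost on ties)."""
    if len(peptide) < CORE_LENGTH:
        raise PredictionError(
            f"peptide must have length >= {CORE_LENGTH}, got {len(peptide)}"
        )
    n_windows = len(peptide) - CORE_LENGTH + 1
    scores = np.empty(n_windows)
    for off in range(n_windows):
        scores[off] = score_window(peptide[off : off + CORE_LENGTH], profiles, include_pocket1)
    best = int(np.argmax(scores))  # first maximum = leftmost tie-break
    return CorePrediction(
        peptide=peptide,
        predicted_core=peptide[best : best + CORE_LENGTH],
        offset=best,
        window_scores=scores,
    )


@dataclass(frozen=True)
class EvaluationRow:
    pdb_id: str
    allele: str
    annotated: str
    predicted: str | None
    correct: bool
    error: str | None = None


@dataclass(frozen=True)
class EvaluationReport:
    """Per-complex predictions and the total error count of one evaluation run."""

    rows: tuple[EvaluationRow, ...]
    total_errors: int
    parameters: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "pdb_id": r.pdb_id,
                    "allele": r.allele,
                    "annotated": r.annotated,
                    "predicted": r.predicted if r.predicted is not None else "",
                    "correct": r.correct,
                    "error": r.error or "",
                }
                for r in self.rows
            ]
        )


def evaluate(
    records: Sequence[ComplexRecord],
    predictor: Callable[[str], Mapping[int, object]],
    include_pocket1: bool = True,
    parameters: Mapping | None = None,
) -> EvaluationReport:
    """Predict a binding core for every record and count exact-string mismatches.

    ``predictor`` maps an allele name to its pocket -> profile mapping.  An
    allele the predictor cannot resolve produces a per-record error entry
    (counted as an error), never a crash.  Report rows keep input order.
    """
    rows = []
    n_errors = 0
    for record in records:
        try:
            profiles = predictor(record.allele)
            pred = predict_core(record.peptide, profiles, include_pocket1)
            correct = pred.predicted_core == record.core
            rows.append(
                EvaluationRow(
                    pdb_id=record.pdb_id,
                    allele=record.allele,
                    annotated=record.core,
                    predicted=pred.predicted_core,
                    correct=correct,
                )
            )
            if not correct:
                n_errors += 1
        except (UnknownAlleleError, MissingProfileError) as exc:
            rows.append(
                EvaluationRow(
                    pdb_id=record.pdb_id,
                    allele=record.allele,
                    annotated=record.core,
                    predicted=None,
                    correct=False,
                    error=str(exc),
                )
            )
            n_errors += 1
    return EvaluationReport(
        rows=tuple(rows),
        total_errors=n_errors,
        parameters=dict(parameters or {}),
    )


def alpha_sweep(
    records: Sequence[ComplexRecord],
    predictor_factory: Callable[[str, float], Callable[[str], Mapping[int, object]]],
    modes: Sequence[str] = ("rms", "mean", "sum"),
    alphas: Sequence[float] = (1, 2, 3, 4, 5, 10, 15, 20),
    include_pocket1: bool = True,
) -> pd.DataFrame:
    """Error counts over a (mode, alpha) grid, all other parameters fixed.

    ``predictor_factory(mode, alpha)`` must return an allele -> profiles
    callable.  The result is a long-format table with columns
    ``mode, alpha, errors`` — one evaluation run per cell.
    """
    if not records:
        raise PredictionError("no records to evaluate")
    if not modes or not alphas:
        raise PredictionError("modes and alphas must be non-empty")
    cells = []
    for mode in modes:
        for alpha in alphas:
            predictor = predictor_factory(mode, alpha)
            report = evaluate(records, predictor, include_pocket1)
            cells.append({"mode": mode, "alpha": alpha, "errors": report.total_errors})
    return pd.DataFrame(cells, columns=["mode", "alpha", "errors"])
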