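"""Scoring of alignment columns for response determination.

A column is a candidate response-determining position when receptor pairs
sharing the same residue there have more similar odorant-response profiles
than pairs with different residues.  The score of a column is

    mean response distance over mismatched pairs
  - mean response distance over matched pairs,

in spikes, where the response distance between two receptors is the mean
absolute difference of their responses over the odorants both were measured
on.  Pairs with a gap (or unknown residue ``X``) at the column contribute no
evidence and are excluded.  Columns are eligible when they have at least one
matched and one mismatched pair (a configurable stricter minimum is
available); the top-K eligible columns by score form the candidate
response-determining set (K = 20 by default, matching the scale at which
receptor function is typically dissected).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, RankingError, UndefinedDistanceError
from .io import (
    GAP,
    UNKNOWN,
    OrthologAlignment,
    ReferencePositionMap,
    ResponseMatrix,
    build_reference_map,
)

__all__ = [
    "PositionScoreTable",
    "response_distance",
    "pairwise_response_distances",
    "position_score",
    "rank_positions",
]


@dataclass(frozen=True)
class PositionScoreTable:
    """Per-column scores plus the ordered top-K eligible columns.

    ``scores`` has one row per alignment column with columns: ``column``,
    ``ref_index`` (NaN where the reference is gapped), ``score`` (spikes, NaN
    if ineligible), ``n_match_pairs``, ``n_mismatch_pairs``, ``eligible``,
    ``rank`` (1-based over eligible columns, NaN otherwise) and ``in_top_k``.
    """

    scores: pd.DataFrame
    top_k: tuple[int, ...]  # alignment column indices, best first
    k: int

    def score_of(self, column: int) -> float:
        return float(self.scores.loc[self.scores["column"] == column, "score"].iloc[0])

    @property
    def top_k_ref(self) -> tuple:
        """Top-K columns in reference numbering (None where unmapped)."""
        sub = self.scores.set_index("column").loc[list(self.top_k), "ref_index"]
        return tuple(None if math.isnan(v) else int(v) for v in sub)

    def to_tsv(self, path) -> None:
        self.scores.to_csv(path, sep="\t", index=False, float_format="%.6g")


def response_distance(m: ResponseMatrix, i: str, j: str) -> float:
    """Mean absolute response difference over odorants measured in both receptors."""
    if i == j:
        raise ValueError("response_distance requires two distinct receptors")
    a, b = m.row(i), m.row(j)
    shared = a.notna() & b.notna()
    if not shared.any():
        raise UndefinedDistanceError(f"receptors {i!r} and {j!r} share no measured odorant")
    return float((a[shared] - b[shared]).abs().mean())


def pairwise_response_distances(m: ResponseMatrix) -> pd.DataFrame:
    """All pairwise response distances (NaN where undefined, 0 on the diagonal)."""
    v = m.data.to_numpy(dtype=float)
    diff = np.abs(v[:, None, :] - v[None, :, :])  # (R, R, O)
    shared = np.isfinite(diff).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(shared > 0, np.nansum(diff, axis=2) / shared, np.nan)
    ids = list(m.receptor_ids)
    return pd.DataFrame(d, index=ids, columns=ids)


def _check_receptors(aln: OrthologAlignment, m: ResponseMatrix) -> None:
    if set(aln.receptor_ids) != set(m.receptor_ids):
        raise ValueError("alignment and response matrix name different receptor sets")


def position_score(
    aln: OrthologAlignment,
    m: ResponseMatrix,
    column: int,
    min_pairs: int = 1,
) -> tuple[float, int, int, bool]:
    """Score one alignment column by explicit pair enumeration.

    Returns ``(score, n_match_pairs, n_mismatch_pairs, eligible)``; the score
    is NaN when the column is ineligible.  ``rank_positions`` computes the same
    quantity vectorised over all columns.
    """
    _check_receptors(aln, m)
    if not 1 <= column <= aln.alignment_length:
        raise IndexError(f"column {column} outside alignment")
    ids = aln.receptor_ids
    res = {rid: aln.sequence(rid)[column - 1] for rid in ids}
    match_d, mismatch_d = [], []
    for a_pos, i in enumerate(ids):
        for j in ids[a_pos + 1:]:
            ri, rj = res[i], res[j]
            if GAP in (ri, rj) or UNKNOWN in (ri, rj):
                continue
            try:
                d = response_distance(m, i, j)
            except UndefinedDistanceError:
                continue
            (match_d if ri == rj else mismatch_d).append(d)
    eligible = len(match_d) >= min_pairs and len(mismatch_d) >= min_pairs
    score = (
        float(np.mean(mismatch_d) - np.mean(match_d)) if eligible else float("nan")
    )
    return score, len(match_d), len(mismatch_d), eligible


def _score_all_columns(aln: OrthologAlignment, m: ResponseMatrix, min_pairs: int):
    """Vectorised scores for every column: (score, n_match, n_mismatch, eligible)."""
    arr = aln.as_array()  # (R, L) residue byte codes
    morder = m.reorder(receptor_ids=aln.receptor_ids)
    d = pairwise_response_distances(morder).to_numpy()
    iu, ju = np.triu_indices(aln.n_receptors, k=1)
    dp = d[iu, ju]  # (P,)
    defined = np.isfinite(dp)

    a, b = arr[iu], arr[ju]  # (P, L)
    gap, unknown = ord(GAP), ord(UNKNOWN)
    informative = (
        (a != gap) & (b != gap) & (a != unknown) & (b != unknown) & defined[:, None]
    )
    match = informative & (a == b)
    mismatch = informative & (a != b)

    n_match = match.sum(axis=0)
    n_mismatch = mismatch.sum(axis=0)
    dp_filled = np.where(defined, dp, 0.0)  # NaN distances are already masked out
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_match = (dp_filled[:, None] * match).sum(axis=0) / n_match
        mean_mismatch = (dp_filled[:, None] * mismatch).sum(axis=0) / n_mismatch
    eligible = (n_match >= min_pairs) & (n_mismatch >= min_pairs)
    score = np.where(eligible, mean_mismatch - mean_match, np.nan)
    return score, n_match, n_mismatch, eligible


def rank_positions(
    aln: OrthologAlignment,
    m: ResponseMatrix,
    k: int = 20,
    min_pairs: int = 1,
    ref_map: ReferencePositionMap | None = None,
) -> PositionScoreTable:
    """Score every alignment column and select the top-K eligible columns.

    Eligible columns are ordered by descending score; ties are broken by
    smaller reference index, then smaller column index, so output is fully
    deterministic.
    """
    _check_receptors(aln, m)
    if aln.n_receptors < 3:
        raise InsufficientDataError("position ranking needs at least 3 receptors")
    if k < 1:
        raise ValueError("k must be >= 1")
    if ref_map is None:
        ref_map = build_reference_map(aln)

    score, n_match, n_mismatch, eligible = _score_all_columns(aln, m, min_pairs)
    if not eligible.any():
        raise RankingError("no eligible alignment column (no matched+mismatched pairs)")

    columns = np.arange(1, aln.alignment_length + 1)
    ref_idx = np.array(
        [np.nan if r is None else r for r in ref_map.column_to_ref], dtype=float
    )

    elig_cols = columns[eligible]
    tie_ref = np.where(np.isnan(ref_idx[eligible]), np.inf, ref_idx[eligible])
    order = sorted(
        range(elig_cols.size),
        key=lambda i: (-score[eligible][i], tie_ref[i], elig_cols[i]),
    )
    ranked_cols = elig_cols[order]
    rank = np.full(columns.size, np.nan)
    rank[ranked_cols - 1] = np.arange(1, ranked_cols.size + 1)

    top = tuple(int(c) for c in ranked_cols[: min(k, ranked_cols.size)])
    in_top = np.isin(columns, top)

    table = pd.DataFrame(
        {
            "column": columns,
            "ref_index": ref_idx,
            "score": score,
            "n_match_pairs": n_match,
            "n_mismatch_pairs": n_mismatch,
            "eligible": eligible,
            "rank": rank,
            "in_top_k": in_top,
        }
    )
    return PositionScoreTable(table, top, k)
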