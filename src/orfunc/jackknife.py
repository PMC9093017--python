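"""Leave-one-species-out robustness of the top-K position set.

Two indicators: (1) the frequency with which each column appears among the
top-K sets recomputed with each receptor removed, and whether the K most
frequent columns match the original top-K; (2) how many of the original
top-K survive each single-receptor removal (retention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import InsufficientDataError, RankingError
from .io import OrthologAlignment, ResponseMatrix, build_reference_map
from .ranking import PositionScoreTable, rank_positions

__all__ = ["JackknifeResult", "jackknife_top_positions", "frequency_concordance"]


@dataclass(frozen=True)
class JackknifeResult:
    original_top: tuple[int, ...]  # alignment columns, full dataset
    per_exclusion: dict  # excluded receptor id -> tuple of columns (or None on failure)
    frequency_table: dict  # column -> appearance count over exclusions
    frequency_top: tuple[int, ...]
    retention: dict  # excluded receptor id -> |recalculated & original_top|
    mean_retention: float
    k: int
    full_table: PositionScoreTable

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        freq = pd.DataFrame(
            sorted(self.frequency_table.items(), key=lambda kv: (-kv[1], kv[0])),
            columns=["column", "frequency"],
        )
        ret = pd.DataFrame(
            [(rid, r) for rid, r in sorted(self.retention.items())],
            columns=["excluded_receptor", "retention"],
        )
        return freq, ret

    def summary(self) -> dict:
        matched, k = frequency_concordance(self)
        return {
            "k": self.k,
            "mean_retention": self.mean_retention,
            "frequency_top_matches_original": matched,
            "n_exclusions": len(self.per_exclusion),
            "retention": {rid: r for rid, r in self.retention.items()},
        }


def jackknife_top_positions(
    aln: OrthologAlignment,
    m: ResponseMatrix,
    k: int = 20,
    min_pairs: int = 1,
) -> JackknifeResult:
    """Recompute the top-K position set with each receptor removed in turn.

    Each exclusion removes both the sequence and the response row.  A reduced
    dataset on which no column is eligible is recorded as a failed exclusion
    and excluded from the summaries.
    """
    if aln.n_receptors < 4:
        raise InsufficientDataError("jackknife needs at least 4 receptors")
    ref_map = build_reference_map(aln)
    full = rank_positions(aln, m, k=k, min_pairs=min_pairs, ref_map=ref_map)
    original = set(full.top_k)

    per_exclusion: dict = {}
    retention: dict = {}
    counts: dict = {}
    for heldout in aln.receptor_ids:
        remaining = [r for r in aln.receptor_ids if r != heldout]
        if heldout == aln.reference_id:
            sub_aln = OrthologAlignment(
                tuple(r for r in aln.records if r[0] != heldout), remaining[0]
            )
        else:
            sub_aln = aln.drop(heldout)
        try:
            table = rank_positions(
                sub_aln, m.drop(heldout), k=k, min_pairs=min_pairs, ref_map=ref_map
            )
        except (RankingError, InsufficientDataError):
            per_exclusion[heldout] = None
            continue
        per_exclusion[heldout] = table.top_k
        retention[heldout] = len(original.intersection(table.top_k))
        for col in table.top_k:
            counts[col] = counts.get(col, 0) + 1

    if not retention:
        raise RankingError("every jackknife reduction failed to rank")

    # frequency ranking: ties broken by full-dataset score, then reference
    # index, then column, mirroring the primary ranking's tie-break
    scores = full.scores.set_index("column")

    def _tie(col: int):
        ref = scores.loc[col, "ref_index"]
        score = scores.loc[col, "score"]
        return (
            -counts[col],
            -(score if math.isfinite(score) else -math.inf),
            ref if math.isfinite(ref) else math.inf,
            col,
        )

    frequency_top = tuple(sorted(counts, key=_tie)[:k])
    return JackknifeResult(
        original_top=full.top_k,
        per_exclusion=per_exclusion,
        frequency_table=counts,
        frequency_top=frequency_top,
        retention=retention,
        mean_retention=sum(retention.values()) / len(retention),
        k=k,
        full_table=full,
    )


def frequency_concordance(r: JackknifeResult) -> tuple[int, int]:
    """How many of the K most frequent jackknife positions are original top-K."""
    return len(set(r.frequency_top) & set(r.original_top)), r.k
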