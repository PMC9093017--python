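"""Leave-one-receptor-out response prediction with a shuffled control.

The response of a held-out receptor to each odorant is predicted as a
similarity-weighted mean of the training receptors' responses, where the
weight of training receptor *j* is its sequence similarity to the held-out
receptor at the top-K response-determining columns raised to a sharpening
exponent ``alpha`` (default 10; similarities of a small ortholog panel are
tightly clustered, and a power kernel of that order lets near-exact matches
at the determining columns dominate without collapsing to strict nearest
neighbor).  By default each column contributes to the similarity in
proportion to its ranking score, so marginal columns in the top-K do not
dilute the signal.  Prediction error is D_pred = |predicted - actual| in
spikes.  The control destroys the sequence-response linkage: training
response rows are randomly reassigned to the training sequences, the same
predictor is re-run, and D_ctrl is the mean absolute error over shuffles.
Negative D_pred - D_ctrl means the sequence-informed prediction beat the
control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from zlib import crc32

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .io import GAP, UNKNOWN, OrthologAlignment, ResponseMatrix, build_reference_map
from .ranking import rank_positions

__all__ = [
    "PredictionReport",
    "similarity_at_positions",
    "predict_response",
    "shuffled_control",
    "loo_evaluate",
]


def similarity_at_positions(
    aln: OrthologAlignment, positions, a: str, b: str, position_weights=None
) -> float:
    """Fraction of the given columns at which the two receptors carry the same residue.

    Columns where either receptor is gapped are dropped from the denominator;
    ``X`` counts as identical to nothing.  Returns 0 when no column remains.
    With ``position_weights`` (non-negative, aligned with ``positions``) the
    fraction becomes weighted, so strongly response-determining columns count
    more than marginal ones.
    """
    positions = list(positions)
    if not positions:
        raise ValueError("positions must be non-empty")
    if position_weights is None:
        position_weights = [1.0] * len(positions)
    elif len(position_weights) != len(positions):
        raise ValueError("position_weights must align with positions")
    sa, sb = aln.sequence(a), aln.sequence(b)
    num = den = 0.0
    for c, wp in zip(positions, position_weights):
        ra, rb = sa[c - 1], sb[c - 1]
        if GAP in (ra, rb):
            continue
        den += wp
        if ra == rb and ra != UNKNOWN:
            num += wp
    return num / den if den else 0.0


def _training_ids(aln: OrthologAlignment, m: ResponseMatrix, heldout_id: str):
    if heldout_id not in aln.receptor_ids:
        raise KeyError(heldout_id)
    # canonical (sorted) order so predictions and sampled controls do not
    # depend on how the input records happen to be ordered
    train = sorted(r for r in aln.receptor_ids if r != heldout_id and r in m.receptor_ids)
    if len(train) < 2:
        raise InsufficientDataError(
            f"need >= 2 training receptors, have {len(train)} for held-out {heldout_id!r}"
        )
    return train


DEFAULT_ALPHA = 10.0


def _weights(aln, positions, heldout_id, train, alpha, position_weights=None):
    w = np.array(
        [
            similarity_at_positions(aln, positions, heldout_id, j, position_weights)
            for j in train
        ]
    )
    return w**alpha


def _weighted_predictions(resp: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted nan-mean of training rows, with unweighted-mean fallback.

    ``resp`` is (..., n_train, n_odorants); weights apply along the training
    axis.  Where every available response carries zero weight the prediction
    falls back to the unweighted mean of available responses; odorants with no
    available response give NaN.
    """
    mask = np.isfinite(resp)
    filled = np.where(mask, resp, 0.0)
    w_col = w.reshape((1,) * (resp.ndim - 2) + (-1, 1))
    wsum = (w_col * mask).sum(axis=-2)
    n_avail = mask.sum(axis=-2)
    with np.errstate(invalid="ignore", divide="ignore"):
        weighted = (w_col * filled).sum(axis=-2) / wsum
        unweighted = filled.sum(axis=-2) / n_avail
    pred = np.where(wsum > 0, weighted, unweighted)
    return np.where(n_avail > 0, pred, np.nan)


def predict_response(
    aln: OrthologAlignment,
    m: ResponseMatrix,
    positions,
    heldout_id: str,
    alpha: float = DEFAULT_ALPHA,
    position_weights=None,
) -> pd.Series:
    """Predict the held-out receptor's response to every odorant (spikes)."""
    train = _training_ids(aln, m, heldout_id)
    w = _weights(aln, positions, heldout_id, train, alpha, position_weights)
    resp = m.data.loc[train].to_numpy(dtype=float)
    pred = _weighted_predictions(resp, w)
    return pd.Series(pred, index=list(m.odorant_ids), name=heldout_id)


def _permutation_indices(n_train: int, n_shuffles: int, rng: np.random.Generator):
    """Permutations of the training rows: exhaustive when the budget allows.

    When ``n_shuffles`` is at least n_train!, every permutation is enumerated
    exactly once (deterministically), so the Monte-Carlo estimate coincides
    with the exact permutation average; otherwise ``n_shuffles`` uniform
    random permutations are drawn from ``rng``.
    """
    n_perms = math.factorial(n_train)
    if n_shuffles >= n_perms:
        return np.array(list(permutations(range(n_train))), dtype=int)
    return np.array([rng.permutation(n_train) for _ in range(n_shuffles)], dtype=int)


def shuffled_control(
    aln: OrthologAlignment,
    m: ResponseMatrix,
    positions,
    heldout_id: str,
    n_shuffles: int = 1000,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    position_weights=None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Control prediction under random sequence-response reassignment.

    Returns ``(control, d_ctrl)``: the mean shuffled prediction per odorant and
    the mean absolute error of the shuffled predictions against the held-out
    receptor's actual responses.
    """
    train = _training_ids(aln, m, heldout_id)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([seed, crc32(heldout_id.encode())]))
    w = _weights(aln, positions, heldout_id, train, alpha, position_weights)
    resp = m.data.loc[train].to_numpy(dtype=float)
    perms = _permutation_indices(len(train), n_shuffles, rng)
    preds = _weighted_predictions(resp[perms], w)  # (S, n_odorants)
    actual = m.data.loc[heldout_id].to_numpy(dtype=float) if heldout_id in m.receptor_ids else None
    odorants = list(m.odorant_ids)
    control = pd.Series(preds.mean(axis=0), index=odorants, name=heldout_id)
    if actual is None:
        d_ctrl = pd.Series(np.nan, index=odorants, name=heldout_id)
    else:
        d_ctrl = pd.Series(
            np.abs(preds - actual[None, :]).mean(axis=0), index=odorants, name=heldout_id
        )
    return control, d_ctrl


@dataclass(frozen=True)
class PredictionReport:
    """Per-(held-out receptor, odorant) prediction errors and their summaries.

    ``entries`` columns: heldout_id, odorant_id, actual, predicted, control,
    d_pred, d_ctrl, delta (= d_pred - d_ctrl; negative means the model beat
    the control).  ``improvement_percent`` compares the overall mean errors;
    ``improvement_percent_receptor_mean`` averages per-receptor improvements
    instead (the two orders of averaging differ in general, so both are
    reported).
    """

    entries: pd.DataFrame
    per_receptor: pd.DataFrame
    per_odorant: pd.DataFrame
    mean_d_pred: float
    mean_d_ctrl: float
    improvement_percent: float
    improvement_percent_receptor_mean: float
    n_missing: int
    k: int
    n_shuffles: int
    seed: int

    def summary(self) -> dict:
        return {
            "mean_d_pred": self.mean_d_pred,
            "mean_d_ctrl": self.mean_d_ctrl,
            "mean_delta": self.mean_d_pred - self.mean_d_ctrl,
            "improvement_percent": self.improvement_percent,
            "improvement_percent_receptor_mean": self.improvement_percent_receptor_mean,
            "n_missing": self.n_missing,
            "per_receptor": {
                r: {c: float(v) for c, v in row.items()}
                for r, row in self.per_receptor.iterrows()
            },
            "per_odorant": {
                o: {c: float(v) for c, v in row.items()}
                for o, row in self.per_odorant.iterrows()
            },
        }

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False, float_format="%.6g")


def loo_evaluate(
    aln: OrthologAlignment,
    m: ResponseMatrix,
    k: int = 20,
    n_shuffles: int = 1000,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    min_pairs: int = 1,
    score_weighted: bool = True,
) -> PredictionReport:
    """Leave-one-receptor-out evaluation over the whole panel.

    For each receptor in turn: the response-determining columns are re-ranked
    on the remaining receptors only, the held-out responses are predicted from
    those columns, and a shuffled control is run.  With ``score_weighted``
    (the default) the similarity between the held-out and each training
    sequence weights each top-K column by its (positive part) ranking score,
    so columns that strongly determine the response dominate the kernel.
    Per-receptor random streams derive from (seed, crc32 of the receptor id),
    so results do not depend on receptor ordering.
    """
    if set(aln.receptor_ids) != set(m.receptor_ids):
        raise ValueError("alignment and response matrix name different receptor sets")
    if aln.n_receptors < 3:
        raise InsufficientDataError("leave-one-out needs at least 3 receptors")

    ref_map = build_reference_map(aln)  # full-alignment reference numbering
    rows = []
    for heldout in sorted(aln.receptor_ids):
        remaining = [r for r in aln.receptor_ids if r != heldout]
        if heldout == aln.reference_id:
            # reference numbering is preserved via ref_map; the reduced
            # alignment just needs some designated record to stay valid
            sub_aln = OrthologAlignment(
                tuple(r for r in aln.records if r[0] != heldout), remaining[0]
            )
        else:
            sub_aln = aln.drop(heldout)
        sub_m = m.drop(heldout)
        table = rank_positions(sub_aln, sub_m, k=k, min_pairs=min_pairs, ref_map=ref_map)
        positions = table.top_k
        position_weights = None
        if score_weighted:
            position_weights = [max(table.score_of(c), 0.0) for c in positions]
            if sum(position_weights) == 0:
                position_weights = None

        predicted = predict_response(
            aln, sub_m, positions, heldout, alpha=alpha, position_weights=position_weights
        )
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, crc32(heldout.encode())])
        )
        control, d_ctrl = shuffled_control(
            aln, m, positions, heldout, n_shuffles=n_shuffles, alpha=alpha,
            position_weights=position_weights, rng=rng,
        )
        actual = m.row(heldout)
        for odorant in m.odorant_ids:
            a_val = float(actual[odorant])
            p_val = float(predicted[odorant])
            rows.append(
                {
                    "heldout_id": heldout,
                    "odorant_id": odorant,
                    "actual": a_val,
                    "predicted": p_val,
                    "control": float(control[odorant]),
                    "d_pred": abs(p_val - a_val),
                    "d_ctrl": float(d_ctrl[odorant]),
                }
            )

    entries = pd.DataFrame(rows)
    entries["delta"] = entries["d_pred"] - entries["d_ctrl"]
    defined = entries.dropna(subset=["d_pred", "d_ctrl"])
    n_missing = len(entries) - len(defined)

    per_receptor = defined.groupby("heldout_id")[["d_pred", "d_ctrl", "delta"]].mean()
    per_odorant = defined.groupby("odorant_id")[["d_pred", "d_ctrl", "delta"]].mean()
    mean_d_pred = float(defined["d_pred"].mean())
    mean_d_ctrl = float(defined["d_ctrl"].mean())
    improvement = (
        100.0 * (mean_d_ctrl - mean_d_pred) / mean_d_ctrl if mean_d_ctrl > 0 else float("nan")
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        per_r_impr = 100.0 * (per_receptor["d_ctrl"] - per_receptor["d_pred"]) / per_receptor["d_ctrl"]
    return PredictionReport(
        entries=entries,
        per_receptor=per_receptor,
        per_odorant=per_odorant,
        mean_d_pred=mean_d_pred,
        mean_d_ctrl=mean_d_ctrl,
        improvement_percent=improvement,
        improvement_percent_receptor_mean=float(per_r_impr.mean()),
        n_missing=n_missing,
        k=k,
        n_shuffles=n_shuffles,
        seed=seed,
    )
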