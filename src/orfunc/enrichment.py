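"""Structural clustering of top positions: neighborhood hypergeometric tests.

Given a residue neighborhood (all residues whose alpha-carbon lies within a
radius, default 15 angstrom, of a seed residue's alpha-carbon), the overlap
between the neighborhood and the top-K response-determining positions is
tested for over-representation with an upper-tail hypergeometric test:
population N = protein length, K top positions, n neighborhood residues,
observed overlap k, p = P(X >= k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .io import StructureModel

__all__ = [
    "NeighborhoodEnrichment",
    "residue_neighborhood",
    "hypergeom_upper_tail",
    "enrichment_from_counts",
    "enrichment_test",
    "union_enrichment",
]


@dataclass(frozen=True)
class NeighborhoodEnrichment:
    """Overlap of a structural neighborhood with the top position set."""

    seed_ref_index: int | None
    radius: float | None
    neighborhood: frozenset  # reference residue indices; empty if counts-only
    n: int  # |neighborhood|
    k_overlap: int
    N: int  # protein length
    K: int  # |top positions|
    expected: float  # n * K / N
    p_value: float

    def to_dict(self) -> dict:
        return {
            "seed_ref_index": self.seed_ref_index,
            "radius_angstrom": self.radius,
            "n_neighborhood": self.n,
            "k_overlap": self.k_overlap,
            "protein_length": self.N,
            "n_top_positions": self.K,
            "expected_overlap": self.expected,
            "p_value": self.p_value,
        }


def residue_neighborhood(
    s: StructureModel, seed_ref_index: int, radius: float = 15.0
) -> frozenset:
    """Residues whose alpha-carbon is within ``radius`` of the seed's (seed included).

    The boundary is inclusive: a residue at exactly ``radius`` is inside.
    """
    center = s.coord(seed_ref_index)
    dist = np.linalg.norm(s.coords - center, axis=1)
    return frozenset(int(i) for i in s.ref_indices[dist <= radius])


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), via log-space combinatorics.

    Summing log-binomial terms (gammaln) keeps the tail accurate far below
    floating-point underflow of individual factorials.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K, n <= N; got N={N}, K={K}, n={n}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"require 0 <= k <= min(n, K); got k={k}, n={n}, K={K}")
    lo = max(k, n + K - N)
    if lo <= max(0, n + K - N):
        return 1.0  # tail covers the whole support
    j = np.arange(lo, min(n, K) + 1)

    def lchoose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    log_terms = lchoose(K, j) + lchoose(N - K, n - j) - lchoose(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def enrichment_from_counts(
    N: int,
    K: int,
    n: int,
    k: int,
    seed_ref_index: int | None = None,
    radius: float | None = None,
    neighborhood: frozenset = frozenset(),
) -> NeighborhoodEnrichment:
    """Enrichment from printed counts alone (no structure required)."""
    return NeighborhoodEnrichment(
        seed_ref_index=seed_ref_index,
        radius=radius,
        neighborhood=neighborhood,
        n=n,
        k_overlap=k,
        N=N,
        K=K,
        expected=n * K / N,
        p_value=hypergeom_upper_tail(N, K, n, k),
    )


def enrichment_test(
    s: StructureModel,
    top,
    seed_ref_index: int,
    radius: float = 15.0,
    N: int | None = None,
) -> NeighborhoodEnrichment:
    """Neighborhood test of the top positions (reference numbering) around a seed."""
    top = set(int(t) for t in top)
    if N is None:
        N = s.n_residues
    if top and (min(top) < 1 or max(top) > N):
        raise ValueError(f"top positions outside [1, {N}]")
    neigh = residue_neighborhood(s, seed_ref_index, radius)
    return enrichment_from_counts(
        N=N,
        K=len(top),
        n=len(neigh),
        k=len(neigh & top),
        seed_ref_index=seed_ref_index,
        radius=radius,
        neighborhood=neigh,
    )


def union_enrichment(
    e1: NeighborhoodEnrichment, e2: NeighborhoodEnrichment, top, N: int
) -> NeighborhoodEnrichment:
    """Enrichment on the union of two neighborhoods (same structure and top set)."""
    top = set(int(t) for t in top)
    union = frozenset(e1.neighborhood | e2.neighborhood)
    return enrichment_from_counts(
        N=N,
        K=len(top),
        n=len(union),
        k=len(union & top),
        neighborhood=union,
    )
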