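"""MIC-based feature pre-selection (filter stage).

Features whose MIC with the class label falls below an irrelevance threshold
are dropped; among the survivors, whenever two features have pairwise MIC
above a redundancy threshold, the one less relevant to the label is dropped.
Redundancy is resolved by a greedy sweep in descending relevance: each
accepted feature eliminates every not-yet-accepted feature too similar to it,
so the most relevant representative of each redundant group survives and the
result is deterministic even for redundancy chains.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import FeatureMatrix
from .mic import MicConfig, compute_mic, relevance_scores


@dataclass
class PrefilterResult:
    """Audit trail of the filter stage.

    ``kept`` is ordered by descending relevance. ``removed_redundant`` pairs
    are (dropped index, kept partner it was redundant with). ``kept``,
    ``removed_irrelevant`` and the dropped members of ``removed_redundant``
    partition the original column indices.
    """

    kept: list[int]
    relevance: np.ndarray
    removed_irrelevant: list[int]
    removed_redundant: list[tuple[int, int]]
    thresholds: tuple[float, float]
    kept_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "kept": list(map(int, self.kept)),
            "kept_names": list(self.kept_names),
            "relevance": [float(v) for v in self.relevance],
            "removed_irrelevant": list(map(int, self.removed_irrelevant)),
            "removed_redundant": [[int(a), int(b)]
                                  for a, b in self.removed_redundant],
            "thresholds": {"irrelevant": self.thresholds[0],
                           "redundant": self.thresholds[1]},
        }


def _greedy_redundancy(order: np.ndarray, pair_mic, t_red: float
                       ) -> tuple[list[int], list[tuple[int, int]]]:
    """Accept candidates in relevance order; drop near-duplicates of accepted."""
    accepted: list[int] = []
    dropped: list[tuple[int, int]] = []
    for idx in order:
        partner = next((a for a in accepted if pair_mic(idx, a) > t_red), None)
        if partner is None:
            accepted.append(int(idx))
        else:
            dropped.append((int(idx), int(partner)))
    return accepted, dropped


def mic_prefilter(F: FeatureMatrix, t_irr: float = 0.2, t_red: float = 0.8,
                  config: MicConfig | None = None) -> PrefilterResult:
    """Two-step MIC pre-selection with thresholds ``t_irr`` / ``t_red``.

    Step 1 removes feature i iff ``mic(x_i, y) < t_irr`` (strict). Step 2
    computes pairwise MIC among survivors and, for each pair exceeding
    ``t_red`` (strict), drops the member with the smaller label relevance
    (ties: the higher column index is dropped). Survivors are returned
    sorted by descending relevance.
    """
    if not 0.0 <= t_irr < 1.0:
        raise ValueError("t_irr must lie in [0, 1)")
    if not 0.0 < t_red <= 1.0:
        raise ValueError("t_red must lie in (0, 1]")
    relevance = relevance_scores(F, config)
    survivors = np.flatnonzero(relevance >= t_irr)
    removed_irr = [int(i) for i in np.flatnonzero(relevance < t_irr)]
    if survivors.size == 0:
        raise ValueError(
            "all features fell below the irrelevance threshold "
            f"{t_irr}; relax t_irr (max relevance was {relevance.max():.3f})")

    # descending relevance; ties broken by ascending index so the
    # lower-index member of a tied redundant pair is kept
    order = survivors[np.lexsort((survivors, -relevance[survivors]))]

    cache: dict[tuple[int, int], float] = {}

    def pair_mic(i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in cache:
            cache[key] = compute_mic(F.values[:, key[0]], F.values[:, key[1]],
                                     config).value
        return cache[key]

    kept, removed_red = _greedy_redundancy(order, pair_mic, t_red)
    if not kept:
        raise ValueError("all features removed; relax the thresholds")
    return PrefilterResult(
        kept=kept,
        relevance=relevance,
        removed_irrelevant=removed_irr,
        removed_redundant=removed_red,
        thresholds=(t_irr, t_red),
        kept_names=[F.names[i] for i in kept],
    )
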