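"""Ranked top-K subcellular-localization features and their dense encoder.

Instead of a handful of hand-picked compartments, the feature space is the
K most populous localization terms: terms are ranked by how many network
proteins they annotate, the top K (default 1024) become feature columns,
and each entry is the annotation's confidence score normalized to [0, 1].
Three fully connected layers (K -> 64 -> 64 -> batch norm -> 16, ReLU
throughout) compress a protein's sparse row into a 16-dimensional feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .io_formats import LocalizationEntry
from .nn import batch_norm_forward, dense_forward

logger = logging.getLogger(__name__)

__all__ = [
    "TermRanking",
    "LocalizationMatrix",
    "LocalizationBranchWeights",
    "rank_localization_terms",
    "build_localization_matrix",
    "localization_branch_forward",
    "K_PRESETS",
]

#: Feature-space sizes mirroring the ablation grid over top-K terms.
K_PRESETS = (11, 64, 128, 256, 512, 1024)


@dataclass(frozen=True)
class TermRanking:
    """Localization terms with their network-protein counts, sorted descending.

    Ties in count are broken lexicographically by term id so the ranking is
    reproducible.
    """

    terms: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(a < b for a, b in zip(self.counts, self.counts[1:])):
            raise ValueError("counts must be non-increasing")


@dataclass
class LocalizationMatrix:
    """Protein-by-K matrix of normalized confidences; columns follow the ranking."""

    proteins: list[str]
    terms: list[str]
    values: np.ndarray  # (n_proteins, K), entries in [0, 1]


def rank_localization_terms(
    entries: Sequence[LocalizationEntry], network: nx.Graph
) -> TermRanking:
    """Count, per term, the distinct network proteins annotated to it."""
    if not entries:
        raise ValueError("no localization entries")
    members: dict[str, set[str]] = {}
    nodes = set(network.nodes)
    for e in entries:
        if e.protein in nodes:
            members.setdefault(e.term, set()).add(e.protein)
    ranked = sorted(members.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return TermRanking(
        terms=tuple(t for t, _ in ranked), counts=tuple(len(m) for _, m in ranked)
    )


def build_localization_matrix(
    entries: Sequence[LocalizationEntry],
    ranking: TermRanking,
    proteins: Sequence[str],
    K: int = 1024,
    norm_max: float = 5.0,
) -> LocalizationMatrix:
    """Top-K feature matrix with confidences divided by ``norm_max``, clipped at 1.

    Proteins with no selected term are all-zero rows.  If the ranking has
    fewer than K terms the trailing columns stay zero (logged).
    """
    if K <= 0:
        raise ValueError("K must be positive")
    if norm_max <= 0:
        raise ValueError("norm_max must be positive")
    selected = list(ranking.terms[:K])
    if len(selected) < K:
        logger.warning("only %d terms available for K=%d; trailing columns zero", len(selected), K)
    term_col = {t: j for j, t in enumerate(selected)}
    prot_row = {p: i for i, p in enumerate(proteins)}
    values = np.zeros((len(proteins), K))
    for e in entries:
        i = prot_row.get(e.protein)
        j = term_col.get(e.term)
        if i is not None and j is not None:
            values[i, j] = min(e.confidence / norm_max, 1.0)
    return LocalizationMatrix(proteins=list(proteins), terms=selected, values=values)


@dataclass
class LocalizationBranchWeights:
    """Parameters of the three-layer dense encoder with batch norm."""

    w1: np.ndarray  # (K, 64)
    b1: np.ndarray
    w2: np.ndarray  # (64, 64)
    b2: np.ndarray
    bn_gamma: np.ndarray
    bn_beta: np.ndarray
    bn_mean: np.ndarray
    bn_var: np.ndarray
    bn_eps: float
    w3: np.ndarray  # (64, 16)
    b3: np.ndarray


def localization_branch_forward(
    row: np.ndarray, weights: LocalizationBranchWeights, mode: str = "infer"
) -> np.ndarray:
    """Dense(K->64, ReLU) -> Dense(64->64, ReLU) -> batch norm -> Dense(64->16, ReLU)."""
    squeeze = row.ndim == 1
    x = row[None] if squeeze else row
    if x.shape[1] != weights.w1.shape[0]:
        raise ValueError(f"row length {x.shape[1]} does not match weights ({weights.w1.shape[0]})")
    x = dense_forward(x, weights.w1, weights.b1, activation="relu")
    x = dense_forward(x, weights.w2, weights.b2, activation="relu")
    x, _, _ = batch_norm_forward(
        x,
        weights.bn_gamma,
        weights.bn_beta,
        eps=weights.bn_eps,
        mode=mode,
        running_mean=weights.bn_mean,
        running_var=weights.bn_var,
    )
    x = dense_forward(x, weights.w3, weights.b3, activation="relu")
    return x[0] if squeeze else x
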