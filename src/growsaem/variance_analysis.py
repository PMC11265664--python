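"""Heritability ratios and genetic/marginal correlation summaries.

The model has no formal heritability; when each growth trait carries one
genetic effect, the ratio of the genetic to the genetic-plus-plant variance
on that trait's diagonal, ``G_gg / (G_gg + P_pp)``, is reported as a
heritability proxy.  The pairing between G and P diagonals is explicit:
in the irrigation-interaction model G is 4x4 (main and interaction effects)
while P is 2x2, and each interaction effect is compared against its trait's
plant variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model_core import (
    Dataset,
    DesignMatrices,
    DesignSpec,
    Kinship,
    SchemaError,
    Theta,
    build_designs,
    marginal_phi_covariance,
    symmetrize,
)

__all__ = [
    "HeritabilityReport",
    "heritability",
    "correlation_from_covariance",
    "average_marginal_correlation",
]


@dataclass
class HeritabilityReport:
    ratios: Dict[str, float]
    mapping: List[Tuple[int, int]]

    def __getitem__(self, key: str) -> float:
        return self.ratios[key]


def heritability(
    G: np.ndarray,
    P: np.ndarray,
    mapping: Sequence[Tuple[int, int]],
    names: Optional[Sequence[str]] = None,
) -> HeritabilityReport:
    """Ratios G_gg / (G_gg + P_pp) for each (g_index, p_index) pair.

    With ``G = k P`` and the identity mapping every ratio is exactly
    ``k / (k + 1)``.  All ratios lie in [0, 1]; they are invariant to a
    common rescaling of G and P.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    P = np.atleast_2d(np.asarray(P, dtype=float))
    mapping = [(int(g), int(p)) for g, p in mapping]
    if names is None:
        names = [f"h_{g + 1}" for g, _ in mapping]
    if len(names) != len(mapping):
        raise ValueError("names and mapping lengths differ")
    ratios: Dict[str, float] = {}
    for name, (g_ix, p_ix) in zip(names, mapping):
        g_var = G[g_ix, g_ix]
        p_var = P[p_ix, p_ix]
        if g_var < 0 or p_var <= 0:
            raise ValueError(
                f"nonpositive variance diagonal for ratio '{name}': "
                f"G[{g_ix},{g_ix}]={g_var}, P[{p_ix},{p_ix}]={p_var}"
            )
        ratios[name] = g_var / (g_var + p_var)
    return HeritabilityReport(ratios=ratios, mapping=mapping)


def correlation_from_covariance(M: np.ndarray) -> np.ndarray:
    """Convert a covariance matrix to a correlation matrix."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    d = np.diag(M)
    if np.any(d <= 0):
        raise ValueError("covariance matrix has nonpositive diagonal entries")
    scale = 1.0 / np.sqrt(d)
    R = symmetrize(M * np.outer(scale, scale))
    np.fill_diagonal(R, 1.0)
    return R


def average_marginal_correlation(
    spec: DesignSpec,
    theta: Theta,
    kinship: Kinship,
    dataset: Dataset,
    condition: Optional[Dict[str, float]] = None,
    designs: Optional[DesignMatrices] = None,
) -> np.ndarray:
    """Average over varieties of the marginal phi covariance, as correlation.

    The marginal covariance of ``phi_i`` is
    ``Z_i (K (x) G) Z_i' + P = K_{v_i v_i} Z_block G Z_block' + P``; it
    varies between varieties through the kinship diagonal and between
    conditions through ``Z_block``.  One representative plant per variety
    matching ``condition`` (exact covariate equality) contributes; the
    per-variety covariances are averaged and then converted to a
    correlation matrix.
    """
    if designs is None:
        designs = build_designs(dataset, spec)

    def matches(rec) -> bool:
        if not condition:
            return True
        return all(rec.covariates.get(k) == v for k, v in condition.items())

    chosen: Dict[int, int] = {}
    for i, rec in enumerate(dataset.plants):
        v = designs.v_idx[i]
        if v not in chosen and matches(rec):
            chosen[v] = i
    if not chosen:
        raise SchemaError("no plant matches the requested condition")
    covs = [
        marginal_phi_covariance(spec, theta, kinship, designs, i)
        for i in chosen.values()
    ]
    return correlation_from_covariance(np.mean(covs, axis=0))
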