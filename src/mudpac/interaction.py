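"""Topology-aware Interaction Factor.

For a gene pair (i, j) inside one pathway three quantities are combined:

* ``d_ij`` — unweighted shortest-path hop count on the pathway topology
  (mutational influence is assumed to decay with functional distance);
* ``C_ij`` — fraction of samples in which exactly one of the two genes is
  non-synonymously mutated (pairwise exclusive coverage);
* ``ME_ij`` — mutual exclusivity: exclusive samples over the union of
  mutated samples.

The pair's interaction strength is ``f_ij = C_ij * ME_ij / (1 + d_ij)``
(zero for disconnected pairs), and the gene's Interaction Factor is the
mean of f over all |P|-1 partners, a pair contributing only when
``f_ij >= alpha``. When no partner passes the gate the IF is floored at
alpha so the downstream ranking score stays strictly positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict

import networkx as nx
import numpy as np

from .matrix import MutationMatrix
from .types import PathwayGraph


@dataclass(frozen=True)
class PairStats:
    """Shortest distance, exclusive coverage, exclusivity and strength of a pair."""

    d: float  # hop count; math.inf when disconnected
    c: float
    me: float
    f: float


@dataclass(frozen=True)
class InteractionFactor:
    gene: str
    pathway_id: str
    value: float  # in (0, 1)
    n_passing: int

    def __post_init__(self) -> None:
        if not (0 < self.value < 1):
            raise ValueError("interaction factor must lie strictly in (0, 1)")


def shortest_distance(pw: PathwayGraph, gi: str, gj: str) -> float:
    """Unweighted shortest-path hop count; inf when disconnected."""
    if gi not in pw.genes:
        raise KeyError(f"gene {gi!r} not in pathway {pw.pathway_id}")
    if gj not in pw.genes:
        raise KeyError(f"gene {gj!r} not in pathway {pw.pathway_id}")
    if gi == gj:
        return 0
    g = pw.to_networkx()
    try:
        return nx.shortest_path_length(g, gi, gj)
    except nx.NetworkXNoPath:
        return math.inf


def pairwise_coverage(mat: MutationMatrix, gi: str, gj: str) -> float:
    """Fraction of samples where exactly one of the two genes is NSY-mutated."""
    a = mat.nsy_counts[mat.gene_row(gi)] > 0
    b = mat.nsy_counts[mat.gene_row(gj)] > 0
    return float((a ^ b).sum()) / mat.n_samples


def mutual_exclusivity(mat: MutationMatrix, gi: str, gj: str) -> float:
    """Exclusive-sample count over union-sample count; 0 for an empty union."""
    a = mat.nsy_counts[mat.gene_row(gi)] > 0
    b = mat.nsy_counts[mat.gene_row(gj)] > 0
    union = int((a | b).sum())
    if union == 0:
        return 0.0
    return float((a ^ b).sum()) / union


def interaction_strength(d: float, c: float, me: float) -> float:
    """Combine distance, coverage and exclusivity into f in [0, 1).

    f = (c * me) / (1 + d); disconnected pairs (d = inf) exert no influence.
    """
    if math.isinf(d):
        return 0.0
    return (c * me) / (1.0 + d)


def pair_stats(pw: PathwayGraph, mat: MutationMatrix, gi: str, gj: str) -> PairStats:
    d = shortest_distance(pw, gi, gj)
    c = pairwise_coverage(mat, gi, gj)
    me = mutual_exclusivity(mat, gi, gj)
    return PairStats(d=d, c=c, me=me, f=interaction_strength(d, c, me))


def interaction_factor(
    pw: PathwayGraph, mat: MutationMatrix, gi: str, alpha: float
) -> InteractionFactor:
    """Interaction Factor of one gene within one pathway.

    IF_i = (1 / (|P| - 1)) * sum_{j != i} f_ij * 1[f_ij >= alpha]; floored at
    alpha when no partner passes. Partners that fail the gate contribute
    zero but stay in the denominator.
    """
    if gi not in pw.genes:
        raise KeyError(f"gene {gi!r} not in pathway {pw.pathway_id}")
    if len(pw.genes) < 2:
        raise ValueError(f"pathway {pw.pathway_id} is a singleton; IF undefined")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    total = 0.0
    n_passing = 0
    for gj in pw.genes:
        if gj == gi:
            continue
        f = pair_stats(pw, mat, gi, gj).f
        if f >= alpha:
            total += f
            n_passing += 1
    value = total / (len(pw.genes) - 1)
    if n_passing == 0:
        value = alpha
    return InteractionFactor(gene=gi, pathway_id=pw.pathway_id, value=value,
                             n_passing=n_passing)


def distance_matrix(pw: PathwayGraph, members: list) -> np.ndarray:
    """(k, k) hop-count matrix over ``members`` (inf when disconnected)."""
    g = pw.to_networkx()
    k = len(members)
    dmat = np.full((k, k), np.inf)
    idx = {m_: i for i, m_ in enumerate(members)}
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        if src not in idx:
            continue
        i = idx[src]
        for dst, d in lengths.items():
            if dst in idx:
                dmat[i, idx[dst]] = d
    return dmat


def interaction_factors_from_profiles(
    mut: np.ndarray, dmat: np.ndarray, alpha: float
) -> tuple:
    """Batched IF evaluation from binary mutation profiles.

    Parameters
    ----------
    mut : bool array (..., k, m)
        Non-synonymous mutation indicator per member gene per sample;
        leading axes batch independent replicates (e.g. permutations).
    dmat : (k, k)
        Shortest-distance matrix over the same member ordering.

    Returns
    -------
    values, n_passing : arrays of shape (..., k)
    """
    k, m = mut.shape[-2], mut.shape[-1]
    if k < 2:
        raise ValueError("need at least two member genes")
    mi = mut.astype(np.int64)
    counts = mi.sum(axis=-1)  # (..., k)
    inter = np.einsum("...im,...jm->...ij", mi, mi)
    both = counts[..., :, None] + counts[..., None, :]
    exclusive = both - 2 * inter
    union = both - inter
    c = exclusive / m
    me = np.where(union > 0, exclusive / np.maximum(union, 1), 0.0)
    with np.errstate(invalid="ignore"):
        f = np.where(np.isinf(dmat), 0.0, (c * me) / (1.0 + dmat))
    eye = np.eye(k, dtype=bool)
    f = np.where(eye, 0.0, f)
    passing = (f >= alpha) & ~eye
    values = (f * passing).sum(axis=-1) / (k - 1)
    n_pass = passing.sum(axis=-1)
    values = np.where(n_pass == 0, alpha, values)
    return values, n_pass


def pathway_interaction_factors(
    pw: PathwayGraph, mat: MutationMatrix, alpha: float
) -> Dict[str, InteractionFactor]:
    """Interaction Factors for every gene of a pathway, computed in bulk.

    Equivalent to calling :func:`interaction_factor` per gene but evaluates
    the pairwise statistics with one BFS pass and one boolean matrix
    product, which matters at hundreds of pathways.
    """
    if len(pw.genes) < 2:
        raise ValueError(f"pathway {pw.pathway_id} is a singleton; IF undefined")
    members = sorted(pw.genes)
    rows = np.array([mat.gene_row(g) for g in members])
    mut = mat.nsy_counts[rows] > 0  # (k, m)
    dmat = distance_matrix(pw, members)
    values, n_pass = interaction_factors_from_profiles(mut, dmat, alpha)
    return {
        g_: InteractionFactor(gene=g_, pathway_id=pw.pathway_id,
                              value=float(values[i]), n_passing=int(n_pass[i]))
        for i, g_ in enumerate(members)
    }
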