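"""Greedy construction of the collaborative driver-pathway set.

A pathway *covers* a sample when at least one of its genes carries a
non-synonymous mutation there; a set of pathways is *collaborative* in a
sample when every member covers it. The Maximal Coverage Rate (MCR) of a
set is the fraction of samples it collaborates in (intersection coverage).

Starting from the enrichment step's top candidates, the greedy walk picks
at each step the unselected pathway with the largest tentative joint MCR
(ties broken by the candidate pool order, i.e. enrichment rank), subject to
two constraints:

* single-gene dominance — the tentative MCR must exceed the pathway's top
  single-gene mutation rate by at least ``dominance_delta`` (default 5%),
  so that coverage attributable to one hypermutated gene (a TP53-style
  pattern) cannot masquerade as pathway collaboration;
* collaboration significance — redistributing the candidate's mutation
  events uniformly over samples must rarely reach the observed joint MCR
  (permutation p strictly below ``collab_p_threshold``, default 0.01).

The first pathway is exempt from the permutation test (it has no partners)
but must still pass dominance. The walk falls through to the next-best
candidate on failure and stops when none qualifies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .matrix import MutationMatrix
from .types import PathwayGraph, RunConfig

log = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass(frozen=True)
class CoverageProfile:
    pathway_id: str
    covered_samples: FrozenSet[str]
    rate: float


@dataclass(frozen=True)
class SelectionStep:
    pathway_id: str
    mcr_after: float
    p: float  # nan for the first step (no partners to test against)
    max_gene_rate: float


@dataclass
class CollaborativeSet:
    steps: List[SelectionStep]
    covered_samples: FrozenSet[str]
    n_samples: int

    @property
    def mcr(self) -> float:
        if not self.steps:
            return 0.0
        return len(self.covered_samples) / self.n_samples

    @property
    def pathway_ids(self) -> List[str]:
        return [s.pathway_id for s in self.steps]


def pathway_coverage(mat: MutationMatrix, pw: PathwayGraph) -> CoverageProfile:
    """Samples with >= 1 non-synonymous mutation in any member gene."""
    rows = [mat.gene_row(g) for g in sorted(pw.genes) if g in mat._gene_index]
    if not rows:
        raise ValueError(
            f"pathway {pw.pathway_id} has no gene in the mutation matrix"
        )
    covered = (mat.nsy_counts[rows] > 0).any(axis=0)
    samples = frozenset(s for s, c in zip(mat.samples, covered) if c)
    return CoverageProfile(
        pathway_id=pw.pathway_id,
        covered_samples=samples,
        rate=float(covered.sum()) / mat.n_samples,
    )


def joint_coverage(profiles: Sequence[CoverageProfile], m: int) -> float:
    """Fraction of samples covered by every profile (intersection coverage)."""
    if not profiles:
        raise ValueError("joint_coverage needs at least one profile")
    common = set(profiles[0].covered_samples)
    for pr in profiles[1:]:
        common &= pr.covered_samples
    return len(common) / m


def max_single_gene_rate(mat: MutationMatrix, pw: PathwayGraph) -> Tuple[str, float]:
    """The member gene with the highest per-sample NSY mutation rate.

    Genes absent from the matrix count as unmutated; ties break
    alphabetically.
    """
    best_gene, best_rate = None, -1.0
    for g in sorted(pw.genes):
        if g in mat._gene_index:
            rate = float((mat.nsy_counts[mat.gene_row(g)] > 0).sum()) / mat.n_samples
        else:
            rate = 0.0
        if rate > best_rate + _EPS:
            best_gene, best_rate = g, rate
    return best_gene, max(best_rate, 0.0)


def dominance_ok(mcr_candidate: float, max_gene_rate: float, delta: float) -> bool:
    """True iff the candidate MCR clears the top gene rate by delta (>=)."""
    return mcr_candidate + _EPS >= max_gene_rate + delta


def _candidate_mask(mat: MutationMatrix, pw: PathwayGraph) -> np.ndarray:
    rows = [mat.gene_row(g) for g in sorted(pw.genes) if g in mat._gene_index]
    if not rows:
        return np.zeros(mat.n_samples, dtype=bool)
    return (mat.nsy_counts[rows] > 0).any(axis=0)


def collab_pvalue(
    mat: MutationMatrix,
    candidate: PathwayGraph,
    selected_profiles: Sequence[CoverageProfile],
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """Mutation-redistribution permutation test for pathway collaboration.

    Every non-synonymous mutation event of the candidate's genes is
    reassigned independently to a uniformly random sample (with
    replacement, total event count preserved); the background MCR is the
    fraction of samples covered by the permuted candidate and by every
    already-selected pathway (selected coverages held at their observed
    values). p = #{background MCR >= observed MCR} / n_perm. A candidate
    with zero mutation events returns p = 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    m = mat.n_samples
    rows = [mat.gene_row(g) for g in sorted(candidate.genes) if g in mat._gene_index]
    n_events = int(mat.nsy_counts[rows].sum()) if rows else 0
    if n_events == 0:
        return 1.0

    sample_idx = {s: j for j, s in enumerate(mat.samples)}
    selected_mask = np.ones(m, dtype=bool)
    for pr in selected_profiles:
        mask = np.zeros(m, dtype=bool)
        mask[[sample_idx[s] for s in pr.covered_samples]] = True
        selected_mask &= mask

    cand_mask = (mat.nsy_counts[rows] > 0).any(axis=0)
    observed = float((cand_mask & selected_mask).sum()) / m

    count = 0
    chunk = max(1, int(2e7) // max(n_events, 1))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        idx = rng.integers(0, m, size=(b, n_events))
        covered = np.zeros((b, m), dtype=bool)
        covered[np.repeat(np.arange(b), n_events), idx.ravel()] = True
        bg = (covered & selected_mask[None, :]).sum(axis=1) / m
        count += int((bg >= observed - _EPS).sum())
        done += b
    return count / n_perm


def greedy_select(
    mat: MutationMatrix,
    top_pathways: Sequence[PathwayGraph],
    cfg: RunConfig,
    rng: np.random.Generator,
    constrained: bool = True,
) -> CollaborativeSet:
    """Greedy walk assembling the collaborative set.

    ``top_pathways`` is the ordered candidate pool (enrichment rank order,
    used to break ties in tentative MCR). With ``constrained=False`` the
    dominance and significance filters are switched off and the walk simply
    adds the pathway with the highest tentative MCR until none improves on
    zero — the diagnostic variant that exposes single-gene-driven patterns.
    """
    if not top_pathways:
        raise ValueError("candidate pool is empty")
    m = mat.n_samples
    masks: Dict[str, np.ndarray] = {}
    gene_rates: Dict[str, Tuple[str, float]] = {}
    pool_order: Dict[str, int] = {}
    by_id: Dict[str, PathwayGraph] = {}
    for i, pw in enumerate(top_pathways):
        masks[pw.pathway_id] = _candidate_mask(mat, pw)
        gene_rates[pw.pathway_id] = max_single_gene_rate(mat, pw)
        pool_order[pw.pathway_id] = i
        by_id[pw.pathway_id] = pw

    steps: List[SelectionStep] = []
    selected_profiles: List[CoverageProfile] = []
    current_mask = np.ones(m, dtype=bool)
    remaining = [pw.pathway_id for pw in top_pathways]

    while remaining:
        # rank remaining candidates by the joint MCR they would produce
        tentative = []
        for pid in remaining:
            mcr = float((current_mask & masks[pid]).sum()) / m
            tentative.append((pid, mcr))
        tentative.sort(key=lambda t: (-t[1], pool_order[t[0]]))

        chosen = None
        for pid, mcr in tentative:
            if mcr <= 0:
                break  # nothing below can cover anything either
            gene, rate = gene_rates[pid]
            if constrained:
                if not dominance_ok(mcr, rate, cfg.dominance_delta):
                    log.info(
                        "reject %s: MCR %.3f vs top gene %s rate %.3f (+%.2f)",
                        pid, mcr, gene, rate, cfg.dominance_delta,
                    )
                    continue
                if selected_profiles:
                    p = collab_pvalue(
                        mat, by_id[pid], selected_profiles, cfg.n_perm_collab, rng
                    )
                    if not p < cfg.collab_p_threshold:
                        log.info("reject %s: collaboration p %.4f", pid, p)
                        continue
                else:
                    p = float("nan")
            else:
                p = float("nan")
            chosen = (pid, mcr, p, rate)
            break
        if chosen is None:
            break
        pid, mcr, p, rate = chosen
        current_mask &= masks[pid]
        covered = frozenset(s for s, c in zip(mat.samples, current_mask) if c)
        cand_covered = frozenset(
            s for s, c in zip(mat.samples, masks[pid]) if c
        )
        selected_profiles.append(
            CoverageProfile(pid, cand_covered, float(masks[pid].sum()) / m)
        )
        steps.append(SelectionStep(pid, mcr, p, rate))
        remaining.remove(pid)
        log.info(
            "select %s: MCR %.3f, top gene rate %.3f, p %s",
            pid, mcr, rate, "n/a" if math.isnan(p) else f"{p:.4f}",
        )

    if steps:
        covered = frozenset(s for s, c in zip(mat.samples, current_mask) if c)
    else:
        covered = frozenset()
    return CollaborativeSet(steps=steps, covered_samples=covered, n_samples=m)
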