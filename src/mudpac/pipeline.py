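"""End-to-end orchestration of the two-step pipeline.

Step 1 scores genes (Mutation Factor x Interaction Factor), ranks them per
pathway and computes weighted-KS enrichment p-values with FDR; step 2 runs
the greedy collaborative-set search over the top enriched pathways. All
randomness derives from the master seed in :class:`~mudpac.types.RunConfig`:
each stage (and each sample group) gets a sub-seed hashed from the master
seed and a stable label, so adding a group never perturbs the others.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .collaboration import CollaborativeSet, greedy_select
from .enrichment import EnrichmentOutcome, enrichment_analysis, select_top_pathways
from .matrix import DataError, ImpactBounds, MutationMatrix, build_matrix
from .types import MutationRecord, PathwayGraph, RunConfig

log = logging.getLogger(__name__)


def derive_seed(master_seed: int, label: str) -> int:
    """Stable sub-seed from (master seed, label), below 2**31."""
    digest = hashlib.blake2b(f"{master_seed}:{label}".encode(), digest_size=8).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def attach_impacts(
    records: Sequence[MutationRecord],
    impact_table: Mapping[Tuple[str, str, str], float],
) -> List[MutationRecord]:
    """Fill missing impact fields from the (gene, sample, position) table."""
    out = []
    for r in records:
        if r.impact is None:
            score = impact_table.get((r.gene, r.sample, r.position))
            if score is not None:
                r = MutationRecord(r.gene, r.sample, r.variant_class, r.position,
                                   score, r.length)
        out.append(r)
    return out


@dataclass
class Step1Result:
    matrix: MutationMatrix
    bounds: ImpactBounds
    outcome: EnrichmentOutcome


@dataclass
class PipelineResult:
    step1: Step1Result
    collab: CollaborativeSet
    config: RunConfig


def run_step1(
    records: Sequence[MutationRecord],
    pathways: Sequence[PathwayGraph],
    coverage: Mapping[str, int],
    impact_table: Optional[Mapping[Tuple[str, str, str], float]] = None,
    cfg: Optional[RunConfig] = None,
    samples: Optional[Sequence[str]] = None,
    bounds: Optional[ImpactBounds] = None,
) -> Step1Result:
    """Mutational pathway enrichment analysis.

    The gene universe of the mutation matrix is the union of mutated genes
    and all pathway genes, so unmutated pathway members participate in the
    interaction statistics with all-zero profiles.
    """
    cfg = cfg or RunConfig()
    if impact_table:
        records = attach_impacts(records, impact_table)
    if samples is None:
        samples = sorted({r.sample for r in records})
    if bounds is None:
        try:
            bounds = ImpactBounds.from_records(records)
        except DataError:
            # no scored missense mutation anywhere (e.g. an empty sample
            # group): fall back to degenerate bounds; coverage statistics
            # downstream depend on counts, not impact magnitudes
            log.warning("no scored missense mutations; using zero impact bounds")
            bounds = ImpactBounds(0.0, 0.0, 0.0)
    universe = sorted(
        {r.gene for r in records} | {g for pw in pathways for g in pw.genes}
    )
    mat = build_matrix(records, coverage, bounds, samples, universe)
    log.info(
        "step 1: %d records, %d genes, %d samples, %d pathways",
        len(records), mat.n_genes, mat.n_samples, len(pathways),
    )
    rng = np.random.default_rng(derive_seed(cfg.rng_seed, "enrichment"))
    outcome = enrichment_analysis(mat, pathways, cfg, rng)
    log.info("step 1: tested %d pathways (%d skipped)",
             len(outcome.results), len(outcome.skipped))
    return Step1Result(matrix=mat, bounds=bounds, outcome=outcome)


def run_step2(
    mat: MutationMatrix,
    outcome: EnrichmentOutcome,
    pathways: Sequence[PathwayGraph],
    cfg: Optional[RunConfig] = None,
    constrained: bool = True,
) -> CollaborativeSet:
    """Greedy collaborative-set search over the top enriched pathways."""
    cfg = cfg or RunConfig()
    if not outcome.results:
        return CollaborativeSet(steps=[], covered_samples=frozenset(),
                                n_samples=mat.n_samples)
    top_ids = select_top_pathways(outcome.results, cfg.top_k_pathways)
    by_id = {pw.pathway_id: pw for pw in pathways}
    candidates = [by_id[pid] for pid in top_ids if pid in by_id]
    rng = np.random.default_rng(derive_seed(cfg.rng_seed, "collaboration"))
    collab = greedy_select(mat, candidates, cfg, rng, constrained=constrained)
    log.info("step 2: selected %d pathways, MCR %.3f",
             len(collab.steps), collab.mcr)
    return collab


def run_pipeline(
    records: Sequence[MutationRecord],
    pathways: Sequence[PathwayGraph],
    coverage: Mapping[str, int],
    impact_table: Optional[Mapping[Tuple[str, str, str], float]] = None,
    cfg: Optional[RunConfig] = None,
    samples: Optional[Sequence[str]] = None,
    constrained: bool = True,
) -> PipelineResult:
    """Both steps end-to-end."""
    cfg = cfg or RunConfig()
    step1 = run_step1(records, pathways, coverage, impact_table, cfg, samples)
    collab = run_step2(step1.matrix, step1.outcome, pathways, cfg,
                       constrained=constrained)
    return PipelineResult(step1=step1, collab=collab, config=cfg)


def run_per_group(
    records: Sequence[MutationRecord],
    group_assignments: Mapping[str, str],
    pathways: Sequence[PathwayGraph],
    coverage: Mapping[str, int],
    impact_table: Optional[Mapping[Tuple[str, str, str], float]] = None,
    cfg: Optional[RunConfig] = None,
    samples: Optional[Sequence[str]] = None,
    constrained: bool = True,
) -> Tuple[Dict[str, PipelineResult], pd.DataFrame]:
    """Run the full pipeline independently per sample group.

    Every sample must be assigned to exactly one group. Returns per-group
    results plus a pathway x group comparison table of selected pathways
    (shared vs group-specific membership).
    """
    cfg = cfg or RunConfig()
    if samples is None:
        samples = sorted({r.sample for r in records})
    missing = [s for s in samples if s not in group_assignments]
    if missing:
        raise DataError(f"samples without a group assignment: {missing[:5]}")
    group_names = sorted(set(group_assignments[s] for s in samples))

    results: Dict[str, PipelineResult] = {}
    for gname in group_names:
        g_samples = [s for s in samples if group_assignments[s] == gname]
        g_records = [r for r in records if r.sample in set(g_samples)]
        g_cfg = cfg.replace(rng_seed=derive_seed(cfg.rng_seed, f"group:{gname}"))
        log.info("group %s: %d samples, %d records", gname, len(g_samples),
                 len(g_records))
        results[gname] = run_pipeline(
            g_records, pathways, coverage, impact_table, g_cfg,
            samples=g_samples, constrained=constrained,
        )

    all_selected = sorted(
        {pid for res in results.values() for pid in res.collab.pathway_ids}
    )
    table = pd.DataFrame(
        {
            g: [pid in results[g].collab.pathway_ids for pid in all_selected]
            for g in group_names
        },
        index=pd.Index(all_selected, name="pathway_id"),
    )
    if not table.empty:
        table["shared"] = table[group_names].all(axis=1)
    return results, table
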