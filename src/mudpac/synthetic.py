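"""Synthetic somatic-mutation cohorts with known ground truth.

The generator emulates the four inputs the pipeline consumes — MAF-style
mutation records, a per-gene covered-base table, a per-mutation impact
table, and pathway definitions with random connected topologies — and
plants two kinds of structure on top of an independent background:

* *collaborative groups*: a per-sample Bernoulli indicator marks a sample
  as belonging to the co-mutated block, and every member pathway of the
  group then receives at least one non-synonymous mutation there, spread
  across randomly chosen member genes rather than a fixed one (a driver
  pathway need not be dominated by a single gene — this is exactly what
  makes dominance-filter and MCR tests meaningful);
* *single-gene-dominated pathways*: all coverage arrives through one
  designated gene, whose partners are excluded from the non-synonymous
  background so the dominance filter has a clean target.

Everything is drawn from one seeded generator in a fixed order, so a given
spec and seed reproduce the cohort byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from . import io_formats
from .types import MutationRecord, PathwayGraph, VariantClass

#: high-impact classes emitted for a small fraction of non-synonymous events
_HIGH_IMPACT = (VariantClass.INDEL, VariantClass.NONSENSE, VariantClass.SPLICE_SITE)


@dataclass(frozen=True)
class ImpactModel:
    """Bounds and spread of the synthetic functional-impact score."""

    ma_min: float = 0.2
    ma_max: float = 5.0
    missense_mean: float = 2.0
    missense_sd: float = 0.8
    unscored_fraction: float = 0.1  # missense events left out of the impact table


@dataclass(frozen=True)
class PlantedSet:
    """A group of pathways co-mutated in a Bernoulli(target) block of samples."""

    pathway_indices: Tuple[int, ...]
    target: float
    group: Optional[str] = None  # restrict the block to one sample group


@dataclass(frozen=True)
class DominatedPathway:
    pathway_index: int
    gene_coverage: float  # the designated gene's per-sample mutation rate


@dataclass(frozen=True)
class CohortSpec:
    m_samples: int
    n_genes: int
    n_pathways: int
    genes_per_pathway: Tuple[int, int]
    background_nsy_rate: float
    background_sy_rate: float
    planted_sets: Tuple[PlantedSet, ...] = ()
    dominated_pathways: Tuple[DominatedPathway, ...] = ()
    impact: ImpactModel = field(default_factory=ImpactModel)
    sample_groups: Optional[Tuple[Tuple[str, int], ...]] = None
    extra_edge_prob: float = 0.2
    high_impact_fraction: float = 0.1
    disjoint_pathways: bool = False  # gene-disjoint pathways (independent decoys)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("background_nsy_rate", "background_sy_rate",
                     "high_impact_fraction", "extra_edge_prob"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.genes_per_pathway
        if not (1 <= lo <= hi <= self.n_genes):
            raise ValueError("invalid genes_per_pathway range")
        if self.sample_groups is not None:
            if sum(n for _, n in self.sample_groups) != self.m_samples:
                raise ValueError("sample_groups sizes must sum to m_samples")
        groups = {g for g, _ in (self.sample_groups or ())}
        for ps in self.planted_sets:
            if not (0 <= ps.target <= 1):
                raise ValueError("planted joint coverage target must lie in [0, 1]")
            if ps.target < self.background_nsy_rate:
                raise ValueError("planted target below the background rate")
            for i in ps.pathway_indices:
                if not (0 <= i < self.n_pathways):
                    raise ValueError(f"planted pathway index {i} out of range")
            if ps.group is not None and ps.group not in groups:
                raise ValueError(f"unknown sample group {ps.group!r}")
        for dp in self.dominated_pathways:
            if not (0 <= dp.gene_coverage <= 1):
                raise ValueError("dominant gene coverage must lie in [0, 1]")
            if not (0 <= dp.pathway_index < self.n_pathways):
                raise ValueError("dominated pathway index out of range")


@dataclass
class GroundTruth:
    planted_sets: List[Dict]  # {"pathway_ids": [...], "group": ..., "samples": [...]}
    dominated: List[Dict]  # {"pathway_id": ..., "gene": ...}

    def to_json(self) -> str:
        return json.dumps(
            {"planted_sets": self.planted_sets, "dominated": self.dominated},
            indent=2,
            sort_keys=True,
        )


@dataclass
class SyntheticCohort:
    records: List[MutationRecord]
    coverage: Dict[str, int]
    impact_table: Dict[Tuple[str, str, str], float]
    pathways: List[PathwayGraph]
    samples: List[str]
    groups: Dict[str, str]  # sample -> group name ("all" when ungrouped)
    truth: GroundTruth

    def write(self, out_dir: str) -> None:
        """Write the four pipeline inputs plus truth/groups to a directory."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        io_formats.write_maf(self.records, os.path.join(out_dir, "cohort.maf"))
        io_formats.write_coverage(self.coverage, os.path.join(out_dir, "coverage.tsv"))
        io_formats.write_impact_table(
            self.impact_table, os.path.join(out_dir, "impacts.tsv")
        )
        io_formats.write_pathways(self.pathways, os.path.join(out_dir, "pathways.txt"))
        with open(os.path.join(out_dir, "samples.tsv"), "w") as fh:
            for s in self.samples:
                fh.write(f"{s}\t{self.groups[s]}\n")
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            fh.write(self.truth.to_json())
            fh.write("\n")


def _random_connected_pathway(
    pid: str, name: str, members: Sequence[str], extra_edge_prob: float,
    rng: np.random.Generator,
) -> PathwayGraph:
    members = list(members)
    order = list(rng.permutation(members))
    edges = []
    for i in range(1, len(order)):
        j = int(rng.integers(0, i))
        edges.append((order[j], order[i]))
    # sprinkle extra edges over the remaining pairs
    present = {tuple(sorted(e)) for e in edges}
    for i in range(len(order)):
        for j in range(i + 1, len(order)):
            pair = tuple(sorted((order[i], order[j])))
            if pair not in present and rng.random() < extra_edge_prob:
                edges.append(pair)
                present.add(pair)
    return PathwayGraph.make(pid, name, members, edges)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full synthetic cohort from a :class:`CohortSpec`.

    Deterministic given ``spec.rng_seed``: same spec and seed give
    byte-identical files.
    """
    rng = np.random.default_rng(spec.rng_seed)

    # --- samples and groups
    if spec.sample_groups:
        samples: List[str] = []
        groups: Dict[str, str] = {}
        for gname, n in spec.sample_groups:
            for j in range(n):
                s = f"{gname}-{j:04d}"
                samples.append(s)
                groups[s] = gname
    else:
        samples = [f"S{j:04d}" for j in range(spec.m_samples)]
        groups = {s: "all" for s in samples}
    m = len(samples)

    genes = [f"G{i:04d}" for i in range(spec.n_genes)]

    # --- pathways with random connected topology
    lo, hi = spec.genes_per_pathway
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_pathways)]
    pathways: List[PathwayGraph] = []
    if spec.disjoint_pathways:
        if sum(sizes) > spec.n_genes:
            raise ValueError(
                "disjoint pathways need sum(sizes) <= n_genes "
                f"({sum(sizes)} > {spec.n_genes})"
            )
        pool = list(rng.permutation(genes))
        offset = 0
        member_sets = []
        for size in sizes:
            member_sets.append(sorted(pool[offset:offset + size]))
            offset += size
    else:
        member_sets = [
            sorted(rng.choice(genes, size=size, replace=False)) for size in sizes
        ]
    for k, members in enumerate(member_sets):
        pathways.append(
            _random_connected_pathway(
                f"PW{k:03d}", f"pathway_{k}", members, spec.extra_edge_prob, rng
            )
        )

    # genes whose background NSY mutations are suppressed so that dominated
    # pathways are covered only through their designated gene
    dominant_gene: Dict[int, str] = {}
    suppressed: set = set()
    for dp in spec.dominated_pathways:
        members = sorted(pathways[dp.pathway_index].genes)
        dominant_gene[dp.pathway_index] = members[0]
        suppressed.update(members[1:])

    records: List[MutationRecord] = []
    impact_table: Dict[Tuple[str, str, str], float] = {}
    position_counter: Dict[str, int] = {g: 0 for g in genes}
    imp = spec.impact

    def add_nsy(gene: str, sample: str) -> None:
        position_counter[gene] += 1
        pos = str(position_counter[gene])
        if rng.random() < spec.high_impact_fraction:
            vc = _HIGH_IMPACT[int(rng.integers(0, len(_HIGH_IMPACT)))]
            records.append(MutationRecord(gene, sample, vc, pos))
        else:
            records.append(MutationRecord(gene, sample, VariantClass.MISSENSE, pos))
            score = float(
                np.clip(rng.normal(imp.missense_mean, imp.missense_sd),
                        imp.ma_min, imp.ma_max)
            )
            if rng.random() >= imp.unscored_fraction:
                impact_table[(gene, sample, pos)] = score

    def add_sy(gene: str, sample: str) -> None:
        position_counter[gene] += 1
        records.append(
            MutationRecord(gene, sample, VariantClass.SILENT, str(position_counter[gene]))
        )

    # --- independent background
    if spec.background_nsy_rate > 0:
        for gene in genes:
            if gene in suppressed:
                continue
            hits = np.nonzero(rng.random(m) < spec.background_nsy_rate)[0]
            for j in hits:
                add_nsy(gene, samples[j])
    if spec.background_sy_rate > 0:
        for gene in genes:
            hits = np.nonzero(rng.random(m) < spec.background_sy_rate)[0]
            for j in hits:
                add_sy(gene, samples[j])

    # --- planted collaborative blocks
    truth_sets: List[Dict] = []
    for ps in spec.planted_sets:
        eligible = (
            [s for s in samples if groups[s] == ps.group]
            if ps.group is not None
            else samples
        )
        flags = rng.random(len(eligible)) < ps.target
        block = [s for s, f in zip(eligible, flags) if f]
        member_lists = {
            i: sorted(pathways[i].genes - suppressed) or sorted(pathways[i].genes)
            for i in ps.pathway_indices
        }
        for s in block:
            for i in ps.pathway_indices:
                gene = member_lists[i][int(rng.integers(0, len(member_lists[i])))]
                add_nsy(gene, s)
        truth_sets.append(
            {
                "pathway_ids": [pathways[i].pathway_id for i in ps.pathway_indices],
                "group": ps.group,
                "samples": block,
            }
        )

    # --- single-gene-dominated pathways
    truth_dom: List[Dict] = []
    for dp in spec.dominated_pathways:
        gene = dominant_gene[dp.pathway_index]
        hits = np.nonzero(rng.random(m) < dp.gene_coverage)[0]
        for j in hits:
            add_nsy(gene, samples[j])
        truth_dom.append(
            {"pathway_id": pathways[dp.pathway_index].pathway_id, "gene": gene}
        )

    coverage = {
        g: int(rng.integers(50_000, 200_001)) for g in genes
    }

    return SyntheticCohort(
        records=records,
        coverage=coverage,
        impact_table=impact_table,
        pathways=pathways,
        samples=samples,
        groups=groups,
        truth=GroundTruth(planted_sets=truth_sets, dominated=truth_dom),
    )


def spec_presets() -> Dict[str, CohortSpec]:
    """Named cohort specifications exercising each pipeline property.

    * ``null`` — no planted structure; 200 pathways over 200 samples, for
      p-value calibration.
    * ``planted_trio`` — three pathways co-mutated in 60% of 500 samples
      plus seven decoys with independent background mutations, for greedy
      recovery.
    * ``dominated`` — one pathway whose entire coverage flows through a
      single gene mutated in 72% of samples (the classic TP53 pattern),
      plus an honest co-mutated pair, for the dominance filter.
    * ``breast_like`` — four sample groups sized like breast-cancer
      subtype cohorts (93/57/224/124), each with its own planted set.
    """
    return {
        "null": CohortSpec(
            m_samples=200,
            n_genes=1000,
            n_pathways=200,
            genes_per_pathway=(4, 10),
            background_nsy_rate=0.02,
            background_sy_rate=0.01,
        ),
        "planted_trio": CohortSpec(
            m_samples=500,
            n_genes=120,
            n_pathways=10,
            genes_per_pathway=(6, 10),
            background_nsy_rate=0.05,
            background_sy_rate=0.02,
            planted_sets=(PlantedSet((0, 1, 2), 0.6),),
            disjoint_pathways=True,
        ),
        "dominated": CohortSpec(
            m_samples=300,
            n_genes=60,
            n_pathways=6,
            genes_per_pathway=(5, 8),
            background_nsy_rate=0.04,
            background_sy_rate=0.02,
            planted_sets=(PlantedSet((1, 2), 0.5),),
            dominated_pathways=(DominatedPathway(0, 0.72),),
            disjoint_pathways=True,
        ),
        "breast_like": CohortSpec(
            m_samples=498,
            n_genes=150,
            n_pathways=12,
            genes_per_pathway=(6, 10),
            background_nsy_rate=0.03,
            background_sy_rate=0.015,
            sample_groups=(
                ("Basal", 93),
                ("HER2", 57),
                ("LumA", 224),
                ("LumB", 124),
            ),
            planted_sets=(
                PlantedSet((0, 1), 0.7, group="Basal"),
                PlantedSet((2, 3), 0.6, group="HER2"),
                PlantedSet((4, 5, 6), 0.65, group="LumA"),
                PlantedSet((7, 8), 0.55, group="LumB"),
            ),
            disjoint_pathways=True,
        ),
    }
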