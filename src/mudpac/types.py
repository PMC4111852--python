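"""Core domain types shared across the pipeline.

A cohort is described by somatic mutation calls (:class:`MutationRecord`),
pathway definitions with topology (:class:`PathwayGraph`), a per-gene
covered-base table, and a per-mutation functional-impact score table.
:class:`RunConfig` collects every tunable threshold of the two-step method.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from enum import Enum
from typing import FrozenSet, Optional, Tuple


class VariantClass(str, Enum):
    """Collapsed somatic variant classification.

    Mirrors the classes the impact-scoring rule distinguishes: protein
    truncating / structure disrupting classes (indel, nonsense, splice site)
    receive the maximal impact score, silent mutations the minimal one, and
    missense mutations carry their own computed score.
    """

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    INDEL = "indel"
    SPLICE_SITE = "splice_site"
    SILENT = "silent"
    OTHER = "other"


#: MAF Variant_Classification values -> collapsed enum (lower-cased keys).
MAF_CLASS_MAP = {
    "silent": VariantClass.SILENT,
    "synonymous": VariantClass.SILENT,
    "missense_mutation": VariantClass.MISSENSE,
    "missense": VariantClass.MISSENSE,
    "nonsense_mutation": VariantClass.NONSENSE,
    "nonsense": VariantClass.NONSENSE,
    "frame_shift_ins": VariantClass.INDEL,
    "frame_shift_del": VariantClass.INDEL,
    "in_frame_ins": VariantClass.INDEL,
    "in_frame_del": VariantClass.INDEL,
    "indel": VariantClass.INDEL,
    "splice_site": VariantClass.SPLICE_SITE,
}


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation call.

    Parameters
    ----------
    gene : str
        HGNC-style gene symbol; non-empty.
    sample : str
        Sample (tumor) barcode; non-empty.
    variant_class : VariantClass
        Collapsed variant classification.
    position : str
        1-based coordinate, treated as an opaque key (it is only used to
        match mutations against the external impact-score table).
    impact : float, optional
        Functional impact score, if one was computed for this mutation.
        Non-negative when present.
    length : int
        Number of mutated bases; defaults to 1 (point mutation). Indels may
        carry their recorded length.
    """

    gene: str
    sample: str
    variant_class: VariantClass
    position: str = "0"
    impact: Optional[float] = None
    length: int = 1

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("MutationRecord.gene must be non-empty")
        if not self.sample:
            raise ValueError("MutationRecord.sample must be non-empty")
        if not isinstance(self.variant_class, VariantClass):
            raise ValueError(f"invalid variant class: {self.variant_class!r}")
        if self.impact is not None and self.impact < 0:
            raise ValueError("impact score must be >= 0")
        if self.length < 1:
            raise ValueError("length must be >= 1")


@dataclass(frozen=True)
class PathwayGraph:
    """A named gene set with undirected topology.

    Only unweighted shortest-path hop counts are ever read off the topology,
    so edges are stored as unordered pairs and the graph is simple (no
    self-edges, no multi-edges).
    """

    pathway_id: str
    name: str
    genes: FrozenSet[str]
    edges: FrozenSet[Tuple[str, str]]  # each tuple sorted (a < b)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.pathway_id}: empty gene set")
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"pathway {self.pathway_id}: self-edge {a}")
            if a not in self.genes or b not in self.genes:
                raise ValueError(
                    f"pathway {self.pathway_id}: edge {a}-{b} has an endpoint "
                    "outside the declared gene list"
                )

    @staticmethod
    def make(pathway_id: str, name: str, genes, edges) -> "PathwayGraph":
        """Build a graph normalising edge orientation."""
        norm = frozenset(tuple(sorted((a, b))) for a, b in edges)
        return PathwayGraph(pathway_id, name, frozenset(genes), norm)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(sorted(self.genes))
        g.add_edges_from(self.edges)
        return g


@dataclass
class RunConfig:
    """All tunable parameters of the two-step pipeline.

    Attributes
    ----------
    alpha : float
        Interaction-strength gate: a gene pair contributes to the
        interaction factor only when f_ij >= alpha. Also the floor applied
        to IF when no pair passes, and the fallback scale for imputed
        non-passing genes. Default 0.005.
    n_perm_enrichment : int
        Permutations for the weighted-KS enrichment p-value. Default 5000.
    n_perm_collab : int
        Permutations for the pathway-collaboration test. Default 5000.
    top_k_pathways : int
        Number of enriched pathways carried into the greedy step. Default 60.
    dominance_delta : float
        The collaborative set's coverage must exceed the top single-gene
        mutation rate of each member pathway by at least this margin.
        Default 0.05.
    collab_p_threshold : float
        Strict upper bound on the collaboration permutation p-value.
        Default 0.01.
    rng_seed : int
        Master seed; every source of randomness derives from it.
    """

    alpha: float = 0.005
    n_perm_enrichment: int = 5000
    n_perm_collab: int = 5000
    top_k_pathways: int = 60
    dominance_delta: float = 0.05
    collab_p_threshold: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.dominance_delta < 1):
            raise ValueError("dominance_delta must be in (0, 1)")
        if not (0 < self.collab_p_threshold < 1):
            raise ValueError("collab_p_threshold must be in (0, 1)")
        for name in ("n_perm_enrichment", "n_perm_collab", "top_k_pathways"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def replace(self, **kw) -> "RunConfig":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(kw)
        return RunConfig(**d)
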