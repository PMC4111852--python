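"""Impact scoring, the paired mutation matrix, and the per-gene Mutation Factor.

The cohort is summarised as a pair of n x m matrices: for every gene i and
sample j, ``nsy[i, j]`` accumulates the impact-weighted non-synonymous
mutation burden and ``sy[i, j]`` the synonymous one, each normalised by the
gene's number of sufficiently covered bases. Raw event counts are kept
alongside because coverage and exclusivity statistics downstream depend on
whether a gene is mutated at all, not on impact magnitude.

Impact scoring rule
-------------------
Truncating or structure-disrupting variants (indels, nonsense, splice site)
take the highest attainable impact score; silent variants take the lowest;
missense variants keep their computed score, or the cohort-wide mean
missense score when none was computed. Variants of class "other" fall
outside the rule and are skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np

from .types import MutationRecord, VariantClass

log = logging.getLogger(__name__)


class DataError(ValueError):
    """Raised when cohort inputs are mutually inconsistent."""


@dataclass(frozen=True)
class ImpactBounds:
    """Attainable range of the functional impact score.

    ``ma_max`` is assigned to indel/nonsense/splice-site variants, ``ma_min``
    to silent ones, and ``missense_mean`` to missense variants lacking a
    computed score.
    """

    ma_max: float
    ma_min: float
    missense_mean: float

    def __post_init__(self) -> None:
        if not (self.ma_min <= self.missense_mean <= self.ma_max):
            raise ValueError("need ma_min <= missense_mean <= ma_max")

    @classmethod
    def from_records(cls, records: Iterable[MutationRecord]) -> "ImpactBounds":
        """Derive bounds from the scores present in a cohort.

        Uses the observed missense impact scores: their max, min and mean.
        Raises :class:`DataError` when the cohort carries no scored missense
        mutation at all (bounds must then be supplied explicitly).
        """
        scores = [
            r.impact
            for r in records
            if r.variant_class is VariantClass.MISSENSE and r.impact is not None
        ]
        if not scores:
            raise DataError(
                "no scored missense mutations in the cohort; "
                "supply ImpactBounds explicitly"
            )
        arr = np.asarray(scores, dtype=float)
        return cls(ma_max=float(arr.max()), ma_min=float(arr.min()),
                   missense_mean=float(arr.mean()))


def assign_impact_score(rec: MutationRecord, bounds: ImpactBounds) -> Optional[float]:
    """Apply the impact scoring rule to one mutation.

    Returns the impact score, or ``None`` for class "other" (the variant is
    skipped, not scored zero).
    """
    vc = rec.variant_class
    if vc in (VariantClass.INDEL, VariantClass.NONSENSE, VariantClass.SPLICE_SITE):
        return bounds.ma_max
    if vc is VariantClass.SILENT:
        return bounds.ma_min
    if vc is VariantClass.MISSENSE:
        return rec.impact if rec.impact is not None else bounds.missense_mean
    return None


@dataclass
class MutationMatrix:
    """Paired non-synonymous / synonymous impact matrices plus raw counts."""

    genes: List[str]
    samples: List[str]
    nsy: np.ndarray  # (n, m) impact-weighted, coverage-normalised
    sy: np.ndarray
    nsy_counts: np.ndarray  # (n, m) raw event counts
    sy_counts: np.ndarray

    def __post_init__(self) -> None:
        n, m = len(self.genes), len(self.samples)
        for name in ("nsy", "sy", "nsy_counts", "sy_counts"):
            a = getattr(self, name)
            if a.shape != (n, m):
                raise ValueError(f"{name} has shape {a.shape}, expected {(n, m)}")
        if (self.nsy < 0).any() or (self.sy < 0).any():
            raise ValueError("impact entries must be non-negative")
        # an impact entry may be nonzero only where an event was counted
        if ((self.nsy > 0) & (self.nsy_counts == 0)).any():
            raise ValueError("nsy impact without a counted event")
        if ((self.sy > 0) & (self.sy_counts == 0)).any():
            raise ValueError("sy impact without a counted event")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._sample_index = {s: j for j, s in enumerate(self.samples)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_row(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def nsy_mutated(self) -> np.ndarray:
        """Boolean (n, m): gene carries >=1 non-synonymous event in sample."""
        return self.nsy_counts > 0


def build_matrix(
    records: Sequence[MutationRecord],
    coverage: Mapping[str, int],
    bounds: ImpactBounds,
    samples: Sequence[str],
    genes: Optional[Sequence[str]] = None,
) -> MutationMatrix:
    """Accumulate mutation records into a :class:`MutationMatrix`.

    Each mutation contributes ``length * impact / covered_bases(gene)`` to
    its gene x sample entry: silent events into the synonymous matrix,
    missense/nonsense/indel/splice-site events into the non-synonymous one.
    "other" events are skipped with a logged count.

    Parameters
    ----------
    genes : sequence, optional
        Row universe; defaults to the sorted distinct genes of ``records``.
        Extra genes (e.g. unmutated pathway members) get all-zero rows and
        need no coverage entry.
    """
    if genes is None:
        genes = sorted({r.gene for r in records})
    genes = list(genes)
    samples = list(samples)
    gi = {g: i for i, g in enumerate(genes)}
    sj = {s: j for j, s in enumerate(samples)}
    n, m = len(genes), len(samples)
    nsy = np.zeros((n, m))
    sy = np.zeros((n, m))
    nsy_counts = np.zeros((n, m), dtype=np.int64)
    sy_counts = np.zeros((n, m), dtype=np.int64)

    n_skipped = 0
    for rec in records:
        score = assign_impact_score(rec, bounds)
        if score is None:
            n_skipped += 1
            continue
        if rec.gene not in gi:
            raise DataError(f"mutated gene {rec.gene!r} outside the gene universe")
        if rec.sample not in sj:
            raise DataError(f"sample {rec.sample!r} outside the sample list")
        cov = coverage.get(rec.gene)
        if cov is None or cov <= 0:
            raise DataError(f"mutated gene {rec.gene!r} missing from the coverage table")
        i, j = gi[rec.gene], sj[rec.sample]
        contribution = rec.length * score / cov
        if rec.variant_class is VariantClass.SILENT:
            sy[i, j] += contribution
            sy_counts[i, j] += 1
        else:
            nsy[i, j] += contribution
            nsy_counts[i, j] += 1
    if n_skipped:
        log.info("skipped %d mutations of class 'other'", n_skipped)
    return MutationMatrix(genes, samples, nsy, sy, nsy_counts, sy_counts)


def mutation_factors(mat: MutationMatrix) -> np.ndarray:
    """Mutation Factor for every gene (vectorised).

    MF_i = (N_i_NSY / max(N_i_SY, 1)) * mean_j(nsy[i, j] - sy[i, j]), where
    N_* are total raw event counts across samples. The max(., 1) guard keeps
    the non-synonymous/synonymous count ratio defined for genes without any
    synonymous event.
    """
    n_nsy = mat.nsy_counts.sum(axis=1)
    n_sy = mat.sy_counts.sum(axis=1)
    weight = n_nsy / np.maximum(n_sy, 1)
    return weight * (mat.nsy - mat.sy).mean(axis=1)


def mutation_factor(mat: MutationMatrix, gene: str) -> float:
    """Mutation Factor of one gene; KeyError if the gene is not in the matrix."""
    i = mat.gene_row(gene)
    n_nsy = int(mat.nsy_counts[i].sum())
    n_sy = int(mat.sy_counts[i].sum())
    return (n_nsy / max(n_sy, 1)) * float((mat.nsy[i] - mat.sy[i]).mean())
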