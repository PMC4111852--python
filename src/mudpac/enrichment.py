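"""Gene ranking and weighted Kolmogorov–Smirnov pathway enrichment.

Per pathway, member genes are scored ``exp(MF) * IF`` (exponentiating keeps
the score positive and monotone in both factors), genes outside the pathway
get imputed scores drawn from a cohort-wide background distribution, and
the resulting ranked list is tested GSEA-style: the maximum deviation (MD)
between the score-weighted cumulative distribution of members and the
uniform cumulative distribution of non-members, with a permutation null
obtained by shuffling membership flags over list positions.

Imputation mirrors the gated structure of real interaction factors: with
probability equal to the pathway's fraction of gate-passing members, an
outside gene draws from Normal(background mean, background sd) truncated
at a small positive floor; otherwise it falls back to ``exp(MF) * alpha``,
exactly the score a real member with no passing partner would get.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .interaction import (
    distance_matrix,
    interaction_factors_from_profiles,
    pathway_interaction_factors,
)
from .matrix import MutationMatrix, mutation_factors
from .types import PathwayGraph, RunConfig

log = logging.getLogger(__name__)

#: lower truncation for imputed scores, keeps every score strictly positive
SCORE_FLOOR = 1e-12


@dataclass(frozen=True)
class GeneScore:
    gene: str
    mf: float
    if_value: float
    score: float
    imputed: bool

    def __post_init__(self) -> None:
        if self.score <= 0:
            raise ValueError("ranking score must be strictly positive")


def ranking_score(mf: float, if_value: float) -> float:
    """Combined ranking score exp(MF) * IF; requires IF in (0, 1)."""
    if not (0 < if_value < 1):
        raise ValueError(f"IF must lie strictly in (0, 1), got {if_value}")
    return math.exp(mf) * if_value


@dataclass
class RankedList:
    """All genes sorted by descending score with aligned membership flags."""

    pathway_id: str
    entries: List[GeneScore]
    membership: np.ndarray  # bool, aligned to entries

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=bool)
        if len(self.entries) != self.membership.size:
            raise ValueError("entries and membership must align")
        scores = np.array([e.score for e in self.entries])
        if scores.size and (np.diff(scores) > 1e-15).any():
            raise ValueError("entries must be sorted by non-increasing score")
        if not self.membership.any() or self.membership.all():
            raise ValueError("need at least one member and one non-member")

    @classmethod
    def build(
        cls,
        pathway_id: str,
        member_scores: Sequence[GeneScore],
        outside_scores: Sequence[GeneScore],
    ) -> "RankedList":
        tagged = [(s, True) for s in member_scores] + [(s, False) for s in outside_scores]
        tagged.sort(key=lambda t: (-t[0].score, t[0].gene))
        return cls(
            pathway_id=pathway_id,
            entries=[t[0] for t in tagged],
            membership=np.array([t[1] for t in tagged]),
        )

    def scores(self) -> np.ndarray:
        return np.array([e.score for e in self.entries])


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    md: float
    p: float
    fdr: float = float("nan")
    rank: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.md <= 1 + 1e-12):
            raise ValueError("maximum deviation must lie in [0, 1]")
        if not (0 < self.p <= 1):
            raise ValueError("permutation p-value must lie in (0, 1]")


def impute_outside_scores(
    outside: Sequence[Tuple[str, float]],
    background_mean: float,
    background_sd: float,
    pass_rate: float,
    alpha: float,
    rng: np.random.Generator,
) -> List[GeneScore]:
    """Impute ranking scores for genes outside a pathway.

    Parameters
    ----------
    outside : sequence of (gene, mf)
        Outside genes with their own Mutation Factors (needed for the
        non-passing fallback ``exp(mf) * alpha``).
    pass_rate : float
        Fraction of in-pathway genes whose IF gate passed; an outside gene
        draws from the background Normal with this probability.
    """
    if background_sd < 0:
        raise ValueError("background_sd must be >= 0")
    if not (0 <= pass_rate <= 1):
        raise ValueError("pass_rate must lie in [0, 1]")
    n = len(outside)
    if n == 0:
        return []
    if pass_rate == 0:
        drawn = np.zeros(n, dtype=bool)
    else:
        drawn = rng.random(n) < pass_rate
    draws = np.empty(n)
    k = int(drawn.sum())
    if k:
        draws[drawn] = rng.normal(background_mean, background_sd, size=k)
    out: List[GeneScore] = []
    for i, (gene, mf) in enumerate(outside):
        if drawn[i]:
            score = max(draws[i], SCORE_FLOOR)
        else:
            score = max(math.exp(mf) * alpha, SCORE_FLOOR)
        out.append(GeneScore(gene=gene, mf=mf, if_value=alpha, score=score, imputed=True))
    return out


def _block_boundaries(scores: np.ndarray) -> np.ndarray:
    """Indices of the last position of each distinct-score block.

    Exactly tied scores (e.g. the many genes sitting at the alpha floor)
    form one atomic block: both CDFs jump together and the deviation is
    evaluated only at block ends, so the statistic does not depend on the
    arbitrary within-tie ordering.
    """
    n = scores.size
    boundary = np.empty(n, dtype=bool)
    boundary[-1] = True
    boundary[:-1] = scores[:-1] != scores[1:]
    return np.nonzero(boundary)[0]


def _cdf_curves(scores: np.ndarray, membership: np.ndarray):
    member_weight = np.where(membership, scores, 0.0)
    total = member_weight.sum()
    if total <= 0:
        raise ValueError("total member score is zero; scores are corrupt")
    cdf_hit = np.cumsum(member_weight) / total
    n_miss = int((~membership).sum())
    cdf_miss = np.cumsum(~membership) / n_miss
    return cdf_hit, cdf_miss


def wks_statistic(rl: RankedList) -> float:
    """Maximum deviation between member and non-member CDFs along the list.

    Walking positions i from the top, CDF_hit(i) is the member-score mass
    accumulated so far over the total member mass, CDF_miss(i) the fraction
    of non-members seen so far; MD = max_i |CDF_hit - CDF_miss|, the max
    taken over distinct-score block ends (every position when scores are
    all distinct).
    """
    scores = rl.scores()
    cdf_hit, cdf_miss = _cdf_curves(scores, rl.membership)
    idx = _block_boundaries(scores)
    return float(np.abs(cdf_hit - cdf_miss)[idx].max())


def enrichment_pvalue(
    rl: RankedList, n_perm: int, rng: np.random.Generator
) -> EnrichmentResult:
    """Membership-shuffle permutation p-value for a pathway's MD.

    Membership flags are shuffled uniformly over list positions (scores
    fixed), preserving the member count; p = (#{MD_perm >= MD_obs} + 1) /
    (n_perm + 1), so p is always strictly positive. This null assumes the
    member scores are an exchangeable draw from the list — adequate for a
    quick screen, but it ignores the correlation that pathway-level
    interaction statistics induce among member scores; the profile-shuffle
    scheme (:func:`profile_shuffle_pvalue`) is the calibrated default.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    scores = rl.scores()
    membership = rl.membership
    md_obs = wks_statistic(rl)
    idx = _block_boundaries(scores)

    n = scores.size
    n_member = int(membership.sum())
    n_miss = n - n_member
    count = 0
    # chunked so memory stays bounded at large n_perm x n
    chunk = max(1, int(2e7) // max(n, 1))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        # b random permutations of the membership vector via argsort of noise
        order = np.argsort(rng.random((b, n)), axis=1)
        mem = np.zeros((b, n), dtype=bool)
        np.put_along_axis(mem, order[:, :n_member], True, axis=1)
        w = np.where(mem, scores[None, :], 0.0)
        cdf_hit = np.cumsum(w, axis=1)
        cdf_hit /= cdf_hit[:, -1][:, None]
        cdf_miss = np.cumsum(~mem, axis=1) / n_miss
        md_perm = np.abs(cdf_hit - cdf_miss)[:, idx].max(axis=1)
        count += int((md_perm >= md_obs - 1e-12).sum())
        done += b
    p = (count + 1) / (n_perm + 1)
    return EnrichmentResult(pathway_id=rl.pathway_id, md=md_obs, p=p)


def _md_from_member_scores(
    member_scores: np.ndarray, outside_sorted_asc: np.ndarray
) -> np.ndarray:
    """MD for batches of member-score vectors against a fixed outside list.

    ``member_scores`` has shape (..., k). Between member jumps the hit CDF
    is constant and the miss CDF monotone, so the deviation is extremal
    just before a member block starts or right where it ends; evaluating
    those 2k candidate points reproduces the full ranked-list walk.
    """
    M = outside_sorted_asc.size
    s = np.sort(member_scores, axis=-1)[..., ::-1]
    cumw = np.cumsum(s, axis=-1)
    total = cumw[..., -1:]
    h_after = cumw / total
    h_before = np.concatenate([np.zeros_like(total), cumw[..., :-1]], axis=-1) / total
    n_ge = M - np.searchsorted(outside_sorted_asc, s, side="left")
    n_gt = M - np.searchsorted(outside_sorted_asc, s, side="right")
    dev_a = np.abs(h_after - n_ge / M)
    dev_b = np.abs(h_before - n_gt / M)
    return np.maximum(dev_a, dev_b).max(axis=-1)


def profile_shuffle_pvalue(
    rl: RankedList,
    mut: np.ndarray,
    dmat: np.ndarray,
    member_mf: np.ndarray,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
) -> EnrichmentResult:
    """Mutation-status-shuffle permutation p-value for a pathway's MD.

    Each permutation independently shuffles every member gene's
    non-synonymous mutation profile across samples (preserving its mutated
    sample count), recomputes the pairwise interaction statistics and
    member scores, and re-evaluates the MD against the pathway's fixed
    imputed outside list. The Mutation Factor is invariant under a profile
    shuffle (it averages over all samples), so only the Interaction Factor
    is recomputed. This is the calibrated null: it preserves the
    correlation structure that shared pairwise terms induce among member
    scores.

    Parameters
    ----------
    rl : RankedList
        The observed ranked list (members + imputed outside genes).
    mut : bool (k, m)
        Observed member mutation indicators, rows ordered like the sorted
        member genes of ``rl``.
    dmat : (k, k)
        Shortest-distance matrix over the same ordering.
    member_mf : (k,)
        Mutation Factors of the member genes, same ordering.

    Notes
    -----
    With few mutated samples per gene the permuted MD is genuinely
    discrete, and a plain >=-count p-value is severely conservative (half
    the permutations can tie the observed value exactly). The tie mass is
    therefore split uniformly at random using the run's seeded generator:
    ``p = (#{>} + 1 + U * #{=}) / (n_perm + 1)`` — the classical
    randomized construction that is exactly valid and calibrated under
    exchangeability, while the +1 keeps p >= 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    md_obs = wks_statistic(rl)
    k, m = mut.shape
    outside_sorted = np.sort(
        np.array([e.score for e, is_m in zip(rl.entries, rl.membership) if not is_m])
    )
    exp_mf = np.exp(member_mf)

    n_greater = 0
    n_equal = 0
    chunk = max(1, int(5e6) // max(k * m, 1))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        shuffled = np.empty((b, k, m), dtype=bool)
        for i in range(k):
            noise = rng.random((b, m))
            order = np.argsort(noise, axis=1)
            row = mut[i]
            shuffled[:, i, :] = np.take_along_axis(
                np.broadcast_to(row, (b, m)), order, axis=1
            )
        values, _ = interaction_factors_from_profiles(shuffled, dmat, alpha)
        member_scores = exp_mf[None, :] * values
        md_perm = _md_from_member_scores(member_scores, outside_sorted)
        n_greater += int((md_perm > md_obs + 1e-12).sum())
        n_equal += int((np.abs(md_perm - md_obs) <= 1e-12).sum())
        done += b
    u = rng.random()
    p = (n_greater + 1 + u * n_equal) / (n_perm + 1)
    return EnrichmentResult(pathway_id=rl.pathway_id, md=md_obs, p=p)


def fdr_correct(
    results: Sequence[EnrichmentResult], m_total: int
) -> List[EnrichmentResult]:
    """Rank-based FDR: fdr_k = p_k * m_total / k, made monotone and capped at 1.

    Results are sorted by ascending p (ties by pathway_id); the raw
    Benjamini–Hochberg quantity is then swept with a cumulative minimum
    from the bottom so the reported fdr is non-decreasing in rank.
    ``m_total`` is the total number of pathways in the study, which may
    exceed the number actually tested.
    """
    if m_total < len(results):
        raise ValueError("m_total must be >= number of results")
    ordered = sorted(results, key=lambda r: (r.p, r.pathway_id))
    raw = np.array([r.p * m_total / (k + 1) for k, r in enumerate(ordered)])
    adj = np.minimum.accumulate(raw[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    return [
        replace(r, fdr=float(adj[k]), rank=k + 1) for k, r in enumerate(ordered)
    ]


def select_top_pathways(results: Sequence[EnrichmentResult], k: int) -> List[str]:
    """The k pathway ids with smallest p (ties: larger MD, then pathway_id)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(results, key=lambda r: (r.p, -r.md, r.pathway_id))
    return [r.pathway_id for r in ordered[:k]]


@dataclass
class EnrichmentOutcome:
    """Full step-1 output: tested pathways with p/FDR plus diagnostics."""

    results: List[EnrichmentResult]  # sorted by ascending p, FDR-annotated
    ranked_lists: Dict[str, RankedList]
    pass_rates: Dict[str, float]
    background_mean: float
    background_sd: float
    skipped: List[str]  # pathways not testable (fewer than 2 genes in matrix)


def enrichment_analysis(
    mat: MutationMatrix,
    pathways: Sequence[PathwayGraph],
    cfg: RunConfig,
    rng: np.random.Generator,
    m_total: Optional[int] = None,
    perm_scheme: str = "profile",
) -> EnrichmentOutcome:
    """Run the full per-pathway enrichment analysis over a cohort.

    Pathway gene sets are restricted to genes present in the matrix (the
    caller normally builds the matrix over the union of mutated and pathway
    genes, so nothing is lost); pathways left with fewer than two genes are
    skipped and reported.

    ``perm_scheme`` selects the permutation null: ``"profile"`` (default)
    shuffles member mutation profiles across samples and recomputes scores;
    ``"membership"`` shuffles membership flags over the fixed ranked list.
    """
    if perm_scheme not in ("profile", "membership"):
        raise ValueError(f"unknown permutation scheme {perm_scheme!r}")
    mf_all = mutation_factors(mat)
    mf_of = dict(zip(mat.genes, mf_all))
    universe = list(mat.genes)

    member_scores: Dict[str, List[GeneScore]] = {}
    pass_rates: Dict[str, float] = {}
    tested: List[PathwayGraph] = []
    skipped: List[str] = []
    for pw in pathways:
        present = pw.genes & set(universe)
        if len(present) < 2 or len(present) >= len(universe):
            skipped.append(pw.pathway_id)
            continue
        if present != pw.genes:
            pw = PathwayGraph.make(
                pw.pathway_id,
                pw.name,
                present,
                [e for e in pw.edges if e[0] in present and e[1] in present],
            )
        ifs = pathway_interaction_factors(pw, mat, cfg.alpha)
        scores = [
            GeneScore(
                gene=g,
                mf=mf_of[g],
                if_value=ifs[g].value,
                score=ranking_score(mf_of[g], ifs[g].value),
                imputed=False,
            )
            for g in sorted(present)
        ]
        member_scores[pw.pathway_id] = scores
        pass_rates[pw.pathway_id] = (
            sum(1 for g in sorted(present) if ifs[g].n_passing > 0) / len(present)
        )
        tested.append(pw)
    if skipped:
        log.info("skipped %d untestable pathways: %s", len(skipped), ", ".join(skipped))

    all_real = np.array([s.score for ss in member_scores.values() for s in ss])
    if all_real.size == 0:
        return EnrichmentOutcome([], {}, {}, float("nan"), float("nan"), skipped)
    bg_mean = float(all_real.mean())
    bg_sd = float(all_real.std(ddof=0))

    results: List[EnrichmentResult] = []
    ranked_lists: Dict[str, RankedList] = {}
    for pw in tested:
        scores = member_scores[pw.pathway_id]
        members = {s.gene for s in scores}
        outside = [(g, mf_of[g]) for g in universe if g not in members]
        imputed = impute_outside_scores(
            outside, bg_mean, bg_sd, pass_rates[pw.pathway_id], cfg.alpha, rng
        )
        rl = RankedList.build(pw.pathway_id, scores, imputed)
        ranked_lists[pw.pathway_id] = rl
        if perm_scheme == "profile":
            ordered = sorted(members)
            rows = np.array([mat.gene_row(g) for g in ordered])
            mut = mat.nsy_counts[rows] > 0
            dmat = distance_matrix(pw, ordered)
            member_mf = np.array([mf_of[g] for g in ordered])
            results.append(
                profile_shuffle_pvalue(
                    rl, mut, dmat, member_mf, cfg.alpha,
                    cfg.n_perm_enrichment, rng,
                )
            )
        else:
            results.append(enrichment_pvalue(rl, cfg.n_perm_enrichment, rng))

    m_tot = m_total if m_total is not None else len(results)
    results = fdr_correct(results, m_tot)
    return EnrichmentOutcome(results, ranked_lists, pass_rates, bg_mean, bg_sd, skipped)
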