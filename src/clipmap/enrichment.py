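"""Gene-ontology and protein-complex enrichment.

GO enrichment is a per-term chi-squared test (df=1, no continuity
correction) on the 2x2 in-list x has-term table with Bonferroni
correction over the tested terms; term assignments are taken as given
(no GO-graph propagation).

Complex enrichment is an empirical permutation test: the observed complex
score is the mean member score and the null is the distribution of mean
scores of random same-size protein sets, with add-one smoothing so
p-values stay in (0, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import GOAssociation

logger = logging.getLogger(__name__)

#: ranked-curve significance cutoff for complex enrichment
DEFAULT_COMPLEX_P_CUTOFF = 5.012e-2


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k_list: int
    n_list: int
    k_bg: int
    n_bg: int
    chi2_stat: float
    p_raw: float
    p_bonferroni: float


def go_enrichment(
    gene_list: set[str],
    background: set[str],
    associations: list[GOAssociation],
    min_term_size: int = 5,
) -> list[EnrichmentResult]:
    """Chi-squared GO term enrichment of ``gene_list`` against
    ``background`` (gene_list must be a subset of the background).

    Terms annotated to fewer than ``min_term_size`` background genes are
    not tested; terms with a degenerate 2x2 margin (e.g. covering the
    whole background) are skipped and logged.  Results sorted by raw p.
    """
    if not gene_list or not background:
        raise ValueError("gene list and background must be non-empty")
    if not gene_list <= background:
        raise ValueError("gene_list must be a subset of background")
    genes_by_term: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for a in associations:
        if a.gene_id in background:
            genes_by_term.setdefault(a.term_id, set()).add(a.gene_id)
            names.setdefault(a.term_id, a.term_name or a.term_id)

    testable = {t: g for t, g in genes_by_term.items() if len(g) >= min_term_size}
    results: list[EnrichmentResult] = []
    n_list, n_bg = len(gene_list), len(background)
    skipped = 0
    for term, term_genes in sorted(testable.items()):
        k_list = len(gene_list & term_genes)
        k_bg = len(term_genes)
        table = np.array(
            [
                [k_list, n_list - k_list],
                [k_bg - k_list, (n_bg - n_list) - (k_bg - k_list)],
            ]
        )
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            skipped += 1
            continue
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        results.append(
            EnrichmentResult(
                term_id=term,
                term_name=names[term],
                k_list=k_list,
                n_list=n_list,
                k_bg=k_bg,
                n_bg=n_bg,
                chi2_stat=float(chi2),
                p_raw=float(p),
                p_bonferroni=1.0,  # filled below once n_tested is known
            )
        )
    if skipped:
        logger.info("go_enrichment: skipped %d terms with degenerate margins", skipped)
    n_tested = len(results)
    for r in results:
        r.p_bonferroni = min(1.0, r.p_raw * n_tested)
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id, "term_name": r.term_name,
                "k_list": r.k_list, "n_list": r.n_list,
                "k_bg": r.k_bg, "n_bg": r.n_bg,
                "chi2_stat": r.chi2_stat, "p_raw": r.p_raw,
                "p_bonferroni": r.p_bonferroni,
            }
            for r in results
        ],
        columns=["term_id", "term_name", "k_list", "n_list", "k_bg", "n_bg",
                 "chi2_stat", "p_raw", "p_bonferroni"],
    )


@dataclass
class ComplexResult:
    complex_id: str
    members: list[str]
    n_members_in_data: int
    score: float
    p_perm: float
    rank: int = 0
    passes_cutoff: bool = False


def complex_enrichment(
    protein_scores: dict[str, float],
    complexes: dict[str, list[str]],
    n_perm: int = 1000,
    min_members: int = 3,
    seed: int = 0,
    p_cutoff: float = DEFAULT_COMPLEX_P_CUTOFF,
) -> list[ComplexResult]:
    """Permutation enrichment of protein complexes in a scored protein
    list.

    Observed score = mean member score; members absent from the data
    contribute the background minimum (logged).  The null draws ``n_perm``
    random member sets of the same size from all scored proteins;
    p = (1 + #{null >= observed}) / (1 + n_perm).  Results are ranked by
    score (ranked-curve order) and flagged against ``p_cutoff``.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; empirical p-values will be coarse")
    if not protein_scores:
        raise ValueError("empty protein score table")
    proteins = sorted(protein_scores)
    values = np.array([protein_scores[p] for p in proteins], dtype=float)
    floor = float(values.min())
    rng = np.random.default_rng(seed)

    sized: list[tuple[str, list[str], int, float]] = []
    n_missing_total = 0
    for cid, members in sorted(complexes.items()):
        present = [m for m in members if m in protein_scores]
        if len(members) < min_members:
            continue
        n_missing = len(members) - len(present)
        n_missing_total += n_missing
        obs = (sum(protein_scores[m] for m in present) + floor * n_missing) / len(members)
        sized.append((cid, list(members), len(present), obs))
    if n_missing_total:
        logger.info(
            "complex_enrichment: %d absent members contributed the background minimum",
            n_missing_total,
        )
    if not sized:
        return []

    results = []
    for cid, members, n_present, obs in sized:
        m = len(members)
        # random same-size sets without replacement, vectorised
        keys = rng.random((n_perm, len(values)))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        null = values[idx].mean(axis=1)
        p = (1 + int((null >= obs - 1e-12).sum())) / (1 + n_perm)
        results.append(
            ComplexResult(
                complex_id=cid,
                members=members,
                n_members_in_data=n_present,
                score=obs,
                p_perm=p,
            )
        )
    results.sort(key=lambda r: (-r.score, r.complex_id))
    for i, r in enumerate(results, start=1):
        r.rank = i
        r.passes_cutoff = r.p_perm < p_cutoff
    return results


def ranked_curve_table(results: list[ComplexResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": r.rank, "complex_id": r.complex_id,
                "n_members": len(r.members), "n_members_in_data": r.n_members_in_data,
                "score": r.score, "p_perm": r.p_perm,
                "passes_cutoff": r.passes_cutoff,
            }
            for r in results
        ],
        columns=["rank", "complex_id", "n_members", "n_members_in_data",
                 "score", "p_perm", "passes_cutoff"],
    )


def hit_fraction_in_networks(
    hits: set[str],
    complex_results: list[ComplexResult],
    cutoff_p: float = DEFAULT_COMPLEX_P_CUTOFF,
) -> tuple[int, int, float]:
    """Fraction of hit proteins participating in >= 1 enriched complex.

    Returns (k, n, percentage-to-1-decimal); with no passing complexes the
    percentage is 0.0.
    """
    if not hits:
        raise ValueError("empty hit list")
    in_networks = set()
    for r in complex_results:
        if r.p_perm < cutoff_p:
            in_networks.update(r.members)
    k = len(hits & in_networks)
    n = len(hits)
    return k, n, round(100.0 * k / n, 1)
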