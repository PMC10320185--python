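"""Functional analysis of CRISPR-KO selection screens with miRNA elements.

Workflow: take the top positively or negatively selected miRNAs from a
MAGeCK-style ranking, test term enrichment of the union of their targets
(classic hypergeometric), then ask whether those targets show a coherent
trend in the *opposite* gene ranking — a knocked-out miRNA de-represses its
targets, so targets of negatively selected miRNAs should drift toward the
top of the positive gene ranking (and vice versa). The trend test is CAMERA
pre-ranked by default, or a one-sided Fisher exact test on the top-k of the
opposite ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .datamodel import InteractionSet, MirnaQuery, ScreenTable, TermCollection
from .enrichment import EnrichmentRow, build_target_set, enrich
from .errors import DomainError
from .stats import UrnSpec, camera_pr, hypergeom_upper_tail


@dataclass
class ScreenAnalysisRow:
    term_id: str
    direction: str  # direction the miRNAs were selected from
    enrichment: EnrichmentRow
    opposite_test: str  # camera | fisher_topk
    opposite_statistic: float
    opposite_p: float
    k_top: Optional[int] = None


def select_top_mirnas(
    screen: ScreenTable, direction: str, top_n: int
) -> MirnaQuery:
    """The top_n miRNA rows of the chosen selection direction, by rank."""
    if direction not in ("positive", "negative"):
        raise DomainError(f"direction must be positive or negative, got {direction}")
    col = "pos_rank" if direction == "positive" else "neg_rank"
    mirnas = screen.mirna_rows().sort_values(col)
    if len(mirnas) < top_n:
        raise DomainError(
            f"requested top {top_n} miRNAs but the screen has only {len(mirnas)}"
        )
    return MirnaQuery(list(mirnas["element_id"].head(top_n)))


def screen_enrich(
    selected: MirnaQuery,
    interactions: InteractionSet,
    terms: TermCollection,
    min_overlap: int = 1,
) -> list[EnrichmentRow]:
    """Union of the selected miRNAs' targets, classic hypergeometric enrichment."""
    tset = build_target_set(selected, interactions, mode="union")
    return enrich(tset, terms, method="classic", min_overlap=min_overlap)


def opposite_rank_test(
    row: EnrichmentRow,
    screen: ScreenTable,
    selected_direction: str,
    method: str = "camera",
    k_top: Optional[int] = None,
    rho: float = 0.01,
) -> ScreenAnalysisRow:
    """Test the term's targeted genes for a trend in the opposite ranking.

    Only gene-type screen rows form the ranking (targets are genes). For
    positively selected miRNAs the negative gene ranking is assessed, and
    vice versa; in both cases "favorable" means the rank's top, i.e. small
    scores, so the one-sided alternative is "less".
    """
    if selected_direction not in ("positive", "negative"):
        raise DomainError(f"unknown direction: {selected_direction}")
    if method not in ("camera", "fisher_topk"):
        raise DomainError(f"unknown opposite test: {method}")
    opp = "negative" if selected_direction == "positive" else "positive"
    score_col = "neg_score" if opp == "negative" else "pos_score"
    rank_col = "neg_rank" if opp == "negative" else "pos_rank"
    genes = screen.gene_rows()
    member = set(row.targeted_gene_ids) & set(genes["element_id"])
    if not member:
        raise DomainError(
            f"term {row.term_id}: no targeted gene appears in the screen's gene rows"
        )
    if method == "camera":
        stat = dict(zip(genes["element_id"], genes[score_col].astype(float)))
        res = camera_pr(stat, member, rho=rho, alternative="less")
        return ScreenAnalysisRow(
            term_id=row.term_id,
            direction=selected_direction,
            enrichment=row,
            opposite_test="camera",
            opposite_statistic=res.statistic,
            opposite_p=res.p_value,
        )
    if k_top is None:
        raise DomainError("fisher_topk requires k_top")
    n_genes = len(genes)
    if not (1 <= k_top <= n_genes):
        raise DomainError(f"k_top={k_top} outside [1, {n_genes}]")
    # ranks within gene rows only: re-rank the direction's rank column
    order = genes.sort_values(rank_col)["element_id"]
    top = set(order.head(k_top))
    k = len(top & member)
    res = hypergeom_upper_tail(UrnSpec(n_genes, len(member), k_top, k))
    return ScreenAnalysisRow(
        term_id=row.term_id,
        direction=selected_direction,
        enrichment=row,
        opposite_test="fisher_topk",
        opposite_statistic=float(k),
        opposite_p=res.p_value,
        k_top=k_top,
    )


def screen_analysis(
    screen: ScreenTable,
    interactions: InteractionSet,
    terms: TermCollection,
    direction: str = "negative",
    top_n: int = 3,
    opposite_test: str = "camera",
    k_top: Optional[int] = None,
    rho: float = 0.01,
    min_overlap: int = 1,
    alpha: float = 0.05,
) -> list[ScreenAnalysisRow]:
    """End-to-end screen workflow: select, enrich, opposite-rank test.

    The opposite-rank test is run for every enriched term with adjusted
    p <= alpha (or, if none clears it, for the single most enriched term so
    the report is never empty on weak screens).
    """
    selected = select_top_mirnas(screen, direction, top_n)
    enriched = screen_enrich(selected, interactions, terms, min_overlap=min_overlap)
    if not enriched:
        return []
    chosen = [r for r in enriched if r.p_adjusted <= alpha] or [enriched[0]]
    return [
        opposite_rank_test(r, screen, direction, method=opposite_test, k_top=k_top, rho=rho)
        for r in chosen
    ]
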