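"""Term-centric miRNA discovery.

Given terms of interest, rank every miRNA in the interaction resource by how
over-represented its targets are inside those terms: per miRNA-term pair a
one-sided urn test (same urn as the miRNA-centric engine, transposed
reading), per miRNA the per-term p-values merged with Fisher's method, then
BH across miRNAs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .datamodel import InteractionSet, TermCollection
from .errors import DomainError, EmptyInputError
from .stats import (
    UrnSpec,
    bh_adjust,
    estimate_bias_odds,
    fisher_combine,
    hypergeom_upper_tail,
    wallenius_upper_tail,
)


@dataclass
class MirnaRankRow:
    mirna_id: str
    per_term_p: dict[str, float]
    combined_statistic: float
    combined_p: float
    p_adjusted: float
    targets_in_terms: int
    targets_in_universe: int


def term_centric_scan(
    term_ids: Sequence[str],
    terms: TermCollection,
    interactions: InteractionSet,
    method: str = "classic",
    bias: Optional[Mapping[str, float]] = None,
    min_targets: int = 5,
) -> list[MirnaRankRow]:
    """Rank miRNAs by target over-representation in the requested terms.

    Only miRNAs with >= min_targets targets inside the term universe are
    tested (tiny target sets yield uninformative p-values). Urn per pair:
    N = universe size, K = term size, n = miRNA targets in universe,
    k = overlap. Output sorted by (combined_p, mirna_id).
    """
    if method not in ("classic", "wallenius"):
        raise DomainError(f"unknown method: {method}")
    if method == "wallenius" and bias is None:
        raise DomainError("wallenius scan requires a bias covariate")
    if not term_ids:
        raise DomainError("at least one term_id is required")
    requested = [terms.get(t) for t in term_ids]  # KeyError names unknown ids
    if len(interactions) == 0:
        raise EmptyInputError("interaction set is empty")
    universe = terms.universe_set
    N = len(universe)

    rows: list[MirnaRankRow] = []
    for mirna in sorted(interactions.index):
        targets = interactions.targets(mirna) & universe
        n = len(targets)
        if n < min_targets:
            continue
        flags = {g: 1 for g in targets}
        per_term: dict[str, float] = {}
        total_in = 0
        for t in requested:
            k = len(t.genes & targets)
            total_in += k
            if method == "classic":
                p = hypergeom_upper_tail(UrnSpec(N, len(t.genes), n, k)).p_value
            else:
                w = estimate_bias_odds(t.genes, flags, bias, universe)
                p = wallenius_upper_tail(UrnSpec(N, len(t.genes), n, k, w)).p_value
            per_term[t.term_id] = p
        comb = fisher_combine(list(per_term.values()))
        rows.append(
            MirnaRankRow(
                mirna_id=mirna,
                per_term_p=per_term,
                combined_statistic=comb.statistic,
                combined_p=comb.p_value,
                p_adjusted=1.0,
                targets_in_terms=total_in,
                targets_in_universe=n,
            )
        )
    if not rows:
        warnings.warn(f"no miRNA has >= {min_targets} targets in the universe", stacklevel=2)
        return rows
    adj = bh_adjust([r.combined_p for r in rows])
    for r, a in zip(rows, adj):
        r.p_adjusted = max(a, r.combined_p)
    rows.sort(key=lambda r: (r.combined_p, r.mirna_id))
    return rows
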