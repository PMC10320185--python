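"""Seeded synthetic-fixture generation with plantable signal.

Emulates the statistical structure of the real inputs — an interaction
resource, a term collection, raw expression with context labels and a
MAGeCK-style screen — with one designated planted mechanism threading
through all of them: a planted term whose genes are targeted by the planted
miRNAs at ``planted_term_fold`` times the background density, those targeted
genes repressed by ``planted_context_shift`` log2 units in one designated
context, and a screen in which the planted miRNAs sit at the top of the
negative ranking while their targets drift to the top of the positive gene
ranking.

All randomness flows from ``FixtureSpec.seed`` through per-component child
streams, so adding a component never perturbs the others and identical
spec + seed reproduce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import Interaction, InteractionSet, ScreenTable, Term, TermCollection
from .io import write_gmt, write_interactions, write_screen

#: child-stream codes per fixture component (stable; append-only)
_STREAMS = {"terms": 1, "interactions": 2, "expression": 3, "screen": 4}


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic fixture."""

    seed: int = 0
    n_genes: int = 600
    n_mirnas: int = 20
    n_terms: int = 20
    term_size_range: tuple[int, int] = (20, 50)
    background_target_density: float = 0.05
    planted_term_fold: float = 4.0
    planted_mirna_count: int = 3
    n_contexts: int = 6
    samples_per_context: int = 100
    planted_context_shift: float = 1.0  # log2 units of expression repression
    screen_size: int = 600
    planted_screen_fraction: float = 0.8
    expression_mode: str = "single_cell"  # single_cell | tissue

    def __post_init__(self):
        if not (0.0 < self.background_target_density < 1.0):
            raise ValueError("background_target_density must be in (0, 1)")
        if not (0.0 < self.planted_screen_fraction <= 1.0):
            raise ValueError("planted_screen_fraction must be in (0, 1]")
        if self.planted_term_fold < 1.0:
            raise ValueError("planted_term_fold must be >= 1")
        if self.planted_mirna_count > self.n_mirnas:
            raise ValueError("planted_mirna_count exceeds n_mirnas")
        if self.screen_size > self.n_genes:
            raise ValueError("screen_size exceeds n_genes")


@dataclass
class FixtureData:
    """In-memory fixture: the objects every workflow consumes, plus truth."""

    interactions: InteractionSet
    terms: TermCollection
    raw_expression: pd.DataFrame  # genes x samples
    sample_contexts: dict[str, str]
    screen: ScreenTable
    manifest: dict


def _rng(spec: FixtureSpec, component: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[component], spec.seed % (2**31)])


def generate_fixture(spec: FixtureSpec) -> FixtureData:
    """Generate the full fixture in memory."""
    genes = [f"GENE{i:04d}" for i in range(spec.n_genes)]
    mirnas = [f"hsa-miR-{i + 1:03d}" for i in range(spec.n_mirnas)]
    planted_mirnas = mirnas[: spec.planted_mirna_count]

    # term collection; the first term carries the planted signal
    rng_t = _rng(spec, "terms")
    lo, hi = spec.term_size_range
    term_list = []
    for i in range(spec.n_terms):
        size = int(rng_t.integers(lo, hi + 1))
        members = rng_t.choice(spec.n_genes, size=size, replace=False)
        term_list.append(
            Term(f"TERM{i + 1:04d}", f"synthetic term {i + 1}",
                 frozenset(genes[j] for j in members))
        )
    terms = TermCollection(term_list)
    planted_term = term_list[0]

    # interaction edges: iid Bernoulli, boosted inside the planted block
    rng_i = _rng(spec, "interactions")
    dens = spec.background_target_density
    boosted = spec.planted_term_fold * dens
    if boosted > 0.95:
        warnings.warn("planted density capped at 0.95", stacklevel=2)
        boosted = 0.95
    planted_gene_idx = {genes.index(g) for g in planted_term.genes}
    prob = np.full((spec.n_mirnas, spec.n_genes), dens)
    for mi in range(spec.planted_mirna_count):
        for gj in planted_gene_idx:
            prob[mi, gj] = boosted
    draw = rng_i.random((spec.n_mirnas, spec.n_genes)) < prob
    edges = [
        Interaction(mirnas[mi], genes[gj])
        for mi in range(spec.n_mirnas)
        for gj in range(spec.n_genes)
        if draw[mi, gj]
    ]
    interactions = InteractionSet(edges)

    planted_targeted = sorted(
        g
        for g in planted_term.genes
        if any(g in interactions.targets(m) for m in planted_mirnas)
    )

    # raw expression with one repressed context for the planted targets
    rng_e = _rng(spec, "expression")
    contexts = [f"ctx{c}" for c in range(spec.n_contexts)]
    planted_context = contexts[0]
    samples, sample_contexts = [], {}
    for c in contexts:
        for s in range(spec.samples_per_context):
            sid = f"{c}_s{s:03d}"
            samples.append(sid)
            sample_contexts[sid] = c
    n_samp = len(samples)
    shift_factor = 2.0 ** (-spec.planted_context_shift)
    planted_set = set(planted_targeted)
    if spec.expression_mode == "single_cell":
        base_mean = rng_e.lognormal(mean=0.7, sigma=0.5, size=spec.n_genes)
    else:
        base_mean = rng_e.lognormal(mean=np.log(15.0), sigma=1.0, size=spec.n_genes)
    mean_matrix = np.tile(base_mean[:, None], (1, n_samp))
    ctx0_cols = np.array([sample_contexts[s] == planted_context for s in samples])
    for gi, g in enumerate(genes):
        if g in planted_set:
            mean_matrix[gi, ctx0_cols] *= shift_factor
    if spec.expression_mode == "single_cell":
        r = 2.0  # NB dispersion: variance = mu + mu^2 / r
        p = r / (r + mean_matrix)
        values = rng_e.negative_binomial(r, p).astype(float)
    else:
        values = mean_matrix * rng_e.lognormal(mean=0.0, sigma=0.8, size=mean_matrix.shape)
    raw = pd.DataFrame(values, index=genes, columns=samples)

    # screen: latent N(0,1) selection scores, planted elements at the extremes
    rng_s = _rng(spec, "screen")
    screen_genes = genes[: spec.screen_size]
    elements = screen_genes + mirnas
    n_el = len(elements)
    neg = rng_s.normal(size=n_el)
    pos = rng_s.normal(size=n_el)
    planted_target_union = sorted(
        set().union(*(interactions.targets(m) for m in planted_mirnas))
    )
    shifted_genes = [
        g
        for g in planted_target_union
        if g in set(screen_genes) and rng_s.random() < spec.planted_screen_fraction
    ]
    el_index = {e: i for i, e in enumerate(elements)}
    # -3 sigma concentrates the planted elements in the ranking's top decile
    for m in planted_mirnas:
        neg[el_index[m]] -= 3.0
    for g in shifted_genes:
        pos[el_index[g]] -= 3.0
    from scipy.stats import norm

    def ranks_of(score: np.ndarray) -> np.ndarray:
        order = np.lexsort((np.array(elements), score))
        r = np.empty(n_el, dtype=int)
        r[order] = np.arange(1, n_el + 1)
        return r

    df = pd.DataFrame(
        {
            "element_id": elements,
            "element_type": ["gene"] * len(screen_genes) + ["mirna"] * len(mirnas),
            "neg_score": neg,
            "neg_p": norm.cdf(neg),
            "neg_rank": ranks_of(neg),
            "pos_score": pos,
            "pos_p": norm.cdf(pos),
            "pos_rank": ranks_of(pos),
        }
    )
    screen = ScreenTable(df, dialect="rra")

    manifest = {
        "seed": spec.seed,
        "spec": dataclasses.asdict(spec),
        "planted": {
            "term_id": planted_term.term_id,
            "mirnas": planted_mirnas,
            "targeted_genes": planted_targeted,
            "context_id": planted_context,
            "screen_shifted_genes": shifted_genes,
        },
    }
    return FixtureData(interactions, terms, raw, sample_contexts, screen, manifest)


def simulate_fixture(spec: FixtureSpec, outdir) -> dict:
    """Generate a fixture and write every file; returns the manifest.

    Files: interactions.tsv, terms.gmt, expression.tsv, context_map.tsv,
    screen.tsv, manifest.json. Identical spec + seed give byte-identical
    output.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = generate_fixture(spec)
    write_interactions(data.interactions, outdir / "interactions.tsv")
    write_gmt(data.terms, outdir / "terms.gmt")
    data.raw_expression.to_csv(outdir / "expression.tsv", sep="\t", index_label="gene_id")
    pd.DataFrame(
        {
            "sample_id": list(data.sample_contexts),
            "context_id": [data.sample_contexts[s] for s in data.sample_contexts],
        }
    ).to_csv(outdir / "context_map.tsv", sep="\t", index=False)
    write_screen(data.screen, outdir / "screen.tsv")
    manifest = dict(data.manifest)
    manifest["files"] = {
        "interactions": "interactions.tsv",
        "terms": "terms.gmt",
        "expression": "expression.tsv",
        "context_map": "context_map.tsv",
        "screen": "screen.tsv",
    }
    # tuples -> lists for stable JSON
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=list)
        fh.write("\n")
    return manifest
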