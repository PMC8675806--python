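"""Hypergeometric (Fisher exact) enrichment of node sets.

Whether a dominating set is over-represented in an annotation class
(essential genes, kinases, transcription factors, drug targets, ...) is
tested one-sided against the hypergeometric null: draw ``set_size``
nodes without replacement from the ``universe_n`` network nodes, of
which ``annotation_size`` carry the annotation, and ask for the upper
tail P(X >= overlap). The universe is the network node count, and
annotation members absent from the network are excluded from the
margins, keeping the table consistent. No multiple-testing correction
is applied across annotation sets; consumers testing many sets should
correct downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .classification import classify
from .graph_io import GeneSet, Network
from .models import MdsetCollection

__all__ = ["EnrichmentResult", "fisher_enrichment", "enrich_collection"]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class EnrichmentResult:
    """One upper-tail hypergeometric test."""

    universe_n: int
    set_size: int
    annotation_size: int
    overlap: int
    p_value: float
    alpha: float = DEFAULT_ALPHA

    @property
    def enriched(self) -> bool:
        return self.p_value < self.alpha


def fisher_enrichment(
    universe_n: int,
    set_size: int,
    annotation_size: int,
    overlap: int,
    alpha: float = DEFAULT_ALPHA,
) -> EnrichmentResult:
    """Upper-tail hypergeometric p-value P(X >= overlap).

    X ~ Hypergeom(universe_n, annotation_size, set_size). Computed via
    scipy's log-gamma-based survival function; ``p = 1`` when the
    overlap is zero (the upper tail is the whole mass) and ``enriched``
    is the comparison against ``alpha`` (default 0.05).
    """
    if not (0 <= annotation_size <= universe_n):
        raise ValueError("annotation_size must lie in [0, universe_n]")
    if not (0 <= set_size <= universe_n):
        raise ValueError("set_size must lie in [0, universe_n]")
    if not (0 <= overlap <= min(set_size, annotation_size)):
        raise ValueError("overlap must lie in [0, min(set_size, annotation_size)]")
    if overlap < max(0, set_size + annotation_size - universe_n):
        raise ValueError("overlap below the hypergeometric support")
    p = float(stats.hypergeom.sf(overlap - 1, universe_n, annotation_size, set_size))
    p = min(max(p, 0.0), 1.0)
    return EnrichmentResult(
        universe_n=universe_n,
        set_size=set_size,
        annotation_size=annotation_size,
        overlap=overlap,
        p_value=p,
        alpha=alpha,
    )


def enrich_collection(
    collection: MdsetCollection,
    genesets: list[GeneSet],
    net: Network,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Enrichment table over every generated MDSet and the critical strata.

    One row per (node set, gene set), covering each MDSet in order plus
    the k-critical and (k-1)-critical sets derived from the collection.
    Gene sets are intersected with the network before the margins are
    formed.
    """
    cls = classify(collection, net)
    labeled: list[tuple[str, frozenset[str]]] = [
        (f"MDSet{i + 1}", m.members) for i, m in enumerate(collection.mdsets)
    ]
    labeled.append(("k-critical", cls.k_critical))
    labeled.append(("km1-critical", cls.km1_critical))
    rows = []
    for gs in genesets:
        annot = gs.restricted_to(net)
        for label, members in labeled:
            res = fisher_enrichment(
                universe_n=net.n,
                set_size=len(members),
                annotation_size=len(annot),
                overlap=len(members & annot),
                alpha=alpha,
            )
            rows.append(
                {
                    "set_label": label,
                    "gene_set": gs.name,
                    "set_size": res.set_size,
                    "annotation_size": res.annotation_size,
                    "overlap": res.overlap,
                    "p_value": res.p_value,
                    "enriched": res.enriched,
                }
            )
    return pd.DataFrame(rows)
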