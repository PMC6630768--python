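"""Annotation enrichment between dark and non-dark proteins.

Each distinct (field, subcategory, text) annotation yields a 2x2 protein
count table (presence/absence per protein), tested with a two-sided Fisher
exact test; p-values are Benjamini–Hochberg adjusted per annotation family
(DE and FT corrected separately) and results with adjusted p <= alpha
(default 1%) are kept, sorted by adjusted p.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .types import (
    AnnotationEntry,
    AnnotationField,
    ContingencyTable,
    Direction,
    EnrichmentConfig,
    EnrichmentResult,
    ProteinRecord,
)

__all__ = [
    "build_tables",
    "fisher_exact",
    "bh_adjust",
    "enrich",
    "enrichment_table",
]


def build_tables(
    universe: Sequence[ProteinRecord], dark_labels: Mapping[str, bool]
) -> dict[AnnotationEntry, ContingencyTable]:
    """One 2x2 table per distinct annotation present in the universe.

    A protein counts at most once per distinct annotation (presence/absence,
    not instance counting). Annotations held by nobody are absent by
    construction.
    """
    missing = [p.accession for p in universe if p.accession not in dark_labels]
    if missing:
        raise ValueError(f"dark labels missing for accessions {missing[:5]}")
    n_dark = sum(bool(dark_labels[p.accession]) for p in universe)
    n_nondark = len(universe) - n_dark
    counts: dict[AnnotationEntry, list[int]] = {}
    for prot in universe:
        is_dark = bool(dark_labels[prot.accession])
        for ann in set(prot.annotations):
            c = counts.setdefault(ann, [0, 0])
            c[0 if is_dark else 1] += 1
    return {
        ann: ContingencyTable(
            dark_with=dw,
            dark_without=n_dark - dw,
            nondark_with=nw,
            nondark_without=n_nondark - nw,
        )
        for ann, (dw, nw) in counts.items()
    }


def fisher_exact(table: ContingencyTable) -> tuple[float, float]:
    """Two-sided Fisher exact p and the sample odds ratio.

    p sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed that of the observed table.
    The summation runs in exact integer arithmetic (conditional weights
    C(r1, a') * C(r2, c1 - a') over the support), so probability ties are
    decided exactly; only the final ratio is a float.
    Odds ratio = (dark_with * nondark_without) / (dark_without * nondark_with),
    +inf when only the denominator is 0, and 1 when both are 0.
    """
    a, b = table.dark_with, table.dark_without
    c, d = table.nondark_with, table.nondark_without
    if table.total == 0:
        raise ValueError("Fisher test on an all-zero table")
    r1, r2, c1 = a + b, c + d, a + c
    w_obs = math.comb(r1, a) * math.comb(r2, c)
    numer = 0
    for a2 in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = math.comb(r1, a2) * math.comb(r2, c1 - a2)
        if w <= w_obs:
            numer += w
    p = numer / math.comb(r1 + r2, c1)
    num, den = a * d, b * c
    if den > 0:
        odds = num / den
    elif num > 0:
        odds = math.inf
    else:
        odds = 1.0
    return p, odds


def bh_adjust(pvals: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjusted p-values and ranks, in input order.

    adjusted_(i) = min(1, min_{j >= i} p_(j) * n / j) over the ascending
    order statistics; ties share the rank of their first position after a
    stable sort.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=int)
    if np.any((p < 0.0) | (p > 1.0)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = multipletests(p, method="fdr_bh")[1]
    order = np.argsort(p, kind="stable")
    ranks = np.empty(p.size, dtype=int)
    ranks[order] = np.arange(1, p.size + 1)
    # ties share the first (smallest) rank of their value
    sorted_p = p[order]
    first_rank = np.arange(1, p.size + 1)
    for i in range(1, p.size):
        if sorted_p[i] == sorted_p[i - 1]:
            first_rank[i] = first_rank[i - 1]
    ranks[order] = first_rank
    return adjusted, ranks


def enrich(
    universe: Sequence[ProteinRecord],
    dark_labels: Mapping[str, bool],
    config: EnrichmentConfig | None = None,
) -> list[EnrichmentResult]:
    """Full enrichment analysis: tables -> Fisher -> BH -> filter at alpha.

    Excluded subcategories (default: SIMILARITY, which only identifies
    groups of near-identical proteins) are dropped before testing. DE and FT
    families are corrected separately; output is sorted by adjusted p
    ascending (ties by raw p, then annotation key, for determinism).
    """
    if config is None:
        config = EnrichmentConfig()
    if not universe:
        raise ValueError("enrichment on an empty universe")
    excluded = {s.upper() for s in config.excluded_subcategories}
    tables = {
        ann: tab
        for ann, tab in build_tables(universe, dark_labels).items()
        if ann.subcategory.upper() not in excluded
    }
    results: list[EnrichmentResult] = []
    for fam in (AnnotationField.DE, AnnotationField.FT):
        fam_anns = [ann for ann in tables if ann.field is fam]
        if not fam_anns:
            continue
        fam_anns.sort(key=lambda a: (a.subcategory, a.text))
        stats = [fisher_exact(tables[ann]) for ann in fam_anns]
        pvals = [s[0] for s in stats]
        adjusted, ranks = bh_adjust(pvals)
        for ann, (p, odds), p_adj, k in zip(fam_anns, stats, adjusted, ranks):
            if p_adj > config.alpha:
                continue
            results.append(
                EnrichmentResult(
                    annotation=ann,
                    table=tables[ann],
                    odds_ratio=odds,
                    p=p,
                    p_adjusted=float(p_adj),
                    direction=Direction.over if odds > 1.0 else Direction.under,
                    rank_k=int(k),
                )
            )
    results.sort(
        key=lambda r: (
            r.p_adjusted,
            r.p,
            r.annotation.field.value,
            r.annotation.subcategory,
            r.annotation.text,
        )
    )
    return results


def enrichment_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Tabular output mirroring the published enrichment-table layout."""
    rows = [
        {
            "non_dark": r.table.nondark_with,
            "dark": r.table.dark_with,
            "ratio": r.odds_ratio,
            "total": r.table.n_with,
            "fisher_p": r.p,
            "adjusted_p": r.p_adjusted,
            "field": r.annotation.field.value,
            "subcategory": r.annotation.subcategory,
            "annotation": r.annotation.text,
            "direction": r.direction.value,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "non_dark",
            "dark",
            "ratio",
            "total",
            "fisher_p",
            "adjusted_p",
            "field",
            "subcategory",
            "annotation",
            "direction",
        ],
    )
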