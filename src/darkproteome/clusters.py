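"""Chromosomal runs of consecutive dark genes, with permutation p-values.

Per chromosome, proteins are ordered by the central nucleotide of their
gene (duplicated proteins keep only their first occurrence; position ties
break lexicographically by accession). The statistic is the longest run of
consecutive dark entries in that order; its p-value is the fraction of
random re-orderings of the label vector (default 1,000) attaining a run at
least as long.
"""

from __future__ import annotations

import zlib
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    ChromosomeOrder,
    ClusterMember,
    ClusterResult,
    LinkTable,
    ProteinRecord,
)

__all__ = [
    "build_order",
    "longest_run",
    "longest_true_run",
    "permutation_pvalue",
    "composition_bias",
    "find_dark_clusters",
    "clusters_table",
    "members_table",
]


def build_order(
    loci: pd.DataFrame, dark_labels: Mapping[str, bool]
) -> dict[str, ChromosomeOrder]:
    """Per-chromosome gene orders from a locus table
    (accession, chromosome, central_position)."""
    orders: dict[str, ChromosomeOrder] = {}
    for chrom, group in loci.groupby("chromosome", sort=True):
        g = group.sort_values(
            ["central_position", "accession"], kind="stable"
        ).drop_duplicates("accession", keep="first")
        entries = [
            (row.accession, int(row.central_position), bool(dark_labels[row.accession]))
            for row in g.itertuples(index=False)
        ]
        orders[str(chrom)] = ChromosomeOrder(chromosome=str(chrom), entries=entries)
    return orders


def longest_true_run(labels: np.ndarray) -> tuple[int, int]:
    """(length, start index) of the longest run of True; leftmost on ties."""
    best_len = best_start = 0
    run = start = 0
    for i, v in enumerate(labels):
        if v:
            if run == 0:
                start = i
            run += 1
            if run > best_len:
                best_len, best_start = run, start
        else:
            run = 0
    return best_len, best_start


def longest_run(order: ChromosomeOrder) -> tuple[int, list[str]]:
    """Longest run of consecutive dark entries and its member accessions."""
    labels = order.labels
    length, start = longest_true_run(labels)
    members = [order.entries[i][0] for i in range(start, start + length)]
    return length, members


def permutation_pvalue(
    order: ChromosomeOrder,
    n_permutations: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    plus_one: bool = False,
) -> float:
    """Fraction of random label re-orderings whose longest dark run is at
    least the observed one.

    Label counts are preserved under shuffling. The plain count/n estimate is
    the default (the smallest attainable nonzero rate is 1/n); ``plus_one``
    switches to the (count+1)/(n+1) variant.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if len(order) == 0:
        raise ValueError("permutation test on an empty chromosome")
    if rng is None:
        rng = np.random.default_rng(seed)
    labels = order.labels
    observed, _ = longest_true_run(labels)
    if observed == 0:
        return 1.0
    hits = 0
    work = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(work)
        if longest_true_run(work)[0] >= observed:
            hits += 1
    if plus_one:
        return (hits + 1) / (n_permutations + 1)
    return hits / n_permutations


def composition_bias(sequence: str) -> float:
    """Largest single-amino-acid composition of a sequence, as a percentage."""
    if not sequence:
        raise ValueError("composition bias of an empty sequence")
    counts: dict[str, int] = {}
    for ch in sequence:
        counts[ch] = counts.get(ch, 0) + 1
    return 100.0 * max(counts.values()) / len(sequence)


def find_dark_clusters(
    loci: pd.DataFrame,
    dark_labels: Mapping[str, bool],
    links: LinkTable | None = None,
    sequences: Mapping[str, str] | None = None,
    lengths: Mapping[str, int] | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
) -> list[ClusterResult]:
    """Longest dark run per chromosome with permutation p-value and member
    summaries (protein length, binding partners within the cluster, largest
    single-amino-acid composition).

    Missing sequences leave the bias absent; without a link table the Binds
    column is absent. Each chromosome's permutation stream derives from
    ``seed`` and the chromosome name, so results are order-independent.
    """
    orders = build_order(loci, dark_labels)
    results = []
    for chrom in sorted(orders):
        order = orders[chrom]
        length, members = longest_run(order)
        chrom_seed = np.random.SeedSequence((seed, zlib.crc32(chrom.encode())))
        p = permutation_pvalue(
            order, n_permutations, rng=np.random.default_rng(chrom_seed)
        )
        member_set = set(members)
        summaries = []
        for acc in members:
            binds = None
            if links is not None:
                partners = set()
                df = links.df
                for a, b, _ in df[
                    (df["accession_a"] == acc) | (df["accession_b"] == acc)
                ].itertuples(index=False):
                    other = b if a == acc else a
                    if other in member_set:
                        partners.add(other)
                binds = len(partners)
            seq = sequences.get(acc) if sequences else None
            summaries.append(
                ClusterMember(
                    accession=acc,
                    length=(len(seq) if seq else (lengths.get(acc) if lengths else None)),
                    binds=binds,
                    bias_pct=composition_bias(seq) if seq else None,
                )
            )
        results.append(
            ClusterResult(
                chromosome=chrom,
                run_length=length,
                run_members=members,
                p_perm=p,
                n_permutations=n_permutations,
                seed=seed,
                members=summaries,
            )
        )
    return results


def clusters_table(results: Sequence[ClusterResult]) -> pd.DataFrame:
    rows = [
        {
            "chromosome": r.chromosome,
            "run_length": r.run_length,
            "p_perm": r.p_perm,
            "n_permutations": r.n_permutations,
            "members": ",".join(r.run_members),
        }
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["chromosome", "run_length", "p_perm", "n_permutations", "members"]
    )


def members_table(results: Sequence[ClusterResult]) -> pd.DataFrame:
    """Per-member summary mirroring the published cluster-table columns."""
    rows = [
        {
            "chromosome": r.chromosome,
            "accession": m.accession,
            "length": m.length,
            "binds": m.binds,
            "bias_pct": m.bias_pct,
        }
        for r in results
        for m in r.members
    ]
    return pd.DataFrame(
        rows, columns=["chromosome", "accession", "length", "binds", "bias_pct"]
    )
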