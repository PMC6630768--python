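"""Per-residue darkness, the score D, and the four-way proteome partition.

A residue is non-dark when at least one coverage interval — criterion A
(aligned onto an ATOM record of a matched structure) or criterion B (aligned
onto a PDB entry cross-referenced in the UniProt record) — covers it; all
other residues are dark. D is the dark fraction of the protein: D = 0 is a
white (PDB) protein, D = 1 a dark protein, 0 < D < 1 a grey protein.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    CoverageInterval,
    DarknessProfile,
    ProteinClass,
    ProteinRecord,
    ProteomePartition,
)

__all__ = [
    "residue_mask",
    "darkness_score",
    "classify",
    "profile",
    "compute_profiles",
    "proteome_partition",
    "dark_labels_from_profiles",
    "darkness_table",
    "partition_table",
]


def residue_mask(
    protein: ProteinRecord, coverage: Iterable[CoverageInterval]
) -> np.ndarray:
    """Boolean dark mask of length ``protein.length`` (True = dark).

    A residue is non-dark iff covered by at least one interval of either
    criterion (the union); intervals must belong to this protein and respect
    its length.
    """
    mask = np.ones(protein.length, dtype=bool)
    for iv in coverage:
        if iv.accession != protein.accession:
            raise ValueError(
                f"interval for {iv.accession!r} applied to {protein.accession!r}"
            )
        if iv.end > protein.length:
            raise ValueError(
                f"{protein.accession}: interval [{iv.start}, {iv.end}] exceeds "
                f"length {protein.length}"
            )
        mask[iv.start - 1 : iv.end] = False
    return mask


def darkness_score(mask: np.ndarray) -> float:
    """Dark fraction of a residue mask (dark count / length)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty residue mask")
    return float(mask.sum()) / mask.size


def classify(score: float) -> ProteinClass:
    """White iff D = 0, dark iff D = 1, grey otherwise (exact thresholds)."""
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"darkness score {score} outside [0, 1]")
    if score == 0.0:
        return ProteinClass.white
    if score == 1.0:
        return ProteinClass.dark
    return ProteinClass.grey


def profile(
    protein: ProteinRecord, coverage: Iterable[CoverageInterval]
) -> DarknessProfile:
    return DarknessProfile.from_mask(protein.accession, residue_mask(protein, coverage))


def compute_profiles(
    proteins: Sequence[ProteinRecord],
    coverage: Iterable[CoverageInterval],
) -> dict[str, DarknessProfile]:
    """Profiles for a whole universe; coverage is grouped by accession."""
    by_acc: dict[str, list[CoverageInterval]] = {p.accession: [] for p in proteins}
    for iv in coverage:
        if iv.accession not in by_acc:
            raise ValueError(f"coverage interval for unknown accession {iv.accession!r}")
        by_acc[iv.accession].append(iv)
    return {p.accession: profile(p, by_acc[p.accession]) for p in proteins}


def proteome_partition(profiles: Iterable[DarknessProfile]) -> ProteomePartition:
    """Residue-level four-way split of a proteome, in percent.

    Residues of dark proteins, dark residues of grey proteins (dark regions),
    non-dark residues of grey proteins (grey regions), and residues of white
    proteins (PDB regions), each over the summed length of the universe. The
    four percentages sum to 100 and total darkness is the first two summed.
    """
    dark = regions = grey = white = 0
    total = 0
    for p in profiles:
        total += p.length
        if p.klass is ProteinClass.dark:
            dark += p.length
        elif p.klass is ProteinClass.white:
            white += p.length
        else:
            regions += p.n_dark
            grey += p.length - p.n_dark
    if total == 0:
        raise ValueError("proteome partition of an empty universe")
    f = 100.0 / total
    return ProteomePartition(dark * f, regions * f, grey * f, white * f)


def dark_labels_from_profiles(
    profiles: Mapping[str, DarknessProfile],
    definition: str = "strict_D1",
    threshold: float = 1.0,
) -> dict[str, bool]:
    """Per-accession dark labels: strictly D = 1 (default) or D >= threshold."""
    if definition == "strict_D1":
        return {a: p.klass is ProteinClass.dark for a, p in profiles.items()}
    if definition == "dark_or_grey_threshold":
        return {a: p.score_D >= threshold for a, p in profiles.items()}
    raise ValueError(f"unknown dark definition {definition!r}")


def darkness_table(profiles: Mapping[str, DarknessProfile]) -> pd.DataFrame:
    rows = [
        {
            "accession": p.accession,
            "length": p.length,
            "dark_residues": p.n_dark,
            "score_D": p.score_D,
            "class": p.klass.value,
            "n_dark_runs": len(p.dark_runs),
        }
        for p in profiles.values()
    ]
    return pd.DataFrame(
        rows,
        columns=["accession", "length", "dark_residues", "score_D", "class", "n_dark_runs"],
    )


def partition_table(
    partitions: Mapping[str, ProteomePartition]
) -> pd.DataFrame:
    """One row per labelled universe (organism or taxon group)."""
    rows = [
        {
            "set": name,
            "pct_dark_proteins": part.pct_dark_proteins,
            "pct_dark_regions": part.pct_dark_regions,
            "pct_grey_regions": part.pct_grey_regions,
            "pct_pdb_regions": part.pct_pdb_regions,
            "total_darkness": part.total_darkness,
        }
        for name, part in partitions.items()
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "set",
            "pct_dark_proteins",
            "pct_dark_regions",
            "pct_grey_regions",
            "pct_pdb_regions",
            "total_darkness",
        ],
    )
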