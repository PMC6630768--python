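"""Protein autonomy from the interaction network.

A protein with no links at any confidence is fully autonomous (score 1);
one that keeps a partner above combined score 900 is fully non-autonomous
(score 0). In between, the score is 1 - N*/1000 where N* is the smallest
score cutoff on the integer grid [0, 900] at which the protein has no
partner with a strictly greater combined score — i.e. its maximum incident
score. m(N) counts partners with combined score strictly greater than N.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence
import warnings

import numpy as np
import pandas as pd

from .types import AutonomyRecord, LinkTable, ProteinRecord

__all__ = [
    "interaction_counts",
    "autonomy_score",
    "autonomy_records",
    "autonomy_distribution",
    "DegreeDistributions",
    "autonomy_table",
    "QUALITY_LOW",
    "QUALITY_HIGH",
]

# STRING confidence tiers: low < 400, medium 400-700, high > 700
QUALITY_LOW = 400
QUALITY_HIGH = 700


def _score_from_incident(scores: np.ndarray) -> float:
    if scores.size == 0:
        return 1.0
    s = int(scores.max())
    if s > 900:
        return 0.0
    return (1000 - s) / 1000.0  # exact: avoids 1 - 0.9 != 0.1


def interaction_counts(protein: str | ProteinRecord, links: LinkTable, cutoff: int) -> int:
    """Number of distinct partners with combined score strictly above ``cutoff``."""
    if not (0 <= cutoff <= 999):
        raise ValueError(f"cutoff {cutoff} outside [0, 999]")
    acc = protein.accession if isinstance(protein, ProteinRecord) else protein
    return int((links.incident_scores(acc) > cutoff).sum())


def autonomy_score(protein: str | ProteinRecord, links: LinkTable) -> float:
    """Autonomy in [0, 1]: 1 with no links, 0 past score 900, else 1 - s/1000
    with s the maximum incident combined score."""
    acc = protein.accession if isinstance(protein, ProteinRecord) else protein
    return _score_from_incident(links.incident_scores(acc))


def autonomy_records(
    universe: Sequence[ProteinRecord], links: LinkTable
) -> dict[str, AutonomyRecord]:
    """Autonomy for a whole universe in one pass over the link table."""
    incident = links.incident_score_map()
    out: dict[str, AutonomyRecord] = {}
    empty = np.empty(0, dtype=np.int64)
    for p in universe:
        scores = incident.get(p.accession, empty)
        out[p.accession] = AutonomyRecord(
            accession=p.accession,
            max_incident_score=int(scores.max()) if scores.size else None,
            autonomy=_score_from_incident(scores),
            incident_scores=scores,
        )
    return out


@dataclass
class DegreeDistributions:
    """Interaction-count histograms for the dark and non-dark classes."""

    cutoff: int
    dark_counts: np.ndarray  # per-protein partner counts, dark class
    nondark_counts: np.ndarray

    @property
    def dark_median(self) -> float:
        return float(np.median(self.dark_counts)) if self.dark_counts.size else float("nan")

    @property
    def nondark_median(self) -> float:
        return (
            float(np.median(self.nondark_counts)) if self.nondark_counts.size else float("nan")
        )

    def histogram(self, klass: str) -> np.ndarray:
        counts = self.dark_counts if klass == "dark" else self.nondark_counts
        if counts.size == 0:
            return np.zeros(0, dtype=np.int64)
        return np.bincount(counts)


def autonomy_distribution(
    universe: Sequence[ProteinRecord],
    dark_labels: Mapping[str, bool],
    links: LinkTable,
    cutoff: int = QUALITY_HIGH,
) -> DegreeDistributions:
    """Per-class interaction-count distributions at a confidence cutoff
    (default: high quality, 700)."""
    incident = links.incident_score_map()
    empty = np.empty(0, dtype=np.int64)
    dark, nondark = [], []
    for p in universe:
        n = int((incident.get(p.accession, empty) > cutoff).sum())
        (dark if dark_labels[p.accession] else nondark).append(n)
    if not dark or not nondark:
        warnings.warn("empty dark or non-dark class in autonomy distribution")
    return DegreeDistributions(
        cutoff=cutoff,
        dark_counts=np.asarray(dark, dtype=np.int64),
        nondark_counts=np.asarray(nondark, dtype=np.int64),
    )


def autonomy_table(
    records: Mapping[str, AutonomyRecord],
    dark_labels: Mapping[str, bool],
    cutoff: int = QUALITY_HIGH,
) -> pd.DataFrame:
    rows = [
        {
            "accession": r.accession,
            "is_dark": bool(dark_labels[r.accession]),
            "max_incident_score": -1 if r.max_incident_score is None else r.max_incident_score,
            "autonomy": r.autonomy,
            f"n_interactions_at_{cutoff}": r.m(cutoff),
        }
        for r in records.values()
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "accession",
            "is_dark",
            "max_incident_score",
            "autonomy",
            f"n_interactions_at_{cutoff}",
        ],
    )
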