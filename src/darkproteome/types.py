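"""Domain types shared by all pipeline stages.

Residue coordinates are 1-based inclusive throughout (the UniProt FT
convention); conversion to 0-based half-open happens only inside array
code at the I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "TaxonGroup",
    "Criterion",
    "AnnotationField",
    "ProteinClass",
    "AnnotationEntry",
    "PdbCrossRef",
    "GeneLocus",
    "ProteinRecord",
    "CoverageInterval",
    "LinkTable",
    "ExpressionMatrix",
    "DarknessProfile",
    "ProteomePartition",
    "ContingencyTable",
    "EnrichmentResult",
    "EnrichmentConfig",
    "AutonomyRecord",
    "ChromosomeOrder",
    "ClusterMember",
    "ClusterResult",
    "TissueDarkness",
]


class TaxonGroup(str, Enum):
    archaea = "archaea"
    bacteria = "bacteria"
    eukaryota = "eukaryota"
    viruses = "viruses"


class Criterion(str, Enum):
    """How a residue was declared structurally covered.

    A: aligned onto the ATOM record of a matched structure.
    B: aligned onto a PDB entry cross-referenced in the UniProt record.
    """

    A = "A"
    B = "B"


class AnnotationField(str, Enum):
    DE = "DE"
    FT = "FT"


class ProteinClass(str, Enum):
    white = "white"
    grey = "grey"
    dark = "dark"


@dataclass(frozen=True)
class AnnotationEntry:
    """One annotation unit: (field, subcategory, text) is the enrichment key."""

    field: AnnotationField
    subcategory: str
    text: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "field", AnnotationField(self.field))
        if not self.subcategory:
            raise ValueError("annotation subcategory must be non-empty")


@dataclass(frozen=True)
class PdbCrossRef:
    structure_id: str
    chain_ranges: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        for start, end in self.chain_ranges:
            if not (1 <= start <= end):
                raise ValueError(
                    f"invalid chain range {start}-{end} in {self.structure_id}"
                )


@dataclass(frozen=True)
class GeneLocus:
    chromosome: str
    central_position: int

    def __post_init__(self) -> None:
        if self.central_position < 0:
            raise ValueError("central_position must be non-negative")


@dataclass
class ProteinRecord:
    """One Swiss-Prot-style entry."""

    accession: str
    organism: str = ""
    taxon_group: TaxonGroup = TaxonGroup.eukaryota
    length: int = 1
    annotations: list[AnnotationEntry] = field(default_factory=list)
    pdb_crossrefs: list[PdbCrossRef] = field(default_factory=list)
    gene_locus: Optional[GeneLocus] = None
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        self.taxon_group = TaxonGroup(self.taxon_group)
        if self.length < 1:
            raise ValueError(
                f"{self.accession}: protein length must be >= 1, got {self.length}"
            )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.accession}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )
        for xref in self.pdb_crossrefs:
            for start, end in xref.chain_ranges:
                if end > self.length:
                    raise ValueError(
                        f"{self.accession}: chain range {start}-{end} of "
                        f"{xref.structure_id} exceeds length {self.length}"
                    )

    def coverage_from_crossrefs(self) -> list["CoverageInterval"]:
        """Criterion-B intervals derived from the DR PDB chain annotations."""
        out = []
        for xref in self.pdb_crossrefs:
            for start, end in xref.chain_ranges:
                out.append(
                    CoverageInterval(
                        accession=self.accession,
                        start=start,
                        end=end,
                        criterion=Criterion.B,
                        source_id=xref.structure_id,
                    )
                )
        return out


@dataclass(frozen=True)
class CoverageInterval:
    """A residue range declared structurally covered under criterion A or B."""

    accession: str
    start: int
    end: int
    criterion: Criterion
    source_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "criterion", Criterion(self.criterion))
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.accession}: invalid coverage interval "
                f"[{self.start}, {self.end}]"
            )


class LinkTable:
    """Undirected protein-protein functional links with combined scores 0-999.

    Normalized on construction: each undirected pair stored once
    (lexicographically ordered endpoints); duplicate rows collapse, keeping
    the maximum score; self-links are rejected.
    """

    COLUMNS = ("accession_a", "accession_b", "combined_score")

    def __init__(self, rows: pd.DataFrame | Iterable[tuple[str, str, int]]):
        if not isinstance(rows, pd.DataFrame):
            rows = pd.DataFrame(list(rows), columns=list(self.COLUMNS))
        df = rows.loc[:, list(self.COLUMNS)].copy()
        if len(df):
            scores = df["combined_score"].to_numpy()
            bad = (scores < 0) | (scores > 999)
            if bad.any():
                raise ValueError(
                    f"combined_score outside [0, 999]: {scores[bad][:5].tolist()}"
                )
            if (df["accession_a"] == df["accession_b"]).any():
                raise ValueError("self-links are not allowed")
            a = df["accession_a"].to_numpy(dtype=object)
            b = df["accession_b"].to_numpy(dtype=object)
            swap = a > b
            a[swap], b[swap] = b[swap], a[swap]
            df["accession_a"], df["accession_b"] = a, b
            df = (
                df.groupby(["accession_a", "accession_b"], as_index=False)[
                    "combined_score"
                ]
                .max()
                .sort_values(["accession_a", "accession_b"], kind="stable")
                .reset_index(drop=True)
            )
        df["combined_score"] = df["combined_score"].astype(np.int64) if len(df) else pd.Series(dtype=np.int64)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def incident_scores(self, accession: str) -> np.ndarray:
        """Combined scores of all links touching ``accession``."""
        df = self.df
        mask = (df["accession_a"] == accession) | (df["accession_b"] == accession)
        return df.loc[mask, "combined_score"].to_numpy()

    def incident_score_map(self) -> dict[str, np.ndarray]:
        """Per-accession arrays of incident scores (single pass, for bulk use)."""
        out: dict[str, list[int]] = {}
        for a, b, s in self.df.itertuples(index=False):
            out.setdefault(a, []).append(s)
            out.setdefault(b, []).append(s)
        return {k: np.asarray(v, dtype=np.int64) for k, v in out.items()}

    def accessions(self) -> set[str]:
        return set(self.df["accession_a"]) | set(self.df["accession_b"])


class ExpressionMatrix:
    """Tissue x protein normalized-intensity table (log-scale floats).

    Missing entries (no measurement) are NaN and are distinguishable from a
    literal 0 until :func:`darkproteome.tissues.zero_fill` is applied.
    """

    def __init__(self, values: pd.DataFrame):
        self.values = values.astype(float)
        self.values.index.name = "tissue"
        self.values.columns.name = "accession"

    @property
    def tissues(self) -> list[str]:
        return list(self.values.index)

    @property
    def proteins(self) -> list[str]:
        return list(self.values.columns)

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ExpressionMatrix) and self.values.equals(other.values)


def _runs_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as 1-based inclusive intervals."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    padded = np.concatenate(([False], m, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


@dataclass
class DarknessProfile:
    """Per-residue darkness of one protein.

    ``mask[i]`` is True when residue ``i+1`` is dark (uncovered by every
    criterion-A and criterion-B interval). ``score_D`` is the dark fraction;
    0 means white (fully covered), 1 means dark, anything between is grey.
    """

    accession: str
    mask: np.ndarray
    score_D: float
    klass: ProteinClass
    dark_runs: list[tuple[int, int]]

    @classmethod
    def from_mask(cls, accession: str, mask: np.ndarray) -> "DarknessProfile":
        mask = np.asarray(mask, dtype=bool)
        if mask.size == 0:
            raise ValueError(f"{accession}: empty residue mask")
        score = float(mask.sum()) / mask.size
        if score == 0.0:
            klass = ProteinClass.white
        elif score == 1.0:
            klass = ProteinClass.dark
        else:
            klass = ProteinClass.grey
        return cls(accession, mask, score, klass, _runs_from_mask(mask))

    @property
    def length(self) -> int:
        return int(self.mask.size)

    @property
    def n_dark(self) -> int:
        return int(self.mask.sum())


@dataclass
class ProteomePartition:
    """Residue-level four-way split of a proteome, in percent.

    The four percentages sum to 100; ``total_darkness`` is the dark-protein
    share plus the dark-region share.
    """

    pct_dark_proteins: float
    pct_dark_regions: float
    pct_grey_regions: float
    pct_pdb_regions: float

    @property
    def total_darkness(self) -> float:
        return self.pct_dark_proteins + self.pct_dark_regions

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (
            self.pct_dark_proteins,
            self.pct_dark_regions,
            self.pct_grey_regions,
            self.pct_pdb_regions,
        )


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 protein counts for one annotation: dark/non-dark x with/without."""

    dark_with: int
    dark_without: int
    nondark_with: int
    nondark_without: int

    def __post_init__(self) -> None:
        if min(self.dark_with, self.dark_without, self.nondark_with, self.nondark_without) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.dark_with + self.dark_without + self.nondark_with + self.nondark_without

    @property
    def n_with(self) -> int:
        return self.dark_with + self.nondark_with


class Direction(str, Enum):
    over = "over"
    under = "under"


@dataclass
class EnrichmentResult:
    annotation: AnnotationEntry
    table: ContingencyTable
    odds_ratio: float
    p: float
    p_adjusted: float
    direction: Direction
    rank_k: int


@dataclass
class EnrichmentConfig:
    """Knobs of the annotation-enrichment stage.

    alpha is the acceptable false-discovery fraction for the BH step-up
    (the analysis keeps annotations with adjusted p <= alpha).
    dark_definition selects which proteins count as "dark": strictly D = 1
    (default) or D above a threshold.
    """

    alpha: float = 0.01
    dark_definition: str = "strict_D1"
    dark_threshold: float = 1.0
    excluded_subcategories: tuple[str, ...] = ("SIMILARITY",)
    treemap_cutoff: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.dark_definition not in ("strict_D1", "dark_or_grey_threshold"):
            raise ValueError(f"unknown dark_definition {self.dark_definition!r}")


@dataclass
class AutonomyRecord:
    """Autonomy of one protein: 1 = no links at any confidence, 0 = a link
    survives above combined score 900."""

    accession: str
    max_incident_score: Optional[int]
    autonomy: float
    incident_scores: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    def m(self, n: int) -> int:
        """Number of partners with combined score strictly greater than n."""
        return int((self.incident_scores > n).sum())


@dataclass
class ChromosomeOrder:
    """Proteins of one chromosome in gene order (central-nucleotide position
    ascending, duplicates collapsed to first occurrence, position ties broken
    by accession)."""

    chromosome: str
    entries: list[tuple[str, int, bool]]  # (accession, central_position, is_dark)

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([e[2] for e in self.entries], dtype=bool)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ClusterMember:
    accession: str
    length: Optional[int] = None
    binds: Optional[int] = None  # partners within the same cluster
    bias_pct: Optional[float] = None  # largest single-amino-acid composition, %


@dataclass
class ClusterResult:
    chromosome: str
    run_length: int
    run_members: list[str]
    p_perm: float
    n_permutations: int
    seed: int
    members: list[ClusterMember] = field(default_factory=list)


@dataclass
class TissueDarkness:
    tissue: str
    ratio_dark_residues: float
    n_expressed: int
    weighting: str = "presence"
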