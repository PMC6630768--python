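"""Synthetic proteome bundles with planted, recoverable structure.

Every pipeline stage is testable without any download: the generator
produces the six input tables (proteins, annotations, coverage, links,
gene positions, expression) in the package's dialects, with planted
parameters — per-class darkness fractions, annotation odds ratios,
interaction degree means, chromosomal dark runs, tissue darkness targets —
recorded in a ground-truth manifest.

Coverage intervals are constructed so the realized darkness score D equals
the planted class exactly: dark proteins get no intervals, white proteins a
full-length interval, grey proteins partial coverage hitting a drawn dark
fraction. A single master seed derives per-component substreams, so the
same spec and seed yield byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as dpio
from .types import (
    AnnotationEntry,
    AnnotationField,
    CoverageInterval,
    Criterion,
    ExpressionMatrix,
    LinkTable,
    ProteinRecord,
    TaxonGroup,
)

__all__ = [
    "UniverseSpec",
    "PlantedAnnotation",
    "PlantedCluster",
    "TissueTarget",
    "PlantedSignals",
    "SyntheticBundle",
    "generate",
]

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class UniverseSpec:
    """Shape of a synthetic proteome.

    Lengths are log-normal (parameters on the ln scale; the defaults put the
    median near 300 residues, Swiss-Prot-like). class_fractions are the
    (dark, grey, white) protein-count fractions; the defaults emulate a
    eukaryote-like universe where roughly half the proteome is structurally
    dark at the residue level. Grey proteins draw their dark fraction
    uniformly from grey_dark_fraction_range.
    """

    n_proteins: int = 1000
    length_lognormal: tuple[float, float] = (5.7, 0.45)
    class_fractions: tuple[float, float, float] = (0.15, 0.55, 0.30)
    grey_dark_fraction_range: tuple[float, float] = (0.1, 0.9)
    taxon_group: str = "eukaryota"
    organism: str = "synthetic organism"
    with_sequences: bool = False
    min_length: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.class_fractions, dtype=float)
        if f.min() < 0 or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("class_fractions must be non-negative and sum to 1")
        lo, hi = self.grey_dark_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("grey_dark_fraction_range must lie within (0, 1)")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")


@dataclass(frozen=True)
class PlantedAnnotation:
    """An annotation with a planted population odds ratio.

    Per-class presence probabilities solve the 2x2 odds identity: with
    non-dark prevalence p0, dark proteins carry the annotation with
    probability p1 = OR*odds0 / (1 + OR*odds0), making the planted odds
    ratio the exact population parameter the enrichment stage estimates.
    """

    subcategory: str
    text: str
    odds_ratio: float
    prevalence_nondark: float
    field: str = "DE"

    def prevalence_dark(self) -> float:
        if not (0.0 < self.prevalence_nondark < 1.0):
            raise ValueError(
                f"prevalence_nondark must be in (0, 1), got {self.prevalence_nondark}"
            )
        if not (self.odds_ratio > 0.0 and np.isfinite(self.odds_ratio)):
            raise ValueError(f"odds_ratio must be positive finite, got {self.odds_ratio}")
        odds = self.odds_ratio * self.prevalence_nondark / (1.0 - self.prevalence_nondark)
        return odds / (1.0 + odds)


@dataclass(frozen=True)
class PlantedCluster:
    chromosome: str
    start_index: int
    run_length: int

    def __post_init__(self) -> None:
        if self.run_length < 1:
            raise ValueError("run_length must be >= 1")
        if self.start_index < 0:
            raise ValueError("start_index must be >= 0")


@dataclass(frozen=True)
class TissueTarget:
    tissue: str
    target_dark_residue_ratio: float
    n_expressed: int = 200

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_dark_residue_ratio <= 1.0):
            raise ValueError("target ratio must lie in [0, 1]")


@dataclass
class PlantedSignals:
    """Planted statistical structure for every downstream analysis.

    degree_means are the Poisson means of per-protein link draws for the
    (dark, non-dark) classes; combined scores are uniform over score_range.
    Null annotations carry the same prevalence in both classes (odds ratio
    1) for calibration studies.
    """

    enriched_annotations: tuple[PlantedAnnotation, ...] = ()
    n_null_annotations: int = 0
    null_prevalence: float = 0.05
    degree_means: tuple[float, float] = (1.0, 10.0)
    score_range: tuple[int, int] = (150, 999)
    clusters: tuple[PlantedCluster, ...] = ()
    n_chromosomes: int = 2
    genes_per_chromosome: int = 200
    tissue_targets: tuple[TissueTarget, ...] = ()
    missing_rate: float = 0.1

    def __post_init__(self) -> None:
        lo, hi = self.score_range
        if not (0 <= lo <= hi <= 999):
            raise ValueError("score_range must lie within [0, 999]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if min(self.degree_means) < 0:
            raise ValueError("degree means must be non-negative")
        # validate planted annotations eagerly, before any drawing
        for ann in self.enriched_annotations:
            ann.prevalence_dark()


@dataclass
class SyntheticBundle:
    proteins: list[ProteinRecord]
    coverage: list[CoverageInterval]
    links: LinkTable
    loci: pd.DataFrame
    expression: ExpressionMatrix
    manifest: dict

    def dark_labels(self) -> dict[str, bool]:
        """Ground-truth labels (planted class == dark)."""
        return {
            acc: klass == "dark" for acc, klass in self.manifest["classes"].items()
        }

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dpio.write_proteins(self.proteins, outdir / "proteins.tsv")
        dpio.write_annotations(self.proteins, outdir / "annotations.tsv")
        dpio.write_coverage(self.coverage, outdir / "coverage.tsv")
        dpio.write_links(self.links, outdir / "links.tsv")
        dpio.write_gene_positions(self.loci, outdir / "genes.tsv")
        dpio.write_expression(self.expression, outdir / "expression.tsv")
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n"
        )


def _draw_universe(spec: UniverseSpec, rng: np.random.Generator):
    width = max(6, len(str(spec.n_proteins)))
    accs = [f"SP{i:0{width}d}" for i in range(1, spec.n_proteins + 1)]
    mu, sigma = spec.length_lognormal
    lengths = np.maximum(
        spec.min_length, np.round(rng.lognormal(mu, sigma, spec.n_proteins))
    ).astype(int)
    classes = rng.choice(
        np.array(["dark", "grey", "white"]),
        size=spec.n_proteins,
        p=np.asarray(spec.class_fractions, dtype=float),
    )
    lo, hi = spec.grey_dark_fraction_range
    dark_counts = np.zeros(spec.n_proteins, dtype=int)
    for i, (klass, L) in enumerate(zip(classes, lengths)):
        if klass == "dark":
            dark_counts[i] = L
        elif klass == "grey":
            d = int(round(rng.uniform(lo, hi) * L))
            dark_counts[i] = min(max(d, 1), L - 1)
    return accs, lengths, classes, dark_counts


def _draw_sequences(
    lengths: np.ndarray, classes: np.ndarray, rng: np.random.Generator
) -> list[str]:
    """Composition-bias toys: dark proteins get one dominant amino acid."""
    seqs = []
    aa = np.array(list(_AMINO_ACIDS))
    for L, klass in zip(lengths, classes):
        if klass == "dark":
            dominant = rng.choice(aa)
            probs = np.full(len(aa), 0.6 / (len(aa) - 1))
            probs[aa == dominant] = 0.4
        else:
            probs = np.full(len(aa), 1.0 / len(aa))
        seqs.append("".join(rng.choice(aa, size=int(L), p=probs)))
    return seqs


def _draw_coverage(
    accs, lengths, classes, dark_counts, rng: np.random.Generator
) -> list[CoverageInterval]:
    out: list[CoverageInterval] = []
    for acc, L, klass, d in zip(accs, lengths, classes, dark_counts):
        if klass == "dark":
            continue
        if klass == "white":
            out.append(CoverageInterval(acc, 1, int(L), Criterion.A, "synthA"))
            continue
        covered = int(L - d)
        start = int(rng.integers(1, d + 2))  # covered block start in [1, d+1]
        end = start + covered - 1
        if covered >= 4 and rng.random() < 0.5:
            # split the covered block across both criteria to exercise the union
            cut = start + covered // 2
            out.append(CoverageInterval(acc, start, cut, Criterion.A, "synthA"))
            out.append(CoverageInterval(acc, cut, end, Criterion.B, "synthB"))
        else:
            crit = Criterion.A if rng.random() < 0.5 else Criterion.B
            out.append(CoverageInterval(acc, start, end, crit, f"synth{crit.value}"))
    return out


def _draw_annotations(
    proteins: Sequence[ProteinRecord],
    is_dark: np.ndarray,
    signals: PlantedSignals,
    rng: np.random.Generator,
) -> None:
    n = len(proteins)
    for planted in signals.enriched_annotations:
        p1 = planted.prevalence_dark()
        p0 = planted.prevalence_nondark
        probs = np.where(is_dark, p1, p0)
        hits = rng.random(n) < probs
        entry = AnnotationEntry(
            AnnotationField(planted.field), planted.subcategory, planted.text
        )
        for prot, hit in zip(proteins, hits):
            if hit:
                prot.annotations.append(entry)
    for j in range(signals.n_null_annotations):
        entry = AnnotationEntry(
            AnnotationField.DE, "MISC", f"background annotation {j:04d}"
        )
        hits = rng.random(n) < signals.null_prevalence
        for prot, hit in zip(proteins, hits):
            if hit:
                prot.annotations.append(entry)


def _draw_links(
    accs: Sequence[str],
    is_dark: np.ndarray,
    signals: PlantedSignals,
    rng: np.random.Generator,
) -> LinkTable:
    n = len(accs)
    rows: list[tuple[str, str, int]] = []
    if n < 2:
        return LinkTable(rows)
    mean_dark, mean_nondark = signals.degree_means
    lo, hi = signals.score_range
    degrees = rng.poisson(np.where(is_dark, mean_dark, mean_nondark))
    for i, k in enumerate(degrees):
        for _ in range(int(k)):
            j = int(rng.integers(0, n - 1))
            if j >= i:
                j += 1
            rows.append((accs[i], accs[j], int(rng.integers(lo, hi + 1))))
    return LinkTable(rows)


def _draw_genome(
    accs: Sequence[str],
    is_dark: np.ndarray,
    signals: PlantedSignals,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n_slots = signals.n_chromosomes * signals.genes_per_chromosome
    if n_slots > len(accs):
        raise ValueError(
            f"genome needs {n_slots} proteins but the universe has {len(accs)}"
        )
    perm = rng.permutation(len(accs))
    chrom_of = {}  # index -> (chromosome, slot)
    slots: dict[str, list[int]] = {}
    pos = 0
    for c in range(signals.n_chromosomes):
        name = f"chr{c + 1}"
        slots[name] = [int(i) for i in perm[pos : pos + signals.genes_per_chromosome]]
        pos += signals.genes_per_chromosome
    leftover = [int(i) for i in perm[pos:]]

    # plant dark runs by swapping dark proteins into the target windows
    protected: set[int] = set()
    for cluster in signals.clusters:
        if cluster.chromosome not in slots:
            raise ValueError(f"planted cluster on unknown chromosome {cluster.chromosome}")
        window = range(cluster.start_index, cluster.start_index + cluster.run_length)
        if cluster.start_index + cluster.run_length > signals.genes_per_chromosome:
            raise ValueError(
                f"planted run on {cluster.chromosome} exceeds the chromosome"
            )
        chrom = slots[cluster.chromosome]
        # donor pool: dark proteins outside every protected window
        donors = [i for i in leftover if is_dark[i]]
        donors += [
            i
            for name, idxs in slots.items()
            for s, i in enumerate(idxs)
            if is_dark[i]
            and (name != cluster.chromosome or s not in window)
            and (id(idxs), s) not in protected
        ]
        donor_iter = iter(donors)
        for s in window:
            protected.add((id(chrom), s))
            if is_dark[chrom[s]]:
                continue
            try:
                donor = next(d for d in donor_iter if d != chrom[s])
            except StopIteration:
                raise ValueError(
                    f"not enough dark proteins to plant a run of "
                    f"{cluster.run_length} on {cluster.chromosome}"
                )
            # swap: donor takes the window slot, displaced protein takes donor's place
            displaced = chrom[s]
            if donor in leftover:
                leftover[leftover.index(donor)] = displaced
            else:
                for idxs in slots.values():
                    for t, v in enumerate(idxs):
                        if v == donor and (id(idxs), t) not in protected:
                            idxs[t] = displaced
                            break
                    else:
                        continue
                    break
            chrom[s] = donor

    rows = []
    for name in sorted(slots):
        size = len(slots[name])
        positions = np.sort(
            rng.choice(np.arange(1, 1000 * size + 1), size=size, replace=False)
        )
        for slot, (i, p) in enumerate(zip(slots[name], positions)):
            rows.append((accs[i], name, int(p)))
    return pd.DataFrame(rows, columns=["accession", "chromosome", "central_position"])


def _draw_expression(
    accs: Sequence[str],
    lengths: np.ndarray,
    dark_counts: np.ndarray,
    signals: PlantedSignals,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    d_frac = dark_counts / lengths
    selected: dict[str, list[int]] = {}
    for target in signals.tissue_targets:
        t = target.target_dark_residue_ratio
        heavy = [i for i in range(len(accs)) if d_frac[i] >= t]
        light = [i for i in range(len(accs)) if d_frac[i] < t]
        rng.shuffle(heavy)
        rng.shuffle(light)
        chosen: list[int] = []
        dark_sum = total_sum = 0.0
        for _ in range(min(target.n_expressed, len(accs))):
            want_heavy = total_sum == 0.0 or dark_sum / total_sum < t
            pool = heavy if (want_heavy and heavy) or not light else light
            i = pool.pop()
            chosen.append(i)
            dark_sum += dark_counts[i]
            total_sum += lengths[i]
        selected[target.tissue] = chosen
    all_cols = sorted({i for idxs in selected.values() for i in idxs})
    col_pos = {i: j for j, i in enumerate(all_cols)}
    values = np.full((len(selected), len(all_cols)), np.nan)
    tissue_names = sorted(selected)
    for r, tissue in enumerate(tissue_names):
        for i in selected[tissue]:
            if rng.random() < signals.missing_rate:
                continue  # measurement missing for this pair
            values[r, col_pos[i]] = max(0.1, rng.normal(5.0, 1.5))
    df = pd.DataFrame(values, index=tissue_names, columns=[accs[i] for i in all_cols])
    return ExpressionMatrix(df)


def generate(spec: UniverseSpec, signals: PlantedSignals | None = None) -> SyntheticBundle:
    """Draw a complete input bundle with the planted structure of ``signals``.

    Substreams (universe, coverage, annotations, links, genome, expression)
    derive from the master seed, so regenerating one component cannot
    perturb the others.
    """
    if signals is None:
        signals = PlantedSignals()
    streams = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(spec.seed).spawn(7)
    ]
    rng_univ, rng_seq, rng_cov, rng_ann, rng_link, rng_gen, rng_expr = streams

    accs, lengths, classes, dark_counts = _draw_universe(spec, rng_univ)
    sequences = (
        _draw_sequences(lengths, classes, rng_seq) if spec.with_sequences else None
    )
    proteins = [
        ProteinRecord(
            accession=acc,
            organism=spec.organism,
            taxon_group=TaxonGroup(spec.taxon_group),
            length=int(L),
            sequence=sequences[i] if sequences else None,
        )
        for i, (acc, L) in enumerate(zip(accs, lengths))
    ]
    is_dark = classes == "dark"
    coverage = _draw_coverage(accs, lengths, classes, dark_counts, rng_cov)
    _draw_annotations(proteins, is_dark, signals, rng_ann)
    links = _draw_links(accs, is_dark, signals, rng_link)
    loci = (
        _draw_genome(accs, is_dark, signals, rng_gen)
        if signals.n_chromosomes > 0
        else pd.DataFrame(columns=["accession", "chromosome", "central_position"])
    )
    expression = _draw_expression(accs, lengths, dark_counts, signals, rng_expr)

    manifest = {
        "seed": spec.seed,
        "spec": dataclasses.asdict(spec),
        "signals": dataclasses.asdict(signals),
        "classes": dict(zip(accs, classes.tolist())),
        "realized": {
            "n_proteins": len(accs),
            "class_counts": {
                k: int((classes == k).sum()) for k in ("dark", "grey", "white")
            },
            "total_residues": int(lengths.sum()),
            "total_dark_residues": int(dark_counts.sum()),
            "n_links": len(links),
        },
    }
    return SyntheticBundle(proteins, coverage, links, loci, expression, manifest)
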