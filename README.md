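# darkproteome

Roughly half of the eukaryotic protein universe has no observed or
homology-modelled 3D structure — the *dark proteome*. This package maps that
darkness at residue level and runs the downstream analyses that characterise
it, for structural bioinformaticians who have per-residue structural coverage
(from sequence-to-structure alignments and PDB cross-references) and want to
ask: how dark is a proteome, what is special about its dark proteins, and
where do they live?

## The model

For a protein of length *L*, each residue is **non-dark** if it is covered by
at least one interval from either evidence route: alignment onto the ATOM
record of a matched structure (criterion A) or alignment onto a PDB entry
cross-referenced in the protein's UniProt record (criterion B). The
**darkness score** is

> D = (number of dark residues) / L

with D = 0 a *white* (PDB) protein, D = 1 a *dark* protein, and 0 < D < 1 a
*grey* protein containing dark regions. A proteome is then partitioned at
residue level into dark-protein residues, dark regions, grey regions and PDB
regions (four percentages summing to 100; *total darkness* is the first two
summed).

Around this core:

- **Enrichment** — each distinct annotation (Swiss-Prot description-family
  or feature-family) yields a 2×2 dark/non-dark presence table, tested with
  a two-sided Fisher exact test and Benjamini–Hochberg adjusted per family;
  annotations with adjusted p ≤ α (default 1%) are reported and exportable
  as a treemap JSON with cell area −log₁₀(p_adj).
- **Autonomy** — per protein, from a STRING-style link table with combined
  scores 0–999: autonomy 1 with no links at any confidence, 0 with a
  partner above score 900, otherwise 1 − s/1000 for maximum incident
  score s.
- **Dark gene clusters** — per chromosome, the longest run of consecutive
  dark genes in central-nucleotide order, with a p-value from 1,000 random
  re-orderings of the gene labels.
- **Dark tissues** — per tissue, the fraction of dark residues among
  proteins expressed there (nonzero normalized intensity after zero-filling
  unmeasured entries).
- **Synthetic data** — a generator that plants class fractions, annotation
  odds ratios, degree gaps, chromosomal runs and tissue darkness targets,
  so every stage is testable against known ground truth.

## Worked example

```sh
darkproteome simulate --out bundle --seed 7 --n-proteins 400
darkproteome report --in bundle --out results
```

prints (abridged):

```
total darkness 40.2% (13.3% dark proteins + 26.9% dark regions)
1 annotations at adjusted p <= 0.01
median interactions at >700: dark 3, non-dark 7
chr1: longest dark run 8, p = 0
chr2: longest dark run 2, p = 0.91
heart: 50% dark residues
liver: 35% dark residues
brain: 23% dark residues
```

Reading this: 40.2% of all residues in the simulated universe are dark,
split into whole-dark proteins (13.3%) and dark regions inside grey proteins
(26.9%) — the same identity the residue partition always satisfies. The
planted membrane annotation is the one surviving FDR control at 1%. Dark
proteins interact less than non-dark ones (medians 3 vs 7 at the
high-confidence cutoff). The dark-gene run of 8 planted on chr1 is never
reached in 1,000 re-orderings (p = 0), while chr2's best run of 2 is
unremarkable (p = 0.91). The tissue ranking recovers the planted darkness
targets (0.50 / 0.35 / 0.25).

The same analyses are available as library calls (`darkproteome.darkness`,
`.enrichment`, `.autonomy`, `.clusters`, `.tissues`, `.simulate`) on
in-memory domain objects; `darkproteome.io` reads and writes the TSV
dialects and single UniProt flat-file records.

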