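"""Tissue darkness: the dark-residue fraction among expressed proteins.

A protein is expressed in a tissue when its normalized intensity is
positive after zero-fill (unmeasured entries become literal 0). The
tissue's darkness ratio is the summed dark residues of its expressed
proteins over their summed lengths; intensity weighting multiplies both
sums by the intensity instead of counting presence.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import DarknessProfile, ExpressionMatrix, TissueDarkness

__all__ = ["zero_fill", "tissue_darkness", "tissues_table"]


def zero_fill(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every MISSING (NaN) entry with a literal 0; nothing else changes."""
    return ExpressionMatrix(matrix.values.fillna(0.0))


def tissue_darkness(
    matrix: ExpressionMatrix,
    profiles: Mapping[str, DarknessProfile],
    weighting: str = "presence",
    min_intensity: float = 0.0,
) -> list[TissueDarkness]:
    """Per-tissue dark-residue ratios, sorted descending (ties by tissue name).

    Requires a zero-filled matrix and a darkness profile for every expressed
    accession. ``min_intensity`` optionally restricts "expressed" to
    intensities strictly above the threshold (default: any positive value).
    A tissue with no expressed protein is omitted with a warning.
    """
    if weighting not in ("presence", "intensity"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if matrix.n_missing():
        raise ValueError("matrix must be zero-filled before tissue darkness")
    threshold = max(0.0, min_intensity)
    accs = list(matrix.values.columns)
    missing = [a for a in accs if a not in profiles]
    if missing:
        raise ValueError(f"no darkness profile for expressed accessions {missing[:5]}")
    lengths = np.array([profiles[a].length for a in accs], dtype=float)
    dark = np.array([profiles[a].n_dark for a in accs], dtype=float)
    out: list[TissueDarkness] = []
    for tissue, row in matrix.values.iterrows():
        vals = row.to_numpy(dtype=float)
        expressed = vals > threshold
        n_expr = int(expressed.sum())
        if n_expr == 0:
            warnings.warn(f"tissue {tissue!r} has no expressed proteins; omitted")
            continue
        w = vals[expressed] if weighting == "intensity" else 1.0
        ratio = float(np.sum(w * dark[expressed]) / np.sum(w * lengths[expressed]))
        out.append(
            TissueDarkness(
                tissue=str(tissue),
                ratio_dark_residues=ratio,
                n_expressed=n_expr,
                weighting=weighting,
            )
        )
    out.sort(key=lambda t: (-t.ratio_dark_residues, t.tissue))
    return out


def tissues_table(ranked: Sequence[TissueDarkness], percent_decimals: int | None = 0) -> pd.DataFrame:
    """Ranked table; ratio as a percentage, rounded as configured
    (``percent_decimals=None`` keeps full precision)."""
    rows = []
    for rank, t in enumerate(ranked, start=1):
        pct = 100.0 * t.ratio_dark_residues
        if percent_decimals is not None:
            pct = round(pct, percent_decimals)
        rows.append(
            {
                "rank": rank,
                "tissue": t.tissue,
                "ratio_dark_residues_pct": pct,
                "n_expressed": t.n_expressed,
                "weighting": t.weighting,
            }
        )
    return pd.DataFrame(
        rows, columns=["rank", "tissue", "ratio_dark_residues_pct", "n_expressed", "weighting"]
    )
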