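"""Bisulfite cloning-and-sequencing analysis.

Each clone derives from a single molecule, so its per-site calls are
binary (C only = methylated, T only = unmethylated).  Seven to nineteen
clones per sample give a per-site percent methylation, and pooling the
methylated/unmethylated site-calls over clones and samples supports a
group-level density contrast by Pearson chi-squared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CloneCallMatrix:
    """clones x sites binary call matrix; NaN marks missing calls."""

    sample_id: str
    strand: str
    matrix: pd.DataFrame  # index: clone ids, columns: site indices, values {0, 1, NaN}

    def __post_init__(self) -> None:
        if self.matrix.shape[0] < 1:
            raise ValueError("at least one clone required")
        vals = self.matrix.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            raise ValueError("clone calls must be 0, 1 or missing")

    @property
    def clone_count(self) -> int:
        return self.matrix.shape[0]


def percent_methylation(matrix: CloneCallMatrix) -> pd.Series:
    """Per-site methylated fraction: methylated / non-missing clones.

    Sites where every clone is missing are absent from the result (not 0).
    Missing entries are excluded from both numerator and denominator.
    """
    m = matrix.matrix.astype(float)
    frac = m.mean(axis=0, skipna=True)
    return frac.dropna()


def pooled_counts(matrices: Iterable[CloneCallMatrix]) -> tuple[int, int]:
    """(methylated, unmethylated) site-calls pooled over clones and samples."""
    meth = unmeth = 0
    for cm in matrices:
        vals = cm.matrix.to_numpy(dtype=float)
        meth += int(np.nansum(vals == 1.0))
        unmeth += int(np.nansum(vals == 0.0))
    return meth, unmeth


def pooled_density_test(group_a: Sequence[CloneCallMatrix],
                        group_b: Sequence[CloneCallMatrix]) -> dict:
    """2x2 Pearson chi-squared on pooled methylated/unmethylated counts."""
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    table = np.array([pooled_counts(group_a), pooled_counts(group_b)], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero-margin contingency table")
    if table[0, 0] / table[0].sum() == table[1, 0] / table[1].sum():
        # identical proportions: chi2 exactly 0 without relying on fp rounding
        return {"chi2": 0.0, "p": 1.0, "table": table.astype(int).tolist()}
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {"chi2": float(chi2), "p": float(p), "table": table.astype(int).tolist()}


CLONE_COLUMNS = ["sample_id", "strand", "clone_id"]


def write_clone_matrices(matrices: Sequence[CloneCallMatrix], path) -> None:
    sites = sorted({c for m in matrices for c in m.matrix.columns})
    rows = []
    for cm in matrices:
        for clone_id, r in cm.matrix.iterrows():
            row = {"sample_id": cm.sample_id, "strand": cm.strand, "clone_id": clone_id}
            for s in sites:
                v = r.get(s, np.nan)
                row[f"site_{s}"] = "NA" if pd.isna(v) else str(int(v))
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_clone_matrices(path) -> list[CloneCallMatrix]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "clone_id": str},
                     na_values=["NA"])
    site_cols = [c for c in df.columns if c.startswith("site_")]
    out = []
    for (sid, strand), grp in df.groupby(["sample_id", "strand"], sort=False):
        mat = grp.set_index("clone_id")[site_cols].astype(float)
        mat.columns = [int(c.split("_", 1)[1]) for c in site_cols]
        out.append(CloneCallMatrix(sid, strand, mat))
    return out
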