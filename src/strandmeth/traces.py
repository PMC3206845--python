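"""Chromatogram peak-ratio methylation calling.

Direct Sanger sequencing of a bisulfite PCR product reports, at every CpG,
a superposition of C signal (methylated molecules) and T signal
(unmethylated molecules).  The reference index classifies each site into
four density categories from the relative C/T peak heights:

    T only   C undetected, T detected    -> no methylation
    C <= T   both detected, C <= T       -> mC on < 10% of molecules
    C > T    both detected, C > T        -> mC on ~10-25%
    C only   C detected, T undetected    -> mC on ~25% or more

The fraction bands are calibration metadata established against
reconstituted methylated/unmethylated mixtures; classification itself uses
only the peak-comparison rules above.  A channel is "detected" when its
height exceeds the noise floor (by default 5% of the taller channel, with
an optional absolute floor).

Before any site is called, a conversion-efficiency gate checks that more
than 95% of non-CpG cytosines read as T: incomplete bisulfite conversion
is indistinguishable from methylation and such samples are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .genome import CpGSiteMap, STRANDS

logger = logging.getLogger(__name__)


class Category(str, Enum):
    T_ONLY = "T_ONLY"
    C_LE_T = "C_LE_T"
    C_GT_T = "C_GT_T"
    C_ONLY = "C_ONLY"
    MISSING = "x"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


#: ascending methylation-density order of the callable categories
DENSITY_ORDER = (Category.T_ONLY, Category.C_LE_T, Category.C_GT_T, Category.C_ONLY)


@dataclass(frozen=True)
class CalibrationIndex:
    """Detection thresholds and the fraction bands behind the four categories."""

    noise_floor_frac: float = 0.05   # relative to the taller channel
    noise_floor_abs: float = 0.0     # absolute fluorescence floor
    band_low: float = 0.10
    band_high: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 < self.band_low < self.band_high < 1.0:
            raise ValueError("band edges must satisfy 0 < low < high < 1")
        if self.noise_floor_frac < 0 or self.noise_floor_abs < 0:
            raise ValueError("noise floors must be nonnegative")

    def detected(self, height: float, other: float) -> bool:
        floor = max(self.noise_floor_abs, self.noise_floor_frac * max(height, other))
        return height > floor


def classify_site(height_C: float, height_T: float,
                  cal: CalibrationIndex | None = None) -> Category:
    """Classify one CpG from its C and T peak heights (ties -> C <= T)."""
    if cal is None:
        cal = CalibrationIndex()
    if height_C < 0 or height_T < 0:
        raise ValueError("peak heights must be nonnegative")
    c_det = cal.detected(height_C, height_T)
    t_det = cal.detected(height_T, height_C)
    if not c_det and not t_det:
        return Category.MISSING
    if not c_det:
        return Category.T_ONLY
    if not t_det:
        return Category.C_ONLY
    return Category.C_GT_T if height_C > height_T else Category.C_LE_T


def category_to_band(category: Category,
                     cal: CalibrationIndex | None = None) -> tuple[float, float]:
    """Methylated-fraction band (lo, hi) a category stands for.

    T_ONLY -> (0, 0); C_LE_T -> (0, low); C_GT_T -> [low, high); C_ONLY ->
    [high, 1].  MISSING has no band.
    """
    if cal is None:
        cal = CalibrationIndex()
    bands = {
        Category.T_ONLY: (0.0, 0.0),
        Category.C_LE_T: (0.0, cal.band_low),
        Category.C_GT_T: (cal.band_low, cal.band_high),
        Category.C_ONLY: (cal.band_high, 1.0),
    }
    if category not in bands:
        raise ValueError("MISSING has no methylated-fraction band")
    return bands[category]


PEAK_COLUMNS = ["sample_id", "strand", "template_pos", "ref_base",
                "height_C", "height_T", "is_cpg", "site_index"]


@dataclass
class PeakTable:
    """Per-position C/T peak heights for one sample and strand.

    ``ref_base`` is the pre-conversion template base; rows with
    ``ref_base == 'C'`` and ``is_cpg == False`` are the conversion-QC
    positions, rows with ``is_cpg == True`` carry a ``site_index``.
    """

    sample_id: str
    strand: str
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")
        df = self.rows
        missing = [c for c in ("template_pos", "ref_base", "height_C", "height_T", "is_cpg")
                   if c not in df.columns]
        if missing:
            raise ValueError(f"peak table missing columns {missing}")
        if (df["height_C"] < 0).any() or (df["height_T"] < 0).any():
            raise ValueError("peak heights must be nonnegative")
        self.rows = df.sort_values("template_pos", kind="stable").reset_index(drop=True)

    def to_frame(self) -> pd.DataFrame:
        df = self.rows.copy()
        df.insert(0, "sample_id", self.sample_id)
        df.insert(1, "strand", self.strand)
        return df[PEAK_COLUMNS]


def write_peak_tables(tables: Iterable[PeakTable], path) -> None:
    frames = [t.to_frame() for t in tables]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=PEAK_COLUMNS)
    out.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_peak_tables(path) -> list[PeakTable]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "strand": str})
    tables = []
    for (sid, strand), grp in df.groupby(["sample_id", "strand"], sort=False):
        tables.append(PeakTable(sid, strand, grp.drop(columns=["sample_id", "strand"])
                                .reset_index(drop=True)))
    return tables


def conversion_efficiency(peaks: PeakTable, cal: CalibrationIndex | None = None) -> float:
    """Fraction of non-CpG former-C positions fully converted (read as T)."""
    if cal is None:
        cal = CalibrationIndex()
    df = peaks.rows
    qc = df[(df["ref_base"] == "C") & (~df["is_cpg"].astype(bool))]
    if qc.empty:
        raise ValueError("no non-CpG cytosine positions; conversion QC undefined")
    converted = 0
    for _, r in qc.iterrows():
        hc, ht = float(r["height_C"]), float(r["height_T"])
        if not cal.detected(hc, ht) and cal.detected(ht, hc):
            converted += 1
    return converted / len(qc)


@dataclass
class CallVector:
    """Per-site categories for one sample/strand plus the QC verdict."""

    sample_id: str
    strand: str
    calls: dict[int, Category]
    qc_pass: bool
    conversion_rate: float

    def non_missing(self) -> dict[int, Category]:
        return {i: c for i, c in self.calls.items() if c != Category.MISSING}


def call_sample(peaks: PeakTable, site_map: CpGSiteMap,
                cal: CalibrationIndex | None = None,
                analyzed_range: Sequence[int] | None = None,
                qc_threshold: float = 0.95) -> CallVector:
    """Classify every analyzed site of one sample after the conversion gate.

    Samples with conversion efficiency <= ``qc_threshold`` (strictly-greater
    gate) are flagged ``qc_pass=False``; their calls are still returned but
    downstream tallies must exclude them.
    """
    if cal is None:
        cal = CalibrationIndex()
    if analyzed_range is None:
        analyzed_range = site_map.indices
    rate = conversion_efficiency(peaks, cal)
    df = peaks.rows
    cpg = df[df["is_cpg"].astype(bool)]
    by_site = {int(r["site_index"]): (float(r["height_C"]), float(r["height_T"]))
               for _, r in cpg.iterrows()}
    calls: dict[int, Category] = {}
    for i in analyzed_range:
        if i not in by_site:
            logger.debug("sample %s %s: no peak row for site %d -> MISSING",
                         peaks.sample_id, peaks.strand, i)
            calls[i] = Category.MISSING
        else:
            calls[i] = classify_site(*by_site[i], cal)
    return CallVector(peaks.sample_id, peaks.strand, calls, rate > qc_threshold, rate)


def write_call_vectors(vectors: Sequence[CallVector], path) -> None:
    if not vectors:
        raise ValueError("no call vectors to write")
    sites = sorted({i for v in vectors for i in v.calls})
    rows = []
    for v in vectors:
        row = {"sample_id": v.sample_id, "strand": v.strand,
               "qc_pass": int(v.qc_pass), "conversion_rate": round(v.conversion_rate, 6)}
        for i in sites:
            row[f"site_{i}"] = str(v.calls.get(i, Category.MISSING))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_call_vectors(path) -> list[CallVector]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    site_cols = [c for c in df.columns if c.startswith("site_")]
    out = []
    for _, r in df.iterrows():
        calls = {int(c.split("_", 1)[1]): Category(str(r[c])) for c in site_cols}
        out.append(CallVector(str(r["sample_id"]), str(r["strand"]), calls,
                              bool(int(r["qc_pass"])), float(r["conversion_rate"])))
    return out
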