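"""Quantitative methylation-specific PCR (qMSP) model.

A standard curve Cq = intercept + slope * log10(copies) is fitted to a
10-fold dilution series of fully methylated converted DNA; the slope
determines the amplification efficiency E = 10^(-1/slope) (E = 2 is
perfect doubling, costing log2(10) ~ 3.32 cycles per 10-fold dilution).
Sample Cq values are inverted through the curve to methylated-copy
estimates, censored at the assay's limit of detection (6 copies).  Input
is normalized to ~150 copies via a BS-actin assay that quantifies total
converted DNA independently of methylation (6 pg DNA per diploid cell),
and duplicate reactions are averaged.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_LOD_COPIES = 6.0
DEFAULT_INPUT_COPIES = 150.0

ASSAYS = ("sense", "antisense", "bs_actin")


@dataclass(frozen=True)
class DilutionSeries:
    assay_id: str
    copies: tuple[float, ...]
    cq: tuple[float, ...]
    dilution_factor: float = 10.0

    def __post_init__(self) -> None:
        if len(self.copies) != len(self.cq):
            raise ValueError("copies and cq must be the same length")
        if len(self.copies) < 3:
            raise ValueError("a dilution series needs at least 3 points")
        if any(c <= 0 for c in self.copies):
            raise ValueError("copy numbers must be positive")
        if len(set(self.copies)) < 2:
            raise ValueError("zero variance in copy numbers")


@dataclass(frozen=True)
class StandardCurve:
    slope: float            # cycles per log10(copies), negative
    intercept: float        # Cq at 1 copy
    r_squared: float = 1.0
    lod_copies: float = DEFAULT_LOD_COPIES
    cq_min: float | None = None  # calibrated Cq range (highest standard)
    cq_max: float | None = None  # lowest standard

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative")
        if self.lod_copies <= 0:
            raise ValueError("limit of detection must be positive")

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope)

    def predict_cq(self, copies: float) -> float:
        if copies <= 0:
            raise ValueError("cannot predict Cq for nonpositive copy number")
        return self.intercept + self.slope * math.log10(copies)

    def copies_from_cq(self, cq: float) -> float:
        return 10.0 ** ((cq - self.intercept) / self.slope)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"slope": self.slope, "intercept": self.intercept,
                       "efficiency": self.efficiency, "r_squared": self.r_squared,
                       "lod_copies": self.lod_copies,
                       "cq_min": self.cq_min, "cq_max": self.cq_max}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "StandardCurve":
        with open(path) as fh:
            d = json.load(fh)
        return cls(slope=d["slope"], intercept=d["intercept"],
                   r_squared=d.get("r_squared", 1.0),
                   lod_copies=d.get("lod_copies", DEFAULT_LOD_COPIES),
                   cq_min=d.get("cq_min"), cq_max=d.get("cq_max"))


def efficiency_to_slope(efficiency: float) -> float:
    """Inverse of the efficiency definition: slope = -1 / log10(E)."""
    if not 1.0 < efficiency <= 2.0 + 1e-9:
        raise ValueError("amplification efficiency must lie in (1, 2]")
    return -1.0 / math.log10(efficiency)


def fit_standard_curve(series: DilutionSeries,
                       lod_copies: float = DEFAULT_LOD_COPIES) -> StandardCurve:
    """Least-squares Cq ~ log10(copies) over the dilution points."""
    x = np.log10(np.asarray(series.copies, dtype=float))
    y = np.asarray(series.cq, dtype=float)
    res = stats.linregress(x, y)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue ** 2), lod_copies=lod_copies,
                         cq_min=float(y.min()), cq_max=float(y.max()))


@dataclass(frozen=True)
class MSPMeasurement:
    sample_id: str
    assay: str
    replicate: int
    cq: float | None  # None = not detected within the run

    def __post_init__(self) -> None:
        if self.cq is not None and self.cq <= 0:
            raise ValueError("Cq must be positive when present")


@dataclass(frozen=True)
class QuantResult:
    sample_id: str
    assay: str
    copies_per_assay: float   # censored to 0 below the limit of detection
    detected: bool
    input_copies: float = DEFAULT_INPUT_COPIES
    normalized_value: float = 0.0  # copies per 150 input copies


def quantify(m: MSPMeasurement, curve: StandardCurve,
             input_copies: float = DEFAULT_INPUT_COPIES,
             target_input: float = DEFAULT_INPUT_COPIES) -> QuantResult:
    """Invert a Cq through the standard curve, censoring below the LOD."""
    if m.cq is None:
        return QuantResult(m.sample_id, m.assay, 0.0, False, input_copies, 0.0)
    if curve.cq_min is not None and curve.cq_max is not None:
        if not (curve.cq_min - 1e-9 <= m.cq <= curve.cq_max + 1e-9):
            warnings.warn(f"Cq {m.cq:.2f} outside calibrated range "
                          f"[{curve.cq_min:.2f}, {curve.cq_max:.2f}]; extrapolating",
                          stacklevel=2)
    copies = curve.copies_from_cq(m.cq)
    # tolerance absorbs round-trip error of the log10/power inversion at the LOD
    detected = copies >= curve.lod_copies * (1.0 - 1e-9)
    censored = copies if detected else 0.0
    factor = normalize_input(input_copies, target_input)
    return QuantResult(m.sample_id, m.assay, censored, detected,
                       input_copies, censored * factor)


def normalize_input(bs_actin_copies: float,
                    target: float = DEFAULT_INPUT_COPIES) -> float:
    """Scaling factor bringing a sample's measured input to the target copies."""
    if bs_actin_copies <= 0:
        raise ValueError("BS-actin copy estimate must be positive")
    return target / bs_actin_copies


def mass_to_copies(mass_pg: float, pg_per_cell: float = 6.0,
                   copies_per_cell: int = 2) -> float:
    """Genome copies in a DNA mass, at 6 pg per (diploid) cell by default."""
    if mass_pg < 0:
        raise ValueError("DNA mass must be nonnegative")
    return mass_pg / pg_per_cell * copies_per_cell


def average_duplicates(a: QuantResult, b: QuantResult) -> QuantResult:
    """Mean of two replicate quantifications.

    A sample counts as "methylation detected" when either replicate reached
    the limit of detection; not-detected replicates contribute 0 to the
    averaged value.
    """
    if (a.sample_id, a.assay) != (b.sample_id, b.assay):
        raise ValueError("duplicates must share sample and assay")
    return QuantResult(a.sample_id, a.assay,
                       (a.copies_per_assay + b.copies_per_assay) / 2.0,
                       a.detected or b.detected,
                       (a.input_copies + b.input_copies) / 2.0,
                       (a.normalized_value + b.normalized_value) / 2.0)


# ---------------------------------------------------------------------------
# TSV interfaces

def write_dilution_series(series_list, path) -> None:
    rows = [{"assay_id": s.assay_id, "copies": c, "cq": round(q, 4)}
            for s in series_list for c, q in zip(s.copies, s.cq)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_dilution_series(path) -> list[DilutionSeries]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for assay_id, grp in df.groupby("assay_id", sort=False):
        grp = grp.sort_values("copies", ascending=False)
        out.append(DilutionSeries(str(assay_id), tuple(grp["copies"].astype(float)),
                                  tuple(grp["cq"].astype(float))))
    return out


def write_measurements(measurements, path) -> None:
    rows = [{"sample_id": m.sample_id, "assay": m.assay, "replicate": m.replicate,
             "cq": "" if m.cq is None else round(m.cq, 4)} for m in measurements]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_measurements(path) -> list[MSPMeasurement]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "assay": str})
    out = []
    for _, r in df.iterrows():
        cq = r["cq"]
        out.append(MSPMeasurement(str(r["sample_id"]), str(r["assay"]),
                                  int(r["replicate"]),
                                  None if pd.isna(cq) else float(cq)))
    return out
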