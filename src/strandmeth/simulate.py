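"""Synthetic cohorts and assay readouts.

The generator emulates the statistical structure the analysis assumes:

* liver-specific, antisense-biased CpG methylation — a zero-inflated
  low-level antisense background in every adult liver group, sense-strand
  methylation essentially confined to tumors (with a small field effect in
  adjacent tissue and an occasional symmetric cirrhotic sample), and no
  methylation at all in non-liver, fetal-liver or mouse-liver controls;
* Sanger chromatograms as per-position C/T peak heights, with a
  calibrated signal bias toward the methylated template (bisulfite PCR
  preferentially amplifies methylated molecules and the sequencer
  normalizes peaks), truncated Gaussian noise, a configurable residual
  conversion-failure rate at non-CpG cytosines, and unreadable antisense
  sites downstream of the post-conversion poly-T run;
* clone sampling (7-19 clones per sample, Bernoulli per site);
* qPCR with Poisson sampling of template molecules at low copy number,
  Cq noise around an ideal log-linear standard curve, and a BS-actin
  input assay around the nominal 150-copy input.

All randomness flows from the single config seed through named
``numpy.random.SeedSequence`` children spawned in a fixed order, so the
same config and seed reproduce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import (ANTISENSE, SENSE, STRANDS, BisulfiteTemplate, CpGSiteMap,
                     MethylationState, ReferenceRegion, bisulfite_convert,
                     enumerate_cpg_sites, flag_unreadable_sites)
from .msp import (DEFAULT_INPUT_COPIES, DEFAULT_LOD_COPIES, DilutionSeries,
                  MSPMeasurement, StandardCurve, efficiency_to_slope,
                  write_dilution_series, write_measurements)
from .traces import CalibrationIndex, PeakTable, write_peak_tables
from .clones import CloneCallMatrix, write_clone_matrices

DEFAULT_SIGNAL_BIAS = 70.0


# ---------------------------------------------------------------------------
# biology configuration

@dataclass(frozen=True)
class FractionModel:
    """Sample-level methylated-molecule fraction for one strand.

    With probability ``prevalence`` the sample is methylated and its
    fraction is drawn uniformly from [low, high]; otherwise the fraction
    is 0.
    """

    prevalence: float = 0.0
    low: float = 0.0
    high: float = 0.0

    def draw(self, rng: np.random.Generator) -> float:
        if self.prevalence > 0 and rng.random() < self.prevalence:
            return float(rng.uniform(self.low, self.high))
        return 0.0


UNMETHYLATED = FractionModel()

#: zero-inflated antisense background of adult liver tissue
LIVER_ANTISENSE_BACKGROUND = FractionModel(prevalence=0.85, low=0.0, high=0.12)


@dataclass(frozen=True)
class GroupBiology:
    """Mixture of (weight, sense model, antisense model) sample subtypes."""

    subtypes: tuple[tuple[float, FractionModel, FractionModel], ...]

    def draw(self, rng: np.random.Generator) -> tuple[float, float]:
        weights = np.array([w for w, _, _ in self.subtypes], dtype=float)
        k = rng.choice(len(self.subtypes), p=weights / weights.sum())
        _, s, a = self.subtypes[k]
        return s.draw(rng), a.draw(rng)


def default_biology() -> dict[str, GroupBiology]:
    one = lambda s, a: GroupBiology(((1.0, s, a),))
    return {
        "HCC": one(FractionModel(0.70, 0.10, 0.60), FractionModel(0.72, 0.10, 0.70)),
        "adjacent_non_HCC": one(FractionModel(0.30, 0.02, 0.10), LIVER_ANTISENSE_BACKGROUND),
        "normal_liver": one(UNMETHYLATED, LIVER_ANTISENSE_BACKGROUND),
        "hepatitis": one(UNMETHYLATED, LIVER_ANTISENSE_BACKGROUND),
        "cirrhosis": GroupBiology((
            (0.35, UNMETHYLATED, LIVER_ANTISENSE_BACKGROUND),   # antisense-biased
            (0.45, UNMETHYLATED, UNMETHYLATED),                  # no methylation
            (0.20, FractionModel(1.0, 0.05, 0.30), FractionModel(1.0, 0.05, 0.30)),
        )),
        "nonliver": one(UNMETHYLATED, UNMETHYLATED),
        "fetal_liver": one(UNMETHYLATED, UNMETHYLATED),
        "mouse_liver": one(UNMETHYLATED, UNMETHYLATED),
    }


def default_cohort_sizes() -> dict[str, int]:
    return {"HCC": 58, "adjacent_non_HCC": 58, "cirrhosis": 41,
            "hepatitis": 39, "normal_liver": 6}


def default_afp_params() -> dict[str, tuple[float, float]]:
    # log-normal (mu, sigma) of serum AFP in ng/mL; HCC shifted so ~42%
    # of tumors exceed the 20 ng/mL positivity cutoff
    hcc = (float(np.log(14.0)), 1.8)
    other = (float(np.log(3.0)), 1.2)
    return {g: (hcc if g == "HCC" else other)
            for g in ("HCC", "adjacent_non_HCC", "cirrhosis", "hepatitis",
                      "normal_liver", "nonliver", "fetal_liver", "mouse_liver")}


@dataclass
class GeneratorConfig:
    seed: int = 0
    cohort_sizes: dict[str, int] = field(default_factory=default_cohort_sizes)
    site_count: int = 30
    analyzed_range: tuple[int, int] = (1, 20)
    biology: dict[str, GroupBiology] = field(default_factory=default_biology)
    trace_noise_sd: float = 0.02
    conversion_failure_rate: float = 0.005
    signal_bias: float = DEFAULT_SIGNAL_BIAS
    max_qc_positions: int | None = None  # cap on emitted non-CpG C rows per trace
    clone_range: tuple[int, int] = (7, 19)
    clone_samples_per_group: dict[str, int] = field(
        default_factory=lambda: {"normal_liver": 4, "HCC": 4, "adjacent_non_HCC": 4})
    qpcr_efficiency: float = 2.0
    qpcr_intercept: float = 38.0  # Cq of a single template copy
    cq_noise_sd: float = 0.15
    poisson_sampling: bool = True
    lod_copies: float = DEFAULT_LOD_COPIES
    input_copies: float = DEFAULT_INPUT_COPIES
    input_copies_range: tuple[float, float] = (120.0, 180.0)
    afp_params: dict[str, tuple[float, float]] = field(default_factory=default_afp_params)
    afp_cutoff: float = 20.0
    region: ReferenceRegion | None = None


# ---------------------------------------------------------------------------
# reference construction

def make_synthetic_region(site_count: int = 30, seed: int | np.random.Generator = 0,
                          poly_purine_after_site: int | None = 20,
                          run_length: int = 16) -> ReferenceRegion:
    """A promoter-like sequence with ``site_count`` planted CpG sites.

    Spacers between sites carry no CG dinucleotide, so the planted sites
    are the only ones.  A purine (A/G) run inserted after the given site
    reads as a >= ``run_length`` poly-T on the converted antisense strand,
    reproducing the read truncation seen past site 20 in the APC region.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pieces = []
    for i in range(site_count):
        n = int(rng.integers(12, 21))
        spacer = list(rng.choice(list("ACGT"), size=n))
        for k in range(1, n):  # break any accidental CG inside the spacer
            if spacer[k - 1] == "C" and spacer[k] == "G":
                spacer[k] = "T"
        pieces.append("".join(spacer))
        pieces.append("CG")
        if poly_purine_after_site is not None and i + 1 == poly_purine_after_site:
            pieces.append("".join(rng.choice(list("AG"), size=run_length)))
    pieces.append("".join(rng.choice(list("AT"), size=10)))
    seq = "".join(pieces)
    return ReferenceRegion("SYNTH_REGION", seq, 1,
                           description="synthetic promoter-like CpG island region")


# ---------------------------------------------------------------------------
# reconstituted standards and chromatogram response

def make_reconstituted_standard(fraction: float, site_map: CpGSiteMap) -> MethylationState:
    """Defined mixture: every CpG methylated at ``fraction`` on both strands."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("mixture fraction must lie in [0, 1]")
    return MethylationState({s.index: fraction for s in site_map}, "symmetric")


def chromatogram_fraction(fraction: float, bias: float = DEFAULT_SIGNAL_BIAS) -> float:
    """Observed C-signal share for a molecule fraction under the signal bias.

    Bisulfite PCR amplification bias plus sequencer peak normalization make
    the C peak over-represented relative to the molar methylated fraction;
    the transfer f' = b*f / (b*f + 1 - f) with the default b calibrates the
    reference index so 10% mixtures read C>T and >=25% mixtures read C only.
    """
    if fraction <= 0.0:
        return 0.0
    if fraction >= 1.0:
        return 1.0
    return bias * fraction / (bias * fraction + 1.0 - fraction)


def min_detectable_fraction(cal: CalibrationIndex | None = None,
                            bias: float = DEFAULT_SIGNAL_BIAS) -> float:
    """Smallest molecule fraction whose C peak clears the noise floor."""
    if cal is None:
        cal = CalibrationIndex()
    c = cal.noise_floor_frac / (1.0 + cal.noise_floor_frac)  # f' must exceed this
    return c / (bias * (1.0 - c) + c)


# ---------------------------------------------------------------------------
# assay simulators

def simulate_trace(state: MethylationState, strand: str, region: ReferenceRegion,
                   site_map: CpGSiteMap, noise_sd: float = 0.0,
                   rng: np.random.Generator | None = None,
                   sample_id: str = "sample",
                   conversion_failure_rate: float = 0.0,
                   signal_bias: float = DEFAULT_SIGNAL_BIAS,
                   max_qc_positions: int | None = None) -> PeakTable:
    """Per-position C/T peak heights for direct sequencing of a population.

    Emits one row per former-C position of the chosen strand: CpG rows with
    the biased C-signal share of the population fraction, non-CpG rows with
    the residual conversion-failure signal.  Antisense sites past the
    poly-T truncation emit zero heights (read as missing).  Noise is
    Gaussian, truncated at zero.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if strand not in STRANDS:
        raise ValueError(f"unknown strand {strand!r}")
    if rng is None:
        rng = np.random.default_rng(0)
    state.validate_sites(site_map)
    fractions = state.strand_values(strand)
    length = len(region)
    seq = region.sequence if strand == SENSE else region.reverse_complement
    if strand == SENSE:
        cpg_pos = {site_map.site(i).sense_c_pos: i for i in site_map.indices}
    else:
        cpg_pos = {length - site_map.site(i).antisense_c_pos + 1: i
                   for i in site_map.indices}
    # read truncation from the fully-converted (unmethylated) template
    zero_state = MethylationState({i: 0.0 for i in site_map.indices}, "symmetric")
    template = bisulfite_convert(region, strand, zero_state, site_map)
    unreadable = template.unreadable_site_indices

    def noisy(x: float) -> float:
        return float(max(0.0, x + rng.normal(0.0, noise_sd))) if noise_sd > 0 else float(x)

    rows = []
    n_qc = 0
    for pos0, base in enumerate(seq):
        pos = pos0 + 1
        if base != "C":
            continue
        if pos in cpg_pos:
            site = cpg_pos[pos]
            if site in unreadable:
                hc = ht = 0.0
            else:
                share = chromatogram_fraction(fractions.get(site, 0.0), signal_bias)
                hc, ht = noisy(share), noisy(1.0 - share)
            rows.append((pos, "C", hc, ht, True, site))
        else:
            if max_qc_positions is not None and n_qc >= max_qc_positions:
                continue
            n_qc += 1
            hc = noisy(conversion_failure_rate)
            ht = noisy(1.0 - conversion_failure_rate)
            rows.append((pos, "C", hc, ht, False, np.nan))
    df = pd.DataFrame(rows, columns=["template_pos", "ref_base", "height_C",
                                     "height_T", "is_cpg", "site_index"])
    return PeakTable(sample_id, strand, df)


def simulate_clones(state: MethylationState, strand: str, n_clones: int,
                    rng: np.random.Generator | None = None,
                    sample_id: str = "sample",
                    site_subset: Sequence[int] | None = None) -> CloneCallMatrix:
    """Independent per-site Bernoulli draws with the population fraction."""
    if n_clones < 1:
        raise ValueError("at least one clone required")
    if rng is None:
        rng = np.random.default_rng(0)
    fractions = state.strand_values(strand)
    sites = list(site_subset) if site_subset is not None else sorted(fractions)
    p = np.array([fractions.get(s, 0.0) for s in sites], dtype=float)
    draws = (rng.random((n_clones, len(sites))) < p).astype(float)
    mat = pd.DataFrame(draws, columns=sites,
                       index=[f"{sample_id}_cl{k + 1}" for k in range(n_clones)])
    return CloneCallMatrix(sample_id, strand, mat)


def simulate_msp(true_copies: float, curve: StandardCurve,
                 rng: np.random.Generator | None = None,
                 cq_noise_sd: float = 0.0, poisson: bool = True) -> float | None:
    """One qPCR reaction: Poisson template sampling, then noisy log-linear Cq.

    Returns the Cq, or None when no template molecule entered the reaction
    (not detected).
    """
    if true_copies < 0:
        raise ValueError("true_copies must be nonnegative")
    if rng is None:
        rng = np.random.default_rng(0)
    templates = float(rng.poisson(true_copies)) if poisson else float(true_copies)
    if templates <= 0:
        return None
    cq = curve.predict_cq(templates)
    if cq_noise_sd > 0:
        cq += float(rng.normal(0.0, cq_noise_sd))
    return float(cq)


# ---------------------------------------------------------------------------
# full cohort

_GROUP_ABBREV = {"HCC": "T", "adjacent_non_HCC": "A", "cirrhosis": "C",
                 "hepatitis": "H", "normal_liver": "N", "nonliver": "X",
                 "fetal_liver": "F", "mouse_liver": "M"}

#: stage/grade frequencies of resected HCC (stage 1/2/3/4/unknown, grade 1/2/3/unknown)
_STAGE_P = (0.48, 0.36, 0.05, 0.02, 0.09)
_GRADE_P = (0.19, 0.57, 0.16, 0.08)


@dataclass
class Cohort:
    config: GeneratorConfig
    region: ReferenceRegion
    site_map: CpGSiteMap
    sample_sheet: pd.DataFrame
    truth: pd.DataFrame
    peak_tables: list[PeakTable] = field(default_factory=list)
    clone_matrices: list[CloneCallMatrix] = field(default_factory=list)
    msp_measurements: list[MSPMeasurement] = field(default_factory=list)
    dilution_series: list[DilutionSeries] = field(default_factory=list)
    curve: StandardCurve | None = None


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_cohort(config: GeneratorConfig,
                    include: Sequence[str] = ("traces", "clones", "msp")) -> Cohort:
    """Generate a complete, seed-reproducible cohort.

    ``include`` selects which assay readouts are simulated ("traces",
    "clones", "msp"); the sample sheet and truth table are always built.
    Randomness: one SeedSequence child per component (region, samples,
    traces, clones, msp, dilutions), spawned in that fixed order.
    """
    unknown = set(config.cohort_sizes) - set(_GROUP_ABBREV)
    if unknown:
        raise ValueError(f"unknown group names: {sorted(unknown)}")
    rng_region, rng_samples, rng_traces, rng_clones, rng_msp, rng_dil = _spawn(config.seed, 6)

    region = config.region or make_synthetic_region(config.site_count, rng_region)
    site_map = enumerate_cpg_sites(region)

    slope = efficiency_to_slope(config.qpcr_efficiency)
    curve = StandardCurve(slope=slope, intercept=config.qpcr_intercept,
                          lod_copies=config.lod_copies)

    # sample sheet + truth
    rows, truth_rows = [], []
    bsp_floor = min_detectable_fraction(bias=config.signal_bias)
    for group in sorted(config.cohort_sizes):
        biology = config.biology[group]
        mu, sigma = config.afp_params[group]
        for k in range(config.cohort_sizes[group]):
            sid = f"{_GROUP_ABBREV[group]}{k + 1}"
            f_s, f_a = biology.draw(rng_samples)
            age = float(np.round(rng_samples.normal(58.0, 12.0), 1))
            sex = "M" if rng_samples.random() < 0.62 else "F"
            hbv = bool(rng_samples.random() < (0.52 if group == "HCC" else 0.2))
            hcv = bool((not hbv) and rng_samples.random() < 0.4)
            if group == "HCC":
                stage = rng_samples.choice(["1", "2", "3", "4", "unknown"], p=_STAGE_P)
                grade = rng_samples.choice(["1", "2", "3", "unknown"], p=_GRADE_P)
                size = float(np.round(max(0.5, rng_samples.normal(5.9, 4.1)), 1))
            else:
                stage = grade = ""
                size = np.nan
            afp = float(np.round(np.exp(rng_samples.normal(mu, sigma)), 2))
            rows.append({"sample_id": sid, "group": group, "age": age, "sex": sex,
                         "hbv": int(hbv), "hcv": int(hcv), "stage": stage,
                         "grade": grade, "afp_ng_ml": afp, "tumor_size_cm": size})
            truth_rows.append({
                "sample_id": sid, "group": group,
                "sense_fraction": round(f_s, 6), "antisense_fraction": round(f_a, 6),
                "sense_msp_truth": int(config.input_copies * f_s >= config.lod_copies),
                "antisense_msp_truth": int(config.input_copies * f_a >= config.lod_copies),
                "sense_bsp_truth": int(f_s >= bsp_floor),
                "antisense_bsp_truth": int(f_a >= bsp_floor),
            })
    sheet = pd.DataFrame(rows, columns=["sample_id", "group", "age", "sex", "hbv",
                                        "hcv", "stage", "grade", "afp_ng_ml",
                                        "tumor_size_cm"])
    truth = pd.DataFrame(truth_rows)
    cohort = Cohort(config, region, site_map, sheet, truth, curve=curve)
    frac = {r["sample_id"]: (r["sense_fraction"], r["antisense_fraction"])
            for r in truth_rows}

    def state_for(sid: str) -> MethylationState:
        f_s, f_a = frac[sid]
        return MethylationState({i: f_s for i in site_map.indices}, "independent",
                                {i: f_a for i in site_map.indices})

    if "traces" in include:
        for sid in sheet["sample_id"]:
            for strand in STRANDS:
                cohort.peak_tables.append(simulate_trace(
                    state_for(sid), strand, region, site_map,
                    noise_sd=config.trace_noise_sd, rng=rng_traces, sample_id=sid,
                    conversion_failure_rate=config.conversion_failure_rate,
                    signal_bias=config.signal_bias,
                    max_qc_positions=config.max_qc_positions))

    if "clones" in include:
        lo, hi = config.clone_range
        for group, n_samples in sorted(config.clone_samples_per_group.items()):
            sids = sheet.loc[sheet["group"] == group, "sample_id"][:n_samples]
            for sid in sids:
                n_clones = int(rng_clones.integers(lo, hi + 1))
                cohort.clone_matrices.append(simulate_clones(
                    state_for(sid), ANTISENSE, n_clones, rng_clones, sample_id=sid,
                    site_subset=range(config.analyzed_range[0],
                                      config.analyzed_range[1] + 1)))

    if "msp" in include:
        lo, hi = config.input_copies_range
        for sid in sheet["sample_id"]:
            f_s, f_a = frac[sid]
            input_copies = float(rng_msp.uniform(lo, hi))
            targets = {"bs_actin": input_copies, "sense": input_copies * f_s,
                       "antisense": input_copies * f_a}
            for assay in ("bs_actin", "sense", "antisense"):
                for rep in (1, 2):
                    cq = simulate_msp(targets[assay], curve, rng_msp,
                                      config.cq_noise_sd, config.poisson_sampling)
                    cohort.msp_measurements.append(MSPMeasurement(sid, assay, rep, cq))
        # 10-fold dilution series per assay for standard-curve fitting
        copies = tuple(10.0 ** e for e in range(5, 0, -1))
        for assay in ("sense", "antisense", "bs_actin"):
            cq = tuple(curve.predict_cq(c) + float(rng_dil.normal(0, config.cq_noise_sd))
                       for c in copies)
            cohort.dilution_series.append(DilutionSeries(assay, copies, cq))
    return cohort


def write_cohort(cohort: Cohort, outdir) -> None:
    """Emit the cohort in the pipeline's TSV/FASTA input formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.region.to_fasta(out / "reference.fa")
    cohort.site_map.to_tsv(out / "site_map.tsv")
    cohort.sample_sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False,
                               float_format="%.2f")
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    for strand in STRANDS:
        tables = [t for t in cohort.peak_tables if t.strand == strand]
        if tables:
            write_peak_tables(tables, out / f"peaks_{strand}.tsv")
    if cohort.clone_matrices:
        write_clone_matrices(cohort.clone_matrices, out / "clones.tsv")
    if cohort.msp_measurements:
        write_measurements(cohort.msp_measurements, out / "msp_measurements.tsv")
    if cohort.dilution_series:
        write_dilution_series(cohort.dilution_series, out / "dilution_series.tsv")
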