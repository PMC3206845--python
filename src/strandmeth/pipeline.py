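"""End-to-end pipeline: QC -> calling -> tallies -> MSP -> biomarker report.

`run_pipeline` reads the TSV/FASTA inputs described by `RunConfig`,
executes every stage in order and returns (and optionally writes) a JSON
report.  All defaults are the study's stated constants: conversion QC
gate 0.95, BSP positivity at >= 50% of readable sites, qMSP limit of
detection 6 copies per assay, 150-copy normalized input, AFP cutoff
20 ng/mL, CpG sites 1-20 analyzed on both strands.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clones as clones_mod
from . import evaluate as ev
from .genome import ANTISENSE, SENSE, STRANDS, ReferenceRegion, enumerate_cpg_sites
from .msp import (DEFAULT_INPUT_COPIES, DEFAULT_LOD_COPIES, average_duplicates,
                  fit_standard_curve, quantify, read_dilution_series,
                  read_measurements)
from .traces import CalibrationIndex, call_sample, read_peak_tables, write_call_vectors

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    reference_fasta: str = "reference.fa"
    sample_sheet: str = "sample_sheet.tsv"
    peaks: dict[str, str] = field(default_factory=lambda: {
        SENSE: "peaks_sense.tsv", ANTISENSE: "peaks_antisense.tsv"})
    clones: str | None = "clones.tsv"
    msp_measurements: str | None = "msp_measurements.tsv"
    dilution_series: str | None = "dilution_series.tsv"
    input_dir: str = "."
    window: tuple[int, int] | None = None          # CpG enumeration window
    analyzed_range: tuple[int, int] = (1, 20)      # site indices, both strands
    qc_threshold: float = 0.95
    positivity_threshold: float = 0.5
    lod_copies: float = DEFAULT_LOD_COPIES
    input_copies: float = DEFAULT_INPUT_COPIES
    afp_cutoff: float = 20.0
    noise_floor_frac: float = 0.05
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.qc_threshold < 1.0:
            raise ValueError("qc_threshold must lie in (0, 1)")
        if not 0.0 < self.positivity_threshold <= 1.0:
            raise ValueError("positivity_threshold must lie in (0, 1]")
        if self.lod_copies <= 0 or self.input_copies <= 0:
            raise ValueError("lod_copies and input_copies must be positive")

    def path(self, name: str | None) -> Path | None:
        return None if name is None else Path(self.input_dir) / name

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        """Flat dotted-key JSON config; unknown keys rejected."""
        with open(path) as fh:
            raw = json.load(fh)
        kwargs = {}
        for key, value in raw.items():
            base = key.split(".", 1)
            if base[0] == "peaks" and len(base) == 2:
                kwargs.setdefault("peaks", {})[base[1]] = value
            else:
                kwargs[key] = tuple(value) if isinstance(value, list) else value
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    return obj


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute all stages and return the evaluation report.

    When ``out_dir`` is given, writes ``report.json`` plus TSV summaries
    (call vectors and per-sample marker table) there.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    cal = CalibrationIndex(noise_floor_frac=config.noise_floor_frac)
    region = ReferenceRegion.from_fasta(config.path(config.reference_fasta))
    if config.window:
        site_map = enumerate_cpg_sites(region, *config.window)
    else:
        site_map = enumerate_cpg_sites(region)
    sheet = pd.read_csv(config.path(config.sample_sheet), sep="\t",
                        dtype={"sample_id": str})
    if sheet.empty:
        raise ValueError("empty cohort: sample sheet has no rows")
    groups = dict(zip(sheet["sample_id"], sheet["group"]))
    report: dict = {"config": {k: v for k, v in dataclasses.asdict(config).items()},
                    "n_samples": int(len(sheet)),
                    "n_cpg_sites": len(site_map)}

    analyzed = range(config.analyzed_range[0], config.analyzed_range[1] + 1)

    # --- stage 1: conversion QC + reference-index calling -----------------
    vectors = {s: [] for s in STRANDS}
    for strand in STRANDS:
        path = config.path(config.peaks.get(strand))
        if path is None or not path.exists():
            continue
        for peaks in read_peak_tables(path):
            v = call_sample(peaks, site_map, cal, analyzed, config.qc_threshold)
            if not v.qc_pass:
                logger.info("sample %s (%s) failed conversion QC (%.3f), excluded",
                            v.sample_id, strand, v.conversion_rate)
            vectors[strand].append(v)
    all_vectors = vectors[SENSE] + vectors[ANTISENSE]
    if all_vectors and not any(v.qc_pass for v in all_vectors):
        raise ValueError("no samples passed QC")
    report["qc"] = {
        strand: {v.sample_id: {"qc_pass": bool(v.qc_pass),
                               "conversion_rate": v.conversion_rate}
                 for v in vectors[strand]} for strand in STRANDS}

    # --- stage 2: density tallies + chi-squared contrasts -----------------
    tallies = {}
    chi2 = {}
    for strand in STRANDS:
        vs = [v for v in vectors[strand] if v.qc_pass]
        if not vs:
            continue
        for mode in ("all_available", "complete_cases"):
            tally = ev.density_tally(vs, groups, mode=mode)
            tallies[f"{strand}.{mode}"] = tally.to_dict()
            for other in ("normal_liver", "adjacent_non_HCC"):
                if "HCC" in tally.index and other in tally.index:
                    cats = [c.name for c in
                            (ev.Category.T_ONLY, ev.Category.C_LE_T,
                             ev.Category.C_GT_T, ev.Category.C_ONLY)]
                    sub = tally.loc[["HCC", other], cats]
                    sub = sub.loc[:, (sub.sum(axis=0) > 0)]
                    try:
                        chi2[f"{strand}.{mode}.HCC_vs_{other}"] = ev.pearson_chi2(sub)
                    except ValueError as exc:
                        logger.warning("chi2 skipped (%s): %s", other, exc)
    report["density_tallies"] = tallies
    report["density_chi2"] = chi2

    # --- stage 3: clone analysis ------------------------------------------
    clone_path = config.path(config.clones)
    if clone_path is not None and clone_path.exists():
        matrices = clones_mod.read_clone_matrices(clone_path)
        per_sample = {m.sample_id: clones_mod.percent_methylation(m).round(6).to_dict()
                      for m in matrices}
        clone_report = {"percent_methylation": per_sample}
        by_group: dict[str, list] = {}
        for m in matrices:
            by_group.setdefault(groups.get(m.sample_id, "?"), []).append(m)
        for other in ("normal_liver", "adjacent_non_HCC"):
            if "HCC" in by_group and other in by_group:
                try:
                    clone_report[f"HCC_vs_{other}"] = clones_mod.pooled_density_test(
                        by_group["HCC"], by_group[other])
                except ValueError as exc:
                    logger.warning("clone density test skipped: %s", exc)
        report["clones"] = clone_report

    # --- stage 4: MSP quantification --------------------------------------
    marker_table = None
    msp_path = config.path(config.msp_measurements)
    if msp_path is not None and msp_path.exists():
        series = read_dilution_series(config.path(config.dilution_series))
        curves = {s.assay_id: fit_standard_curve(s, config.lod_copies) for s in series}
        report["standard_curves"] = {
            a: {"slope": c.slope, "intercept": c.intercept,
                "efficiency": c.efficiency, "r_squared": c.r_squared}
            for a, c in curves.items()}
        measurements = read_measurements(msp_path)
        by_sample: dict[str, dict[str, list]] = {}
        for m in measurements:
            by_sample.setdefault(m.sample_id, {}).setdefault(m.assay, []).append(m)
        rows = []
        import warnings as _warnings
        extrapolated = 0
        for sid, assays in by_sample.items():
            actin = assays.get("bs_actin", [])
            actin_copies = [curves["bs_actin"].copies_from_cq(m.cq)
                            for m in actin if m.cq is not None]
            if not actin_copies:
                logger.warning("sample %s: no BS-actin signal, MSP skipped", sid)
                continue
            input_est = float(np.mean(actin_copies))
            row = {"sample_id": sid, "group": groups.get(sid, "?"),
                   "input_copies": input_est}
            for assay in ("sense", "antisense"):
                reps = sorted(assays.get(assay, []), key=lambda m: m.replicate)
                if not reps:
                    continue
                with _warnings.catch_warnings(record=True) as caught:
                    _warnings.simplefilter("always")
                    quants = [quantify(m, curves[assay], input_est,
                                       config.input_copies) for m in reps]
                extrapolated += len(caught)
                q = quants[0]
                for other_q in quants[1:]:
                    q = average_duplicates(q, other_q)
                row[f"{assay}_copies"] = q.normalized_value
                row[f"{assay}_detected"] = bool(q.detected)
            rows.append(row)
        if extrapolated:
            logger.info("%d reactions quantified below the lowest standard "
                        "(extrapolated toward the limit of detection)", extrapolated)
        marker_table = pd.DataFrame(rows)
    # --- stage 5: biomarker evaluation -------------------------------------
    evaluation: dict = {}
    bsp = {}
    for strand in STRANDS:
        vs = [v for v in vectors[strand] if v.qc_pass and v.non_missing()]
        if not vs:
            continue
        calls = [ev.bsp_positive(v, config.positivity_threshold) for v in vs]
        labels = [groups[v.sample_id] == "HCC" for v in vs]
        if any(labels) and not all(labels):
            bsp[strand] = ev.sensitivity_specificity(calls, labels)
            bsp[strand]["n"] = len(vs)
    if bsp:
        evaluation["bsp"] = bsp

    if marker_table is not None and not marker_table.empty:
        mt = marker_table[marker_table["group"].isin(("HCC",) + ev.NON_HCC_GROUPS)]
        is_hcc = (mt["group"] == "HCC").to_numpy()
        msp_eval: dict = {}
        for strand in STRANDS:
            if f"{strand}_detected" not in mt:
                continue
            calls = mt[f"{strand}_detected"].astype(bool).to_numpy()
            msp_eval[strand] = ev.sensitivity_specificity(calls, is_hcc)
            r = ev.roc(mt[f"{strand}_copies"].to_numpy(), is_hcc)
            msp_eval[strand]["auroc"] = r.auroc
        if {"sense_copies", "antisense_copies"} <= set(mt.columns):
            msp_eval["roc_comparison"] = ev.compare_roc(
                mt["sense_copies"], mt["antisense_copies"], is_hcc)
        evaluation["msp"] = msp_eval

        hcc = mt[mt["group"] == "HCC"].merge(sheet[["sample_id", "afp_ng_ml"]],
                                             on="sample_id")
        hcc = hcc.dropna(subset=["afp_ng_ml"])
        if len(hcc) and "sense_detected" in hcc:
            records = hcc.rename(columns={"sense_detected": "mapc_positive"})
            evaluation["combined_marker"] = ev.combined_marker(records,
                                                               config.afp_cutoff)
        cohort = sheet.merge(
            mt[["sample_id"] + [c for c in ("sense_copies",) if c in mt.columns]],
            on="sample_id", how="inner").rename(columns={"sense_copies":
                                                         "sense_msp_value"})
        if "sense_msp_value" in cohort and (cohort["group"] == "HCC").any():
            evaluation["group_tests"] = ev.group_tests(cohort, config.afp_cutoff)
    report["evaluation"] = evaluation

    report = _round_floats(report)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
        if all_vectors:
            write_call_vectors(all_vectors, out / "call_vectors.tsv")
        if marker_table is not None:
            marker_table.to_csv(out / "marker_table.tsv", sep="\t", index=False,
                                float_format="%.4f")
    return report
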