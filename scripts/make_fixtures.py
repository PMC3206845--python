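"""Regenerate the shipped example cohort under fixtures/.

A small but complete synthetic cohort (all groups, every assay readout)
written with a fixed seed; re-running this script reproduces the files
byte for byte.  Usage: python scripts/make_fixtures.py
"""

from pathlib import Path

from strandmeth.simulate import GeneratorConfig, generate_cohort, write_cohort

FIXTURE_SEED = 20110

CONFIG = GeneratorConfig(
    seed=FIXTURE_SEED,
    cohort_sizes={"HCC": 5, "adjacent_non_HCC": 5, "cirrhosis": 4,
                  "hepatitis": 4, "normal_liver": 3, "nonliver": 2,
                  "mouse_liver": 1},
    clone_samples_per_group={"normal_liver": 2, "HCC": 2, "adjacent_non_HCC": 2},
    max_qc_positions=25,  # keeps the shipped peak tables small
)


def main() -> None:
    outdir = Path(__file__).resolve().parent.parent / "fixtures" / "example_cohort"
    cohort = generate_cohort(CONFIG)
    write_cohort(cohort, outdir)
    print(f"wrote fixture cohort ({len(cohort.sample_sheet)} samples) to {outdir}")


if __name__ == "__main__":
    main()
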