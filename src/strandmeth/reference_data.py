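"""Published summary counts from the strand-resolved APC methylation study.

The original tissue study reported, for the antisense strand over CpG
sites 1-20, that 46.1% (295/640) of HCC site calls were "C only", 5.4%
(29/542) in matched adjacent non-HCC tissue, and 0/295 in pooled normal,
hepatitis and cirrhosis livers; and, for the 53 AFP-evaluable HCC cases,
35 positive for sense-strand methylation of which 21 were AFP-negative,
with 23 AFP-positive overall.

Per-sample calls were published only graphically, so this module expands
the printed counts into synthetic-but-count-exact inputs: the C-only
counts, per-group totals and missing-call counts are exact, while the
split of the remaining calls across T only / C<=T / C>T is an arbitrary
deterministic fill.  Only quantities derived from the C-only fractions,
the totals and the quadrant counts should be asserted against them.
"""

from __future__ import annotations

import itertools

import pandas as pd

from .genome import ANTISENSE
from .traces import CallVector, Category

#: antisense-strand category tallies over CpG sites 1-20 (20 sites/sample):
#: group -> (n_samples, c_only_calls, readable_calls)
ANTISENSE_TALLIES = {
    "HCC": (32, 295, 640),
    "adjacent_non_HCC": (32, 29, 542),
    "pooled_control": (16, 0, 295),  # normal (6) + hepatitis (4) + cirrhosis (6)
}

#: combined-marker quadrants among the 53 AFP-evaluable HCC cases:
#: (mAPC positive, AFP >= 20 ng/mL) -> count
COMBINED_MARKER_QUADRANTS = {
    (True, True): 14,
    (True, False): 21,
    (False, True): 9,
    (False, False): 9,
}

_SITES = tuple(range(1, 21))
_FILL = (Category.T_ONLY, Category.C_LE_T, Category.C_GT_T)


def antisense_call_vectors() -> tuple[list[CallVector], dict[str, str]]:
    """Call vectors whose per-group tallies reproduce the printed counts.

    Returns the vectors and a sample_id -> group mapping suitable for
    :func:`strandmeth.evaluate.density_tally`.
    """
    vectors: list[CallVector] = []
    groups: dict[str, str] = {}
    for group, (n_samples, n_c_only, n_readable) in ANTISENSE_TALLIES.items():
        total = n_samples * len(_SITES)
        n_missing = total - n_readable
        n_other = n_readable - n_c_only
        # deterministic flat layout: C only first, then a round-robin fill
        # of the unpublished remainder, missing calls last
        fill = itertools.cycle(_FILL)
        cats = ([Category.C_ONLY] * n_c_only
                + [next(fill) for _ in range(n_other)]
                + [Category.MISSING] * n_missing)
        it = iter(cats)
        for k in range(n_samples):
            sid = f"{group}_{k + 1}"
            calls = {site: next(it) for site in _SITES}
            vectors.append(CallVector(sid, ANTISENSE, calls, True, 1.0))
            groups[sid] = group
    return vectors, groups


def combined_marker_records() -> pd.DataFrame:
    """The 53 AFP-evaluable HCC cases as a combined-marker input table.

    AFP values are synthetic placeholders on the correct side of the
    20 ng/mL cutoff; only the quadrant counts are faithful.
    """
    rows = []
    k = 0
    for (mapc, afp_pos), n in COMBINED_MARKER_QUADRANTS.items():
        for _ in range(n):
            k += 1
            rows.append({"sample_id": f"HCC_{k}", "mapc_positive": mapc,
                         "afp_ng_ml": 150.0 if afp_pos else 5.0,
                         "mapc_value": 40.0 if mapc else 0.0})
    return pd.DataFrame(rows)
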