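"""Built-in concentration–response functions (CRFs) for PM2.5 and
hospital admissions.

Two CRF families are shipped, both expressed as rate ratios per 10 µg/m³
increase in 2-day average PM2.5:

* wildfire-specific (``WF``) — from an epidemiological study of the 2003
  southern California wildfires, with age strata for respiratory admissions
  and age/sex strata for asthma;
* ambient, non-wildfire (``NF``) — from a multi-county U.S. study of ambient
  PM2.5, respiratory and cardiovascular, all ages.

The NF rate ratios are stored at the precision of the source percentages
(2.07% → RR 1.0207), not their two-decimal rounding.
"""

from __future__ import annotations

import pandas as pd

from .hia_core import CRFSpec

WILDFIRE_CRFS: tuple[CRFSpec, ...] = (
    CRFSpec("respiratory", "all", "WF", 1.028, 1.014, 1.041),
    CRFSpec("respiratory", "ages_0_4", "WF", 1.045, 1.010, 1.082),
    CRFSpec("respiratory", "ages_5_19", "WF", 1.027, 0.984, 1.076),
    CRFSpec("respiratory", "ages_20_64", "WF", 1.024, 1.005, 1.044),
    CRFSpec("respiratory", "ages_65_99", "WF", 1.030, 1.011, 1.049),
    CRFSpec("cardiovascular", "all", "WF", 1.008, 0.999, 1.018),
    CRFSpec("asthma", "all", "WF", 1.048, 1.021, 1.076),
    CRFSpec("asthma", "male", "WF", 1.031, 0.990, 1.073),
    CRFSpec("asthma", "female", "WF", 1.059, 1.022, 1.097),
    CRFSpec("asthma", "ages_0_4", "WF", 1.083, 1.021, 1.149),
    CRFSpec("asthma", "ages_5_19", "WF", 0.999, 0.935, 1.068),
    CRFSpec("asthma", "ages_20_64", "WF", 1.041, 0.995, 1.090),
    CRFSpec("asthma", "ages_65_99", "WF", 1.101, 1.030, 1.178),
)

NONFIRE_CRFS: tuple[CRFSpec, ...] = (
    CRFSpec("respiratory", "all", "NF", 1.0207, 1.0120, 1.0295),
    CRFSpec("cardiovascular", "all", "NF", 1.0189, 1.0134, 1.0245),
)

ALL_CRFS: tuple[CRFSpec, ...] = WILDFIRE_CRFS + NONFIRE_CRFS


def get_crf(outcome: str, crf_type: str = "WF", subgroup: str = "all") -> CRFSpec:
    """Look up a built-in CRF by outcome, type (WF/NF) and subgroup."""
    for crf in ALL_CRFS:
        if (crf.outcome, crf.crf_type, crf.subgroup) == (outcome, crf_type, subgroup):
            return crf
    raise KeyError(f"no built-in CRF for {outcome}/{crf_type}/{subgroup}")


def crf_table(crfs: tuple[CRFSpec, ...] = ALL_CRFS) -> pd.DataFrame:
    """CRF set as a DataFrame (one row per outcome/subgroup/type)."""
    return pd.DataFrame(
        [
            {
                "outcome": c.outcome, "subgroup": c.subgroup, "crf_type": c.crf_type,
                "rr": c.rr, "rr_lo": c.rr_lo, "rr_hi": c.rr_hi,
                "increment": c.increment, "window": c.averaging_window,
            }
            for c in crfs
        ]
    )


def crfs_from_table(df: pd.DataFrame) -> list[CRFSpec]:
    """Parse a CRF table (see :func:`crf_table` for columns) into specs."""
    return [
        CRFSpec(
            outcome=row["outcome"], subgroup=row["subgroup"],
            crf_type=row["crf_type"], rr=float(row["rr"]),
            rr_lo=float(row["rr_lo"]), rr_hi=float(row["rr_hi"]),
            increment=float(row.get("increment", 10.0)),
            averaging_window=int(row.get("window", 2)),
        )
        for _, row in df.iterrows()
    ]
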