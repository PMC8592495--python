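"""Shared stratum definitions: age bands, sexes, deprivation quintiles.

Conventions used throughout the package:

* age bands are nine five-year groups from "50-54" to "85-89" plus "90+";
* sex is encoded as the strings ``"female"`` / ``"male"``;
* area deprivation (IMD) quintile is an integer 1..5 with **1 = most
  deprived** (lower IMD rank = greater deprivation).
"""

from __future__ import annotations

import itertools

import pandas as pd

AGE_BANDS: tuple[str, ...] = (
    "50-54",
    "55-59",
    "60-64",
    "65-69",
    "70-74",
    "75-79",
    "80-84",
    "85-89",
    "90+",
)

SEXES: tuple[str, ...] = ("female", "male")

N_QUINTILES: int = 5
QUINTILES: tuple[int, ...] = tuple(range(1, N_QUINTILES + 1))

#: Ordered frailty categories (robust < pre_frail < frail).
CATEGORIES: tuple[str, ...] = ("robust", "pre_frail", "frail")


def age_band_index(band: str) -> int:
    """Return the 0-based index of an age band, raising on unknown labels."""
    try:
        return AGE_BANDS.index(band)
    except ValueError:
        raise ValueError(
            f"unknown age band {band!r}; expected one of {list(AGE_BANDS)}"
        ) from None


def stratum_grid() -> pd.DataFrame:
    """All 90 (age band, sex, IMD quintile) strata as a DataFrame.

    Row order is the cartesian product age band x sex x quintile with age
    varying slowest, matching the order used by model prediction tables.
    """
    rows = itertools.product(AGE_BANDS, SEXES, QUINTILES)
    return pd.DataFrame(rows, columns=["age_band", "sex", "imd_quintile"])
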