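"""Built-in worked-example data.

``serum_pool_example`` is a published copy-number table from pooled serum
small-RNA sequencing of a three-group colorectal-cancer cohort (healthy,
non-metastatic tumor, metastatic), two pooled replicates per group; values
are average copy numbers per pool replicate, so fold changes computed from
it use raw mode.  ``STOOL_MEAN_CONTROL`` / ``STOOL_MEAN_CRC`` are the group
mean read counts of the same miRNA of interest from a stool sequencing
cohort.  These small tables drive the package's worked examples and
regression checks.
"""
from __future__ import annotations

import pandas as pd

from .pool import PoolCountTable

__all__ = ["serum_pool_example", "STOOL_MEAN_CONTROL", "STOOL_MEAN_CRC", "MIRNA_OF_INTEREST"]

MIRNA_OF_INTEREST = "hsa-miR-486-5p"

# group mean read counts of hsa-miR-486-5p in stool sequencing
STOOL_MEAN_CONTROL = 43.65
STOOL_MEAN_CRC = 223.67

# columns: metastatic_1, metastatic_2, tumor_1, tumor_2, healthy_1, healthy_2
_SERUM_ROWS = {
    "hsa-miR-3614-5p": (588.15, 602.64, 0.0, 0.0, 0.0, 0.0),
    "hsa-miR-1247-5p": (923.17, 124.99, 0.0, 0.0, 0.0, 0.0),
    "hsa-miR-26b-3p": (405.75, 0.0, 693.60, 0.0, 0.0, 0.0),
    "hsa-miR-370-3p": (930.61, 138.38, 0.0, 0.0, 0.0, 0.0),
    "hsa-miR-371b-5p": (655.15, 196.42, 0.0, 0.0, 0.0, 0.0),
    "hsa-miR-92a-1-5p": (201.01, 620.50, 0.0, 0.0, 0.0, 0.0),
    "hsa-miR-1343-3p": (0.0, 178.56, 0.0, 449.91, 0.0, 0.0),
    "hsa-let-7b-3p": (450.42, 111.60, 0.0, 0.0, 0.0, 0.0),
    "hsa-miR-3130-5p": (171.23, 0.0, 610.03, 0.0, 0.0, 0.0),
    "hsa-miR-93-5p": (23101.53, 21016.67, 18685.45, 26506.86, 47283.15, 57832.90),
    "hsa-miR-223-3p": (355620.64, 417538.85, 288671.90, 294471.36, 175026.35, 162243.02),
    "hsa-miR-431-5p": (0.0, 0.0, 0.0, 0.0, 660.62, 748.75),
    "hsa-miR-320a": (129310.50, 120542.28, 57794.55, 53603.04, 191473.93, 241138.63),
    "hsa-miR-486-5p": (708832.85, 796133.48, 937832.71, 815698.98, 1422293.08, 1307148.95),
    "hsa-miR-628-3p": (416.91, 437.47, 434.54, 183.78, 0.0, 0.0),
    "hsa-miR-7-1-3p": (0.0, 441.94, 626.75, 1184.98, 0.0, 0.0),
}

_SERUM_SAMPLES = [
    ("metastatic_1", "metastatic"),
    ("metastatic_2", "metastatic"),
    ("tumor_1", "tumor"),
    ("tumor_2", "tumor"),
    ("healthy_1", "healthy"),
    ("healthy_2", "healthy"),
]


def serum_pool_example() -> PoolCountTable:
    """The serum pooled-sequencing worked-example count table."""
    counts = pd.DataFrame.from_dict(
        _SERUM_ROWS, orient="index", columns=[s for s, _ in _SERUM_SAMPLES]
    )
    groups = pd.Series({s: g for s, g in _SERUM_SAMPLES})
    return PoolCountTable(counts=counts, groups=groups)
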