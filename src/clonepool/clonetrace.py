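"""Clone-level lineage tracing via library-ID read fractions.

Each library ID tags one clonal line, so the fraction of a sample's reads
carrying an ID measures that clone's relative abundance. Trajectories are
the per-arm fractions normalized to the day-0 (baseline) fraction of the
same clone. Fractions are computed from raw (pre-collapse) accepted reads;
ID tracing needs no barcode correction.
"""

from __future__ import annotations

import pandas as pd

from .errors import DataError
from .tables import BarcodeCountTable, parse_sample


def id_fractions(table: BarcodeCountTable, sample: str) -> pd.Series:
    """Read fraction per library ID in one sample (sums to 1)."""
    if sample not in table.samples:
        raise DataError(f"unknown sample {sample!r}")
    sums = table.df.groupby("library_id")[sample].sum()
    total = sums.sum()
    if total <= 0:
        raise DataError(f"sample {sample!r} has zero total reads")
    return sums / total


def fraction_table(table: BarcodeCountTable) -> pd.DataFrame:
    """Tidy (library_id, arm, day, fraction) over all samples."""
    rows = []
    for s in table.samples:
        arm, day = parse_sample(s)
        fr = id_fractions(table, s)
        for lib, f in fr.items():
            rows.append((lib, arm, day, f))
    return pd.DataFrame(rows, columns=["library_id", "arm", "day", "fraction"])


def normalize_to_baseline(fractions: pd.DataFrame, baseline_day: int = 0) -> pd.DataFrame:
    """Divide each (library_id, arm, day) fraction by the same clone and
    arm's baseline-day fraction; adds a ``normalized`` column."""
    out = fractions.copy()
    base = fractions[fractions["day"] == baseline_day].set_index(["library_id", "arm"])[
        "fraction"
    ]
    if base.empty:
        raise DataError(f"no baseline (day {baseline_day}) samples present")
    if (base <= 0).any():
        bad = base[base <= 0].index.tolist()
        raise DataError(f"zero baseline fraction; trajectory undefined for {bad}")
    key = list(zip(out["library_id"], out["arm"]))
    missing = [k for k in set(key) if k not in base.index]
    if missing:
        raise DataError(f"no baseline fraction for {sorted(missing)}")
    out["normalized"] = out["fraction"].to_numpy() / base.loc[key].to_numpy()
    return out


def clone_trajectories(table: BarcodeCountTable, baseline_day: int = 0) -> pd.DataFrame:
    """ID read fractions per sample, normalized to the baseline day."""
    return normalize_to_baseline(fraction_table(table), baseline_day)
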