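"""Barcode-level count tables.

The central object of the pipeline is a table of read counts keyed by
``(library_id, sgrna, barcode)`` with one integer column per sample. Samples
are named ``<arm>_d<day>`` (e.g. ``treated_d14``); the day-0 samples act as
the baseline. The ``gene`` column is carried along for downstream gene-level
statistics.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError

KEY_COLS = ["library_id", "sgrna", "gene", "barcode"]

_SAMPLE_RE = re.compile(r"^(?P<arm>[A-Za-z]+)_d(?P<day>\d+)$")


def parse_sample(name: str) -> tuple[str, int]:
    """Split a sample name ``<arm>_d<day>`` into ``(arm, day)``."""
    m = _SAMPLE_RE.match(name)
    if m is None:
        raise DataError(f"sample name {name!r} does not follow '<arm>_d<day>'")
    return m.group("arm"), int(m.group("day"))


def sample_name(arm: str, day: int) -> str:
    return f"{arm}_d{day}"


class BarcodeCountTable:
    """Counts keyed by (library_id, sgrna, barcode) across samples.

    Parameters
    ----------
    df:
        DataFrame containing the key columns ``library_id, sgrna, gene,
        barcode`` plus one integer column per sample.
    samples:
        Explicit sample column order; defaults to every non-key column.
    """

    def __init__(self, df: pd.DataFrame, samples: Iterable[str] | None = None):
        missing = [c for c in KEY_COLS if c not in df.columns]
        if missing:
            raise DataError(f"count table is missing key columns: {missing}")
        if samples is None:
            samples = [c for c in df.columns if c not in KEY_COLS]
        samples = list(samples)
        if not samples:
            raise DataError("count table has no sample columns")
        self.df = df[KEY_COLS + samples].reset_index(drop=True)
        self.samples = samples

    # -- basic container behaviour ------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"BarcodeCountTable({len(self)} rows x {len(self.samples)} samples)"

    def copy(self) -> "BarcodeCountTable":
        return BarcodeCountTable(self.df.copy(), self.samples)

    def sorted(self) -> "BarcodeCountTable":
        """Canonical row order (stable sort on the key columns)."""
        df = self.df.sort_values(KEY_COLS, kind="mergesort").reset_index(drop=True)
        return BarcodeCountTable(df, self.samples)

    def equals(self, other: "BarcodeCountTable") -> bool:
        if self.samples != other.samples:
            return False
        a = self.sorted().df
        b = other.sorted().df
        if len(a) != len(b):
            return False
        if not a[KEY_COLS].reset_index(drop=True).equals(b[KEY_COLS].reset_index(drop=True)):
            return False
        return bool(
            np.array_equal(
                a[self.samples].to_numpy(dtype=np.int64),
                b[self.samples].to_numpy(dtype=np.int64),
            )
        )

    def sample_totals(self) -> pd.Series:
        return self.df[self.samples].sum()

    def subset_samples(self, samples: list[str]) -> "BarcodeCountTable":
        missing = [s for s in samples if s not in self.samples]
        if missing:
            raise DataError(f"unknown samples: {missing}")
        return BarcodeCountTable(self.df[KEY_COLS + samples], samples)

    def subset_library(self, library_id: str) -> "BarcodeCountTable":
        df = self.df[self.df["library_id"] == library_id]
        if df.empty:
            raise DataError(f"no rows for library ID {library_id!r}")
        return BarcodeCountTable(df.reset_index(drop=True), self.samples)

    # -- I/O ------------------------------------------------------------
    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "BarcodeCountTable":
        df = pd.read_csv(path, sep="\t", dtype={"library_id": str, "sgrna": str,
                                                "gene": str, "barcode": str})
        return cls(df)

    # -- construction ----------------------------------------------------
    @classmethod
    def from_sample_counts(
        cls,
        sample_counts: Mapping[str, Mapping[tuple[str, str, str], int]],
        gene_lookup: Mapping[tuple[str, str], str],
        samples: Iterable[str] | None = None,
    ) -> "BarcodeCountTable":
        """Assemble a table from per-sample counters.

        ``sample_counts`` maps sample name -> {(library_id, sgrna, barcode):
        count}; ``gene_lookup`` maps (library_id, sgrna) -> gene.
        """
        if samples is None:
            samples = list(sample_counts)
        samples = list(samples)
        keys: set[tuple[str, str, str]] = set()
        for s in samples:
            keys.update(sample_counts[s].keys())
        ordered = sorted(keys)
        index = {k: i for i, k in enumerate(ordered)}
        mat = np.zeros((len(ordered), len(samples)), dtype=np.int64)
        for j, s in enumerate(samples):
            for k, n in sample_counts[s].items():
                mat[index[k], j] = n
        genes = []
        for lib, sg, _bc in ordered:
            try:
                genes.append(gene_lookup[(lib, sg)])
            except KeyError:
                raise DataError(f"(library_id={lib}, sgrna={sg}) absent from manifest")
        df = pd.DataFrame(
            {
                "library_id": [k[0] for k in ordered],
                "sgrna": [k[1] for k in ordered],
                "gene": genes,
                "barcode": [k[2] for k in ordered],
            }
        )
        for j, s in enumerate(samples):
            df[s] = mat[:, j]
        return cls(df, samples)
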