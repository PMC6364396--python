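"""Barcode collapsing, count filters, and built-in replicate construction.

The processing order is fixed: collapse Hamming-distance-1 barcodes within
each sgRNA, discard barcodes below the per-sample read floor, discard sgRNAs
with too few surviving barcodes, split barcodes into built-in replicate
groups, then discard sgRNAs whose day-14 replicates fall below the read
floor. ``run_filter_pipeline`` applies all stages and records survivors.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .tables import KEY_COLS, BarcodeCountTable

logger = logging.getLogger(__name__)


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValidationError(f"hamming: unequal lengths {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def _within(a: str, b: str, d: int) -> bool:
    # early-exit Hamming comparison
    m = 0
    for x, y in zip(a, b):
        if x != y:
            m += 1
            if m > d:
                return False
    return True


@dataclass(frozen=True)
class CollapsePolicy:
    """How barcodes within one sgRNA are merged.

    A pair of barcodes within ``max_distance`` is collapsed by adding the
    smaller-count barcode into the larger (``pair_rule="sum_into_larger"``)
    or by simply dropping the smaller one (``"keep_larger"``). Connected
    components of three or more barcodes keep only the largest-count member
    with its own counts (``component_rule="keep_max_only"``) or sum the
    whole component into it (``"sum_into_max"``). Count comparisons use the
    total across samples; ties break to the lexicographically smaller
    barcode.
    """

    max_distance: int = 1
    pair_rule: str = "sum_into_larger"
    component_rule: str = "keep_max_only"
    tie_break: str = "lexicographic"

    def __post_init__(self):
        if self.max_distance < 0:
            raise ValidationError("max_distance must be >= 0")
        if self.pair_rule not in ("sum_into_larger", "keep_larger"):
            raise ValidationError(f"unknown pair_rule {self.pair_rule!r}")
        if self.component_rule not in ("keep_max_only", "sum_into_max"):
            raise ValidationError(f"unknown component_rule {self.component_rule!r}")
        if self.tie_break != "lexicographic":
            raise ValidationError(f"unknown tie_break {self.tie_break!r}")


def collapse_barcodes(
    bc_counts: Mapping[str, Sequence[int] | np.ndarray],
    policy: CollapsePolicy = CollapsePolicy(),
) -> dict[str, np.ndarray]:
    """Collapse the barcodes of a single sgRNA.

    ``bc_counts`` maps barcode -> per-sample count vector. Returns the
    collapsed mapping with the same vector layout.
    """
    bcs = sorted(bc_counts)
    if bcs and any(len(b) != len(bcs[0]) for b in bcs):
        raise ValidationError("barcodes of one sgRNA must share a length")
    vecs = {b: np.asarray(bc_counts[b], dtype=np.int64) for b in bcs}
    n = len(bcs)
    if n <= 1:
        return vecs

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _within(bcs[i], bcs[j], policy.max_distance):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(find(i), []).append(i)

    out: dict[str, np.ndarray] = {}
    for members in components.values():
        if len(members) == 1:
            b = bcs[members[0]]
            out[b] = vecs[b]
            continue
        # keeper: largest total, ties to the lexicographically smaller barcode
        keeper = min(members, key=lambda i: (-int(vecs[bcs[i]].sum()), bcs[i]))
        if len(members) == 2:
            other = members[0] if members[1] == keeper else members[1]
            if policy.pair_rule == "sum_into_larger":
                out[bcs[keeper]] = vecs[bcs[keeper]] + vecs[bcs[other]]
            else:
                out[bcs[keeper]] = vecs[bcs[keeper]]
        else:
            if policy.component_rule == "sum_into_max":
                total = sum((vecs[bcs[i]] for i in members), np.zeros_like(vecs[bcs[keeper]]))
                out[bcs[keeper]] = total
            else:
                out[bcs[keeper]] = vecs[bcs[keeper]]
    return out


def collapse_table(
    table: BarcodeCountTable, policy: CollapsePolicy = CollapsePolicy()
) -> BarcodeCountTable:
    """Apply barcode collapsing within every (library_id, sgrna) group."""
    df = table.df
    mat = df[table.samples].to_numpy(dtype=np.int64)
    keep_rows: list[int] = []
    new_counts: list[np.ndarray] = []
    grouped = df.groupby(["library_id", "sgrna"], sort=False).indices
    for _, idx in grouped.items():
        idx = np.asarray(idx)
        if len(idx) == 1:
            keep_rows.append(int(idx[0]))
            new_counts.append(mat[idx[0]])
            continue
        bc_counts = {df["barcode"].iat[i]: mat[i] for i in idx}
        collapsed = collapse_barcodes(bc_counts, policy)
        bc_to_row = {df["barcode"].iat[i]: int(i) for i in idx}
        for bc in sorted(collapsed):
            keep_rows.append(bc_to_row[bc])
            new_counts.append(collapsed[bc])
    out = df.iloc[keep_rows][KEY_COLS].reset_index(drop=True)
    cmat = np.vstack(new_counts) if new_counts else np.zeros((0, len(table.samples)), int)
    for j, s in enumerate(table.samples):
        out[s] = cmat[:, j]
    return BarcodeCountTable(out, table.samples).sorted()


def filter_min_count(
    table: BarcodeCountTable,
    min_count: int = 5,
    samples: Iterable[str] | None = None,
) -> BarcodeCountTable:
    """Drop (sgrna, barcode) rows below ``min_count`` in ANY listed sample.

    A row is retained only if its count is >= ``min_count`` in every sample
    of ``samples`` (default: all samples of the table).
    """
    if samples is None:
        samples = table.samples
    samples = list(samples)
    if not samples:
        raise ValidationError("filter_min_count: empty sample set")
    missing = [s for s in samples if s not in table.samples]
    if missing:
        raise DataError(f"filter_min_count: unknown samples {missing}")
    mask = (table.df[samples] >= min_count).all(axis=1)
    return BarcodeCountTable(table.df[mask].reset_index(drop=True), table.samples)


def filter_min_barcodes(table: BarcodeCountTable, min_bcs: int = 3) -> BarcodeCountTable:
    """Drop sgRNAs with fewer than ``min_bcs`` retained barcodes."""
    sizes = table.df.groupby(["library_id", "sgrna"])["barcode"].transform("size")
    mask = sizes >= min_bcs
    return BarcodeCountTable(table.df[mask].reset_index(drop=True), table.samples)


@dataclass
class ReplicateTable:
    """Per-sgRNA counts summed within built-in replicate groups.

    ``df`` has one row per (library_id, sgrna, gene) and one column
    ``<sample>.r<k>`` per sample and replicate group. ``assignment`` keeps
    the barcode -> group map used to build it.
    """

    df: pd.DataFrame
    samples: list[str]
    n_groups: int
    assignment: pd.DataFrame = field(repr=False, default=None)
    normalized: bool = False

    def rep_columns(self, sample: str) -> list[str]:
        return [f"{sample}.r{g + 1}" for g in range(self.n_groups)]

    def all_rep_columns(self) -> list[str]:
        return [c for s in self.samples for c in self.rep_columns(s)]


def build_replicates(
    table: BarcodeCountTable, n_groups: int = 3, seed: int = 0
) -> ReplicateTable:
    """Randomly split each sgRNA's barcodes into ``n_groups`` built-in
    replicates and sum counts within each group.

    Groups are dealt round-robin after a seeded shuffle so sizes differ by
    at most one; per sgRNA and sample the group sums conserve the sgRNA
    total.
    """
    rng = np.random.default_rng(seed)
    df = table.sorted().df
    mat = df[table.samples].to_numpy(dtype=np.int64)
    grouped = df.groupby(["library_id", "sgrna"], sort=True).indices
    rows = []
    assign_rows = []
    for (lib, sg), idx in grouped.items():
        idx = np.asarray(idx)
        if len(idx) < n_groups:
            raise DataError(
                f"sgRNA {sg!r} (library {lib!r}) has {len(idx)} barcodes; "
                f"{n_groups} are required for built-in replicates"
            )
        perm = rng.permutation(len(idx))
        groups = np.empty(len(idx), dtype=int)
        groups[perm] = np.arange(len(idx)) % n_groups
        sums = np.zeros((n_groups, len(table.samples)), dtype=np.int64)
        for local, g in enumerate(groups):
            sums[g] += mat[idx[local]]
        gene = df["gene"].iat[idx[0]]
        rows.append((lib, sg, gene, sums))
        for local, g in enumerate(groups):
            assign_rows.append((lib, sg, df["barcode"].iat[idx[local]], int(g)))
    out = pd.DataFrame(
        {
            "library_id": [r[0] for r in rows],
            "sgrna": [r[1] for r in rows],
            "gene": [r[2] for r in rows],
        }
    )
    for j, s in enumerate(table.samples):
        for g in range(n_groups):
            out[f"{s}.r{g + 1}"] = [r[3][g, j] for r in rows]
    assignment = pd.DataFrame(
        assign_rows, columns=["library_id", "sgrna", "barcode", "group"]
    )
    return ReplicateTable(out, list(table.samples), n_groups, assignment)


def filter_day14_replicates(
    reptable: ReplicateTable, min_count: int = 5, day: int = 14
) -> ReplicateTable:
    """Drop sgRNAs with any built-in replicate below ``min_count`` at the
    day-``day`` samples (both arms)."""
    pat = re.compile(rf"_d{day}\.r\d+$")
    cols = [c for c in reptable.df.columns if pat.search(c)]
    if not cols:
        raise DataError(f"no day-{day} replicate columns present")
    mask = (reptable.df[cols] >= min_count).all(axis=1)
    df = reptable.df[mask].reset_index(drop=True)
    keys = set(zip(df["library_id"], df["sgrna"]))
    assignment = reptable.assignment
    if assignment is not None:
        am = [
            (lib, sg) in keys
            for lib, sg in zip(assignment["library_id"], assignment["sgrna"])
        ]
        assignment = assignment[am].reset_index(drop=True)
    return ReplicateTable(df, reptable.samples, reptable.n_groups, assignment)


@dataclass
class PipelineResult:
    replicates: ReplicateTable
    collapsed: BarcodeCountTable
    filtered: BarcodeCountTable
    stage_counts: dict[str, int]


def run_filter_pipeline(
    table: BarcodeCountTable,
    policy: CollapsePolicy = CollapsePolicy(),
    min_count: int = 5,
    min_count_samples: Iterable[str] | None = None,
    min_bcs: int = 3,
    n_groups: int = 3,
    rep_min_count: int = 5,
    rep_day: int = 14,
    seed: int = 0,
) -> PipelineResult:
    """Collapse -> min-count -> min-barcodes -> replicates -> day-14 filter.

    Returns the replicate table plus the number of rows/sgRNAs surviving
    each stage.
    """
    stage = {"raw_barcodes": len(table)}
    collapsed = collapse_table(table, policy)
    stage["collapsed_barcodes"] = len(collapsed)
    filtered = filter_min_count(collapsed, min_count, min_count_samples)
    stage["min_count_barcodes"] = len(filtered)
    filtered = filter_min_barcodes(filtered, min_bcs)
    stage["min_barcode_barcodes"] = len(filtered)
    stage["min_barcode_sgrnas"] = int(
        filtered.df.groupby(["library_id", "sgrna"]).ngroups
    )
    reps = build_replicates(filtered, n_groups=n_groups, seed=seed)
    stage["replicate_sgrnas"] = len(reps.df)
    reps = filter_day14_replicates(reps, rep_min_count, rep_day)
    stage["day14_sgrnas"] = len(reps.df)
    logger.info("filter pipeline survivors: %s", stage)
    return PipelineResult(reps, collapsed, filtered, stage)
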