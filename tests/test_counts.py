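"""Barcode collapsing against a brute-force oracle, the three count filters,
and built-in replicate construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from clonepool import counts as cm
from clonepool.errors import DataError, ValidationError
from clonepool.tables import BarcodeCountTable


# ------------------------------------------------------------------ hamming
def test_hamming():
    assert cm.hamming("AAAA", "AAAA") == 0
    assert cm.hamming("AAAA", "AAAT") == 1
    assert cm.hamming("ACGT", "TGCA") == 4
    with pytest.raises(ValidationError):
        cm.hamming("AAA", "AAAA")


# ------------------------------------------------------------------ collapse
def oracle_collapse(bc_counts, max_distance=1, pair_rule="sum_into_larger",
                    component_rule="keep_max_only"):
    """Independent implementation: explicit all-pairs distance matrix and
    BFS connected components, then the pair/component rules."""
    bcs = sorted(bc_counts)
    vec = {b: np.asarray(bc_counts[b], dtype=np.int64) for b in bcs}
    adj = {b: set() for b in bcs}
    for i, a in enumerate(bcs):
        for b in bcs[i + 1 :]:
            if sum(x != y for x, y in zip(a, b)) <= max_distance:
                adj[a].add(b)
                adj[b].add(a)
    seen = set()
    out = {}
    for b in bcs:
        if b in seen:
            continue
        comp = []
        stack = [b]
        seen.add(b)
        while stack:
            x = stack.pop()
            comp.append(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        keeper = sorted(comp, key=lambda x: (-vec[x].sum(), x))[0]
        if len(comp) == 1:
            out[keeper] = vec[keeper]
        elif len(comp) == 2:
            if pair_rule == "sum_into_larger":
                out[keeper] = vec[comp[0]] + vec[comp[1]]
            else:
                out[keeper] = vec[keeper]
        else:
            if component_rule == "sum_into_max":
                out[keeper] = sum(vec[x] for x in comp)
            else:
                out[keeper] = vec[keeper]
    return out


def _eq(a, b):
    return set(a) == set(b) and all(np.array_equal(a[k], b[k]) for k in a)


def test_collapse_singleton_passthrough():
    assert _eq(cm.collapse_barcodes({"AAAA": [10]}), {"AAAA": np.array([10])})


def test_collapse_pair_sums_into_larger():
    out = cm.collapse_barcodes({"AAAA": [10], "AAAT": [3]})
    assert _eq(out, {"AAAA": np.array([13])})


def test_collapse_chain_keeps_max_only():
    out = cm.collapse_barcodes({"AAAA": [10], "AAAT": [8], "AATT": [7]})
    assert _eq(out, {"AAAA": np.array([10])})


def test_collapse_tie_breaks_lexicographically():
    out = cm.collapse_barcodes({"TAAA": [7], "AAAA": [7]})
    assert _eq(out, {"AAAA": np.array([14])})


def test_collapse_alternative_rules():
    pol = cm.CollapsePolicy(pair_rule="keep_larger", component_rule="sum_into_max")
    assert _eq(cm.collapse_barcodes({"AAAA": [10], "AAAT": [3]}, pol),
               {"AAAA": np.array([10])})
    assert _eq(cm.collapse_barcodes({"AAAA": [10], "AAAT": [8], "AATT": [7]}, pol),
               {"AAAA": np.array([25])})


def test_collapse_distance_zero_is_identity():
    counts = {"AAAA": [1], "AAAT": [2]}
    out = cm.collapse_barcodes(counts, cm.CollapsePolicy(max_distance=0))
    assert _eq(out, {k: np.asarray(v) for k, v in counts.items()})


@given(st.data())
def test_collapse_matches_oracle(data):
    rng = np.random.default_rng(data.draw(st.integers(0, 2 ** 31 - 1)))
    n = int(rng.integers(1, 13))
    length = int(rng.integers(3, 6))
    # two-letter alphabet forces dense Hamming neighborhoods
    bcs = {"".join(rng.choice(list("AC"), length)) for _ in range(n)}
    counts = {b: rng.integers(1, 50, size=2) for b in bcs}
    out = cm.collapse_barcodes(counts)
    assert _eq(out, oracle_collapse(counts))
    # never more barcodes, never more total reads
    assert len(out) <= len(counts)
    assert sum(v.sum() for v in out.values()) <= sum(v.sum() for v in counts.values())


def test_collapse_pairs_conserve_total():
    # far-apart pairs only: grand total conserved under the pair rule
    counts = {"AAAA": [10], "AAAT": [2], "GGGG": [5], "GGGC": [1]}
    out = cm.collapse_barcodes(counts)
    assert sum(v.sum() for v in out.values()) == 18


# ------------------------------------------------------------------ filters
def _table(rows, samples=("s1", "s2")):
    df = pd.DataFrame(
        [
            {"library_id": "GCCTAA", "sgrna": sg, "gene": f"g_{sg}", "barcode": bc,
             **{s: c for s, c in zip(samples, cs)}}
            for sg, bc, cs in rows
        ]
    )
    return BarcodeCountTable(df, list(samples))


def test_filter_min_count_boundaries():
    t = _table([("S1", "AAAA", (5, 7)), ("S2", "CCCC", (4, 9))])
    out = cm.filter_min_count(t, 5)
    assert out.df["sgrna"].tolist() == ["S1"]
    assert len(cm.filter_min_count(t, 0)) == 2  # identity
    with pytest.raises(ValidationError):
        cm.filter_min_count(t, 5, samples=[])


def test_filter_min_count_single_sample_subset():
    t = _table([("S1", "AAAA", (4, 9))])
    assert len(cm.filter_min_count(t, 5, samples=["s2"])) == 1
    assert len(cm.filter_min_count(t, 5, samples=["s1"])) == 0


def test_filter_min_barcodes_boundaries():
    t = _table(
        [("S1", "AAAA", (1, 1)), ("S1", "CCCC", (1, 1)), ("S1", "GGGG", (1, 1)),
         ("S2", "AAAA", (1, 1)), ("S2", "CCCC", (1, 1))]
    )
    out = cm.filter_min_barcodes(t, 3)
    assert set(out.df["sgrna"]) == {"S1"}
    assert len(cm.filter_min_barcodes(t, 1)) == len(t)


# ------------------------------------------------------------------ replicates
def _rep_table(n_bcs, counts=(10, 20)):
    # distinct 4-char barcodes, pairwise Hamming distance >= 1 but arbitrary;
    # collapsing is not applied here
    bcs = ["".join("ACGT"[(i >> (2 * j)) & 3] for j in range(4)) for i in range(n_bcs)]
    return _table([("S1", bc, counts) for bc in bcs])


def test_build_replicates_round_robin_sizes_and_conservation():
    t = _rep_table(9)
    reps = cm.build_replicates(t, n_groups=3, seed=0)
    sizes = reps.assignment.groupby("group").size()
    assert sizes.tolist() == [3, 3, 3]
    row = reps.df.iloc[0]
    assert row[["s1.r1", "s1.r2", "s1.r3"]].sum() == 9 * 10
    assert row[["s2.r1", "s2.r2", "s2.r3"]].sum() == 9 * 20

    t4 = _rep_table(4)
    reps4 = cm.build_replicates(t4, n_groups=3, seed=0)
    assert sorted(reps4.assignment.groupby("group").size().tolist()) == [1, 1, 2]


def test_build_replicates_deterministic_and_errors():
    t = _rep_table(5)
    a = cm.build_replicates(t, seed=42)
    b = cm.build_replicates(t, seed=42)
    assert a.assignment.equals(b.assignment)
    assert a.df.equals(b.df)
    with pytest.raises(DataError, match="S1"):
        cm.build_replicates(_rep_table(2), n_groups=3, seed=0)


def _day14_reptable(rep_counts):
    df = pd.DataFrame([
        {"library_id": "GCCTAA", "sgrna": f"S{i}", "gene": f"g{i}",
         "treated_d14.r1": c[0], "treated_d14.r2": c[1], "treated_d14.r3": c[2],
         "untreated_d14.r1": 9, "untreated_d14.r2": 9, "untreated_d14.r3": 9}
        for i, c in enumerate(rep_counts)
    ])
    return cm.ReplicateTable(df, ["treated_d14", "untreated_d14"], 3,
                             pd.DataFrame(columns=["library_id", "sgrna", "barcode", "group"]))


def test_filter_day14_replicates_boundaries():
    rt = _day14_reptable([(5, 5, 5), (12, 4, 30)])
    out = cm.filter_day14_replicates(rt, 5)
    assert out.df["sgrna"].tolist() == ["S0"]
    assert len(cm.filter_day14_replicates(rt, 0).df) == 2
    with pytest.raises(DataError):
        cm.filter_day14_replicates(rt, 5, day=9)


# ------------------------------------------------------------------ pipeline
def test_pipeline_records_stage_counts(wt_screen):
    table = wt_screen.counts.subset_library("GCCTAA")
    res = cm.run_filter_pipeline(table, seed=1)
    sc = res.stage_counts
    assert sc["raw_barcodes"] >= sc["collapsed_barcodes"] >= sc["min_count_barcodes"]
    assert sc["min_count_barcodes"] >= sc["min_barcode_barcodes"]
    assert sc["replicate_sgrnas"] >= sc["day14_sgrnas"]
    # replicate sums conserve the filtered table totals
    filt = res.filtered
    for s in filt.samples:
        cols = res.replicates.rep_columns(s)
        # restrict to surviving sgRNAs
        keys = set(zip(res.replicates.df["library_id"], res.replicates.df["sgrna"]))
        mask = [
            (l, g) in keys for l, g in zip(filt.df["library_id"], filt.df["sgrna"])
        ]
        assert res.replicates.df[cols].to_numpy().sum() == filt.df.loc[mask, s].sum()
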