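"""Normalization, sgRNA fold changes, and the permutation rank-aggregation
gene test (with exact-enumeration cross-checks)."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from clonepool import counts as cm
from clonepool import enrich
from clonepool.errors import DataError


def _reptable(mat, samples=("t", "u"), n_groups=1, normalized=False):
    mat = np.asarray(mat, dtype=float)
    df = pd.DataFrame({
        "library_id": "GCCTAA",
        "sgrna": [f"S{i:03d}" for i in range(mat.shape[0])],
        "gene": [f"g{i:03d}" for i in range(mat.shape[0])],
    })
    cols = [f"{s}.r{g + 1}" for s in samples for g in range(n_groups)]
    for j, c in enumerate(cols):
        df[c] = mat[:, j]
    return cm.ReplicateTable(df, list(samples), n_groups,
                             pd.DataFrame(columns=["library_id", "sgrna", "barcode", "group"]),
                             normalized=normalized)


# ---------------------------------------------------------- normalization
def test_median_ratio_identical_samples():
    rt = _reptable([[10, 10], [40, 40], [90, 90]])
    norm, factors = enrich.median_ratio_normalize(rt)
    assert np.allclose(factors, factors.iloc[0])
    assert np.allclose(norm.df[["t.r1", "u.r1"]].to_numpy(),
                       rt.df[["t.r1", "u.r1"]].to_numpy() / factors.iloc[0])


def test_median_ratio_depth_factor_two():
    a = np.array([10.0, 40, 90, 25])
    rt = _reptable(np.column_stack([a, 2 * a]))
    norm, factors = enrich.median_ratio_normalize(rt)
    assert factors["u.r1"] / factors["t.r1"] == pytest.approx(2.0)
    assert np.allclose(norm.df["t.r1"], norm.df["u.r1"])


def test_median_ratio_single_sgrna():
    rt = _reptable([[8, 2]])
    _, factors = enrich.median_ratio_normalize(rt)
    geo = math.sqrt(8 * 2)
    assert factors["t.r1"] == pytest.approx(8 / geo)
    assert factors["u.r1"] == pytest.approx(2 / geo)


def test_median_ratio_fallback_totals():
    rt = _reptable([[10, 0], [0, 10]])
    _, factors = enrich.median_ratio_normalize(rt)
    assert np.allclose(factors, 1.0)  # equal totals


# ---------------------------------------------------------- log2fc
def test_log2fc_zero_when_equal():
    rt = _reptable([[5, 5], [50, 50]])
    stats = enrich.replicate_log2fc(rt, "t", "u")
    assert np.allclose(stats["log2fc"], 0.0)
    assert sorted(stats["rank"]) == [1, 2]


def test_log2fc_closed_form():
    rt = _reptable([[400, 100]])
    stats = enrich.replicate_log2fc(rt, "t", "u", pseudocount=1e-9)
    assert stats["log2fc"].iloc[0] == pytest.approx(2.0, abs=1e-6)


def test_log2fc_replicate_order_invariant():
    rt1 = _reptable([[1, 2, 3, 1, 2, 3]], n_groups=3)
    rt2 = _reptable([[3, 1, 2, 3, 1, 2]], n_groups=3)
    a = enrich.replicate_log2fc(rt1, "t", "u")["log2fc"].iloc[0]
    b = enrich.replicate_log2fc(rt2, "t", "u")["log2fc"].iloc[0]
    assert a == pytest.approx(b)


# ---------------------------------------------------------- gene test
def _stats(gene_ranks: dict, n_total: int, ntc_prefix="NTC"):
    """Build an sgRNA stats frame with prescribed ranks; remaining ranks are
    NTC sgRNAs."""
    used = [r for rs in gene_ranks.values() for r in rs]
    assert len(set(used)) == len(used)
    rows = []
    for gene, rs in gene_ranks.items():
        for r in rs:
            rows.append((f"sg{r:05d}", gene, r))
    free = [r for r in range(1, n_total + 1) if r not in set(used)]
    for i, r in enumerate(free):
        rows.append((f"sg{r:05d}", f"{ntc_prefix}{i:05d}", r))
    df = pd.DataFrame(rows, columns=["sgrna", "gene", "rank"])
    df["library_id"] = "GCCTAA"
    df["log2fc"] = 0.0
    return df.sort_values("rank").reset_index(drop=True)


def oracle_gene_p(gene_qs, pool_qs, n_total, alpha=0.25):
    """Exact subset enumeration with an independent scoring path: the Beta
    tail P(Beta(j, n-j+1) <= q) computed as a binomial sum."""

    def binom_tail(n, j, q):
        return sum(math.comb(n, i) * q ** i * (1 - q) ** (n - i) for i in range(j, n + 1))

    def score(qs):
        qs = sorted(qs)
        n = len(qs)
        k = max(1, sum(q <= alpha for q in qs))
        return min(binom_tail(n, j + 1, qs[j]) for j in range(k))

    obs = score(gene_qs)
    count = 0
    total = 0
    for combo in itertools.combinations(pool_qs, len(gene_qs)):
        total += 1
        if score(combo) <= obs + 1e-12:
            count += 1
    return max(count, 1) / total


def test_gene_rank_test_exact_matches_enumeration():
    """20-sgRNA instance: permutation p in exact mode equals full subset
    enumeration via an independent oracle."""
    gene_ranks = {"HIT": [1, 2, 3], "MID": [5, 9, 14]}
    stats = _stats(gene_ranks, 20)
    ntc = set(g for g in stats["gene"] if g.startswith("NTC"))
    res = enrich.gene_rank_test(stats, ntc_genes=ntc, exact=True, min_pool=10).set_index("gene")
    pool = sorted(stats.loc[stats["gene"].isin(ntc), "rank"] / 20)
    for gene, rs in gene_ranks.items():
        expected = oracle_gene_p([r / 20 for r in rs], pool, 20)
        assert res.loc[gene, "p_value"] == pytest.approx(expected)
    assert res.loc["HIT", "rank"] == 1


def test_gene_rank_test_top_gene_minimal_p():
    stats = _stats({"HIT": list(range(1, 13))}, 2000)
    ntc = set(g for g in stats["gene"] if g.startswith("NTC"))
    res = enrich.gene_rank_test(stats, ntc_genes=ntc, n_perm=1000, seed=1)
    hit = res.set_index("gene").loc["HIT"]
    assert hit["p_value"] <= 1 / 1000
    assert hit["rank"] == 1


def test_gene_rank_test_single_gene_fdr_equals_p():
    stats = _stats({"ONLY": [3, 8]}, 40)
    ntc = set(g for g in stats["gene"] if g.startswith("NTC"))
    res = enrich.gene_rank_test(stats, ntc_genes=ntc, n_perm=500, seed=2)
    assert len(res) == 1
    assert res["fdr"].iloc[0] == res["p_value"].iloc[0]


def test_gene_rank_test_null_p_uniform():
    """Genes whose sgRNA ranks are random draws get ~Uniform(0,1] p-values."""
    rng = np.random.default_rng(3)
    n_total = 1000
    ranks = rng.permutation(n_total) + 1
    genes = {}
    pos = 0
    for i in range(120):
        genes[f"g{i:03d}"] = list(ranks[pos : pos + 4])
        pos += 4
    stats = _stats(genes, n_total)
    ntc = set(g for g in stats["gene"] if g.startswith("NTC"))
    res = enrich.gene_rank_test(stats, ntc_genes=ntc, n_perm=2000, seed=4)
    ks = kstest(res["p_value"], "uniform")
    assert ks.pvalue > 0.01
    assert (res["p_value"] > 0).all() and (res["p_value"] <= 1).all()


def test_gene_rank_test_deterministic():
    stats = _stats({"A": [2, 11], "B": [7, 19]}, 60)
    ntc = set(g for g in stats["gene"] if g.startswith("NTC"))
    r1 = enrich.gene_rank_test(stats, ntc_genes=ntc, n_perm=400, seed=9)
    r2 = enrich.gene_rank_test(stats, ntc_genes=ntc, n_perm=400, seed=9)
    pd.testing.assert_frame_equal(r1, r2)


def test_gene_scores_ranks_are_permutation(wt_screen):
    from clonepool.counts import run_filter_pipeline

    pl = run_filter_pipeline(wt_screen.counts.subset_library("GCCTAA"), seed=0)
    norm, _ = enrich.median_ratio_normalize(pl.replicates)
    stats = enrich.replicate_log2fc(norm, "treated_d14", "untreated_d14")
    scored = enrich.gene_scores(stats, ntc_genes=wt_screen.manifest.ntc_genes())
    assert sorted(scored["rank"]) == list(range(1, len(scored) + 1))
    assert (np.diff(scored.sort_values("rank")["score"]) >= 0).all()


# ---------------------------------------------------------- MAGeCK export
def test_export_mageck_format_and_roundtrip(tmp_path):
    rt = _reptable([[5, 9], [7, 3]])
    path = tmp_path / "counts.txt"
    enrich.export_mageck(rt, path)
    lines = path.read_text().splitlines()
    assert len(lines) == 3
    assert lines[0] == "sgRNA\tgene\tt.r1\tu.r1"
    back = enrich.read_mageck(path)
    assert back["sgRNA"].tolist() == ["S000", "S001"]
    assert back["t.r1"].tolist() == [5, 7]
    assert back["u.r1"].tolist() == [9, 3]


def test_export_mageck_column_order_follows_samples(tmp_path):
    rt = _reptable([[1, 2]], samples=("t", "u"))
    path = tmp_path / "c.txt"
    enrich.export_mageck(rt, path, samples=["u", "t"])
    assert path.read_text().splitlines()[0] == "sgRNA\tgene\tu.r1\tt.r1"


def test_export_mageck_refuses_normalized(tmp_path):
    rt = _reptable([[1.5, 2.5]], normalized=True)
    with pytest.raises(DataError):
        enrich.export_mageck(rt, tmp_path / "x.txt")
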