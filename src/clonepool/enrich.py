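"""Gene-level positive-selection statistics from built-in replicates.

Counts are normalized by median-of-ratios size factors, sgRNAs are ranked
by replicate-averaged treated-vs-untreated log2 fold change, and genes are
scored with a robust rank aggregation statistic: the minimum over the
gene's top sgRNA rank quantiles of the Beta(j, n-j+1) tail probability,
considering only sgRNAs within the top ``alpha`` fraction of the library
(at least one). Significance comes from a permutation null that redraws the
same number of sgRNA rank quantiles from the non-target-control pool; this
is a self-contained stand-in for the external MAGeCK analysis, for which an
exact count export is provided.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import betainc
from scipy.stats import false_discovery_control

from .counts import ReplicateTable
from .errors import DataError, ValidationError

logger = logging.getLogger(__name__)


# -- normalization -------------------------------------------------------------
def median_ratio_normalize(
    reptable: ReplicateTable,
) -> tuple[ReplicateTable, pd.Series]:
    """Median-of-ratios size factors across all replicate columns.

    The size factor of a column is the median over sgRNAs of
    count / (geometric mean of the sgRNA across columns); sgRNAs with a zero
    anywhere are excluded from factor estimation. Falls back to total-count
    factors (with a warning) when no sgRNA is everywhere nonzero.
    """
    cols = reptable.all_rep_columns()
    mat = reptable.df[cols].to_numpy(dtype=float)
    eligible = (mat > 0).all(axis=1)
    if eligible.any():
        logg = np.log(mat[eligible])
        geomean = np.exp(logg.mean(axis=1))
        factors = np.median(mat[eligible] / geomean[:, None], axis=0)
    else:
        logger.warning(
            "no sgRNA is nonzero in every replicate; falling back to "
            "total-count normalization"
        )
        totals = mat.sum(axis=0)
        if totals.sum() == 0:
            raise DataError("all counts are zero; cannot normalize")
        factors = totals / totals.mean()
    if (factors <= 0).any():
        raise DataError("non-positive size factor; check input counts")
    df = reptable.df.copy()
    df[cols] = mat / factors
    out = ReplicateTable(
        df, reptable.samples, reptable.n_groups, reptable.assignment, normalized=True
    )
    return out, pd.Series(factors, index=cols, name="size_factor")


def normalize_columns(df: pd.DataFrame, cols: Sequence[str]) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios normalization over arbitrary count columns
    (same estimator as :func:`median_ratio_normalize`)."""
    mat = df[list(cols)].to_numpy(dtype=float)
    eligible = (mat > 0).all(axis=1)
    if eligible.any():
        geomean = np.exp(np.log(mat[eligible]).mean(axis=1))
        factors = np.median(mat[eligible] / geomean[:, None], axis=0)
    else:
        totals = mat.sum(axis=0)
        if totals.sum() == 0:
            raise DataError("all counts are zero; cannot normalize")
        factors = totals / totals.mean()
    out = df.copy()
    out[list(cols)] = mat / factors
    return out, pd.Series(factors, index=list(cols), name="size_factor")


# -- sgRNA statistics ----------------------------------------------------------
def sgrna_log2fc(
    df: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Replicate-averaged log2 fold change per sgRNA.

    ``pairs`` lists (treated_column, untreated_column) replicate pairs; the
    statistic is the mean over pairs of log2((t + pc) / (u + pc)). Returns
    library_id/sgrna/gene/log2fc plus a dense rank (1 = most enriched).
    """
    if not pairs:
        raise ValidationError("at least one replicate pair is required")
    lfc = np.zeros(len(df), dtype=float)
    for t, u in pairs:
        lfc += np.log2(
            (df[t].to_numpy(dtype=float) + pseudocount)
            / (df[u].to_numpy(dtype=float) + pseudocount)
        )
    lfc /= len(pairs)
    out = df[["library_id", "sgrna", "gene"]].copy()
    out["log2fc"] = lfc
    out = out.sort_values(
        ["log2fc", "library_id", "sgrna"], ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def replicate_log2fc(
    reptable: ReplicateTable,
    treated_sample: str,
    untreated_sample: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """sgRNA log2 fold changes pairing built-in replicates by group index."""
    pairs = list(
        zip(reptable.rep_columns(treated_sample), reptable.rep_columns(untreated_sample))
    )
    return sgrna_log2fc(reptable.df, pairs, pseudocount)


# -- gene-level rank aggregation -------------------------------------------------
def _rho_scores(q_sorted: np.ndarray, alpha: float) -> np.ndarray:
    """Rank-aggregation score per row of sorted quantiles.

    rho = min over j <= k of P(Beta(j, n-j+1) <= q_(j)), where k is the
    number of quantiles <= alpha (at least 1). Smaller is stronger.
    """
    m, n_g = q_sorted.shape
    j = np.arange(1, n_g + 1, dtype=float)
    tail = betainc(j[None, :], n_g - j[None, :] + 1.0, q_sorted)
    k = np.clip((q_sorted <= alpha).sum(axis=1), 1, n_g)
    masked = np.where(np.arange(n_g)[None, :] < k[:, None], tail, 1.0)
    return masked.min(axis=1)


def _null_scores_perm(
    pool: np.ndarray, n_g: int, alpha: float, n_perm: int, rng: np.random.Generator,
    chunk: int = 2000,
) -> np.ndarray:
    """Permutation null: rho scores of random n_g-subsets of the pool."""
    replace = n_g > pool.size
    if replace:
        logger.warning(
            "null pool (%d) smaller than gene size (%d); sampling with replacement",
            pool.size, n_g,
        )
    out = np.empty(n_perm, dtype=float)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        if replace:
            draws = pool[rng.integers(0, pool.size, size=(m, n_g))]
        else:
            keys = rng.random((m, pool.size))
            idx = np.argpartition(keys, n_g - 1, axis=1)[:, :n_g]
            draws = pool[idx]
        draws.sort(axis=1)
        out[done : done + m] = _rho_scores(draws, alpha)
        done += m
    return out


def _null_scores_exact(
    pool: np.ndarray, n_g: int, alpha: float, max_subsets: int = 500_000
) -> np.ndarray:
    n_comb = math.comb(pool.size, n_g)
    if n_comb > max_subsets:
        raise ValidationError(
            f"exact enumeration infeasible: C({pool.size},{n_g}) = {n_comb}"
        )
    subsets = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(pool.size), n_g)),
        dtype=np.int64,
    ).reshape(n_comb, n_g)
    draws = pool[subsets]
    draws.sort(axis=1)
    return _rho_scores(draws, alpha)


def gene_scores(
    stats: pd.DataFrame,
    ntc_genes: Iterable[str] = (),
    alpha: float = 0.25,
    include_ntc: bool = False,
) -> pd.DataFrame:
    """Gene rank-aggregation scores (no p-values), ranked ascending.

    Ranks are deterministic given the sgRNA statistics: ties in score break
    by gene name.
    """
    n = len(stats)
    if n == 0:
        raise DataError("no sgRNA statistics provided")
    ntc = set(ntc_genes)
    q = stats["rank"].to_numpy(dtype=float) / n
    rows = []
    for gene, idx in stats.groupby("gene", sort=True).indices.items():
        if gene in ntc and not include_ntc:
            continue
        qs = np.sort(q[np.asarray(idx)])
        score = float(_rho_scores(qs[None, :], alpha)[0])
        rows.append((gene, len(idx), score))
    out = pd.DataFrame(rows, columns=["gene", "n_sgrna", "score"])
    out = out.sort_values(["score", "gene"], kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def gene_rank_test(
    stats: pd.DataFrame,
    ntc_genes: Iterable[str] = (),
    alpha: float = 0.25,
    n_perm: int = 10_000,
    seed: int = 0,
    exact: bool = False,
    include_ntc: bool = False,
    min_pool: int = 20,
) -> pd.DataFrame:
    """Permutation rank-aggregation test for positive selection.

    The null pool is the rank-quantile set of the NTC sgRNAs (all sgRNAs if
    fewer than ``min_pool`` NTCs survive the filters). For each gene with
    n_g sgRNAs, ``n_perm`` random n_g-subsets of the pool are scored and
    p = (1 + #(null <= observed)) / (n_perm + 1); with ``exact=True`` all
    subsets are enumerated and p = max(1, #(null <= observed)) / #subsets.
    FDR is Benjamini-Hochberg; genes are ranked by score.
    """
    n = len(stats)
    if n == 0:
        raise DataError("no sgRNA statistics provided")
    ntc = set(ntc_genes)
    q = stats["rank"].to_numpy(dtype=float) / n
    is_ntc = stats["gene"].isin(ntc).to_numpy()
    pool = q[is_ntc]
    if pool.size < min_pool:
        if ntc:
            logger.warning(
                "only %d NTC sgRNAs in the null pool; using all sgRNA quantiles",
                pool.size,
            )
        pool = q
    scored = gene_scores(stats, ntc_genes=ntc, alpha=alpha, include_ntc=include_ntc)
    rng = np.random.default_rng(seed)
    pvals = np.empty(len(scored), dtype=float)
    for n_g in sorted(scored["n_sgrna"].unique()):
        sel = scored["n_sgrna"].to_numpy() == n_g
        if exact:
            null = _null_scores_exact(pool, int(n_g), alpha)
            counts = (null[None, :] <= scored.loc[sel, "score"].to_numpy()[:, None]).sum(axis=1)
            pvals[sel] = np.maximum(counts, 1) / null.size
        else:
            null = _null_scores_perm(pool, int(n_g), alpha, n_perm, rng)
            counts = (null[None, :] <= scored.loc[sel, "score"].to_numpy()[:, None]).sum(axis=1)
            pvals[sel] = (1.0 + counts) / (n_perm + 1.0)
    out = scored.copy()
    out["p_value"] = pvals
    out["fdr"] = false_discovery_control(pvals, method="bh")
    out = out.sort_values(["score", "gene"], kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out[["gene", "n_sgrna", "score", "p_value", "fdr", "rank"]]


# -- MAGeCK export ---------------------------------------------------------------
def export_mageck(
    reptable: ReplicateTable, path, samples: Sequence[str] | None = None
) -> None:
    """Write the replicate table in MAGeCK count format.

    Layout: a header line ``sgRNA<TAB>gene<TAB><one column per
    sample.replicate>`` followed by one row per sgRNA with integer counts;
    column order follows sample registration order then replicate index.
    Normalized tables are refused; non-integer raw counts are rounded with
    a warning.
    """
    if reptable.normalized:
        raise DataError("refusing to export a normalized table to MAGeCK format")
    if samples is None:
        samples = reptable.samples
    cols = [c for s in samples for c in reptable.rep_columns(s)]
    mat = reptable.df[cols].to_numpy(dtype=float)
    if not np.allclose(mat, np.round(mat)):
        logger.warning("non-integer counts in MAGeCK export; rounding")
    mat = np.round(mat).astype(np.int64)
    with open(str(path), "w") as fh:
        fh.write("sgRNA\tgene\t" + "\t".join(cols) + "\n")
        sg = reptable.df["sgrna"].tolist()
        gene = reptable.df["gene"].tolist()
        for i in range(len(reptable.df)):
            fh.write(sg[i] + "\t" + gene[i] + "\t" + "\t".join(map(str, mat[i])) + "\n")


def read_mageck(path) -> pd.DataFrame:
    """Read back a MAGeCK count file (for round trips and tests)."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "sgRNA" or df.columns[1] != "gene":
        raise DataError("not a MAGeCK count file: header must start sgRNA<TAB>gene")
    return df
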