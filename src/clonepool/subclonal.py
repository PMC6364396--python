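"""Barcode-level statistics: sub-clonal dispersion, pair reproducibility,
and the barcode-subsampling saturation analysis.

Each (sgRNA, barcode) pair marks one lentiviral integration event, so the
spread of barcode fold changes within an sgRNA measures how heterogeneously
sub-clonal lineages carrying the same perturbation responded to treatment.
Dispersion is summarized per sgRNA as the interquartile range (IQR) of
barcode log2 fold changes; clones are compared by a Mann-Whitney rank-sum
test on their IQR distributions. Saturation analysis repeatedly subsamples
a fraction of each sgRNA's barcodes and tracks how gene ranks from the
enrichment test degrade as screen complexity shrinks.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from . import enrich
from .errors import DataError, ValidationError
from .tables import BarcodeCountTable, sample_name

logger = logging.getLogger(__name__)


# -- barcode fold changes --------------------------------------------------------
def barcode_log2fc(
    table: BarcodeCountTable,
    day: int = 14,
    min_count: int = 5,
    pseudocount: float = 0.0,
    treated_arm: str = "treated",
    untreated_arm: str = "untreated",
) -> pd.DataFrame:
    """log2 fold change per (sgRNA, barcode) at one day, treated over
    untreated, after per-sample total-count scaling.

    Only barcodes with at least ``min_count`` reads in BOTH samples are
    kept, which makes pseudocount 0 safe.
    """
    t = sample_name(treated_arm, day)
    u = sample_name(untreated_arm, day)
    for s in (t, u):
        if s not in table.samples:
            raise DataError(f"sample {s!r} not in table")
    df = table.df
    totals = table.sample_totals()
    keep = (df[t] >= min_count) & (df[u] >= min_count)
    sub = df[keep]
    lfc = np.log2(
        (sub[t].to_numpy(float) / totals[t] + pseudocount)
        / (sub[u].to_numpy(float) / totals[u] + pseudocount)
    )
    out = sub[["library_id", "sgrna", "gene", "barcode"]].copy()
    out["log2fc"] = lfc
    return out.reset_index(drop=True)


def dispersion_by_sgrna(fold_changes: pd.DataFrame, min_barcodes: int = 2) -> pd.DataFrame:
    """IQR (Q3 - Q1, linear-interpolation quantiles) of each sgRNA's barcode
    log2 fold changes; sgRNAs with fewer than ``min_barcodes`` barcodes are
    omitted (logged)."""
    rows = []
    omitted = 0
    for (lib, sg), idx in fold_changes.groupby(["library_id", "sgrna"], sort=True).indices.items():
        vals = fold_changes["log2fc"].to_numpy()[np.asarray(idx)]
        if vals.size < min_barcodes:
            omitted += 1
            continue
        q1, q3 = np.percentile(vals, [25, 75])
        rows.append((lib, sg, vals.size, float(q3 - q1)))
    if omitted:
        logger.info("dispersion: omitted %d sgRNAs with < %d barcodes", omitted, min_barcodes)
    return pd.DataFrame(rows, columns=["library_id", "sgrna", "n_bc", "iqr"])


# -- rank-sum comparison ----------------------------------------------------------
@dataclass(frozen=True)
class DispersionComparison:
    p_value: float
    location_shift: float  # Hodges-Lehmann estimate, group A minus group B
    method: str  # "exact" or "asymptotic"


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p by full enumeration of group assignments.

    U counts pairs (a > b) + 0.5 * ties; p is the fraction of C(n1+n2, n1)
    relabelings whose U deviates from its mean at least as much as observed.
    """
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    mean = n1 * n2 / 2.0

    def u_of(avals: np.ndarray, bvals: np.ndarray) -> float:
        diff = avals[:, None] - bvals[None, :]
        return float((diff > 0).sum() + 0.5 * (diff == 0).sum())

    obs_dev = abs(u_of(a, b) - mean)
    count = 0
    total = 0
    idx_all = set(range(n1 + n2))
    for combo in itertools.combinations(range(n1 + n2), n1):
        sa = pooled[list(combo)]
        sb = pooled[list(idx_all - set(combo))]
        total += 1
        if abs(u_of(sa, sb) - mean) >= obs_dev - 1e-12:
            count += 1
    return count / total


def compare_dispersion(
    a: Sequence[float] | pd.DataFrame,
    b: Sequence[float] | pd.DataFrame,
    exact: bool | None = None,
    max_enumeration: int = 200_000,
) -> DispersionComparison:
    """Two-sided Mann-Whitney comparison of two IQR (or any value) sets.

    ``a`` and ``b`` may be dispersion record frames (the ``iqr`` column is
    used) or plain value sequences. Exact enumeration is used when the
    number of group assignments C(n1+n2, n1) is at most
    ``max_enumeration`` (or when forced); otherwise the normal approximation
    with tie correction. The location shift is the Hodges-Lehmann estimate
    (median of all pairwise differences a_i - b_j).
    """
    if isinstance(a, pd.DataFrame):
        a = a["iqr"].to_numpy()
    if isinstance(b, pd.DataFrame):
        b = b["iqr"].to_numpy()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both groups must be non-empty")
    shift = float(np.median((a[:, None] - b[None, :]).ravel()))
    n_comb = math.comb(a.size + b.size, a.size)
    use_exact = exact if exact is not None else n_comb <= max_enumeration
    if use_exact:
        if n_comb > max_enumeration:
            raise ValidationError(
                f"exact enumeration infeasible: C({a.size + b.size},{a.size}) = {n_comb}"
            )
        return DispersionComparison(_exact_ranksum_p(a, b), shift, "exact")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return DispersionComparison(1.0, shift, "asymptotic")
    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return DispersionComparison(float(min(res.pvalue, 1.0)), shift, "asymptotic")


# -- pair reproducibility ----------------------------------------------------------
def pair_reproducibility(
    table: BarcodeCountTable,
    reference: str = "untreated_d14",
    queries: Sequence[str] = ("untreated_d0", "untreated_d4", "untreated_d9"),
    n_bins: int = 10,
) -> pd.DataFrame:
    """Detection of sgRNA-barcode pairs across time points.

    Pairs detected in the reference sample are binned by the quantiles of
    their log2 reference read counts into ``n_bins`` bins (ties at a bin
    edge fall to the lower bin); for each query sample the proportion of
    pairs in each bin with at least one read is reported.
    """
    if reference not in table.samples:
        raise DataError(f"reference sample {reference!r} not in table")
    for qs in queries:
        if qs not in table.samples:
            raise DataError(f"query sample {qs!r} not in table")
    ref = table.df[reference].to_numpy()
    det = ref >= 1
    if not det.any():
        raise DataError(f"reference sample {reference!r} has no detected pairs")
    logc = np.log2(ref[det].astype(float))
    edges = np.quantile(logc, np.linspace(0, 1, n_bins + 1)[1:-1])
    bins = np.searchsorted(edges, logc, side="left")  # ties -> lower bin
    rows = []
    for qs in queries:
        qdet = (table.df[qs].to_numpy()[det] >= 1)
        for bin_i in range(n_bins):
            sel = bins == bin_i
            n = int(sel.sum())
            prop = float(qdet[sel].mean()) if n else float("nan")
            rows.append((bin_i, qs, n, prop))
    return pd.DataFrame(rows, columns=["bin", "query", "n_pairs", "proportion"])


# -- subsampling saturation ----------------------------------------------------------
def _achievable_k(p: float, n_bc: int) -> int:
    """Barcodes to draw: the achievable proportion k/n_bc closest to p,
    ties resolved upward, never below one barcode."""
    if p <= 0:
        raise ValidationError("subsampling proportion must be > 0")
    k = int(math.floor(p * n_bc + 0.5))
    return min(max(k, 1), n_bc)


def _rank_from_aggregate(
    agg: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    ntc_genes: set[str],
    alpha: float,
    pseudocount: float,
) -> pd.DataFrame:
    norm, _ = enrich.normalize_columns(agg, [c for pair in pairs for c in pair])
    stats = enrich.sgrna_log2fc(norm, list(pairs), pseudocount)
    return enrich.gene_scores(stats, ntc_genes=ntc_genes, alpha=alpha)


def subsample_saturation(
    table: BarcodeCountTable,
    ntc_genes: Sequence[str] | set[str] = (),
    proportions: Sequence[float] = tuple(np.round(np.arange(0.05, 1.0001, 0.05), 2)),
    n_iter: int = 50,
    seed: int = 0,
    baseline_sample: str = "untreated_d0",
    replicate_days: Sequence[int] = (9, 14),
    min_baseline_bcs: int = 4,
    alpha: float = 0.25,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Barcode-subsampling saturation curves of gene ranks.

    Only sgRNAs with at least ``min_baseline_bcs`` barcodes detected at the
    baseline sample are used. Per iteration and proportion p, each sgRNA
    contributes a without-replacement sample of k barcodes (k the achievable
    proportion closest to p, ties upward); barcode counts are summed per
    sgRNA and the enrichment ranking is run with the treated-vs-untreated
    samples at ``replicate_days`` acting as the two replicates. Gene ranks
    are averaged across iterations. Iteration i uses seed ``seed + i``.

    Returns ``(curves, full_ranks)``: curves has one row per (gene,
    proportion) with mean and sd of the rank; full_ranks is the ranking of
    the unsubsampled aggregate.
    """
    if baseline_sample not in table.samples:
        raise DataError(f"baseline sample {baseline_sample!r} not in table")
    cols = []
    pairs = []
    for d in replicate_days:
        t, u = sample_name("treated", d), sample_name("untreated", d)
        for s in (t, u):
            if s not in table.samples:
                raise DataError(f"sample {s!r} required for saturation analysis")
        pairs.append((t, u))
        cols.extend([t, u])
    df = table.df[table.df[baseline_sample] >= 1].reset_index(drop=True)
    sizes = df.groupby(["library_id", "sgrna"])["barcode"].transform("size")
    df = df[sizes >= min_baseline_bcs].reset_index(drop=True)
    if df.empty:
        raise DataError(
            f"no sgRNA has >= {min_baseline_bcs} barcodes at {baseline_sample!r}"
        )
    ntc = set(ntc_genes)
    mat = df[cols].to_numpy(dtype=np.int64)
    groups = df.groupby(["library_id", "sgrna"], sort=True).indices
    group_keys = list(groups)
    group_idx = [np.asarray(groups[k]) for k in group_keys]
    genes = [df["gene"].iat[idx[0]] for idx in group_idx]
    libs = [k[0] for k in group_keys]
    sgs = [k[1] for k in group_keys]

    def aggregate(chosen: list[np.ndarray]) -> pd.DataFrame:
        summed = np.vstack([mat[c].sum(axis=0) for c in chosen])
        agg = pd.DataFrame({"library_id": libs, "sgrna": sgs, "gene": genes})
        for j, c in enumerate(cols):
            agg[c] = summed[:, j]
        return agg

    full_ranks = _rank_from_aggregate(
        aggregate(group_idx), pairs, ntc, alpha, pseudocount
    )
    rank_records: dict[float, list[pd.Series]] = {p: [] for p in proportions}
    for it in range(n_iter):
        rng = np.random.default_rng(seed + it)
        for p in proportions:
            chosen = []
            for idx in group_idx:
                k = _achievable_k(float(p), len(idx))
                if k == len(idx):
                    chosen.append(idx)
                else:
                    chosen.append(rng.choice(idx, size=k, replace=False))
            ranks = _rank_from_aggregate(aggregate(chosen), pairs, ntc, alpha, pseudocount)
            rank_records[p].append(ranks.set_index("gene")["rank"])
    rows = []
    for p in proportions:
        rmat = pd.concat(rank_records[p], axis=1)
        mean = rmat.mean(axis=1)
        sd = rmat.std(axis=1, ddof=1) if rmat.shape[1] > 1 else pd.Series(0.0, index=rmat.index)
        for gene in rmat.index:
            rows.append((gene, float(p), float(mean[gene]), float(sd[gene]), n_iter))
    curves = pd.DataFrame(rows, columns=["gene", "proportion", "mean_rank", "sd_rank", "n_iter"])
    return curves, full_ranks
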