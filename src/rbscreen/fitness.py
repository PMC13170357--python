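"""Gene-level temperature-dependent fitness from normalized barcode counts.

The default ("baseline-normalized") framework: for each gene, the mean
normalized abundance of all its single-locus insertion mutants across all
37 deg C replicates is the baseline; every (mutant, 50 deg C replicate)
abundance is divided by it and log2-transformed, giving one log2(50/37)
ratio per mutant per hot replicate. A one-sample Wilcoxon signed-rank
test asks whether the median ratio differs from 0, p-values are
Benjamini-Hochberg corrected across genes, and a gene is called
temperature-responsive when |mean log2FC| >= 1 and FDR < 0.05. Testing is
restricted to genes with <= 15 uniquely mapped barcodes so insertion
hotspots cannot dominate the variance structure. A Mann-Whitney U
framework comparing the raw abundance distributions between temperatures
is provided as the alternative.

Exact small-sample null distributions are computed in-package (a rank
convolution for the signed-rank test, combination enumeration for
Mann-Whitney) because they must stay exact in the presence of ties;
large samples fall back to scipy's tie-corrected normal approximations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

WILCOXON_EXACT_MAX_N = 25
MANNWHITNEY_EXACT_MAX_N = 20
DEFAULT_MIN_READS = 5
DEFAULT_MAX_BARCODES = 15
DEFAULT_LFC_THRESHOLD = 1.0
DEFAULT_FDR_THRESHOLD = 0.05


@dataclass
class GeneRatioSet:
    """Per-gene baseline-normalized log2 ratios."""

    gene_id: str
    baseline_37: float
    log2_ratios: list[float]
    n_barcodes: int
    n_dropped_zero: int = 0


@dataclass
class GeneFitnessResult:
    gene_id: str
    mean_log2fc: float
    sd: float
    cv_percent: float
    p_value: float
    n_barcodes: int
    fdr: float = float("nan")
    is_hit: bool = False
    direction: str = ""
    n_ratios: int = 0
    note: str = ""


# ----------------------------------------------------------------- filters


def filter_barcodes_and_genes(
    raw: "pd.DataFrame | object",
    pool: pd.DataFrame,
    min_reads: int = DEFAULT_MIN_READS,
) -> pd.DataFrame:
    """Select the single-locus, single-feature genic barcodes whose gene
    survives the read-support filter.

    ``raw`` is the raw (un-normalized) count matrix, barcode-indexed.
    A gene is removed when every one of its (barcode, sample) raw counts
    is below ``min_reads``; multi-feature barcodes (overlapping >= 2
    annotation features) are removed before aggregation.

    Returns the retained rows of the pool (barcode, gene_id).
    """
    counts = getattr(raw, "counts", raw)
    usable = pool[
        (pool["classification"] == "single")
        & (~pool["multi_feature"])
        & (pool["gene_id"] != "intergenic")
    ][["barcode", "gene_id"]]
    usable = usable[usable["barcode"].isin(counts.index)]
    keep_genes = []
    for gene_id, grp in usable.groupby("gene_id"):
        sub = counts.loc[grp["barcode"]]
        if (sub.to_numpy() >= min_reads).any():
            keep_genes.append(gene_id)
    return usable[usable["gene_id"].isin(keep_genes)].reset_index(drop=True)


# ------------------------------------------------------------ log2 ratios


def gene_log2fc(
    norm_counts: pd.DataFrame,
    barcodes: list[str],
    gene_id: str,
    cold_samples: list[str],
    hot_samples: list[str],
    pseudocount: float | None = None,
) -> GeneRatioSet:
    """Baseline-normalized log2 ratios for one gene.

    baseline = mean normalized abundance over {gene barcodes} x {37 deg C
    replicates}; one log2(value/baseline) per barcode per 50 deg C
    replicate. Zero abundances at 50 deg C are dropped (tallied) unless a
    pseudocount is given, in which case log2((value+pseudocount)/baseline)
    is used for them.
    """
    sub = norm_counts.loc[barcodes]
    baseline = float(sub[cold_samples].to_numpy().mean())
    if baseline <= 0:
        return GeneRatioSet(gene_id, baseline, [], len(barcodes))
    hot = sub[hot_samples].to_numpy(dtype=float).ravel()
    ratios: list[float] = []
    dropped = 0
    for v in hot:
        if v > 0:
            ratios.append(math.log2(v / baseline))
        elif pseudocount is not None:
            ratios.append(math.log2((v + pseudocount) / baseline))
        else:
            dropped += 1
    return GeneRatioSet(gene_id, baseline, ratios, len(barcodes), dropped)


# --------------------------------------------------- Wilcoxon signed-rank


def _signed_rank_stat(ratios: np.ndarray) -> tuple[float, np.ndarray]:
    """W+ (sum of positive mid-ranks of |x|, zeros dropped) and the
    mid-rank vector used."""
    x = ratios[ratios != 0]
    ranks = scipy.stats.rankdata(np.abs(x))
    w_plus = float(ranks[x > 0].sum())
    return w_plus, ranks


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p by convolving the signed-rank null distribution.

    Mid-ranks are half-integers at worst; doubling them makes the DP
    integral and tie-exact.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in r2:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    w2 = int(round(2 * w_plus))
    p_le = dist[: w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_one_sample(
    ratios: list[float] | np.ndarray, exact_max_n: int = WILCOXON_EXACT_MAX_N
) -> float:
    """Two-sided one-sample Wilcoxon signed-rank p-value against median 0.

    Zeros are dropped before ranking; exact null enumeration up to
    ``exact_max_n`` non-zero values (tie-exact), tie-corrected normal
    approximation with continuity correction above. All-zero input is the
    degenerate no-signal case and returns p = 1.
    """
    x = np.asarray(ratios, dtype=float)
    if x.size == 0 or np.all(x == 0):
        return 1.0
    nz = x[x != 0]
    if nz.size <= exact_max_n:
        w_plus, ranks = _signed_rank_stat(x)
        return _exact_signed_rank_p(w_plus, ranks)
    res = scipy.stats.wilcoxon(
        nz, zero_method="wilcox", correction=True, alternative="two-sided",
        mode="approx",
    )
    return float(res.pvalue)


# ------------------------------------------------------------ Mann-Whitney


def mann_whitney(
    abund_37: list[float] | np.ndarray,
    abund_50: list[float] | np.ndarray,
    exact_max_n: int = MANNWHITNEY_EXACT_MAX_N,
) -> float:
    """Two-sided Mann-Whitney U p-value comparing the two abundance
    distributions; exact (tie-tolerant, by enumerating group assignments)
    for combined n <= ``exact_max_n``, tie-corrected normal approximation
    with continuity correction otherwise."""
    a = np.asarray(abund_37, dtype=float)
    b = np.asarray(abund_50, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n, m = a.size, b.size
    if n + m <= exact_max_n:
        pooled = np.concatenate([a, b])
        ranks = scipy.stats.rankdata(pooled)
        u_obs = float(ranks[:n].sum()) - n * (n + 1) / 2.0
        us = np.array([
            ranks[list(idx)].sum() - n * (n + 1) / 2.0
            for idx in itertools.combinations(range(n + m), n)
        ])
        eps = 1e-9
        p_le = np.mean(us <= u_obs + eps)
        p_ge = np.mean(us >= u_obs - eps)
        return float(min(1.0, 2.0 * min(p_le, p_ge)))
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


# --------------------------------------------------------------------- BH


def bh_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ------------------------------------------------------------- dispersion


def dispersion(ratios: list[float] | np.ndarray) -> tuple[float, float]:
    """Sample SD (n-1 denominator) and CV% = 100*sd/|mean| of the replicate
    log2 ratios; CV is undefined (NaN) at mean 0."""
    x = np.asarray(ratios, dtype=float)
    if x.size < 2:
        return float("nan"), float("nan")
    sd = float(np.std(x, ddof=1))
    mean = float(np.mean(x))
    cv = float("nan") if mean == 0 else 100.0 * sd / abs(mean)
    return sd, cv


# -------------------------------------------------------------- hit calling


def call_hits(
    results: list[GeneFitnessResult],
    max_barcodes: int = DEFAULT_MAX_BARCODES,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
) -> tuple[list[GeneFitnessResult], list[GeneFitnessResult]]:
    """Apply the barcode-count restriction, BH adjustment and hit rule.

    Genes with more than ``max_barcodes`` uniquely mapped barcodes are
    excluded from testing (returned separately, flagged); among tested
    genes, hits satisfy |mean log2FC| >= lfc_threshold and
    FDR < fdr_threshold, with direction favors-50 when the mean is
    positive.
    """
    tested, excluded = [], []
    for r in results:
        if r.n_barcodes > max_barcodes:
            r.note = f"excluded: >{max_barcodes} barcodes"
            excluded.append(r)
        elif not np.isfinite(r.p_value):
            r.note = r.note or "untestable"
            excluded.append(r)
        else:
            tested.append(r)
    if tested:
        fdrs = bh_adjust([r.p_value for r in tested])
        for r, q in zip(tested, fdrs):
            r.fdr = float(q)
            r.is_hit = bool(abs(r.mean_log2fc) >= lfc_threshold and r.fdr < fdr_threshold)
            r.direction = "favors-50" if r.mean_log2fc > 0 else "favors-37"
    return tested, excluded


# ------------------------------------------------------------ volcano table


def volcano_table(results: list[GeneFitnessResult]) -> pd.DataFrame:
    """One row per tested gene: (gene, mean_log2fc, -log10 fdr, hit flag),
    sorted by fdr ascending then |mean_log2fc| descending."""
    rows = [
        {
            "gene_id": r.gene_id,
            "mean_log2fc": r.mean_log2fc,
            "neg_log10_fdr": -math.log10(r.fdr),
            "is_hit": r.is_hit,
        }
        for r in results
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "mean_log2fc", "neg_log10_fdr", "is_hit"])
    if len(df):
        df = df.sort_values(
            ["neg_log10_fdr", "mean_log2fc"],
            key=lambda s: -s.abs() if s.name == "mean_log2fc" else s,
            ascending=[False, True],
        ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------- pipeline


@dataclass
class FitnessConfig:
    cold_temperature: float = 37.0
    hot_temperature: float = 50.0
    min_reads: int = DEFAULT_MIN_READS
    max_barcodes: int = DEFAULT_MAX_BARCODES
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD
    test: str = "wilcoxon"  # or "mannwhitney"
    pseudocount: float | None = None
    min_nonzero_ratios: int = 3


def fitness_pipeline(
    raw: "object",
    norm: "object",
    pool: pd.DataFrame,
    config: FitnessConfig | None = None,
) -> dict:
    """Run the full gene-level fitness analysis.

    ``raw`` and ``norm`` are the raw and total-count-normalized
    BarcodeCountTables (raw is needed for the read-support filter, norm
    for the ratios). Returns a dict with keys ``results`` (tested genes,
    DataFrame), ``volcano``, ``excluded`` and ``summary``.
    """
    config = config or FitnessConfig()
    cold = [s.sample_id for s in norm.samples if s.temperature == config.cold_temperature]
    hot = [s.sample_id for s in norm.samples if s.temperature == config.hot_temperature]
    if not cold or not hot:
        raise ValueError("need samples at both temperatures")

    usable = filter_barcodes_and_genes(raw, pool, config.min_reads)
    results: list[GeneFitnessResult] = []
    for gene_id, grp in usable.groupby("gene_id"):
        barcodes = list(grp["barcode"])
        rset = gene_log2fc(
            norm.counts, barcodes, gene_id, cold, hot, config.pseudocount
        )
        ratios = np.array(rset.log2_ratios)
        if rset.baseline_37 <= 0:
            results.append(
                GeneFitnessResult(gene_id, float("nan"), float("nan"), float("nan"),
                                  float("nan"), rset.n_barcodes,
                                  note="untestable: zero 37C baseline")
            )
            continue
        n_nonzero = int(np.sum(ratios != 0))
        mean = float(ratios.mean()) if ratios.size else float("nan")
        sd, cv = dispersion(ratios)
        if ratios.size == 0 or n_nonzero < config.min_nonzero_ratios:
            results.append(
                GeneFitnessResult(gene_id, mean, sd, cv, float("nan"),
                                  rset.n_barcodes, n_ratios=len(ratios),
                                  note="untestable: <3 non-zero ratios")
            )
            continue
        if config.test == "mannwhitney":
            sub = norm.counts.loc[barcodes]
            p = mann_whitney(
                sub[cold].to_numpy(dtype=float).ravel(),
                sub[hot].to_numpy(dtype=float).ravel(),
            )
        else:
            p = wilcoxon_one_sample(ratios)
        results.append(
            GeneFitnessResult(gene_id, mean, sd, cv, p, rset.n_barcodes,
                              n_ratios=len(ratios))
        )

    tested, excluded = call_hits(
        results, config.max_barcodes, config.lfc_threshold, config.fdr_threshold
    )
    res_df = _results_frame(tested)
    exc_df = _results_frame(excluded)
    hits = res_df[res_df["is_hit"]]
    summary = {
        "genes_tested": len(res_df),
        "genes_excluded": len(exc_df),
        "n_hits": int(len(hits)),
        "hits_favoring_50": int((hits["direction"] == "favors-50").sum()),
        "hits_favoring_37": int((hits["direction"] == "favors-37").sum()),
    }
    return {
        "results": res_df,
        "volcano": volcano_table(tested),
        "excluded": exc_df,
        "summary": summary,
    }


def _results_frame(results: list[GeneFitnessResult]) -> pd.DataFrame:
    cols = ["gene_id", "n_barcodes", "n_ratios", "mean_log2fc", "sd", "cv_percent",
            "p_value", "fdr", "is_hit", "direction", "note"]
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id, "n_barcodes": r.n_barcodes, "n_ratios": r.n_ratios,
                "mean_log2fc": r.mean_log2fc, "sd": r.sd, "cv_percent": r.cv_percent,
                "p_value": r.p_value, "fdr": r.fdr, "is_hit": r.is_hit,
                "direction": r.direction, "note": r.note,
            }
            for r in results
        ],
        columns=cols,
    )
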