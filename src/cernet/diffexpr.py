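"""Differential expression for RNA-seq count matrices.

Implements the classic small-n two-group workflow for tumour/normal
comparisons: transcript-to-gene aggregation, TMM (trimmed mean of
M-values) normalization, conditional maximum-likelihood estimation of a
common negative-binomial dispersion, the NB exact test conditioned on
per-gene totals, Benjamini-Hochberg FDR adjustment, and DEG calling at
fold change > 2 / FDR < 0.05.

The negative binomial is parameterized by mean mu and dispersion phi,
with variance mu + phi * mu**2 (phi = 0 recovers the Poisson).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

TUMOUR = "tumour"
NORMAL = "normal"

__all__ = [
    "CountsMatrix",
    "NormFactors",
    "aggregate_by_gene",
    "tmm_norm_factors",
    "estimate_common_dispersion",
    "exact_test",
    "bh_adjust",
    "call_degs",
    "deg_directions",
    "normalized_log_transform",
    "de_analysis",
    "volcano_coordinates",
    "heatmap_matrix",
    "read_counts_tsv",
    "write_de_table",
]


@dataclass
class CountsMatrix:
    """Non-negative integer gene x sample count table with condition labels.

    Parameters
    ----------
    counts : pd.DataFrame
        Rows indexed by unique gene IDs, one column per sample.
    condition : dict
        Maps every sample name to ``"tumour"`` or ``"normal"``.
    """

    counts: pd.DataFrame
    condition: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups[:5]}")
        arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if arr.size and not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integral")
        if self.condition:
            missing = [s for s in self.counts.columns if s not in self.condition]
            if missing:
                raise ValueError(f"samples without condition: {missing}")
            bad = {c for c in self.condition.values()} - {TUMOUR, NORMAL}
            if bad:
                raise ValueError(f"unknown conditions: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def group_samples(self, cond: str) -> list[str]:
        return [s for s in self.samples if self.condition.get(s) == cond]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class NormFactors:
    """Per-sample TMM scaling factors (geometric mean 1) and library sizes."""

    factors: pd.Series
    lib_sizes: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")
        gm = float(np.exp(np.mean(np.log(self.factors.to_numpy()))))
        if abs(gm - 1.0) > 1e-9:
            raise ValueError(f"factors must have geometric mean 1, got {gm}")

    def effective_sizes(self) -> pd.Series:
        return self.lib_sizes * self.factors


def aggregate_by_gene(transcript_counts: CountsMatrix, mapping) -> CountsMatrix:
    """Sum transcript-level counts into gene-level counts.

    ``mapping`` is a dict ``transcript -> gene`` or an iterable of
    ``(transcript, gene)`` pairs. A transcript mapped to two different
    genes is an error; transcripts absent from the mapping are dropped
    (their number is logged).
    """
    if isinstance(mapping, dict):
        pairs = list(mapping.items())
    else:
        pairs = list(mapping)
    if not pairs:
        raise ValueError("empty transcript-to-gene mapping")
    tx2gene: dict[str, str] = {}
    for tx, gene in pairs:
        if tx in tx2gene and tx2gene[tx] != gene:
            raise ValueError(f"transcript {tx!r} maps to multiple genes")
        tx2gene[tx] = gene

    idx = transcript_counts.counts.index
    mapped = idx.isin(tx2gene)
    n_unmapped = int((~mapped).sum())
    if n_unmapped:
        logger.info("aggregate_by_gene: dropping %d unmapped transcripts", n_unmapped)
    sub = transcript_counts.counts.loc[mapped]
    genes = sub.index.map(tx2gene)
    agg = sub.groupby(genes, sort=True).sum()
    agg.index.name = transcript_counts.counts.index.name
    return CountsMatrix(agg, dict(transcript_counts.condition))


def _choose_ref_sample(counts: pd.DataFrame) -> str:
    # edgeR convention: sample whose upper quartile of the count
    # proportions is closest to the mean upper quartile.
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    props = counts.to_numpy(dtype=float) / lib
    uq = np.quantile(props, 0.75, axis=0)
    return counts.columns[int(np.argmin(np.abs(uq - uq.mean())))]


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
    min_genes: int = 10,
) -> float:
    """Trimmed weighted mean of M-values of one sample against the reference.

    Genes with a zero in either library are excluded; the top/bottom 30%
    by M and 5% by A are trimmed; remaining M-values are averaged with
    inverse delta-method (binomial) variance weights.
    """
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    if o.size == 0:
        warnings.warn("TMM: no genes expressed in both libraries; factor set to 1")
        return 1.0
    po, pr = o / n_obs, r / n_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # matches edgeR: trivially similar libraries get factor 1
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    if o.size == 1:
        return float(2.0 ** m[0])
    n = m.size
    lo_m = math.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if keep2.sum() < min_genes:
        warnings.warn(
            f"TMM: only {int(keep2.sum())} genes retained after trimming; factor set to 1"
        )
        return 1.0
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    f = np.sum(m[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_norm_factors(counts: CountsMatrix, ref_sample: str | None = None) -> NormFactors:
    """TMM normalization factors for every sample, rescaled to geometric mean 1."""
    df = counts.counts
    if df.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    lib = df.sum(axis=0).astype(float)
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise ValueError(f"all-zero samples: {bad}")
    if ref_sample is None:
        ref_sample = _choose_ref_sample(df)
    elif ref_sample not in df.columns:
        raise ValueError(f"unknown reference sample {ref_sample!r}")
    ref = df[ref_sample].to_numpy()
    n_ref = float(lib[ref_sample])
    factors = {}
    for s in df.columns:
        if s == ref_sample:
            factors[s] = 1.0
        else:
            factors[s] = _tmm_pair_factor(df[s].to_numpy(), ref, float(lib[s]), n_ref)
    f = pd.Series(factors).reindex(df.columns)
    f = f / np.exp(np.mean(np.log(f)))
    return NormFactors(f, lib)


def _equalized_counts(counts: CountsMatrix, factors: NormFactors) -> tuple[np.ndarray, float]:
    """Rescale counts to the geometric mean of effective library sizes, rounded.

    Returns the integer pseudo-count matrix (genes x samples) and the
    common library size. Keeping the counts integral keeps the exact-test
    convolution exact.
    """
    eff = factors.effective_sizes().reindex(counts.samples).to_numpy(dtype=float)
    common = float(np.exp(np.mean(np.log(eff))))
    pseudo = counts.counts.to_numpy(dtype=float) * (common / eff)
    return np.round(pseudo), common


def _cond_loglik_group(y: np.ndarray, phi: float) -> float:
    """NB conditional log-likelihood of one group's counts given their totals.

    ``y`` is genes x samples with (approximately) equal library sizes.
    Terms not involving phi are dropped.
    """
    n = y.shape[1]
    if n < 2:
        return 0.0
    r = 1.0 / phi
    z = y.sum(axis=1)
    ll = (
        gammaln(y + r).sum(axis=1)
        + gammaln(n * r)
        - gammaln(z + n * r)
        - n * gammaln(r)
    )
    return float(ll.sum())


def estimate_common_dispersion(
    counts: CountsMatrix,
    factors: NormFactors,
    lower: float = 1e-6,
    upper: float = 10.0,
) -> float:
    """Common NB dispersion by conditional maximum likelihood.

    Maximizes the summed per-gene conditional log-likelihood (given gene
    totals within each condition) over counts equalized to a common
    effective library size, by golden-section search on log(phi) over
    [lower, upper]. Requires >= 2 samples in at least one condition;
    with n = 1 per group the dispersion must be supplied externally.
    """
    y, _ = _equalized_counts(counts, factors)
    if not y.any():
        raise ValueError("all-zero count matrix")
    groups = []
    for cond in (TUMOUR, NORMAL):
        cols = [counts.samples.index(s) for s in counts.group_samples(cond)]
        if len(cols) >= 2:
            sub = y[:, cols]
            groups.append(sub[sub.sum(axis=1) > 0])
    if not groups:
        raise ValueError(
            "need >= 2 samples in at least one condition to estimate dispersion; "
            "supply phi explicitly for n=1 designs"
        )

    def negll(logphi: float) -> float:
        phi = math.exp(logphi)
        return -sum(_cond_loglik_group(g, phi) for g in groups)

    invphi = (math.sqrt(5) - 1) / 2
    a, b = math.log(lower), math.log(upper)
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = negll(c), negll(d)
    while b - a > 1e-4:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = negll(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = negll(d)
    phi = math.exp((a + b) / 2)
    # monotone-toward-boundary cases collapse to the bound itself
    if negll(math.log(lower)) <= negll(math.log(phi)):
        return lower
    return phi


def _exact_test_pvalue(sum_a: int, sum_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional NB exact test for two group sums.

    Conditioned on z = sum_a + sum_b, the split follows the convolution
    of NB(n_a * mu, phi / n_a) and NB(n_b * mu, phi / n_b) (binomial when
    phi = 0). p is the total probability of all partitions whose point
    probability is <= that of the observed one (ties included).
    """
    z = sum_a + sum_b
    if z == 0:
        return 1.0
    s = np.arange(z + 1)
    if phi < 1e-12:
        # Poisson limit: binomial split of the total
        p_a = n_a / (n_a + n_b)
        logpmf = (
            gammaln(z + 1)
            - gammaln(s + 1)
            - gammaln(z - s + 1)
            + s * math.log(p_a)
            + (z - s) * math.log1p(-p_a)
        )
    else:
        mu = z / (n_a + n_b)  # per-sample mean under the null
        r_a, r_b = n_a / phi, n_b / phi
        m_a, m_b = n_a * mu, n_b * mu
        la = math.log(r_a / (r_a + m_a))
        lb = math.log(r_b / (r_b + m_b))
        l1a = math.log(m_a / (r_a + m_a))
        l1b = math.log(m_b / (r_b + m_b))
        lp_a = gammaln(s + r_a) - gammaln(s + 1) - gammaln(r_a) + r_a * la + s * l1a
        t = z - s
        lp_b = gammaln(t + r_b) - gammaln(t + 1) - gammaln(r_b) + r_b * lb + t * l1b
        logpmf = lp_a + lp_b
    logpmf -= logpmf.max()
    pmf = np.exp(logpmf)
    total = pmf.sum()
    obs = pmf[sum_a]
    # ties included in the rejection mass; tiny slack guards float noise
    p = pmf[pmf <= obs * (1 + 1e-12)].sum() / total
    return float(min(p, 1.0))


def exact_test(
    counts: CountsMatrix,
    factors: NormFactors,
    phi: float,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """NB exact test per gene; returns gene, log2fc, pvalue.

    Counts are equalized to a common library size; conditioning on each
    gene's total, the two group sums follow NB convolutions and the
    two-sided p-value sums all partitions at most as probable as the
    observed one. log2fc is log2 of the ratio of group mean CPM (on the
    TMM-normalized scale) with a prior count added to each group mean.
    """
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    conds = {counts.condition[s] for s in counts.samples}
    if conds != {TUMOUR, NORMAL}:
        raise ValueError("exact test requires exactly the two conditions tumour/normal")
    y, common = _equalized_counts(counts, factors)
    cols_t = [counts.samples.index(s) for s in counts.group_samples(TUMOUR)]
    cols_n = [counts.samples.index(s) for s in counts.group_samples(NORMAL)]
    n_t, n_n = len(cols_t), len(cols_n)
    sums_t = y[:, cols_t].sum(axis=1).astype(np.int64)
    sums_n = y[:, cols_n].sum(axis=1).astype(np.int64)

    cpm_scale = 1e6 / common
    mean_cpm_t = sums_t / n_t * cpm_scale
    mean_cpm_n = sums_n / n_n * cpm_scale
    log2fc = np.log2((mean_cpm_t + prior_count) / (mean_cpm_n + prior_count))

    pvals = np.ones(len(sums_t))
    for i in range(len(sums_t)):
        z = sums_t[i] + sums_n[i]
        if z == 0:
            pvals[i] = 1.0
            log2fc[i] = 0.0
        else:
            pvals[i] = _exact_test_pvalue(int(sums_t[i]), int(sums_n[i]), n_t, n_n, phi)
    return pd.DataFrame(
        {"gene": counts.gene_ids, "log2fc": log2fc, "pvalue": pvals}
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved).

    fdr_i = min over j >= rank(i) of m * p_(j) / j, clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def call_degs(
    results: pd.DataFrame,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Attach direction calls: up/down iff |log2fc| > log2(fc) AND fdr < threshold.

    Both inequalities are strict, matching the ``fold change > 2`` /
    ``FDR < 0.05`` convention.
    """
    if "fdr" not in results.columns:
        raise ValueError("results must carry an fdr column (run bh_adjust first)")
    out = results.copy()
    sig = (np.abs(out["log2fc"]) > np.log2(fc_threshold)) & (out["fdr"] < fdr_threshold)
    out["direction"] = np.where(
        sig, np.where(out["log2fc"] > 0, "up", "down"), "ns"
    )
    return out


def deg_directions(results: pd.DataFrame) -> dict[str, str]:
    """Map of DEG gene -> direction (up/down), dropping non-significant genes."""
    sig = results[results["direction"] != "ns"]
    return dict(zip(sig["gene"], sig["direction"]))


def normalized_log_transform(value):
    """log10(value + 0.001), the heatmap display transform for normalized expression."""
    v = np.asarray(value, dtype=float)
    if np.any(v < 0):
        raise ValueError("normalized expression must be non-negative")
    out = np.log10(v + 0.001)
    return float(out) if np.isscalar(value) or out.ndim == 0 else out


def de_analysis(
    counts: CountsMatrix,
    phi: float | None = None,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Full DE workflow: TMM -> common dispersion -> exact test -> BH -> DEG call."""
    factors = tmm_norm_factors(counts)
    if phi is None:
        phi = estimate_common_dispersion(counts, factors)
    res = exact_test(counts, factors, phi)
    res["fdr"] = bh_adjust(res["pvalue"].to_numpy())
    res = call_degs(res, fc_threshold, fdr_threshold)
    res.attrs["dispersion"] = phi
    return res


def volcano_coordinates(results: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot coordinates: log2(fold change) vs -log10(FDR)."""
    fdr = results["fdr"].to_numpy(dtype=float)
    neg = -np.log10(np.maximum(fdr, np.finfo(float).tiny))
    return pd.DataFrame(
        {"gene": results["gene"], "log2fc": results["log2fc"], "neg_log10_fdr": neg}
    )


def heatmap_matrix(counts: CountsMatrix, factors: NormFactors) -> pd.DataFrame:
    """Normalized CPM on the log10(x + 0.001) display scale (genes x samples)."""
    eff = factors.effective_sizes().reindex(counts.samples).to_numpy(dtype=float)
    cpm = counts.counts.to_numpy(dtype=float) / eff * 1e6
    return pd.DataFrame(
        normalized_log_transform(cpm), index=counts.gene_ids, columns=counts.samples
    )


def read_counts_tsv(counts_path, sample_sheet_path) -> CountsMatrix:
    """Read a gene x sample counts TSV plus a sample sheet (sample, condition)."""
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    cond = dict(zip(sheet["sample"].astype(str), sheet["condition"].astype(str)))
    return CountsMatrix(df, cond)


def write_de_table(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)
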