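"""Expression-dichotomized survival screening of network genes.

Per gene: split the cohort at the median expression, estimate the two
Kaplan-Meier (product-limit) curves, compare them with the two-group
log-rank test, and keep genes significant at p < alpha, recording which
expression group is the risky one. No multiplicity correction gates the
screen (per-gene p < 0.05 reporting), but a BH column is always emitted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "KMCurve",
    "LogRankResult",
    "dichotomize",
    "km_estimator",
    "logrank_test",
    "screen_survival_genes",
    "read_clinical_tsv",
]


@dataclass
class KMCurve:
    """Product-limit survival estimate at the distinct event times."""

    times: np.ndarray       # distinct event times, ascending
    at_risk: np.ndarray     # n_i just before each event time
    events: np.ndarray      # d_i events at each time
    survival: np.ndarray    # S(t_i) = prod_{j<=i} (1 - d_j/n_j)

    def survival_at(self, t: float) -> float:
        """S(t); 1.0 before the first event time."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "n_at_risk": self.at_risk,
             "n_events": self.events, "survival": self.survival}
        )


@dataclass
class LogRankResult:
    gene: str | None
    chi_square: float
    pvalue: float
    n_high: int
    n_low: int
    risky_group: str | None  # "high" | "low" | None when no signal


def dichotomize(expression, rule: str = "median", q: float = 0.5) -> np.ndarray:
    """Label samples "high" (value > cut) or "low" (value <= cut).

    The cut-point is the median by default (``rule="quantile"`` with ``q``
    for other splits). Ties at the cut go to the low group. Requires >= 4
    samples and a non-constant vector so both groups are non-empty.
    """
    v = np.asarray(expression, dtype=float)
    if v.size < 4:
        raise ValueError("dichotomization needs >= 4 samples")
    if np.all(v == v[0]):
        raise ValueError("constant expression vector cannot be dichotomized")
    if rule == "median":
        cut = np.median(v)
    elif rule == "quantile":
        if not 0 < q < 1:
            raise ValueError("quantile must lie in (0, 1)")
        cut = np.quantile(v, q)
    else:
        raise ValueError(f"unknown dichotomization rule {rule!r}")
    labels = np.where(v > cut, "high", "low")
    if len(set(labels)) < 2:
        raise ValueError("degenerate split: one group is empty")
    return labels


def km_estimator(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate with right-censoring.

    Censored-only times reduce the risk set but add no step.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("no records")
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    if not set(np.unique(e)) <= {0, 1}:
        raise ValueError("events must be 0 (censored) or 1 (death)")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    ev_times = np.unique(t[e == 1])
    n = t.size
    at_risk, d, surv = [], [], []
    s = 1.0
    for ti in ev_times:
        n_i = int(np.sum(t >= ti))
        d_i = int(np.sum((t == ti) & (e == 1)))
        s *= 1.0 - d_i / n_i
        at_risk.append(n_i)
        d.append(d_i)
        surv.append(s)
    return KMCurve(
        times=ev_times,
        at_risk=np.array(at_risk, dtype=int),
        events=np.array(d, dtype=int),
        survival=np.array(surv, dtype=float),
    )


def logrank_test(groups, times, events, gene: str | None = None) -> LogRankResult:
    """Two-group log-rank test.

    chi2 = (sum_i (O1_i - E1_i))^2 / sum_i V_i over distinct event times,
    with E1_i = d_i * n1_i / n_i and hypergeometric variance
    V_i = d_i (n1_i/n_i)(1 - n1_i/n_i)(n_i - d_i)/(n_i - 1); p from the
    1-df chi-square upper tail. The risky group is the one with more
    observed than expected events.
    """
    g = np.asarray(groups)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    labels = sorted(set(g.tolist()))
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly two groups, got {labels}")
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    n_high = int(np.sum(g == "high")) if "high" in labels else int(np.sum(g == labels[0]))
    n_low = t.size - n_high
    g1 = labels[1] if "high" not in labels else "high"

    ev_times = np.unique(t[e == 1])
    if ev_times.size == 0:
        warnings.warn("log-rank: no events observed; chi-square set to 0")
        return LogRankResult(gene, 0.0, 1.0, n_high, n_low, None)

    o_minus_e = 0.0
    var = 0.0
    for ti in ev_times:
        at_risk = t >= ti
        n_i = int(at_risk.sum())
        n1_i = int((at_risk & (g == g1)).sum())
        d_i = int(((t == ti) & (e == 1)).sum())
        o1_i = int(((t == ti) & (e == 1) & (g == g1)).sum())
        e1_i = d_i * n1_i / n_i
        o_minus_e += o1_i - e1_i
        if n_i > 1:
            p1 = n1_i / n_i
            var += d_i * p1 * (1 - p1) * (n_i - d_i) / (n_i - 1)
    if var <= 0:
        return LogRankResult(gene, 0.0, 1.0, n_high, n_low, None)
    stat = o_minus_e**2 / var
    p = float(chi2.sf(stat, df=1))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    if o_minus_e > 0:
        risky = g1
    elif o_minus_e < 0:
        risky = [l for l in labels if l != g1][0]
    else:
        risky = None
    return LogRankResult(gene, float(stat), p, n_high, n_low, risky)


def screen_survival_genes(
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    alpha: float = 0.05,
    rule: str = "median",
    q: float = 0.5,
    keep_all: bool = False,
) -> pd.DataFrame:
    """Median-split log-rank screen of every gene in the expression matrix.

    ``expression`` is genes x samples; ``clinical`` has columns sample,
    time_days (or time) and event. Samples are matched by name; genes with
    constant expression in the matched cohort are skipped with a warning.
    Returns significant genes (p < alpha) unless ``keep_all``; the fdr
    column is BH across all tested genes.
    """
    tcol = "time_days" if "time_days" in clinical.columns else "time"
    clin = clinical.drop_duplicates(subset="sample").set_index("sample")
    common = [s for s in expression.columns if s in clin.index]
    if len(common) < 10:
        raise ValueError(f"only {len(common)} samples shared with the clinical table (need >= 10)")
    t = clin.loc[common, tcol].to_numpy(dtype=float)
    e = clin.loc[common, "event"].to_numpy(dtype=int)

    rows = []
    for gene, values in expression[common].iterrows():
        v = values.to_numpy(dtype=float)
        try:
            labels = dichotomize(v, rule=rule, q=q)
        except ValueError as err:
            warnings.warn(f"gene {gene!r} skipped: {err}")
            continue
        res = logrank_test(labels, t, e, gene=gene)
        rows.append(
            {
                "gene": gene,
                "chi_square": res.chi_square,
                "pvalue": res.pvalue,
                "risky_group": res.risky_group,
                "n_high": res.n_high,
                "n_low": res.n_low,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["gene", "chi_square", "pvalue", "fdr", "risky_group", "n_high", "n_low"]
        )
    df = pd.DataFrame(rows)
    df["fdr"] = bh_adjust(df["pvalue"].to_numpy())
    df = df[["gene", "chi_square", "pvalue", "fdr", "risky_group", "n_high", "n_low"]]
    tested = len(df)
    if not keep_all:
        df = df[df["pvalue"] < alpha].reset_index(drop=True)
    logger.info("survival screen: %d genes tested, %d significant at p < %g", tested, int((df['pvalue'] < alpha).sum()), alpha)
    return df.sort_values("pvalue", kind="mergesort").reset_index(drop=True)


def read_clinical_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    tcol = "time_days" if "time_days" in df.columns else "time"
    required = {"sample", tcol, "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    if (df[tcol] <= 0).any():
        raise ValueError("clinical times must be positive")
    if not set(df["event"].unique()) <= {0, 1}:
        raise ValueError("event must be 0/1")
    if df["sample"].duplicated().any():
        raise ValueError("duplicate samples in clinical table")
    return df
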