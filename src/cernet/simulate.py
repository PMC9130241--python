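"""Synthetic tumour/normal ceRNA study generator with a planted ground truth.

Emulates a paired 3-tumour / 3-paratumour RNA-seq design across three RNA
classes (lncRNA, miRNA, mRNA). Counts follow a negative binomial with
variance mu + phi * mu**2; a configurable number of ceRNA triples is
planted with direction-coupled differential expression (high-low-high or
low-high-low), and the downstream resources — interaction tables with
decoys, gene-set collections with one enriched set, and a survival cohort
with expression-dependent hazard — are generated consistently with that
truth, so every pipeline stage has a recoverable answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import CountsMatrix, TUMOUR, NORMAL
from .interactions import InteractionTable
from .enrichment import GeneSetCollection

__all__ = [
    "SimConfig",
    "PlantedTruth",
    "simulate_counts",
    "simulate_interactions",
    "simulate_genesets",
    "simulate_survival",
    "simulate_all",
    "write_simulation",
]

RNA_CLASSES = ("lncRNA", "miRNA", "mRNA")

# trend -> (lncRNA, miRNA, mRNA) differential-expression directions.
# HLH: the sponge lncRNA and its protected mRNA are up, the shared miRNA down.
TREND_DIRECTIONS = {
    "HLH": ("up", "down", "up"),
    "LHL": ("down", "up", "down"),
}


@dataclass
class SimConfig:
    """Stated world of the synthetic study.

    Defaults mirror the desk-scale design: 3 tumour/normal pairs, 20
    planted triples with |log2FC| = 3, NB dispersion 0.1, libraries of
    1e5-2e5 reads, three miRNA-target sources, and an 85-patient survival
    cohort with hazard ratio 3 for the risky expression group.
    """

    n_lnc: int = 200
    n_mir: int = 150
    n_mrna: int = 500
    n_pairs: int = 3
    n_triples: int = 20
    effect_log2fc: float = 3.0
    dispersion: float = 0.1
    lib_size_range: tuple[float, float] = (100_000.0, 200_000.0)
    decoy_pair_rate: float = 0.005
    n_sources: int = 3
    n_genesets: int = 20
    geneset_size_range: tuple[int, int] = (15, 60)
    n_survival_samples: int = 85
    hazard_ratio: float = 3.0
    censor_rate: float = 0.3
    baseline_survival_scale: float = 1500.0  # days; exponential scale for baseline hazard
    allow_confusable: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lnc", "n_mir", "n_mrna", "n_pairs", "n_sources"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_triples < 0:
            raise ValueError("n_triples must be >= 0")
        if self.n_triples > min(self.n_lnc, self.n_mir, self.n_mrna):
            raise ValueError("n_triples exceeds the smallest gene universe")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.decoy_pair_rate <= 1:
            raise ValueError("decoy_pair_rate must lie in [0, 1]")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if self.lib_size_range[0] <= 0 or self.lib_size_range[1] < self.lib_size_range[0]:
            raise ValueError("invalid lib_size_range")
        if self.n_survival_samples < 10:
            raise ValueError("n_survival_samples must be >= 10")


@dataclass
class PlantedTruth:
    """Ground truth of one simulated study.

    de_genes maps each RNA class to {gene: direction}; every triple member
    appears there with the direction its trend dictates.
    """

    de_genes: dict[str, dict[str, str]]
    triples: list[tuple[str, str, str, str]]  # (lncRNA, miRNA, mRNA, trend)
    enriched_set: str | None = None
    survival_genes: dict[str, str] = field(default_factory=dict)  # gene -> "high"/"low" risky

    def check_consistency(self) -> bool:
        """True iff every planted triple is direction-consistent with de_genes."""
        for lnc, mir, mrna, trend in self.triples:
            want = TREND_DIRECTIONS.get(trend)
            if want is None:
                return False
            got = (
                self.de_genes["lncRNA"].get(lnc),
                self.de_genes["miRNA"].get(mir),
                self.de_genes["mRNA"].get(mrna),
            )
            if got != want:
                return False
        return True


def _gene_names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def _class_counts(
    rng: np.random.Generator,
    genes: list[str],
    directions: dict[str, str],
    cfg: SimConfig,
) -> CountsMatrix:
    """NB counts for one RNA class under the planted fold changes.

    Baselines b_g are log-uniform over 4 decades; planted DE genes draw
    from the top 2 decades so a 3 vs 3 design can resolve them. Tumour
    means are b_g * 2**(+-effect) for planted genes; library factors L_i
    are uniform over lib_size_range and apply to the normal-condition
    composition.
    """
    n = len(genes)
    b = 10.0 ** rng.uniform(-4.0, 0.0, size=n)
    idx = {g: i for i, g in enumerate(genes)}
    for g in directions:
        b[idx[g]] = 10.0 ** rng.uniform(-2.0, 0.0)
    b = b / b.sum()

    sign = np.zeros(n)
    for g, d in directions.items():
        sign[idx[g]] = 1.0 if d == "up" else -1.0

    samples, conds = [], {}
    cols = []
    lo, hi = cfg.lib_size_range
    for k in range(1, cfg.n_pairs + 1):
        for cond, tag in ((TUMOUR, "T"), (NORMAL, "N")):
            name = f"{tag}{k}"
            lib = rng.uniform(lo, hi)
            mean = lib * b
            if cond == TUMOUR:
                mean = mean * 2.0 ** (sign * cfg.effect_log2fc)
            phi = cfg.dispersion
            if phi < 1e-12:
                counts = rng.poisson(mean)
            else:
                r = 1.0 / phi
                counts = rng.negative_binomial(r, r / (r + mean))
            samples.append(name)
            conds[name] = cond
            cols.append(counts)
    df = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(genes, name="gene"), columns=samples
    )
    return CountsMatrix(df, conds)


def simulate_counts(config: SimConfig) -> tuple[dict[str, CountsMatrix], PlantedTruth]:
    """Generate per-class count matrices and the planted truth.

    Each planted triple picks distinct genes (one per class, no reuse) and
    a random trend; its members' DE directions follow the trend. Survival
    risk directions are assigned to planted triple mRNAs: HLH mRNAs are
    up in tumour and risky when highly expressed, LHL mRNAs risky when
    lowly expressed.
    """
    rng = np.random.default_rng(config.seed)
    lnc = _gene_names("LNC", config.n_lnc)
    mir = _gene_names("MIR", config.n_mir)
    mrna = _gene_names("MRNA", config.n_mrna)

    pick = lambda pool: list(rng.choice(pool, size=config.n_triples, replace=False))
    t_lnc, t_mir, t_mrna = pick(lnc), pick(mir), pick(mrna)
    trends = rng.choice(list(TREND_DIRECTIONS), size=config.n_triples)

    de: dict[str, dict[str, str]] = {c: {} for c in RNA_CLASSES}
    triples = []
    survival_genes = {}
    for L, M, G, tr in zip(t_lnc, t_mir, t_mrna, trends):
        d_l, d_m, d_g = TREND_DIRECTIONS[tr]
        de["lncRNA"][L] = d_l
        de["miRNA"][M] = d_m
        de["mRNA"][G] = d_g
        triples.append((L, M, G, str(tr)))
        survival_genes[G] = "high" if tr == "HLH" else "low"

    truth = PlantedTruth(de_genes=de, triples=triples, survival_genes=survival_genes)
    counts = {
        "lncRNA": _class_counts(rng, lnc, de["lncRNA"], config),
        "miRNA": _class_counts(rng, mir, de["miRNA"], config),
        "mRNA": _class_counts(rng, mrna, de["mRNA"], config),
    }
    return counts, truth


def _decoy_pairs(
    rng: np.random.Generator,
    regulators: list[str],
    targets: list[str],
    planted: set[tuple[str, str]],
    rate: float,
    forbidden_reg: set[str],
    forbidden_tgt: set[str],
    allow_confusable: bool,
) -> set[tuple[str, str]]:
    """Independent Bernoulli(rate) decoys over all non-planted pairs.

    Unless allow_confusable, a decoy never joins two planted DE genes, so
    no spurious direction-consistent triple can arise among planted genes.
    """
    if rate == 0:
        return set()
    n_r, n_t = len(regulators), len(targets)
    mask = rng.random((n_r, n_t)) < rate
    out = set()
    for i, j in zip(*np.nonzero(mask)):
        pair = (regulators[i], targets[j])
        if pair in planted:
            continue
        if not allow_confusable and pair[0] in forbidden_reg and pair[1] in forbidden_tgt:
            continue
        out.add(pair)
    return out


def simulate_interactions(
    truth: PlantedTruth, config: SimConfig
) -> tuple[InteractionTable, list[InteractionTable]]:
    """Interaction tables: one lncRNA-miRNA source and n_sources miRNA-mRNA sources.

    Every planted lnc-mir pair is present in the single lnc-mir table and
    every planted mir-mRNA pair is present in all miRNA-target sources;
    decoys are added independently per source.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lnc = _gene_names("LNC", config.n_lnc)
    mir = _gene_names("MIR", config.n_mir)
    mrna = _gene_names("MRNA", config.n_mrna)
    planted_lm = {(L, M) for L, M, _, _ in truth.triples}
    planted_mg = {(M, G) for _, M, G, _ in truth.triples}
    de_lnc = set(truth.de_genes["lncRNA"])
    de_mir = set(truth.de_genes["miRNA"])
    de_mrna = set(truth.de_genes["mRNA"])

    lm_pairs = planted_lm | _decoy_pairs(
        rng, lnc, mir, planted_lm, config.decoy_pair_rate,
        de_lnc, de_mir, config.allow_confusable,
    )
    lnc_mir = InteractionTable(source="encori_like", pairs=frozenset(lm_pairs))

    mg_tables = []
    for s in range(config.n_sources):
        pairs = planted_mg | _decoy_pairs(
            rng, mir, mrna, planted_mg, config.decoy_pair_rate,
            de_mir, de_mrna, config.allow_confusable,
        )
        mg_tables.append(InteractionTable(source=f"source_{s + 1}", pairs=frozenset(pairs)))
    return lnc_mir, mg_tables


def simulate_genesets(truth: PlantedTruth, config: SimConfig) -> GeneSetCollection:
    """Gene-set collection over the mRNA universe with one planted-enriched set.

    The enriched set holds >= 80% of the planted triple mRNAs plus random
    fillers; the remaining sets are uniform random samples.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    universe = _gene_names("MRNA", config.n_mrna)
    lo, hi = config.geneset_size_range
    sets: dict[str, tuple[str, frozenset[str]]] = {}

    planted = [G for _, _, G, _ in truth.triples]
    enriched_name = None
    if planted:
        n_in = max(1, int(np.ceil(0.8 * len(planted))))
        members = set(rng.choice(planted, size=n_in, replace=False))
        fillers = [g for g in universe if g not in members]
        size = int(rng.integers(lo, hi + 1))
        n_fill = max(0, size - len(members))
        members |= set(rng.choice(fillers, size=min(n_fill, len(fillers)), replace=False))
        enriched_name = "SET_ENRICHED"
        sets[enriched_name] = ("planted-enriched set", frozenset(members))

    for i in range(1, config.n_genesets + 1):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(universe, size=size, replace=False))
        sets[f"SET_{i:03d}"] = (f"random set {i}", members)

    truth.enriched_set = enriched_name
    return GeneSetCollection(sets=sets, universe=frozenset(universe))


def simulate_survival(
    truth: PlantedTruth, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort expression matrix (genes x samples) and clinical table.

    Expression is log-normal per gene. For each planted survival gene the
    half of the cohort on the risky side of that gene's median has its
    exponential event rate larger by a factor hazard_ratio than the other
    half (the contrast is centred: x sqrt(HR) vs / sqrt(HR), so effects of
    several planted genes multiply without inflating the global time
    scale). Censoring is independent: with probability censor_rate a
    record is censored at a uniform fraction of its event time. Times are
    in days and strictly positive.
    """
    if config.hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    n = config.n_survival_samples
    samples = [f"P{i:03d}" for i in range(1, n + 1)]
    genes = _gene_names("MRNA", config.n_mrna)
    expr = pd.DataFrame(
        rng.lognormal(mean=3.0, sigma=1.0, size=(len(genes), n)),
        index=pd.Index(genes, name="gene"),
        columns=samples,
    )

    log_rate = np.full(n, -np.log(config.baseline_survival_scale))
    for gene, risky in truth.survival_genes.items():
        v = expr.loc[gene].to_numpy()
        high = v > np.median(v)
        risky_mask = high if risky == "high" else ~high
        half_log_hr = 0.5 * np.log(config.hazard_ratio)
        log_rate = log_rate + np.where(risky_mask, half_log_hr, -half_log_hr)

    t_event = rng.exponential(scale=1.0 / np.exp(log_rate))
    censored = rng.random(n) < config.censor_rate
    t_obs = np.where(censored, t_event * rng.uniform(0.05, 0.95, size=n), t_event)
    t_obs = np.maximum(t_obs, 1e-3)
    clinical = pd.DataFrame(
        {"sample": samples, "time_days": t_obs, "event": (~censored).astype(int)}
    )
    return expr, clinical


def simulate_all(config: SimConfig):
    """Run all four generators; returns (counts, truth, interactions, genesets, survival)."""
    counts, truth = simulate_counts(config)
    lnc_mir, mir_mrna = simulate_interactions(truth, config)
    genesets = simulate_genesets(truth, config)
    expr, clinical = simulate_survival(truth, config)
    return counts, truth, (lnc_mir, mir_mrna), genesets, (expr, clinical)


def write_simulation(outdir, config: SimConfig) -> PlantedTruth:
    """Generate everything and write the plain-text artifacts of one study.

    Per class: counts TSV + shared sample sheet; interaction TSVs; GMT;
    clinical TSV; truth JSON.
    """
    from .enrichment import write_gmt
    from .interactions import write_interaction_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, truth, (lnc_mir, mir_mrna), genesets, (expr, clinical) = simulate_all(config)

    any_cm = counts["mRNA"]
    sheet = pd.DataFrame(
        {
            "sample": any_cm.samples,
            "condition": [any_cm.condition[s] for s in any_cm.samples],
            "patient": [s[1:] for s in any_cm.samples],
        }
    )
    sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
    for cls, cm in counts.items():
        cm.counts.to_csv(outdir / f"counts_{cls}.tsv", sep="\t")
    write_interaction_table(lnc_mir, outdir / "interactions_lnc_mir.tsv")
    for t in mir_mrna:
        write_interaction_table(t, outdir / f"interactions_mir_mrna_{t.source}.tsv")
    write_gmt(genesets, outdir / "genesets.gmt")
    expr.to_csv(outdir / "survival_expression.tsv", sep="\t")
    clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "de_genes": truth.de_genes,
                "triples": truth.triples,
                "enriched_set": truth.enriched_set,
                "survival_genes": truth.survival_genes,
            },
            fh,
            indent=2,
        )
    return truth
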