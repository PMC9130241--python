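"""Differential-expression machinery: aggregation, TMM, dispersion, exact test, BH."""

import subprocess
import shutil

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import binom

from cernet import (
    CountsMatrix,
    aggregate_by_gene,
    bh_adjust,
    call_degs,
    estimate_common_dispersion,
    exact_test,
    normalized_log_transform,
    tmm_norm_factors,
)
from cernet.diffexpr import _exact_test_pvalue, heatmap_matrix, volcano_coordinates

from conftest import make_counts


# ---------------------------------------------------------------- aggregation

class TestAggregateByGene:
    def test_sums_member_transcripts(self):
        cm = make_counts([[3, 1], [4, 2], [5, 0]], genes=["t1", "t2", "t3"],
                         conditions={"s0": "tumour", "s1": "normal"})
        out = aggregate_by_gene(cm, {"t1": "G", "t2": "G", "t3": "H"})
        assert out.counts.loc["G"].tolist() == [7, 3]
        assert out.counts.loc["H"].tolist() == [5, 0]

    def test_identity_mapping_renames_rows(self):
        cm = make_counts([[3, 1], [4, 2]], genes=["t1", "t2"],
                         conditions={"s0": "tumour", "s1": "normal"})
        out = aggregate_by_gene(cm, {"t1": "A", "t2": "B"})
        assert np.array_equal(np.sort(out.counts.to_numpy(), axis=0),
                              np.sort(cm.counts.to_numpy(), axis=0))

    def test_conserves_mapped_totals(self, rng):
        # conservation oracle: column totals preserved minus unmapped rows
        arr = rng.integers(0, 100, size=(50, 4))
        genes = [f"tx{i}" for i in range(50)]
        cm = make_counts(arr, genes=genes)
        mapping = {g: f"gene{i % 7}" for i, g in enumerate(genes[:40])}
        out = aggregate_by_gene(cm, mapping)
        expected = arr[:40].sum(axis=0)
        assert np.array_equal(out.counts.sum(axis=0).to_numpy(), expected)

    def test_empty_mapping_rejected(self):
        cm = make_counts([[1, 1]], genes=["t1"], conditions={"s0": "tumour", "s1": "normal"})
        with pytest.raises(ValueError, match="empty"):
            aggregate_by_gene(cm, {})

    def test_conflicting_mapping_rejected(self):
        cm = make_counts([[1, 1]], genes=["t1"], conditions={"s0": "tumour", "s1": "normal"})
        with pytest.raises(ValueError, match="multiple genes"):
            aggregate_by_gene(cm, [("t1", "A"), ("t1", "B")])


# ------------------------------------------------------------------------ TMM

class TestTMM:
    def test_scalar_multiple_libraries_get_unit_factors(self, rng):
        base = rng.integers(10, 1000, size=200)
        cm = make_counts(np.column_stack([base, base * 10]),
                         conditions={"s0": "tumour", "s1": "normal"})
        f = tmm_norm_factors(cm)
        assert np.allclose(f.factors.to_numpy(), 1.0)

    def test_single_shared_gene_uses_its_m_value(self):
        # one gene expressed in both libraries: the factor ratio is 2^M
        arr = np.array([[100, 300], [50, 0], [0, 80]])
        cm = make_counts(arr, conditions={"s0": "tumour", "s1": "normal"})
        f = tmm_norm_factors(cm, ref_sample="s0").factors
        n0, n1 = arr[:, 0].sum(), arr[:, 1].sum()
        m = np.log2((300 / n1) / (100 / n0))
        assert f["s1"] / f["s0"] == pytest.approx(2.0**m, rel=1e-12)

    def test_geometric_mean_is_one(self, small_counts):
        cm, _ = small_counts
        f = tmm_norm_factors(cm).factors.to_numpy()
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_sample_rejected(self):
        cm = make_counts([[5, 0], [3, 0]], conditions={"s0": "tumour", "s1": "normal"})
        with pytest.raises(ValueError, match="all-zero"):
            tmm_norm_factors(cm)

    def test_matches_straight_line_recipe(self, rng):
        """Independent step-by-step re-implementation of trim-then-weighted-mean."""
        arr = rng.negative_binomial(10, 10 / (10 + rng.uniform(5, 500, 500)),
                                    size=(2, 500)).T
        arr[:25, 0] *= 8  # 5% contaminant subset in sample 0
        cm = make_counts(arr, conditions={"s0": "tumour", "s1": "normal"})
        f = tmm_norm_factors(cm, ref_sample="s1").factors

        # oracle: literal recipe
        n0, n1 = arr[:, 0].sum(), arr[:, 1].sum()
        keep = (arr[:, 0] > 0) & (arr[:, 1] > 0)
        o, r = arr[keep, 0] / n0, arr[keep, 1] / n1
        m, a = np.log2(o / r), 0.5 * np.log2(o * r)
        n = m.size
        import math
        from scipy.stats import rankdata
        lo_m, lo_a = math.floor(n * 0.3) + 1, math.floor(n * 0.05) + 1
        sel = ((rankdata(m) >= lo_m) & (rankdata(m) <= n + 1 - lo_m)
               & (rankdata(a) >= lo_a) & (rankdata(a) <= n + 1 - lo_a))
        w = 1.0 / ((n0 - arr[keep, 0]) / (n0 * arr[keep, 0])
                   + (n1 - arr[keep, 1]) / (n1 * arr[keep, 1]))
        raw = 2.0 ** (np.sum(w[sel] * m[sel]) / np.sum(w[sel]))
        expected = np.array([raw, 1.0])
        expected /= np.exp(np.mean(np.log(expected)))
        assert np.allclose(f.to_numpy(), expected, rtol=1e-10)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_tmm_matches_edger(tmp_path, rng):
    """Cross-check against the Bioconductor reference implementation."""
    b = 10.0 ** rng.uniform(-3, 0, 400)
    cols = {}
    for i, lib in enumerate([1e5, 2e5, 1.5e5, 0.9e5]):
        mean = lib * b / b.sum()
        if i == 0:
            mean[:20] *= 8
        cols[f"s{i}"] = rng.negative_binomial(10, 10 / (10 + mean))
    df = pd.DataFrame(cols, index=[f"g{j}" for j in range(400)])
    fixture = tmp_path / "counts.tsv"
    df.to_csv(fixture, sep="\t")
    script = tmp_path / "tmm.R"
    script.write_text(
        "suppressMessages(library(edgeR))\n"
        f"x <- read.delim('{fixture}', row.names=1)\n"
        "cat(sprintf('%.12f\\n', calcNormFactors(as.matrix(x), method='TMM')))\n"
    )
    out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    ref = np.array([float(x) for x in out.stdout.split()])
    cm = make_counts(df.to_numpy(), conditions={f"s{i}": ("tumour" if i < 2 else "normal") for i in range(4)},
                     genes=list(df.index), samples=list(df.columns))
    ours = tmm_norm_factors(cm).factors.to_numpy()
    assert np.allclose(ours, ref, atol=1e-9)


# ----------------------------------------------------------------- dispersion

class TestDispersion:
    def test_identical_counts_hit_lower_bound(self):
        arr = np.tile(np.array([[10], [50], [200]]), (1, 4))
        cm = make_counts(arr)
        f = tmm_norm_factors(cm)
        assert estimate_common_dispersion(cm, f) == pytest.approx(1e-6)

    def test_all_zero_matrix_rejected(self):
        cm = make_counts(np.ones((3, 4), dtype=int))
        f = tmm_norm_factors(cm)
        cm_zero = make_counts(np.zeros((3, 4), dtype=int))
        with pytest.raises(ValueError, match="all-zero"):
            estimate_common_dispersion(cm_zero, f)


# ----------------------------------------------------------------- exact test

class TestExactTest:
    def test_symmetric_split_gives_p_one(self):
        # equal group sums, equal group sizes -> observed split is the mode
        assert _exact_test_pvalue(50, 50, 3, 3, 0.1) == pytest.approx(1.0)

    def test_zero_total_contract(self):
        arr = np.array([[0, 0, 0, 0], [5, 6, 7, 8]])
        cm = make_counts(arr)
        res = exact_test(cm, tmm_norm_factors(cm), phi=0.1)
        assert res.loc[0, "pvalue"] == 1.0
        assert res.loc[0, "log2fc"] == 0.0

    @pytest.mark.parametrize("sum_a,sum_b,n_a,n_b", [(3, 17, 2, 2), (40, 60, 3, 3), (0, 9, 1, 3)])
    def test_poisson_limit_matches_binomial_enumeration(self, sum_a, sum_b, n_a, n_b):
        """phi=0 reduces to a binomial split of the total (enumeration oracle)."""
        z = sum_a + sum_b
        pmf = binom.pmf(np.arange(z + 1), z, n_a / (n_a + n_b))
        expected = pmf[pmf <= pmf[sum_a] * (1 + 1e-12)].sum()
        assert _exact_test_pvalue(sum_a, sum_b, n_a, n_b, 0.0) == pytest.approx(expected, rel=1e-10)

    def test_label_swap_invariance(self, small_counts):
        cm, _ = small_counts
        f = tmm_norm_factors(cm)
        res = exact_test(cm, f, phi=0.1)
        flipped = {s: ("normal" if c == "tumour" else "tumour") for s, c in cm.condition.items()}
        cm2 = CountsMatrix(cm.counts, flipped)
        res2 = exact_test(cm2, tmm_norm_factors(cm2), phi=0.1)
        assert np.allclose(res["pvalue"], res2["pvalue"], rtol=1e-9)
        assert np.allclose(res["log2fc"], -res2["log2fc"], atol=1e-9)


# ------------------------------------------------------------------------- BH

def bh_oracle(p):
    """Brute-force step-up definition: fdr_i = min_{j: p_j >= p_i-rank} m p_(j)/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    out = np.empty(m)
    for pos, i in enumerate(order):
        rank = pos + 1
        candidates = [m * p[order[j]] / (j + 1) for j in range(pos, m)]
        out[i] = min(1.0, min(candidates))
    return out


class TestBH:
    def test_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_brute_force_definition(self, p):
        assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30), st.randoms())
    def test_permutation_invariance(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        direct = bh_adjust(p)
        permuted = bh_adjust([p[i] for i in perm])
        assert np.allclose([direct[i] for i in perm], permuted, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_in_p_rank(self, p):
        adj = bh_adjust(p)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-12)


# ------------------------------------------------------------------ DEG calls

class TestCallDegs:
    @pytest.mark.parametrize(
        "log2fc,fdr,expected",
        [
            (1.3, 0.01, "up"),       # fold change 2.46, significant
            (1.0, 0.001, "ns"),      # fold change exactly 2: strict inequality
            (-2.0, 0.2, "ns"),       # fails FDR
            (-1.7, 0.049, "down"),
        ],
    )
    def test_thresholds(self, log2fc, fdr, expected):
        df = pd.DataFrame({"gene": ["g"], "log2fc": [log2fc], "pvalue": [fdr], "fdr": [fdr]})
        assert call_degs(df)["direction"].iloc[0] == expected


def test_normalized_log_transform_closed_forms():
    assert normalized_log_transform(0.0) == pytest.approx(-3.0)
    assert normalized_log_transform(0.999) == pytest.approx(0.0)
    assert normalized_log_transform(99.999) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        normalized_log_transform(-0.1)


def test_export_coordinate_tables(small_counts):
    cm, _ = small_counts
    from cernet import de_analysis
    res = de_analysis(cm, phi=0.1)
    vol = volcano_coordinates(res)
    assert np.allclose(vol["neg_log10_fdr"], -np.log10(res["fdr"]))
    hm = heatmap_matrix(cm, tmm_norm_factors(cm))
    assert hm.shape == cm.counts.shape
    assert (hm.to_numpy() >= -3 - 1e-9).all()
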