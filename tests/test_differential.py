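"""DE tables, pair concordance, degradation classes, PSM filtering, ranked KS."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paraflux import differential as de
from paraflux.io import ComplexCatalog, ExpressionDataset, GenePair, ValidationError
from paraflux.simulate import simulate_psm_table


def _two_condition_dataset(a, b, genes=None):
    """a, b: gene x replicate arrays for the two conditions (log2)."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    genes = genes or [f"g{i}" for i in range(a.shape[0])]
    samples = [f"a{i}" for i in range(a.shape[1])] + [
        f"b{i}" for i in range(b.shape[1])
    ]
    values = pd.DataFrame(np.hstack([a, b]), index=genes, columns=samples)
    meta = pd.DataFrame(
        {"condition": ["condA"] * a.shape[1] + ["condB"] * b.shape[1],
         "replicate": [str(i) for i in range(a.shape[1])]
         + [str(i) for i in range(b.shape[1])],
         "layer": "protein", "species": "toy"},
        index=samples,
    )
    return ExpressionDataset(values, meta, "log2")


def _hand_welch(x, y):
    nx, ny = len(x), len(y)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    t = (np.mean(y) - np.mean(x)) / math.sqrt(vx / nx + vy / ny)
    df = (vx / nx + vy / ny) ** 2 / (
        (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
    )
    return t, df


class TestDeTable:
    def test_identical_means_not_significant(self):
        ds = _two_condition_dataset([[1.0, 1.1, 0.9]], [[1.1, 0.9, 1.0]])
        out = de.de_table(ds, "condA", "condB")
        assert out.loc[0, "log2_fc"] == pytest.approx(0.0)
        assert not out.loc[0, "significant"]

    def test_fc_boundary_strictly_excluded(self):
        # |log2 FC| exactly at the threshold does not pass the strict rule
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.001, (1, 4))
        b = a + 0.58
        out = de.de_table(_two_condition_dataset(a, b), "condA", "condB")
        assert out.loc[0, "log2_fc"] == pytest.approx(0.58, abs=1e-9)
        assert out.loc[0, "adj_p"] < 0.05
        assert not out.loc[0, "significant"]
        out2 = de.de_table(
            _two_condition_dataset(a, a + 0.6), "condA", "condB"
        )
        assert out2.loc[0, "significant"]

    def test_matches_hand_welch(self):
        a = np.array([[1.0, 1.4, 0.8]])
        b = np.array([[2.0, 2.5, 2.2]])
        out = de.de_table(_two_condition_dataset(a, b), "condA", "condB")
        t, df = _hand_welch(a[0], b[0])
        p = 2 * stats.t.sf(abs(t), df)
        assert out.loc[0, "log2_fc"] == pytest.approx(b.mean() - a.mean())
        assert out.loc[0, "p"] == pytest.approx(p, abs=1e-12)

    def test_antisymmetric_under_condition_swap(self):
        rng = np.random.default_rng(1)
        ds = _two_condition_dataset(rng.normal(0, 1, (5, 3)), rng.normal(1, 1, (5, 3)))
        fwd = de.de_table(ds, "condA", "condB")
        rev = de.de_table(ds, "condB", "condA")
        np.testing.assert_allclose(fwd["log2_fc"], -rev["log2_fc"])
        np.testing.assert_allclose(fwd["p"], rev["p"])

    def test_unknown_condition_rejected(self):
        ds = _two_condition_dataset([[1.0, 1.0]], [[1.0, 1.0]])
        with pytest.raises(ValidationError):
            de.de_table(ds, "condA", "nope")


class TestPairConcordance:
    def _de(self, rows):
        return pd.DataFrame(
            [(g, "x", fc, 0.001, 0.001, sig) for g, fc, sig in rows],
            columns=["gene", "comparison", "log2_fc", "p", "adj_p", "significant"],
        )

    def test_same_sign_concordant(self):
        out = de.pair_concordance(
            self._de([("A", 1.2, True), ("B", 0.7, True)]), [GenePair("A", "B")]
        )
        assert out.loc[0, "concordance"] == "concordant"

    def test_opposite_sign(self):
        out = de.pair_concordance(
            self._de([("A", 1.2, True), ("B", -0.7, True)]), [GenePair("A", "B")]
        )
        assert out.loc[0, "concordance"] == "opposite"

    def test_requires_both_significant(self):
        out = de.pair_concordance(
            self._de([("A", 1.2, True), ("B", 0.7, False)]), [GenePair("A", "B")]
        )
        assert out.empty

    def test_zero_fc_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            out = de.pair_concordance(
                self._de([("A", 0.0, True), ("B", 0.7, True)]), [GenePair("A", "B")]
            )
        assert out.empty

    def test_planted_opposite_fraction_recovered(self):
        # 20% of DE pairs regulated in opposite directions
        rng = np.random.default_rng(2)
        rows, pairs = [], []
        for i in range(500):
            opposite = i < 100
            fa = rng.uniform(0.6, 2.0)
            fb = rng.uniform(0.6, 2.0) * (-1 if opposite else 1)
            rows += [(f"a{i}", fa, True), (f"b{i}", fb, True)]
            pairs.append(GenePair(f"a{i}", f"b{i}"))
        out = de.pair_concordance(self._de(rows), pairs)
        frac = (out["concordance"] == "opposite").mean()
        assert frac == pytest.approx(0.2, abs=0.03)
        assert len(out) == 500  # concordant + opposite = all DE pairs


class TestDegradationClassAnalysis:
    def test_fisher_matches_hypergeometric_oracle(self):
        classes = {f"n{i}": "NED" for i in range(10)}
        classes.update({f"e{i}": "ED" for i in range(10)})
        membership = {f"n{i}": True for i in range(10)}
        membership.update({f"e{i}": False for i in range(10)})
        res = de.degradation_class_analysis(pd.DataFrame(), classes, membership)
        # table (10,0 / 0,10): two-sided Fisher p by exhaustive enumeration
        def hyper_pmf(k, N, K, n):
            return (math.comb(K, k) * math.comb(N - K, n - k)) / math.comb(N, n)

        probs = [hyper_pmf(k, 20, 10, 10) for k in range(0, 11)]
        p_obs = probs[10]
        expected = sum(p for p in probs if p <= p_obs + 1e-12)
        assert res["fisher_p"] == pytest.approx(expected, rel=1e-9)

    def test_identical_delta_distributions(self):
        delta = pd.DataFrame(
            {"gene_a": [f"a{i}" for i in range(20)],
             "gene_b": [f"b{i}" for i in range(20)],
             "delta": list(np.linspace(-1, 1, 20))}
        )
        classes = {}
        for i in range(20):
            classes[f"a{i}"] = "NED" if i % 2 else "ED"
            classes[f"b{i}"] = "ED"
        res = de.degradation_class_analysis(delta, classes, {})
        assert res["ranksum_p"] > 0.3

    def test_planted_delta_shift_detected(self):
        rng = np.random.default_rng(3)
        rows, classes = [], {}
        for i in range(400):
            ned = i < 200
            d = rng.normal(-0.3 if ned else 0.0, 0.3)
            rows.append((f"a{i}", f"b{i}", d))
            classes[f"a{i}"] = "NED" if ned else "ED"
            classes[f"b{i}"] = "ED"
        delta = pd.DataFrame(rows, columns=["gene_a", "gene_b", "delta"])
        res = de.degradation_class_analysis(delta, classes, {})
        assert res["ranksum_p"] < 0.01
        assert np.median(res["delta_ned"]) < np.median(res["delta_ed"])


class TestPsmSummarize:
    def test_fixture_hand_count(self):
        psms, _ = simulate_psm_table(
            20, {"reverse": 0.1, "low_score": 0.15, "low_intensity": 0.05}, seed=5
        )
        matrix, retained = de.psm_summarize(psms)
        assert len(retained) == 14

    def test_single_peptide_protein_dropped(self):
        psms, _ = simulate_psm_table(
            12, {}, seed=6, peptides_per_protein=3, n_single_peptide_proteins=2
        )
        matrix, _ = de.psm_summarize(psms)
        assert not any(p.startswith("SINGLE") for p in matrix.index)
        assert len(matrix) > 0

    def test_row_order_invariant(self):
        psms, _ = simulate_psm_table(
            30, {"reverse": 0.1, "low_score": 0.1}, seed=7
        )
        m1, _ = de.psm_summarize(psms)
        m2, _ = de.psm_summarize(psms.sample(frac=1.0, random_state=1))
        pd.testing.assert_frame_equal(m1, m2)

    def test_all_equal_intensities_flat_after_normalization(self):
        psms, _ = simulate_psm_table(12, {}, seed=8)
        for ch in de.TMT_CHANNELS:
            psms[ch] = 5e4
        matrix, _ = de.psm_summarize(psms)
        np.testing.assert_allclose(matrix.to_numpy(), 0.0, atol=1e-12)

    def test_missing_channel_column_rejected(self):
        psms, _ = simulate_psm_table(5, {}, seed=9)
        with pytest.raises(ValidationError):
            de.psm_summarize(psms.drop(columns=["tmt4"]))


class TestRankedFcKs:
    def test_interleaved_set_small_d(self):
        fc = pd.Series(np.arange(20, dtype=float), index=[f"g{i}" for i in range(20)])
        in_set = [f"g{i}" for i in range(0, 20, 2)]
        d, p = de.ranked_fc_ks(fc, in_set)
        assert d <= 0.2 and p > 0.5

    def test_complete_separation_d_one(self):
        fc = pd.Series(np.arange(10, dtype=float), index=[f"g{i}" for i in range(10)])
        d, _ = de.ranked_fc_ks(fc, [f"g{i}" for i in range(5, 10)])
        assert d == 1.0

    def test_matches_brute_force_ecdf(self):
        vals = [0.1, 0.5, 0.7, 1.1, 1.3, 2.0, -0.4, -0.2, 0.9, 1.7]
        fc = pd.Series(vals, index=[f"g{i}" for i in range(10)])
        in_set = [f"g{i}" for i in range(6)]
        d, p = de.ranked_fc_ks(fc, in_set)
        a = np.sort(fc[in_set].to_numpy())
        b = np.sort(fc.drop(index=in_set).to_numpy())
        grid = np.concatenate([a, b])
        ecdf_a = np.searchsorted(a, grid, side="right") / len(a)
        ecdf_b = np.searchsorted(b, grid, side="right") / len(b)
        assert d == pytest.approx(np.max(np.abs(ecdf_a - ecdf_b)), abs=1e-12)
        # exact p by enumerating all assignments of the 10 values into 6 vs 4
        count = 0
        total = 0
        for comb in itertools.combinations(range(10), 6):
            xa = np.sort(np.asarray(vals)[list(comb)])
            xb = np.sort(np.delete(np.asarray(vals), list(comb)))
            ga = np.searchsorted(xa, grid, side="right") / 6
            gb = np.searchsorted(xb, grid, side="right") / 4
            dd = np.max(np.abs(ga - gb))
            total += 1
            if dd >= d - 1e-12:
                count += 1
        assert p == pytest.approx(count / total, abs=1e-9)

    def test_empty_set_rejected(self):
        fc = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValidationError):
            de.ranked_fc_ks(fc, [])
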