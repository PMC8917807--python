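"""Ratio profiles, moderated t, orthogroup aggregation, Fisher combine,
conserved-signature calling and ratio PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import integrate, stats

from paraflux import conservation as cv
from paraflux.io import ExpressionDataset, GenePair, OrthogroupMap, ValidationError
from paraflux.simulate import (
    SimulationConfig,
    multispecies_gene_pairs,
    simulate_multispecies_proteomes,
)


def _ratio_dataset(ratios_by_condition, gene_pair=("gA", "gB")):
    """Build a 2-gene dataset whose log2 ratio per sample is as given."""
    cols, conds, rows_a, rows_b = [], [], [], []
    for cond, ratios in ratios_by_condition.items():
        for r, val in enumerate(ratios):
            cols.append(f"{cond}_r{r}")
            conds.append(cond)
            rows_a.append(10.0 + val)
            rows_b.append(10.0)
    values = pd.DataFrame(
        [rows_a, rows_b], index=list(gene_pair), columns=cols
    )
    meta = pd.DataFrame(
        {"condition": conds, "replicate": [c.split("_r")[1] for c in cols],
         "layer": "protein", "species": "toy"},
        index=cols,
    )
    return ExpressionDataset(values, meta, "log2")


class TestRatioProfiles:
    def test_log2_subtraction(self):
        ds = _ratio_dataset({"t0": [3.0]})
        prof = cv.ratio_profiles(ds, [GenePair("gA", "gB")])
        assert prof.iloc[0, 0] == pytest.approx(3.0)

    def test_missing_gene_gives_missing_ratio(self):
        ds = _ratio_dataset({"t0": [1.0, 2.0]})
        ds.values.loc["gB", ds.values.columns[1]] = np.nan
        prof = cv.ratio_profiles(ds, [GenePair("gA", "gB")])
        assert not np.isnan(prof.iloc[0, 0])
        assert np.isnan(prof.iloc[0, 1])

    def test_toy_six_ratios_hand_subtraction(self):
        ds = _ratio_dataset({"t0": [0.5, 0.6, 0.7], "t1": [1.5, 1.6, 1.7]})
        prof = cv.ratio_profiles(ds, [GenePair("gA", "gB")])
        np.testing.assert_allclose(
            prof.to_numpy()[0], [0.5, 0.6, 0.7, 1.5, 1.6, 1.7]
        )


class TestModeratedT:
    def test_identical_means_t_zero_p_one(self):
        ds = _ratio_dataset({"t0": [1.0, 2.0, 3.0], "t1": [3.0, 1.0, 2.0]})
        prof = cv.ratio_profiles(ds, [GenePair("gA", "gB")])
        out = cv.ratio_change_test(prof, ds.meta, species="toy")
        assert out.loc[0, "delta"] == pytest.approx(0.0)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_d0_zero_recovers_ordinary_t(self):
        rng = np.random.default_rng(1)
        conds = {"t0": list(rng.normal(0, 1, 4)), "t1": list(rng.normal(1, 1, 4))}
        ds = _ratio_dataset(conds)
        prof = cv.ratio_profiles(ds, [GenePair("gA", "gB")])
        out = cv.ratio_change_test(prof, ds.meta, species="toy", d0=0)
        t_ref, p_ref = stats.ttest_ind(conds["t1"], conds["t0"], equal_var=True)
        assert out.loc[0, "t"] == pytest.approx(t_ref, abs=1e-10)
        assert out.loc[0, "p"] == pytest.approx(p_ref, abs=1e-10)

    def test_fixed_d0_matches_closed_formula(self):
        x0 = [0.0, 0.2, 0.4]
        x1 = [1.0, 1.3, 1.6]
        ds = _ratio_dataset({"t0": x0, "t1": x1})
        prof = cv.ratio_profiles(ds, [GenePair("gA", "gB")])
        d0 = 3.0
        out = cv.ratio_change_test(prof, ds.meta, species="toy", d0=d0)
        d = 4.0
        s2 = (np.var(x0, ddof=1) * 2 + np.var(x1, ddof=1) * 2) / d
        s0_sq = s2  # single pair: ensemble mean variance equals s2
        s_post = np.sqrt((d0 * s0_sq + d * s2) / (d0 + d))
        t = (np.mean(x1) - np.mean(x0)) / (s_post * np.sqrt(1 / 3 + 1 / 3))
        p = 2 * stats.t.sf(abs(t), d0 + d)
        assert out.loc[0, "t"] == pytest.approx(t, abs=1e-10)
        assert out.loc[0, "p"] == pytest.approx(p, abs=1e-10)

    def test_single_replicate_condition_untestable(self):
        ds = _ratio_dataset({"t0": [1.0, 1.1], "t1": [2.0]})
        prof = cv.ratio_profiles(ds, [GenePair("gA", "gB")])
        out = cv.ratio_change_test(prof, ds.meta, species="toy")
        assert np.isnan(out.loc[0, "p"])
        assert out.loc[0, "delta"] == pytest.approx(2.0 - 1.05)

    def test_variance_prior_moment_recovery(self):
        # variances drawn from the scaled-F marginal: MoM should land near truth
        rng = np.random.default_rng(2)
        d, d0, s0_sq = 4.0, 10.0, 0.5
        s2 = s0_sq * stats.f.rvs(d, d0, size=20000, random_state=rng)
        prior = cv.estimate_variance_prior(s2, d)
        assert prior.d0 == pytest.approx(d0, rel=0.2)
        assert prior.s0_sq == pytest.approx(s0_sq, rel=0.1)


class TestAggregateToOrthogroups:
    def _ogmap(self):
        return OrthogroupMap(pd.DataFrame(
            {"gene": ["a1", "a2", "b1", "c1"], "species": "sp1",
             "orthogroup": ["OGA", "OGA", "OGB", "OGC"]}
        ))

    def _changes(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_a", "gene_b", "species", "comparison", "delta", "p"]
        )

    def test_multiple_gene_pairs_averaged(self):
        changes = self._changes([
            ("a1", "b1", "sp1", "c1", 1.0, 0.02),
            ("a2", "b1", "sp1", "c1", 0.5, 0.04),
        ])
        out = cv.aggregate_to_orthogroups(changes, self._ogmap())
        assert len(out) == 1
        assert out.loc[0, "delta"] == pytest.approx(0.75)
        assert out.loc[0, "p"] == pytest.approx(0.03)

    def test_unmapped_gene_dropped(self):
        changes = self._changes([("a1", "zz", "sp1", "c1", 1.0, 0.02)])
        assert cv.aggregate_to_orthogroups(changes, self._ogmap()).empty

    def test_orientation_flip_negates_delta(self):
        # gene pair orientation b1 < c1 maps to orthogroups OGB < OGC: kept;
        # reversing the gene roles flips the orthogroup order and the sign
        fwd = self._changes([("b1", "c1", "sp1", "c1", 1.0, 0.02)])
        rev = self._changes([("c1", "b1", "sp1", "c1", -1.0, 0.02)])
        out_f = cv.aggregate_to_orthogroups(fwd, self._ogmap())
        out_r = cv.aggregate_to_orthogroups(rev, self._ogmap())
        assert out_f.loc[0, "delta"] == pytest.approx(out_r.loc[0, "delta"])

    def test_same_orthogroup_pair_dropped(self):
        changes = self._changes([("a1", "a2", "sp1", "c1", 1.0, 0.02)])
        assert cv.aggregate_to_orthogroups(changes, self._ogmap()).empty


class TestFisherCombine:
    def test_single_p_identity(self):
        for p in (0.01, 0.3, 0.9):
            assert cv.fisher_combine([p]) == pytest.approx(p, abs=1e-12)

    def test_p_one_contributes_nothing(self):
        assert cv.fisher_combine([0.2, 1.0]) == pytest.approx(
            stats.chi2.sf(-2 * np.log(0.2), 4), abs=1e-15
        )

    def test_matches_quadrature_oracle(self):
        p = [0.05, 0.05]
        x2 = -2 * np.sum(np.log(p))
        oracle, err = integrate.quad(
            lambda x: stats.chi2.pdf(x, 4), x2, np.inf
        )
        assert cv.fisher_combine(p) == pytest.approx(oracle, abs=1e-12)

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ps = rng.uniform(0.001, 1.0, rng.integers(1, 8))
            ref = stats.combine_pvalues(ps, method="fisher").pvalue
            assert cv.fisher_combine(ps) == pytest.approx(ref, abs=1e-12)

    @given(hst.lists(hst.floats(1e-6, 1.0), min_size=1, max_size=6),
           hst.integers(0, 5))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_each_p(self, ps, idx):
        idx = idx % len(ps)
        smaller = list(ps)
        smaller[idx] = smaller[idx] / 2
        assert cv.fisher_combine(smaller) <= cv.fisher_combine(ps) + 1e-12

    def test_zero_p_rejected(self):
        with pytest.raises(ValidationError):
            cv.fisher_combine([0.0, 0.5])


class TestConservedSignature:
    def _og_changes(self, signs, p=1e-4, n_species=4):
        """One orthogroup pair observed with given per-comparison delta signs."""
        comparisons = [f"c{j}" for j in range(len(signs))]
        species = [f"sp{j % n_species}" for j in range(len(signs))]
        rows = [
            ("OGA", "OGB", species[j], comparisons[j], float(s), p)
            for j, s in enumerate(signs)
        ]
        return pd.DataFrame(
            rows, columns=["og_a", "og_b", "species", "comparison", "delta", "p"]
        )

    def test_five_of_seven_passes_sign_rule(self):
        out = cv.conserved_signature(
            self._og_changes([1, 1, 1, 1, 1, -1, -1]), n_species=4
        )
        assert out.loc[0, "n_sign_consistent"] == 5
        assert bool(out.loc[0, "conserved"])

    def test_four_of_seven_fails(self):
        out = cv.conserved_signature(
            self._og_changes([1, 1, 1, 1, -1, -1, -1]), n_species=4
        )
        assert out.loc[0, "n_sign_consistent"] == 4
        assert not bool(out.loc[0, "conserved"])

    def test_missing_species_not_conserved(self):
        df = self._og_changes([1, 1, 1, 1, 1, 1, 1])
        df = df[df["species"] != "sp3"]
        out = cv.conserved_signature(df, n_species=4)
        assert not bool(out.loc[0, "conserved"])

    def test_orientation_invariant_sign_count(self):
        up = cv.conserved_signature(self._og_changes([1] * 7), n_species=4)
        down = cv.conserved_signature(self._og_changes([-1] * 7), n_species=4)
        assert up.loc[0, "n_sign_consistent"] == down.loc[0, "n_sign_consistent"] == 7
        # majority orientation is reported as positive either way
        delta_cols = [c for c in up.columns if c.startswith("delta:")]
        assert (down[delta_cols].to_numpy() > 0).all()

    def test_exact_zero_counts_inconsistent(self):
        out = cv.conserved_signature(
            self._og_changes([1, 1, 1, 1, 0, 1, -1]), n_species=4
        )
        assert out.loc[0, "n_sign_consistent"] == 5

    def test_recovery_on_synthetic_multispecies(self):
        cfg = SimulationConfig(
            n_species=4, n_comparisons=7, n_replicates=3,
            n_orthogroup_pairs=300, n_conserved=20,
            effect_size=1.0, noise_sd=0.25, seed=4,
        )
        datasets, ogmap, truth = simulate_multispecies_proteomes(cfg)
        frames = []
        for sp, ds in datasets.items():
            pairs = multispecies_gene_pairs(ogmap, sorted(truth.conserved), sp)
            prof = cv.ratio_profiles(ds, pairs)
            frames.append(cv.ratio_change_test(prof, ds.meta, species=sp))
        og = cv.aggregate_to_orthogroups(pd.concat(frames), ogmap)
        sig = cv.conserved_signature(og, n_species=4)
        called = set(
            map(tuple, sig.loc[sig["conserved"], ["og_a", "og_b"]].to_numpy())
        )
        planted = {k for k, v in truth.conserved.items() if v}
        tp = len(called & planted)
        assert tp / len(planted) >= 0.9
        assert (len(called) - tp) / max(len(called), 1) <= 0.1

    def test_gene_relabeling_invariance(self):
        # renaming every gene id (keeping the orthogroup map in sync) must not
        # change which orthogroup pairs are called conserved
        cfg = SimulationConfig(
            n_species=3, n_comparisons=6, n_replicates=3,
            n_orthogroup_pairs=60, n_conserved=8, effect_size=1.0,
            noise_sd=0.25, seed=5,
        )
        datasets, ogmap, truth = simulate_multispecies_proteomes(cfg)

        def _run(datasets, ogmap):
            frames = []
            for sp, ds in datasets.items():
                pairs = multispecies_gene_pairs(ogmap, sorted(truth.conserved), sp)
                prof = cv.ratio_profiles(ds, pairs)
                frames.append(cv.ratio_change_test(prof, ds.meta, species=sp))
            og = cv.aggregate_to_orthogroups(pd.concat(frames), ogmap)
            sig = cv.conserved_signature(og, n_species=3, n_comparisons=6,
                                         min_consistent=5)
            return set(map(tuple, sig.loc[sig["conserved"],
                                          ["og_a", "og_b"]].to_numpy()))

        called = _run(datasets, ogmap)
        renamed = {
            sp: ExpressionDataset(
                ds.values.rename(index=lambda g: f"zz_{g}"), ds.meta, ds.scale
            )
            for sp, ds in datasets.items()
        }
        og2 = OrthogroupMap(
            ogmap.records.assign(gene=lambda d: "zz_" + d["gene"])
        )
        assert _run(renamed, og2) == called and called


class TestRatioPca:
    def test_rank_one_input_single_component(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        wide = pd.DataFrame(
            np.outer([1.0, 0.5, 2.0], base),
            index=["p1", "p2", "p3"], columns=[f"c{j}" for j in range(4)],
        )
        scores = cv.ratio_pca(wide)
        evr = scores.attrs["explained_variance_ratio"]
        assert evr[0] == pytest.approx(1.0)

    def test_duplicated_comparisons_identical_scores(self):
        rng = np.random.default_rng(6)
        wide = pd.DataFrame(
            rng.normal(0, 1, (10, 3)), columns=["c1", "c2", "c3"]
        )
        wide["c3"] = wide["c1"]
        scores = cv.ratio_pca(wide)
        np.testing.assert_allclose(
            scores.loc["c1"].to_numpy(), scores.loc["c3"].to_numpy(), atol=1e-10
        )

    def test_species_offsets_cluster(self):
        rng = np.random.default_rng(7)
        n_pairs = 60
        offsets = {"sp1": 1.5, "sp2": -1.5}
        cols, data = [], []
        species_dir = {
            sp: rng.normal(0, 1, n_pairs) for sp in offsets
        }
        for sp, off in offsets.items():
            for j in range(3):
                cols.append(f"{sp}_c{j}")
                data.append(off * species_dir[sp] + rng.normal(0, 0.1, n_pairs))
        wide = pd.DataFrame(np.array(data).T, columns=cols)
        scores = cv.ratio_pca(wide)
        pc1 = scores["PC1"]
        sp1 = pc1[[c for c in cols if c.startswith("sp1")]]
        sp2 = pc1[[c for c in cols if c.startswith("sp2")]]
        centroid_sep = abs(sp1.mean() - sp2.mean())
        within = max(sp1.std(), sp2.std())
        assert centroid_sep > within

    def test_too_few_rows_rejected(self):
        wide = pd.DataFrame([[1.0, 2.0]], columns=["c1", "c2"])
        with pytest.raises(ValidationError):
            cv.ratio_pca(wide)


class TestFalsePositiveControl:
    def test_null_effect_fdp_controlled(self):
        # no planted effect: BH on the combined p controls false positives
        n_called = 0
        for seed in range(3):
            cfg = SimulationConfig(
                n_species=3, n_comparisons=6, n_replicates=3,
                n_orthogroup_pairs=200, n_conserved=0, effect_size=0.0,
                noise_sd=0.25, seed=seed,
            )
            datasets, ogmap, truth = simulate_multispecies_proteomes(cfg)
            frames = []
            for sp, ds in datasets.items():
                pairs = multispecies_gene_pairs(ogmap, sorted(truth.conserved), sp)
                prof = cv.ratio_profiles(ds, pairs)
                frames.append(cv.ratio_change_test(prof, ds.meta, species=sp))
            og = cv.aggregate_to_orthogroups(pd.concat(frames), ogmap)
            sig = cv.conserved_signature(og, n_species=3, n_comparisons=6)
            n_called += int(sig["conserved"].sum())
        assert n_called <= 10  # ~alpha-level false calls across 600 null pairs
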