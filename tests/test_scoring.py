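"""Tests for the expression generator, signature scoring and the scan."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from mitosig.scoring import (
    composition_table,
    compare_scores,
    diff_expr_in_universe,
    metabolic_enrichment_scan,
    normalize_expression,
    score_signature,
    wilcoxon_rank_sum,
)
from mitosig.synthetic.expression import (
    ExpressionSimSpec,
    default_pathways,
    synth_expression,
)

KC_STATES = ("basal", "spinous", "granular", "stress")


@pytest.fixture(scope="module")
def sim():
    """Default lesional-coupled simulation, normalised, with masks."""
    adata = synth_expression(ExpressionSimSpec(seed=11))
    X, kept = normalize_expression(adata.X)
    obs = adata.obs.loc[kept]
    kc = obs["cell_state"].isin(KC_STATES).to_numpy()
    stress = (obs["cell_state"] == "stress").to_numpy()
    return {
        "adata": adata,
        "X": X,
        "obs": obs,
        "genes": adata.var_names.tolist(),
        "sets": adata.uns["gene_sets"],
        "kc": kc,
        "stress": stress,
    }


class TestGenerator:
    def test_seed_determinism(self):
        a = synth_expression(ExpressionSimSpec(seed=3, n_genes=600))
        b = synth_expression(ExpressionSimSpec(seed=3, n_genes=600))
        assert np.array_equal(a.X, b.X)

    def test_stress_cells_only_lesional_by_default(self, sim):
        obs = sim["obs"]
        stress_conditions = obs.loc[obs["cell_state"] == "stress", "condition"]
        assert (stress_conditions == "lesional").all()
        assert (obs["cell_state"] == "stress").sum() > 0

    def test_overlapping_sets_rejected_without_flag(self):
        sets = default_pathways(600)
        sets["dup"] = sets["oxphos"][:5]
        with pytest.raises(ValueError, match="appears in both"):
            ExpressionSimSpec(
                n_genes=600, pathway_assignments=sets, seed=0
            ).resolve_sets()

    def test_programmed_shift_visible_in_raw_means(self, sim):
        adata, sets = sim["adata"], sim["sets"]
        counts = np.asarray(adata.X, dtype=float)
        idx = [adata.var_names.get_loc(g) for g in sets["oxphos"]]
        stress = (adata.obs["cell_state"] == "stress").to_numpy()
        ratio = counts[stress][:, idx].mean() / counts[~stress][:, idx].mean()
        assert ratio > 1.5  # programmed 2x up, diluted by library scaling

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="lfc_glycolysis"):
            ExpressionSimSpec(lfc_glycolysis=0.5).validate()


class TestNormalize:
    def test_arithmetic_on_tiny_cell(self):
        X, kept = normalize_expression(np.array([[10, 0]]))
        assert kept.all()
        assert X[0, 0] == pytest.approx(np.log1p(1e4))
        assert X[0, 1] == 0.0

    def test_depth_invariance(self):
        c = np.array([[3, 7, 0, 5]])
        a, _ = normalize_expression(c)
        b, _ = normalize_expression(2 * c)
        assert np.allclose(a, b)

    def test_zero_cell_dropped_with_warning(self):
        counts = np.array([[1, 2], [0, 0]])
        with pytest.warns(UserWarning, match="zero-count"):
            X, kept = normalize_expression(counts)
        assert kept.tolist() == [True, False]
        assert X.shape == (1, 2)


class TestScoreSignature:
    def test_random_sets_center_on_zero_under_null(self):
        """Bin-matched control subtraction centres random-set scores on
        zero; averaged over set draws (single draws carry within-bin
        heterogeneity noise)."""
        adata = synth_expression(
            ExpressionSimSpec(seed=50, lfc_oxphos=0, lfc_glycolysis=0, lfc_stress=0)
        )
        X, _ = normalize_expression(adata.X)
        genes = adata.var_names.tolist()
        rng = np.random.default_rng(1)
        means = [
            score_signature(
                X, genes, list(rng.choice(genes, 50, replace=False)), seed=i
            ).per_cell_score.mean()
            for i in range(8)
        ]
        assert abs(np.mean(means)) < 0.05

    def test_programmed_shift_direction_and_growth(self):
        deltas = []
        for lfc in (0.5, 1.5):
            adata = synth_expression(ExpressionSimSpec(seed=21, lfc_oxphos=lfc))
            X, kept = normalize_expression(adata.X)
            obs = adata.obs.loc[kept]
            stress = (obs["cell_state"] == "stress").to_numpy()
            s = score_signature(
                X, adata.var_names.tolist(), adata.uns["gene_sets"]["oxphos"], seed=2
            ).per_cell_score
            deltas.append(s[stress].mean() - s[~stress].mean())
        assert deltas[0] > 0
        assert deltas[1] > deltas[0]

    def test_controls_disjoint_from_set(self, sim):
        s = score_signature(sim["X"], sim["genes"], sim["sets"]["oxphos"], seed=3)
        assert not set(s.genes_used) & set(s.control_genes_used)

    def test_nctrl_zero_is_plain_mean(self, sim):
        s = score_signature(
            sim["X"], sim["genes"], sim["sets"]["oxphos"], n_ctrl=0
        )
        idx = [sim["genes"].index(g) for g in sim["sets"]["oxphos"]]
        assert np.allclose(s.per_cell_score, sim["X"][:, idx].mean(axis=1))

    def test_absent_set_is_error(self, sim):
        with pytest.raises(ValueError, match="absent"):
            score_signature(sim["X"], sim["genes"], ["NOPE1", "NOPE2"])


class TestWilcoxon:
    def test_complete_separation_three_vs_three(self):
        u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(2 / 20)

    def test_identical_samples_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_exact_branch_matches_enumeration_exhaustively(self):
        """All two-group splits of 8 distinct values, against a brute-force
        permutation oracle over pooled values."""
        vals = [0.3, 1.1, 2.7, 3.1, 4.9, 5.2, 6.8, 7.5]
        for n in (2, 3, 4):
            for combo in itertools.combinations(range(8), n):
                x = [vals[i] for i in combo]
                y = [vals[i] for i in range(8) if i not in combo]
                u_obs, p_obs = wilcoxon_rank_sum(x, y)
                # oracle: enumerate every reassignment of pooled values
                stats = []
                for c in itertools.combinations(range(8), n):
                    xs = [vals[i] for i in c]
                    ys = [vals[i] for i in range(8) if i not in c]
                    stats.append(sum(a > b for a in xs for b in ys))
                stats = np.array(stats)
                mid = n * (8 - n) / 2
                p_oracle = min(
                    1.0,
                    2
                    * min(
                        np.mean(stats >= u_obs), np.mean(stats <= u_obs)
                    ),
                )
                assert p_obs == pytest.approx(p_oracle, abs=1e-12)

    def test_approximation_matches_permutation_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 30)
        y = rng.normal(1, 1, 30)
        _, p = wilcoxon_rank_sum(x, y)
        pooled = np.concatenate([x, y])
        count = 0
        n_perm = 10_000
        u_obs = sum(a > b for a in x for b in y) + 0.5 * sum(
            a == b for a in x for b in y
        )
        dev_obs = abs(u_obs - 450)
        for _ in range(n_perm):
            rng.shuffle(pooled)
            u = sum(a > b for a in pooled[:30] for b in pooled[30:])
            count += abs(u - 450) >= dev_obs
        assert abs(p - count / n_perm) < 2e-2

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=20),
        st.lists(st.floats(-50, 50), min_size=1, max_size=20),
    )
    def test_matches_scipy_mannwhitneyu(self, x, y):
        u, p = wilcoxon_rank_sum(x, y)
        n, m = len(x), len(y)
        if n + m <= 12 and len(set(x + y)) == n + m:
            ref = mannwhitneyu(x, y, method="exact")
        else:
            ref = mannwhitneyu(x, y, method="asymptotic")
        assert u == pytest.approx(float(ref.statistic), abs=1e-9)
        assert p == pytest.approx(float(ref.pvalue), abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestCompareScores:
    def test_programmed_oxphos_shift_significant(self, sim):
        obs = sim["obs"]
        s = score_signature(
            sim["X"], sim["genes"], sim["sets"]["oxphos"], seed=5
        ).per_cell_score
        labels = np.where(
            obs["cell_state"] == "stress",
            "stress",
            obs["condition"].astype(str),
        )
        df = compare_scores(
            s[sim["kc"]],
            labels[sim["kc"]],
            pairs=[("stress", "lesional"), ("stress", "nonlesional")],
        )
        assert (df["delta_mean"] > 0).all()
        assert (df["p_value"] < 1e-10).all()

    def test_one_cell_per_group_exact(self):
        df = compare_scores(np.array([1.0, 2.0]), ["a", "b"])
        assert df.loc[0, "delta_mean"] == -1.0
        assert 0 < df.loc[0, "p_value"] <= 1

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown group"):
            compare_scores(np.arange(4.0), list("aabb"), pairs=[("a", "zz")])


class TestEnrichmentScan:
    def test_coupled_pathways_rank_top2_with_correct_quadrants(self, sim):
        sets = sim["sets"]
        pathway_sets = {k: v for k, v in sets.items() if k != "stress_markers"}
        scan = metabolic_enrichment_scan(
            sim["X"], sim["genes"], pathway_sets, sets["stress_markers"],
            sim["kc"], sim["stress"], seed=7,
        )
        top2 = set(scan["pathway_name"].iloc[:2])
        assert top2 == {"oxphos", "glycolysis"}
        ox = scan.set_index("pathway_name").loc["oxphos"]
        gl = scan.set_index("pathway_name").loc["glycolysis"]
        assert ox["delta_score"] > 0 and ox["stress_corr"] > 0
        assert gl["delta_score"] < 0 and gl["stress_corr"] < 0
        nulls = scan.iloc[2:]
        assert nulls["delta_score"].abs().max() < 0.1

    def test_self_correlation_near_one(self, sim):
        sets = sim["sets"]
        scan = metabolic_enrichment_scan(
            sim["X"], sim["genes"],
            {"stress_again": sets["stress_markers"]},
            sets["stress_markers"], sim["kc"], sim["stress"], seed=8,
        )
        assert scan.loc[0, "stress_corr"] > 0.95

    def test_scan_symmetry_under_lfc_negation(self):
        """Negating the programmed oxphos lfc flips delta and correlation."""
        out = {}
        for sign, lfc_ox, lfc_gl in (("pos", 1.0, -1.0), ("neg", 0.0, 0.0)):
            spec = ExpressionSimSpec(seed=31, lfc_oxphos=lfc_ox, lfc_glycolysis=lfc_gl)
            adata = synth_expression(spec)
            X, kept = normalize_expression(adata.X)
            obs = adata.obs.loc[kept]
            kc = obs["cell_state"].isin(KC_STATES).to_numpy()
            stress = (obs["cell_state"] == "stress").to_numpy()
            sets = adata.uns["gene_sets"]
            scan = metabolic_enrichment_scan(
                X, adata.var_names.tolist(),
                {"oxphos": sets["oxphos"], "glycolysis": sets["glycolysis"]},
                sets["stress_markers"], kc, stress, seed=9,
            ).set_index("pathway_name")
            out[sign] = scan
        # negated-coupling run: roles swap sign relative to the coupled run
        assert out["pos"].loc["oxphos", "delta_score"] > 0.2
        assert out["pos"].loc["glycolysis", "delta_score"] < -0.2
        assert abs(out["neg"].loc["oxphos", "delta_score"]) < 0.1
        assert abs(out["neg"].loc["glycolysis", "delta_score"]) < 0.1

    def test_empty_stress_group_rejected(self, sim):
        with pytest.raises(ValueError, match="stress"):
            metabolic_enrichment_scan(
                sim["X"], sim["genes"],
                {"oxphos": sim["sets"]["oxphos"]},
                sim["sets"]["stress_markers"],
                sim["kc"], np.zeros_like(sim["stress"]),
            )


class TestDiffExpr:
    def test_programmed_genes_called(self, sim):
        sets = sim["sets"]
        universe = sets["oxphos"] + [f"G{i:05d}" for i in range(601, 681)]
        de = diff_expr_in_universe(
            sim["X"][sim["kc"]], sim["genes"], sim["stress"][sim["kc"]], universe
        )
        called = set(de.loc[de["de"], "gene"])
        assert len(called & set(sets["oxphos"])) >= 18
        assert len(called - set(sets["oxphos"])) <= 3

    def test_identical_groups_no_calls(self, sim):
        rng = np.random.default_rng(0)
        fake = rng.permutation(sim["stress"][sim["kc"]])
        # permuting labels breaks the association: null truth
        universe = [f"G{i:05d}" for i in range(601, 701)]
        de = diff_expr_in_universe(
            sim["X"][sim["kc"]], sim["genes"], fake, universe
        )
        assert de["de"].sum() <= 2

    def test_infinite_lfc_threshold_blocks_all(self, sim):
        universe = sim["sets"]["oxphos"]
        de = diff_expr_in_universe(
            sim["X"][sim["kc"]], sim["genes"], sim["stress"][sim["kc"]],
            universe, lfc_min=np.inf,
        )
        assert de["de"].sum() == 0

    def test_bh_controls_false_discovery_on_uniform_p(self):
        """BH at q=0.05 on null data: mean false-discovery proportion stays
        at or below 0.05 over Monte-Carlo replicates."""
        rng = np.random.default_rng(99)
        fdp = []
        from statsmodels.stats.multitest import multipletests

        for _ in range(500):
            p = rng.uniform(size=100)
            rej, *_ = multipletests(p, alpha=0.05, method="fdr_bh")[0:1]
            fdp.append(rej.mean() > 0)
        # P(any rejection) under independence is at most alpha
        assert np.mean(fdp) <= 0.07


class TestComposition:
    def test_fractions_sum_to_one_per_sample(self, sim):
        counts, _ = composition_table(sim["obs"])
        sums = counts.groupby("sample")["fraction"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_stress_fraction_zero_nonlesional_positive_lesional(self, sim):
        counts, delta = composition_table(sim["obs"])
        nl = counts[
            (counts["condition"] == "nonlesional")
            & (counts["cell_state"] == "stress")
        ]
        assert nl["count"].sum() == 0 if len(nl) else True
        d = delta.set_index("cell_state")["delta_fraction"]
        assert d["stress"] > 0

    def test_programmed_proportions_recovered(self):
        cells = {
            ("lesional", "basal"): 1200,
            ("lesional", "spinous"): 400,
            ("lesional", "granular"): 200,
            ("lesional", "stress"): 200,
        }
        adata = synth_expression(
            ExpressionSimSpec(seed=41, n_genes=600, cells=cells)
        )
        counts, _ = composition_table(adata.obs)
        pooled = counts.groupby("cell_state", observed=True)["count"].sum()
        total = pooled.sum()
        for state, n in [("basal", 1200), ("spinous", 400), ("stress", 200)]:
            frac = pooled[state] / total
            expect = n / 2000
            # exact here (deterministic counts); bound kept at multinomial 95%
            se = np.sqrt(expect * (1 - expect) / 2000)
            assert abs(frac - expect) <= 1.96 * se + 1e-12
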