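import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import qpdecon as qd
from qpdecon.signature import (

    _first_local_minimum,
    bh_fdr,
    build_basis,
    candidate_ranking,
    condition_number,
    fit_f_dist,
    filter_expression_range,
    moderated_t,
    select_signature,
    trigamma_inverse,
)

from oracles import bh_step_up, moderated_t_reference


def make_pure(values: dict[str, list[float]], labels: dict[str, str], scale="linear"):
    genes = [f"G{i+1}" for i in range(len(next(iter(values.values()))))]
    expr = qd.ExpressionMatrix(pd.DataFrame(values, index=genes), scale=scale)
    return qd.PureProfileSet(expr, pd.Series(labels))


class TestRangeFilter:
    def test_bounds_apply_to_every_type_mean(self):
        pure = make_pure(
            {
                "a1": [120.0, 9000.0, 0.04, 50.0],
                "a2": [120.0, 3000.0, 0.08, 50.0],
                "b1": [80.0, 100.0, 100.0, 0.05],
                "b2": [80.0, 100.0, 100.0, 0.05],
            },
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        # G2 mean in A = 6000 > hi; G3 mean in A = 0.06 < lo; G4 mean in B < lo
        assert filter_expression_range(pure) == ["G1"]

    def test_empty_result_errors(self):
        pure = make_pure(
            {"a1": [9000.0], "a2": [9000.0], "b1": [8000.0], "b2": [8000.0]},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        with pytest.raises(ValueError, match="widen"):
            filter_expression_range(pure)


class TestModeratedT:
    @staticmethod
    def _two_group_pure(seed=0, n_genes=200, n=3, effects=20, delta=2.0):
        rng = np.random.default_rng(seed)
        log_a = rng.normal(7.0, 1.0, (n_genes, 1)) + rng.normal(0, 0.3, (n_genes, n))
        log_b = log_a[:, :1] + rng.normal(0, 0.3, (n_genes, n))
        log_a = log_a[:, :n] if log_a.shape[1] == n else log_a
        log_b[:effects] += delta
        cols = {f"a{i}": np.exp2(log_a[:, i]) for i in range(n)}
        cols.update({f"b{i}": np.exp2(log_b[:, i]) for i in range(n)})
        labels = {f"a{i}": "A" for i in range(n)} | {f"b{i}": "B" for i in range(n)}
        genes = [f"G{i+1:04d}" for i in range(n_genes)]
        expr = qd.ExpressionMatrix(pd.DataFrame(cols, index=genes))
        return qd.PureProfileSet(expr, pd.Series(labels)), log_a, log_b

    def test_matches_independent_coding_of_closed_forms(self):
        pure, log_a, log_b = self._two_group_pure(seed=3)
        table = moderated_t(pure, "A", "B")
        t_ref, p_ref, d0_ref, s0_ref = moderated_t_reference(log_a, log_b)
        np.testing.assert_allclose(table["t_mod"].to_numpy(), t_ref, atol=1e-10, rtol=1e-10)
        np.testing.assert_allclose(table["p"].to_numpy(), p_ref, atol=1e-10, rtol=1e-8)
        d0, s0 = table.attrs["prior"]
        assert d0 == pytest.approx(d0_ref, rel=1e-9)
        assert s0 == pytest.approx(s0_ref, rel=1e-9)

    def test_matches_limma_ebayes(self, tmp_path):
        """Cross-check against the Bioconductor reference implementation."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the limma cross-check")
        pure, _, _ = self._two_group_pure(seed=4, n_genes=80)
        log2_expr = np.log2(pure.expr.data)
        data_path = tmp_path / "log2.tsv"
        log2_expr.to_csv(data_path, sep="\t")
        script = tmp_path / "limma_check.R"
        script.write_text(
            """
            suppressMessages(library(limma))
            args <- commandArgs(trailingOnly=TRUE)
            x <- as.matrix(read.delim(args[1], row.names=1))
            grp <- factor(c(rep("A",3), rep("B",3)), levels=c("A","B"))
            design <- model.matrix(~0+grp)
            colnames(design) <- levels(grp)
            fit <- lmFit(x, design)
            fit <- contrasts.fit(fit, makeContrasts(A-B, levels=design))
            fit <- eBayes(fit)
            out <- data.frame(gene=rownames(x), t=fit$t[,1], p=fit$p.value[,1])
            write.table(out, args[2], sep="\t", row.names=FALSE, quote=FALSE)
            """
        )
        out_path = tmp_path / "limma_out.tsv"
        subprocess.run(
            ["Rscript", "--vanilla", str(script), str(data_path), str(out_path)],
            check=True,
            capture_output=True,
        )
        ref = pd.read_csv(out_path, sep="\t", index_col=0)
        table = moderated_t(pure, "A", "B")
        np.testing.assert_allclose(
            table["t_mod"].to_numpy(), ref.loc[table.index, "t"].to_numpy(), rtol=1e-6
        )
        np.testing.assert_allclose(
            table["p"].to_numpy(), ref.loc[table.index, "p"].to_numpy(), rtol=1e-5, atol=1e-12
        )

    def test_identical_variances_reduce_to_ordinary_t(self):
        # equal per-gene variances: shrinkage is a no-op, t_mod == pooled t
        base = np.array([1.0, 2.0, 3.0])
        shifts = np.array([0.0, 1.0, 5.0, -2.0])
        cols = {}
        for i in range(3):
            cols[f"a{i}"] = np.exp2(shifts + base[i])
            cols[f"b{i}"] = np.exp2(shifts * 2 + base[i])
        labels = {f"a{i}": "A" for i in range(3)} | {f"b{i}": "B" for i in range(3)}
        expr = qd.ExpressionMatrix(pd.DataFrame(cols, index=["G1", "G2", "G3", "G4"]))
        pure = qd.PureProfileSet(expr, pd.Series(labels))
        with pytest.warns(UserWarning, match="underdispersed"):
            table = moderated_t(pure, "A", "B")
        log_a = np.array([shifts + b for b in base]).T
        log_b = np.array([shifts * 2 + b for b in base]).T
        sp2 = (log_a.var(axis=1, ddof=1) * 2 + log_b.var(axis=1, ddof=1) * 2) / 4
        t_ord = (log_a.mean(1) - log_b.mean(1)) / np.sqrt(sp2 * (2 / 3))
        np.testing.assert_allclose(table["t_mod"], t_ord, rtol=1e-10)

    def test_single_replicate_falls_back_to_pooled_t(self):
        pure, _, _ = self._two_group_pure(seed=5, n_genes=50)
        sub_samples = ["a0", "a1", "a2", "b0"]
        expr = qd.ExpressionMatrix(pure.expr.data[sub_samples])
        sub = qd.PureProfileSet(expr, pure.types[sub_samples])
        with pytest.warns(UserWarning, match="ordinary pooled t"):
            table = moderated_t(sub, "A", "B")
        assert (table["df_total"] == 2.0).all()  # 3 + 1 - 2, no prior df added

    def test_too_few_replicates_errors(self):
        pure = make_pure(
            {"a1": [1.0, 2.0], "b1": [2.0, 3.0], "c1": [1.0, 1.0]},
            {"a1": "A", "b1": "B", "c1": "C"},
        )
        with pytest.raises(ValueError, match="replicates"):
            moderated_t(pure, "A", "B")

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma

        for x in [1e-4, 0.01, 0.5, 2.0, 50.0]:
            y = trigamma_inverse(x)
            assert float(polygamma(1, y)) == pytest.approx(x, rel=1e-10)

    def test_underdispersed_variances_fall_back_to_infinite_prior(self):
        with pytest.warns(UserWarning, match="underdispersed"):
            d0, s0 = fit_f_dist(np.full(50, 0.25), df=4)
        assert np.isinf(d0)
        assert s0 > 0


class TestBhFdr:
    def test_hand_enumerated_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_is_identity(self):
        np.testing.assert_allclose(bh_fdr([0.5]), [0.5])

    def test_capped_at_one(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0]), [1.0, 1.0])

    def test_nan_errors(self):
        with pytest.raises(ValueError, match="NaN"):
            bh_fdr([0.1, np.nan])

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=6
        )
    )
    def test_matches_step_up_enumeration(self, pvals):
        np.testing.assert_allclose(bh_fdr(pvals), bh_step_up(pvals), atol=1e-12)

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        adj = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestRankingAndBasis:
    def test_planted_markers_rank_before_null_genes(self):
        cfg = qd.SimulationConfig(n_types=3, n_genes=800, markers_per_type=30, seed=21)
        pure = qd.generate_pure_profiles(cfg)
        from qpdecon.simulate import marker_genes

        planted = {g for genes in marker_genes(cfg).values() for g in genes}
        ranking = candidate_ranking(pure)
        kept_planted = [g for g in ranking if g in planted]
        # every planted marker surviving the range filter precedes any null gene
        first_null = next((i for i, g in enumerate(ranking) if g not in planted), len(ranking))
        assert first_null == len(kept_planted)
        assert len(kept_planted) >= 80  # range filter may clip a few extremes

    def test_two_types_rank_by_absolute_t(self):
        pure, _, _ = TestModeratedT._two_group_pure(seed=9, n_genes=150, effects=30, delta=3.0)
        # single contrast: ranking must follow |t| on the range-filtered set
        kept = filter_expression_range(pure)
        sub = qd.PureProfileSet(
            qd.ExpressionMatrix(pure.expr.data.loc[kept]), pure.types
        )
        table = moderated_t(sub, "A", "B")
        ranking = candidate_ranking(pure, fdr_threshold=1e-3)
        scores = table["t_mod"].abs()
        ranked_scores = scores[ranking].to_numpy()
        assert np.all(np.diff(ranked_scores) <= 1e-12)

    def test_no_significant_gene_reports_min_fdr(self):
        rng = np.random.default_rng(10)
        cols = {f"a{i}": rng.uniform(50, 60, 40) for i in range(3)}
        cols |= {f"b{i}": rng.uniform(50, 60, 40) for i in range(3)}
        labels = {f"a{i}": "A" for i in range(3)} | {f"b{i}": "B" for i in range(3)}
        expr = qd.ExpressionMatrix(pd.DataFrame(cols, index=[f"G{i}" for i in range(40)]))
        pure = qd.PureProfileSet(expr, pd.Series(labels))
        with pytest.raises(ValueError, match="minimum observed FDR"):
            candidate_ranking(pure, fdr_threshold=1e-12)

    def test_basis_is_replicate_mean(self):
        pure = make_pure(
            {"a1": [100.0, 7.0, 3.0], "a2": [200.0, 9.0, 3.0], "b1": [10.0, 5.0, 4.0]},
            {"a1": "A", "a2": "A", "b1": "B"},
        )
        S = build_basis(pure, ["G1", "G2", "G3"])
        assert S.data.loc["G1", "A"] == pytest.approx(150.0)
        assert S.data.loc["G1", "B"] == pytest.approx(10.0)
        assert S.data.loc["G2", "A"] == pytest.approx(8.0)
        assert S.data.loc["G3", "B"] == pytest.approx(4.0)

    def test_basis_missing_gene_errors(self):
        pure = make_pure(
            {"a1": [1.0, 2.0], "a2": [1.0, 2.0], "b1": [3.0, 4.0]},
            {"a1": "A", "a2": "A", "b1": "B"},
        )
        with pytest.raises(KeyError, match="GX"):
            build_basis(pure, ["G1", "GX"])

    def test_replicate_order_does_not_change_basis(self, three_type_system):
        pure = three_type_system["pure"]
        genes = three_type_system["ranking"][:30]
        S1 = build_basis(pure, genes)
        shuffled_cols = list(pure.expr.sample_ids)[::-1]
        pure2 = qd.PureProfileSet(
            qd.ExpressionMatrix(pure.expr.data[shuffled_cols]), pure.types[shuffled_cols]
        )
        S2 = build_basis(pure2, genes)
        np.testing.assert_allclose(S1.values, S2.data[S1.type_labels].to_numpy())


class TestConditionNumber:
    def test_orthonormal_columns_give_one(self):
        Q = np.linalg.qr(np.random.default_rng(0).normal(size=(6, 3)))[0]
        assert condition_number(Q) == pytest.approx(1.0)

    def test_diagonal_singular_values(self):
        S = np.array([[3.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        assert condition_number(S) == pytest.approx(3.0)

    def test_duplicated_column_is_infinite(self):
        S = np.ones((4, 2))
        with pytest.warns(UserWarning, match="rank-deficient"):
            assert condition_number(S) == np.inf

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 1000), st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariant_and_at_least_one(self, seed, c):
        M = np.random.default_rng(seed).uniform(0.1, 10.0, (8, 3))
        kappa = condition_number(M)
        assert kappa >= 1.0
        assert condition_number(c * M) == pytest.approx(kappa, rel=1e-8)


class TestSelectSignature:
    def test_first_interior_local_minimum(self):
        idx, note = _first_local_minimum([9.0, 5.0, 7.0, 6.0])
        assert idx == 1 and note == ""

    def test_monotone_trace_falls_back_to_global_minimum(self):
        idx, note = _first_local_minimum([9.0, 7.0, 5.0, 3.0])
        assert idx == 3 and "no local minimum" in note

    def test_grid_truncated_when_ranking_short(self, three_type_system):
        pure = three_type_system["pure"]
        ranking = three_type_system["ranking"]
        with pytest.warns(UserWarning, match="truncat"):
            S, trace = select_signature(
                pure, ranking, size_grid=list(range(40, 5000, 500))
            )
        assert trace.sizes[-1] <= len(ranking)
        assert trace.chosen_size in trace.sizes

    def test_condition_number_tracks_rmsd(self, three_type_system):
        """Mirror of the size-sweep relationship: worse-conditioned bases
        deconvolute less accurately."""
        from scipy.stats import spearmanr

        sys3 = three_type_system
        grid = list(range(10, len(sys3["ranking"]) + 1, 10))
        S, trace = select_signature(
            sys3["pure"],
            sys3["ranking"],
            size_grid=grid,
            known_fractions=sys3["truth"],
            data=sys3["mixtures"],
        )
        rho = spearmanr(trace.condition_numbers, trace.rmsd_per_size).statistic
        assert rho > 0

    def test_rmsd_requires_mixture_matrix(self, three_type_system):
        with pytest.raises(ValueError, match="data"):
            select_signature(
                three_type_system["pure"],
                three_type_system["ranking"],
                size_grid=[20, 40],
                known_fractions=three_type_system["truth"],
            )
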