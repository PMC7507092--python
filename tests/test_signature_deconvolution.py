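import numpy as np
import pandas as pd
import pytest

from thymoatlas import counts_norm as cn
from thymoatlas import differential as dd
from thymoatlas import signature_deconvolution as sd
from thymoatlas.synthetic_data import (
    GenomeConfig,
    StageProfileConfig,
    _nb_draw,
    generate_genome_model,
    generate_stage_profiles,
)


class TestMergeLabels:
    @pytest.mark.parametrize(
        "stage,group", [("DN3", "DN3.ISP"), ("ISP", "DN3.ISP"), ("DPCD3pos", "DP"), ("DN2", "DN2")]
    )
    def test_default_map(self, stage, group):
        assert sd.merge_labels([stage]).iloc[0] == group

    def test_identity_map_keeps_labels(self):
        labels = ["X", "Y", "X"]
        out = sd.merge_labels(labels, {"X": "X", "Y": "Y"})
        assert list(out) == labels

    def test_unmapped_label_rejected(self):
        with pytest.raises(KeyError, match="mystery"):
            sd.merge_labels(["mystery"])

    def test_seven_stages_collapse_to_five_groups(self):
        out = sd.merge_labels(list(cn.STAGE_ORDER))
        assert out.nunique() == 5


def _toy_diff(groups, peaks_per_group, offset=0.0):
    """Hand-made one-vs-all results with known selectable peaks."""
    diff = {}
    for gi, g in enumerate(groups):
        idx = [f"{g}_pk{i}" for i in range(peaks_per_group)]
        diff[g] = pd.DataFrame(
            {
                "baseMean": 100.0,
                "log2FoldChange": np.linspace(3, 1, peaks_per_group) + offset,
                "lfcSE": 0.1,
                "stat": 10.0,
                "pvalue": 1e-6,
                "padj": 1e-5,
                "significant": True,
            },
            index=idx,
        )
    return diff


class TestBuildSignature:
    def test_distinct_selections_concatenate(self):
        groups = ["A", "B", "C"]
        diff = _toy_diff(groups, 5)
        samples = [f"{g}{i}" for g in groups for i in range(2)]
        vst = pd.DataFrame(
            1.0, index=[p for g in groups for p in diff[g].index], columns=samples
        )
        labels = pd.Series([g for g in groups for _ in range(2)], index=samples)
        sig = sd.build_signature(diff, vst, labels, n_base=2)
        assert len(sig.peaks) == 6

    def test_shared_peak_deduplicated(self):
        diff = _toy_diff(["A", "B"], 3)
        shared = diff["A"].index[0]
        diff["B"].loc[shared] = diff["B"].iloc[0]
        samples = ["A0", "A1", "B0", "B1"]
        universe = pd.unique(np.concatenate([diff["A"].index, diff["B"].index]))
        vst = pd.DataFrame(1.0, index=universe, columns=samples)
        labels = pd.Series(["A", "A", "B", "B"], index=samples)
        sig = sd.build_signature(diff, vst, labels, n_base=3)
        assert sig.peaks.is_unique
        assert list(sig.peaks).count(shared) == 1


class TestConditionMetric:
    def test_orthonormal_columns_give_one(self):
        q = np.linalg.qr(np.random.default_rng(0).normal(size=(50, 5)))[0]
        assert sd.condition_metric(pd.DataFrame(q)) == pytest.approx(1.0)

    def test_diagonal_singular_value_ratio(self):
        m = pd.DataFrame(np.diag([1.0, 10.0]))
        assert sd.condition_metric(m) == pytest.approx(10.0)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(50, 5))
        s = np.linalg.svd(m, compute_uv=False)
        assert sd.condition_metric(pd.DataFrame(m)) == pytest.approx(s[0] / s[-1])

    def test_rank_deficient_is_infinite(self):
        col = np.arange(10.0)
        m = pd.DataFrame({"a": col, "b": 2 * col})
        assert sd.condition_metric(m) == np.inf


class TestSweep:
    def _setup(self):
        groups = ["A", "B"]
        diff = _toy_diff(groups, 60)
        samples = ["A0", "A1", "B0", "B1"]
        rng = np.random.default_rng(2)
        universe = [p for g in groups for p in diff[g].index]
        vst = pd.DataFrame(rng.normal(5, 1, (len(universe), 4)), index=universe, columns=samples)
        labels = pd.Series(["A", "A", "B", "B"], index=samples)
        return diff, vst, labels

    def test_single_feasible_n_returned(self):
        diff, vst, labels = self._setup()
        best, table = sd.sweep_signature(
            diff, vst, labels, sd.SignatureConfig(n_min=10, n_max=10, n_step=5)
        )
        assert best.n_base == 10 and len(table) == 1

    def test_default_bounds_trace_has_51_rows(self):
        diff, vst, labels = self._setup()
        _, table = sd.sweep_signature(diff, vst, labels, sd.SignatureConfig())
        assert len(table) == 51

    def test_empty_diff_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sd.sweep_signature({}, pd.DataFrame(), pd.Series(dtype=object))


class TestDeconvolve:
    @pytest.fixture()
    def signature(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(2, 12, size=(300, 5))
        return sd.SignatureMatrix(
            values=pd.DataFrame(vals, index=[f"p{i}" for i in range(300)], columns=list("ABCDE")),
            n_base=60,
        )

    def test_pure_column_recovers_fully(self, signature):
        res = sd.deconvolve(signature, signature.values["C"])
        assert res.fractions["C"] >= 0.99
        assert res.correlation > 0.999

    def test_known_two_group_mixture_recovered(self, signature):
        mix = 0.3 * signature.values["A"] + 0.7 * signature.values["B"]
        res = sd.deconvolve(signature, mix)
        assert res.fractions["A"] == pytest.approx(0.3, abs=0.01)
        assert res.fractions["B"] == pytest.approx(0.7, abs=0.01)

    def test_fractions_on_simplex(self, signature):
        rng = np.random.default_rng(4)
        for _ in range(10):
            mix = signature.values @ rng.dirichlet(np.ones(5))
            res = sd.deconvolve(signature, mix + rng.normal(0, 0.3, len(mix)))
            assert (res.fractions >= 0).all()
            assert res.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_mixture_count_rescaling(self):
        rng = np.random.default_rng(5)
        vals = cn.vst(rng.uniform(20, 400, size=(200, 4)), 0.1)
        sig = sd.SignatureMatrix(
            values=pd.DataFrame(vals, index=[f"p{i}" for i in range(200)], columns=list("ABCD")),
            n_base=50,
            vst_dispersion=0.1,
        )
        counts = cn.inverse_vst(sig.values["B"], 0.1)
        a = sd.deconvolve(sig, cn.vst(counts, 0.1))
        b = sd.deconvolve(sig, cn.vst(counts * 7.3, 0.1))
        assert np.allclose(a.fractions, b.fractions, atol=1e-6)

    def test_all_zero_mixture_rejected(self, signature):
        with pytest.raises(ValueError, match="all-zero"):
            sd.deconvolve(signature, signature.values["A"] * 0)

    def test_nusvr_mode_recovers_dominant_group(self, signature):
        mix = 0.8 * signature.values["D"] + 0.2 * signature.values["A"]
        res = sd.deconvolve(signature, mix, method="nusvr")
        assert res.fractions.idxmax() == "D"

    def test_noisy_mixture_weights_recovered(self):
        # known Dirichlet weights on generator group profiles, NB alpha = 0.1
        genome = generate_genome_model(GenomeConfig(seed=21))
        truth, _ = generate_stage_profiles(genome, StageProfileConfig(n_peaks=2000), 21)
        gm = truth.stage_mean_matrix.T.groupby(
            truth.stage_mean_matrix.columns.map(sd.DEFAULT_MERGE_MAP)
        ).mean().T
        idx = gm.var(axis=1).sort_values(ascending=False).index[:1000]
        sig = sd.SignatureMatrix(
            values=cn.vst(gm.loc[idx], 0.1), n_base=200, vst_dispersion=0.1
        )
        rng = np.random.default_rng(22)
        errs = []
        for _ in range(10):
            w = rng.dirichlet(np.ones(5))
            y = _nb_draw(rng, gm.loc[idx].to_numpy() @ w, 0.1).astype(float)
            res = sd.deconvolve(sig, pd.Series(cn.vst(y, 0.1), index=idx))
            errs.append(np.abs(res.fractions.to_numpy() - w).mean())
        assert np.median(errs) <= 0.05


class TestCohensKappa:
    def test_perfect_agreement(self):
        assert sd.cohens_kappa(np.diag([5, 3, 7])) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # p_o = 0.7, p_e = 0.5 -> kappa = 0.4
        assert sd.cohens_kappa([[20, 5], [10, 15]]) == pytest.approx(0.4)

    def test_uniform_matrix_is_chance(self):
        assert sd.cohens_kappa(np.full((3, 3), 4)) == pytest.approx(0.0)

    def test_degenerate_marginals(self):
        assert sd.cohens_kappa([[5, 0], [0, 0]]) == 1.0
        with pytest.raises(ValueError):
            sd.cohens_kappa([[0, 0], [0, 0]])


class TestLooCrossValidate:
    def test_separated_cohort_classified_perfectly(self, cohort):
        report = sd.loo_cross_validate(cohort.thymus_counts, n_base=100)
        assert report.correct_rate >= 0.95
        assert report.cohens_kappa >= 0.9
        assert int(report.confusion.to_numpy().sum()) == len(cohort.thymus_counts.samples)

    def test_confusion_rows_match_group_sizes(self, cohort):
        report = sd.loo_cross_validate(cohort.thymus_counts, n_base=100)
        labels = sd.merge_labels(cohort.thymus_counts.metadata["stage"])
        for g, n in labels.value_counts().items():
            assert report.confusion.loc[g].sum() == n

    def test_permuted_labels_fall_to_chance(self, cohort):
        rng = np.random.default_rng(0)
        labels = sd.merge_labels(cohort.thymus_counts.metadata["stage"])
        perm = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        report = sd.loo_cross_validate(cohort.thymus_counts, labels=perm, n_base=100)
        n = len(perm)
        # chance = 1/5; allow 3 binomial SEs
        assert abs(report.correct_rate - 0.2) <= 3 * np.sqrt(0.2 * 0.8 / n)
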