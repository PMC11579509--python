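import numpy as np
import pandas as pd
import pytest

from linesim import resemblance as rs
from linesim.errors import ValidationError
from linesim.feature_selection import GeneSelection

from conftest import make_matrix
from oracles import naive_group_means, naive_spearman


def all_genes(matrix):
    return GeneSelection(tuple(matrix.index), criterion="iqr_top_k")


class TestSpearmanProfile:
    def test_identical_columns_correlate_perfectly(self, rng):
        pats = make_matrix(rng.normal(0, 1, (20, 3)), samples=["p0", "p1", "p2"])
        cells = pats[["p1"]].copy()
        cells.columns = ["line"]
        profile = rs.spearman_profile(cells, pats, all_genes(pats))
        assert profile.loc["line", "p1"] == pytest.approx(1.0)

    def test_decreasing_transform_gives_minus_one(self, rng):
        pats = make_matrix(rng.normal(0, 1, (15, 1)), samples=["p"])
        cells = pd.DataFrame({"line": -np.exp(pats["p"])}, index=pats.index)
        profile = rs.spearman_profile(cells, pats, all_genes(pats))
        assert profile.loc["line", "p"] == pytest.approx(-1.0)

    def test_ties_match_naive_average_rank_oracle(self, rng):
        genes = [f"g{i}" for i in range(6)]
        pats = make_matrix(rng.integers(0, 3, (6, 4)).astype(float), genes=genes,
                           samples=[f"p{j}" for j in range(4)])
        cells = make_matrix(rng.integers(0, 3, (6, 2)).astype(float), genes=genes,
                            samples=["c0", "c1"])
        profile = rs.spearman_profile(cells, pats, all_genes(pats))
        for c in cells.columns:
            for p in pats.columns:
                expected = naive_spearman(cells[c].tolist(), pats[p].tolist())
                assert profile.loc[c, p] == pytest.approx(expected, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        genes = [f"g{i}" for i in range(30)]
        pats = make_matrix(rng.normal(0, 1, (30, 5)), genes=genes)
        cells = make_matrix(rng.normal(0, 1, (30, 3)), genes=genes,
                            samples=["c0", "c1", "c2"])
        base = rs.spearman_profile(cells, pats, all_genes(pats))
        warped = rs.spearman_profile(np.exp(cells), 3.0 * pats + 11.0, all_genes(pats))
        pd.testing.assert_frame_equal(base, warped)

    def test_constant_sample_is_error(self, rng):
        pats = make_matrix(rng.normal(0, 1, (10, 2)), samples=["ok", "flatline"])
        pats["flatline"] = 2.0
        cells = make_matrix(rng.normal(0, 1, (10, 1)), genes=list(pats.index),
                            samples=["c"])
        with pytest.raises(ValidationError, match="flatline"):
            rs.spearman_profile(cells, pats, all_genes(pats))

    def test_too_few_genes_is_error(self):
        pats = make_matrix([[1, 2], [3, 4]])
        with pytest.raises(ValidationError, match="3 selected genes"):
            rs.spearman_profile(pats, pats, GeneSelection(("g0", "g1"), "iqr_top_k"))


class TestAverageReplicates:
    def test_identical_replicates_idempotent(self):
        profile = pd.DataFrame([[0.5, 0.2], [0.5, 0.2]], index=["L_rep1", "L_rep2"],
                               columns=["p0", "p1"])
        out = rs.average_replicates(profile, {"L_rep1": "L", "L_rep2": "L"})
        assert out.loc["L"].tolist() == [0.5, 0.2]

    def test_arithmetic_mean(self):
        profile = pd.DataFrame([[0.2, 0.4], [0.4, 0.6]], index=["a", "b"],
                               columns=["p0", "p1"])
        out = rs.average_replicates(profile, {"a": "g", "b": "g"})
        np.testing.assert_allclose(out.loc["g"], [0.3, 0.5])

    def test_matches_naive_group_means(self, rng):
        lines = [f"l{i}" for i in range(6)]
        groups = {"l0": "A", "l1": "A", "l2": "B", "l3": "B", "l4": "C", "l5": "C"}
        profile = pd.DataFrame(rng.uniform(-1, 1, (6, 5)), index=lines,
                               columns=[f"p{j}" for j in range(5)])
        out = rs.average_replicates(profile, groups)
        expected = naive_group_means(
            {l: profile.loc[l].tolist() for l in lines}, groups
        )
        for grp, vals in expected.items():
            np.testing.assert_allclose(out.loc[grp], vals, rtol=1e-12)

    def test_unknown_line_in_map_is_error(self):
        profile = pd.DataFrame([[0.1]], index=["known"], columns=["p"])
        with pytest.raises(ValidationError, match="phantom"):
            rs.average_replicates(profile, {"known": "k", "phantom": "k"})


class TestSummarizeAndRank:
    def test_single_line_ranks_first(self):
        profile = pd.DataFrame([[0.3, 0.7]], index=["only"], columns=["p0", "p1"])
        table = rs.summarize_and_rank(profile)
        assert table.loc[0, "rank_all"] == 1

    def test_dominant_profile_wins_under_both_summaries(self):
        profile = pd.DataFrame([[0.5] * 4, [0.4] * 4], index=["hi", "lo"],
                               columns=[f"p{j}" for j in range(4)])
        for summary in ("mean", "median"):
            table = rs.summarize_and_rank(profile, summary=summary)
            assert list(table["cell_line"]) == ["hi", "lo"]

    def test_matches_naive_row_mean_sort(self, rng):
        profile = pd.DataFrame(rng.uniform(0, 1, (10, 50)),
                               index=[f"l{i:02d}" for i in range(10)],
                               columns=[f"p{j}" for j in range(50)])
        table = rs.summarize_and_rank(profile)
        means = {l: profile.loc[l].mean() for l in profile.index}
        expected = sorted(means, key=lambda l: (-means[l], l))
        assert list(table["cell_line"]) == expected
        assert list(table["rank_all"]) == list(range(1, 11))

    def test_mean_commutes_with_replicate_averaging(self, rng):
        lines = [f"l{i}" for i in range(4)]
        profile = pd.DataFrame(rng.uniform(0, 1, (4, 6)), index=lines,
                               columns=[f"p{j}" for j in range(6)])
        groups = {"l0": "A", "l1": "A", "l2": "B", "l3": "B"}
        first = rs.summarize_and_rank(rs.average_replicates(profile, groups))
        per_line = rs.summarize_and_rank(profile).set_index("cell_line")["summary_rho"]
        for grp, members in (("A", ["l0", "l1"]), ("B", ["l2", "l3"])):
            averaged = first.set_index("cell_line").loc[grp, "summary_rho"]
            assert averaged == pytest.approx(per_line[members].mean(), abs=1e-14)

    def test_empty_subset_is_error(self):
        profile = pd.DataFrame([[0.1]], index=["l"], columns=["p"])
        with pytest.raises(ValidationError):
            rs.summarize_and_rank(profile, patient_subset=[])


def annotation_for(patients, labels):
    return pd.DataFrame(
        {
            "sample_id": patients,
            "cohort": "patient",
            "subgroup": labels,
            "replicate_group": patients,
            "excluded": False,
        }
    )


class TestSubgroupContrast:
    def test_plug_in_delta(self):
        pats = [f"p{j}" for j in range(4)]
        profile = pd.DataFrame([[0.6, 0.6, 0.4, 0.4]], index=["line"], columns=pats)
        ann = annotation_for(pats, ["HRD1", "HRD1", "HRD0", "HRD0"])
        table = rs.subgroup_contrast(profile, ann)
        assert table.loc[0, "delta_rho"] == pytest.approx(0.2)
        assert table.loc[0, "delta_rho"] == table.loc[0, "mean_rho_HRD1"] - table.loc[0, "mean_rho_HRD0"]

    def test_single_label_cohort_is_error(self):
        pats = ["p0", "p1"]
        profile = pd.DataFrame([[0.1, 0.2]], index=["line"], columns=pats)
        ann = annotation_for(pats, ["HRD1", "HRD1"])
        with pytest.raises(ValidationError, match="non-empty"):
            rs.subgroup_contrast(profile, ann)

    def test_summary_tracks_planted_resemblance_for_random_lines(self):
        from scipy.stats import spearmanr

        from linesim import counts_io, feature_selection, vst
        from linesim.synthetic_cohort import CohortConfig, simulate_cohort

        gen = np.random.default_rng(99)
        resemblance_values = tuple(gen.uniform(0.05, 0.95, 20))
        config = CohortConfig(
            n_genes=2000, n_patients=100, n_signature_genes=100,
            n_cell_lines=20, resemblance=resemblance_values,
            subgroup_affinity=(0.0,) * 20, seed=99,
        )
        counts, ann, truth = simulate_cohort(config)
        annx = ann.set_index("sample_id")
        patients = [s for s in counts.columns if annx.loc[s, "cohort"] == "patient"]
        lines = [s for s in counts.columns if annx.loc[s, "cohort"] == "cell_line"]
        keep = feature_selection.expression_filter(counts_io.cpm(counts))
        filtered = feature_selection.apply_selection(counts, keep)
        ref_vst, _, _ = vst.blind_vst(filtered[patients])
        selection = feature_selection.top_variable_genes(ref_vst, k=2000)
        comb_vst, _, _ = vst.blind_vst(filtered)
        profile = rs.spearman_profile(comb_vst[lines], comb_vst[patients], selection)
        profile = rs.average_replicates(
            profile, {s: annx.loc[s, "replicate_group"] for s in lines}
        )
        summary = rs.summarize_and_rank(profile).set_index("cell_line")["summary_rho"]
        rho = spearmanr(
            [truth.line_resemblance[l] for l in summary.index], summary.to_numpy()
        ).statistic
        assert rho >= 0.9

    def test_ranks_are_permutations(self, rng):
        pats = [f"p{j}" for j in range(10)]
        labels = ["HRD1"] * 6 + ["HRD0"] * 4
        profile = pd.DataFrame(rng.uniform(0, 1, (5, 10)),
                               index=[f"l{i}" for i in range(5)], columns=pats)
        table = rs.subgroup_contrast(profile, annotation_for(pats, labels))
        for col in ("rank_all", "rank_HRD1", "rank_HRD0"):
            assert sorted(table[col]) == [1, 2, 3, 4, 5]
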