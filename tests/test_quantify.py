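"""Unit and property tests for the centralize / median-correct / rollup
quantification chain, replicate QC and spectra accounting."""

import numpy as np
import pandas as pd
import pytest

from tmtdep import (
    PeptideIntensityMatrix,
    SimConfig,
    SpectraAccounting,
    centralize,
    degrade_sample,
    median_correct,
    protein_abundance,
    quantify,
    replicate_qc,
    rollup_protein,
    simulate_dataset,
    spectra_utilization,
)
from tmtdep.containers import RelativeQuantMatrix


def _pmatrix(rows, index=None, n_wt=2, n_hom=2):
    arr = np.asarray(rows, dtype=float)
    samples = [f"Wt{i}" for i in range(1, n_wt + 1)] + [
        f"Hom{i}" for i in range(1, n_hom + 1)
    ]
    frame = pd.DataFrame(arr, columns=samples[: arr.shape[1]],
                         index=index or [f"p{i}" for i in range(arr.shape[0])])
    groups = pd.Series((["Wt"] * n_wt + ["Hom"] * n_hom)[: arr.shape[1]],
                       index=frame.columns)
    return PeptideIntensityMatrix(frame, groups)


class TestCentralize:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ([1.0, 2.0, 3.0], [0.5, 1.0, 1.5]),
            ([5.0, 5.0, 5.0, 5.0], [1.0, 1.0, 1.0, 1.0]),
        ],
    )
    def test_divides_by_row_mean(self, row, expected):
        m = _pmatrix([row], n_wt=len(row), n_hom=0)
        u = centralize(m)
        np.testing.assert_allclose(u.values.iloc[0].values, expected)

    def test_mean_over_observed_values_only(self):
        # (4, missing, 8, missing): observed mean 6 -> (2/3, missing, 4/3, missing)
        m = _pmatrix([[4.0, np.nan, 8.0, np.nan]])
        row = centralize(m).values.iloc[0]
        assert row.iloc[0] == pytest.approx(2 / 3)
        assert np.isnan(row.iloc[1])
        assert row.iloc[2] == pytest.approx(4 / 3)
        assert np.isnan(row.iloc[3])

    def test_fully_observed_rows_have_mean_one(self, sim_dataset):
        matrix, _, _ = sim_dataset
        u = centralize(matrix)
        full = u.values.dropna(axis=0)
        np.testing.assert_allclose(full.mean(axis=1), 1.0, atol=1e-12)

    def test_all_missing_peptide_dropped_with_warning(self, caplog):
        frame = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [np.nan] * 4],
            index=["ok", "ghost"],
            columns=["Wt1", "Wt2", "Hom1", "Hom2"],
        )
        m = PeptideIntensityMatrix(frame, pd.Series(["Wt", "Wt", "Hom", "Hom"],
                                                    index=frame.columns))
        with caplog.at_level("WARNING"):
            u = centralize(m)
        assert list(u.values.index) == ["ok"]
        assert "ghost" in caplog.text


class TestMedianCorrect:
    def test_identity_when_median_is_one(self):
        vals = pd.DataFrame(
            {"Wt1": [0.5, 1.0, 2.0], "Wt2": [0.5, 1.0, 2.0],
             "Hom1": [0.5, 1.0, 2.0], "Hom2": [0.5, 1.0, 2.0]},
            index=["a", "b", "c"],
        )
        m = RelativeQuantMatrix(vals, pd.Series(["Wt", "Wt", "Hom", "Hom"],
                                                index=vals.columns))
        np.testing.assert_allclose(median_correct(m).values, vals)

    def test_divides_by_column_median(self):
        vals = pd.DataFrame(
            {"Wt1": [2.0, 4.0, 6.0], "Wt2": [1.0, 1.0, 1.0],
             "Hom1": [1.0, 1.0, 1.0], "Hom2": [1.0, 1.0, 1.0]},
            index=["a", "b", "c"],
        )
        m = RelativeQuantMatrix(vals, pd.Series(["Wt", "Wt", "Hom", "Hom"],
                                                index=vals.columns))
        np.testing.assert_allclose(
            median_correct(m).values["Wt1"].values, [0.5, 1.0, 1.5]
        )

    def test_observed_column_median_is_one(self, sim_dataset):
        matrix, _, _ = sim_dataset
        nr = median_correct(centralize(matrix))
        np.testing.assert_allclose(nr.values.median(axis=0, skipna=True), 1.0,
                                   atol=1e-12)

    def test_zero_median_is_hard_error(self):
        vals = pd.DataFrame(
            {"Wt1": [0.0, 0.0, 0.0], "Wt2": [1.0, 1.0, 1.0],
             "Hom1": [1.0, 1.0, 1.0], "Hom2": [1.0, 1.0, 1.0]},
            index=["a", "b", "c"],
        )
        m = RelativeQuantMatrix(vals, pd.Series(["Wt", "Wt", "Hom", "Hom"],
                                                index=vals.columns))
        with pytest.raises(ValueError, match="median is 0"):
            median_correct(m)


class TestRollup:
    def _nr(self, rows, index):
        vals = pd.DataFrame(rows, index=index,
                            columns=["Wt1", "Wt2", "Hom1", "Hom2"])
        return RelativeQuantMatrix(vals, pd.Series(["Wt", "Wt", "Hom", "Hom"],
                                                   index=vals.columns))

    def test_median_odd_and_even_counts(self):
        nr = self._nr(
            [[0.8] * 4, [1.0] * 4, [1.4] * 4, [0.8] * 4, [1.2] * 4],
            ["a1", "a2", "a3", "b1", "b2"],
        )
        pmap = {"a1": {"A"}, "a2": {"A"}, "a3": {"A"}, "b1": {"B"}, "b2": {"B"}}
        q = rollup_protein(nr, pmap)
        assert q.values.loc["A"].tolist() == [1.0] * 4  # odd count
        assert q.values.loc["B"].tolist() == [1.0] * 4  # even: midpoint
        assert q.n_unique_peptides.to_dict() == {"A": 3, "B": 2}

    def test_shared_peptides_excluded_entirely(self):
        nr = self._nr([[1.0] * 4, [99.0] * 4], ["u", "s"])
        q = rollup_protein(nr, {"u": {"A"}, "s": {"A", "B"}})
        assert q.values.loc["A"].tolist() == [1.0] * 4
        assert "B" not in q.values.index  # only a shared peptide -> absent

    def test_adding_shared_peptides_never_changes_r(self, clean_dataset):
        matrix, pmap, _ = clean_dataset
        nr = median_correct(centralize(matrix))
        base = rollup_protein(nr, pmap)
        # graft 10 extra shared rows onto the NR matrix
        extra = nr.values.iloc[:10] * 7.7
        extra.index = [f"shared_{i}" for i in range(10)]
        prots = list(base.values.index)
        pmap2 = dict(pmap)
        aug = pd.concat([nr.values, extra])
        for i, pep in enumerate(extra.index):
            pmap2[pep] = {prots[i], prots[i + 1]}
        q2 = rollup_protein(RelativeQuantMatrix(aug, nr.groups), pmap2)
        pd.testing.assert_frame_equal(base.values, q2.values)

    def test_unmapped_peptide_is_hard_error(self):
        nr = self._nr([[1.0] * 4], ["orphan"])
        with pytest.raises(ValueError, match="absent from the peptide->protein map"):
            rollup_protein(nr, {})


class TestPipelineInvariants:
    def test_global_rescaling_invariance(self, sim_dataset):
        matrix, pmap, _ = sim_dataset
        q1 = quantify(matrix, pmap)
        scaled = PeptideIntensityMatrix(matrix.intensities * 37.5, matrix.groups)
        q2 = quantify(scaled, pmap)
        pd.testing.assert_frame_equal(q1.values, q2.values)

    def test_rank_one_input_gives_all_ones(self):
        # I_ij = a_i * b_j -> every NR and R is exactly 1
        rng = np.random.default_rng(0)
        a = rng.uniform(0.5, 2.0, size=9)
        b = rng.uniform(1e3, 1e6, size=12)
        samples = [f"Wt{i}" for i in range(1, 5)] + [f"Hom{i}" for i in range(1, 6)]
        frame = pd.DataFrame(np.outer(b, a), columns=samples,
                             index=[f"pep{j}" for j in range(12)])
        m = PeptideIntensityMatrix(frame, pd.Series(["Wt"] * 4 + ["Hom"] * 5,
                                                    index=samples))
        pmap = {f"pep{j}": {f"prot{j % 4}"} for j in range(12)}
        q = quantify(m, pmap)
        np.testing.assert_allclose(q.values, 1.0, atol=1e-12)

    def test_matches_brute_force_formula_evaluation(self, sim_dataset):
        """Independent oracle: evaluate U, NR, R cell by cell on a 6x6 slice."""
        matrix, pmap, _ = sim_dataset
        sub = matrix.intensities.iloc[:6, :6]
        groups = matrix.groups[sub.columns]
        m = PeptideIntensityMatrix(sub.copy(), groups.copy())

        vals = m.intensities  # post-construction (0 -> NaN) view
        u = pd.DataFrame(index=vals.index, columns=vals.columns, dtype=float)
        for pep in vals.index:
            obs = [v for v in vals.loc[pep] if not np.isnan(v)]
            mean = sum(obs) / len(obs)
            for s in vals.columns:
                u.loc[pep, s] = vals.loc[pep, s] / mean
        nr = pd.DataFrame(index=vals.index, columns=vals.columns, dtype=float)
        for s in vals.columns:
            col = sorted(v for v in u[s] if not np.isnan(v))
            mid = len(col) // 2
            med = col[mid] if len(col) % 2 else (col[mid - 1] + col[mid]) / 2
            nr[s] = u[s] / med
        owners = {p: next(iter(o)) for p, o in pmap.items() if len(o) == 1}
        expected = {}
        for prot in sorted({owners[p] for p in vals.index if p in owners}):
            peps = [p for p in vals.index if owners.get(p) == prot]
            row = {}
            for s in vals.columns:
                obs = sorted(v for v in nr.loc[peps, s] if not np.isnan(v))
                if not obs:
                    row[s] = np.nan
                    continue
                mid = len(obs) // 2
                row[s] = obs[mid] if len(obs) % 2 else (obs[mid - 1] + obs[mid]) / 2
            expected[prot] = row

        got = rollup_protein(median_correct(centralize(m)), pmap,
                             min_samples_per_group=1)
        for prot in got.values.index:
            for s in got.values.columns:
                assert got.values.loc[prot, s] == pytest.approx(
                    expected[prot][s], nan_ok=True
                )


class TestReplicateQC:
    def test_clean_replicates_not_flagged(self, sim_dataset):
        matrix, pmap, _ = sim_dataset
        flagged, corr = replicate_qc(protein_abundance(matrix, pmap), floor=0.8)
        assert flagged == []
        assert corr.shape == (9, 9)

    def test_planted_outlier_recovered(self, sim_dataset):
        matrix, pmap, _ = sim_dataset
        bad = degrade_sample(matrix, "Wt3", decorrelation=1.0, seed=99)
        flagged, _ = replicate_qc(protein_abundance(bad, pmap), floor=0.8)
        assert flagged == ["Wt3"]

    def test_floor_minus_one_never_flags(self, sim_dataset):
        matrix, pmap, _ = sim_dataset
        bad = degrade_sample(matrix, "Wt3", decorrelation=1.0, seed=99)
        flagged, _ = replicate_qc(protein_abundance(bad, pmap), floor=-1.0)
        assert flagged == []

    def test_two_sample_group_skipped_with_warning(self, caplog):
        cfg = SimConfig(n_proteins=40, n_wt=2, n_hom=3, noise_cv=0.1, seed=1)
        m, pm, _ = simulate_dataset(cfg)
        with caplog.at_level("WARNING"):
            flagged, _ = replicate_qc(protein_abundance(m, pm), floor=0.8)
        assert "skipped" in caplog.text
        assert all(s not in flagged for s in m.samples_of("Wt"))


class TestSpectraAccounting:
    @pytest.mark.parametrize(
        "total,effective,expected",
        [(247_627, 67_318, 27.2), (1000, 1000, 100.0), (1000, 0, 0.0)],
    )
    def test_utilization_percentage(self, total, effective, expected):
        assert spectra_utilization(SpectraAccounting(total, effective)) == expected

    def test_effective_above_total_rejected(self):
        with pytest.raises(ValueError, match="cannot exceed"):
            SpectraAccounting(total_spectra=10, effective_spectra=11)
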