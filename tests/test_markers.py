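import numpy as np
import pandas as pd
import pytest

from phenopred import markers, simulate
from phenopred.dataio import GenotypeMatrix
from phenopred.errors import PhenopredError
from phenopred.predict import predict_new, solve_rrblup


@pytest.fixture
def toy_matrix():
    """Hand-enumerated QC fixture, 6 markers x 4 genotypes:
    M1 all-missing; M2 3/4 missing; M3 2/4 het; M4 monomorphic;
    M5, M6 clean polymorphic."""
    calls = np.array(
        [
            [-1, -1, -1, -1],
            [-1, -1, -1, 0],
            [1, 1, 0, 2],
            [0, 0, 0, 0],
            [0, 2, 0, 2],
            [2, 0, 2, -1],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        calls,
        marker_ids=[f"M{i}" for i in range(1, 7)],
        genotype_ids=["g1", "g2", "g3", "g4"],
    )


class TestOverallQC:
    def test_hand_enumerated_step_counts(self, toy_matrix):
        out, report = markers.qc_overall(toy_matrix)
        removed = [s["removed"] for s in report.steps]
        assert removed == [1, 1, 1, 1]
        assert report.n_remaining == 2
        assert out.marker_ids == ["M5", "M6"]

    def test_clean_matrix_untouched(self):
        calls = np.array([[0, 2, 0], [2, 0, 2]], dtype=np.int8)
        gm = GenotypeMatrix(calls, marker_ids=["a", "b"],
                            genotype_ids=["x", "y", "z"])
        out, report = markers.qc_overall(gm)
        assert all(s["removed"] == 0 for s in report.steps)
        assert out.n_markers == 2

    def test_report_is_additive_and_idempotent(self, toy_matrix):
        out, report = markers.qc_overall(toy_matrix)
        report.validate()
        again, report2 = markers.qc_overall(out)
        assert all(s["removed"] == 0 for s in report2.steps)
        np.testing.assert_array_equal(again.calls, out.calls)

    def test_failing_genotype_flagged_not_dropped(self):
        # g3 is ~all-missing across polymorphic markers
        calls = np.array(
            [[0, 2, -1], [2, 0, -1], [0, 2, -1], [2, 0, 0]], dtype=np.int8
        )
        gm = GenotypeMatrix(
            calls, marker_ids=list("abcd"), genotype_ids=["g1", "g2", "g3"]
        )
        out, report = markers.qc_overall(gm)
        assert out.n_genotypes == 3
        assert [f["genotype_id"] for f in report.genotype_flags] == ["g3"]


class TestPerGroupQC:
    def test_group_specific_monomorphic_removal(self):
        # marker 'a' varies only in group B
        calls = np.array([[0, 0, 0, 2], [0, 2, 0, 2]], dtype=np.int8)
        gm = GenotypeMatrix(calls, marker_ids=["a", "b"],
                            genotype_ids=["g1", "g2", "g3", "g4"])
        gmap = pd.DataFrame(
            {"genotype_id": ["g1", "g2", "g3", "g4"],
             "subgroup": ["A", "A", "B", "B"],
             "major_group": ["A", "A", "B", "B"]}
        )
        out = markers.qc_per_group(gm, gmap)
        assert out["A"][0].marker_ids == ["b"]
        assert out["B"][0].marker_ids == ["a", "b"]

    def test_maf_threshold_is_strict(self):
        rng = np.random.default_rng(0)
        n = 100
        m_low = np.zeros(n, dtype=np.int8)
        m_low[:2] = 2  # MAF 0.02 -> removed
        m_keep = np.zeros(n, dtype=np.int8)
        m_keep[:4] = 2  # MAF 0.04 -> kept at threshold 0.03
        gm = GenotypeMatrix(
            np.vstack([m_low, m_keep]),
            marker_ids=["low", "keep"],
            genotype_ids=[f"g{i}" for i in range(n)],
        )
        gmap = pd.DataFrame(
            {"genotype_id": gm.genotype_ids, "subgroup": "A",
             "major_group": "A"}
        )
        out = markers.qc_per_group(gm, gmap, maf_thr=0.03)
        assert out["A"][0].marker_ids == ["keep"]

    def test_het_calls_become_missing_not_removed(self):
        calls = np.array([[0, 1, 2, 2]], dtype=np.int8)
        gm = GenotypeMatrix(calls, marker_ids=["m"],
                            genotype_ids=list("wxyz"))
        gmap = pd.DataFrame(
            {"genotype_id": list("wxyz"), "subgroup": "A", "major_group": "A"}
        )
        out = markers.qc_per_group(gm, gmap)
        assert out["A"][0].calls.tolist() == [[0, -1, 2, 2]]


class TestImputation:
    def test_mean_imputation_value(self):
        calls = np.array([[0, 2, -1, 2]], dtype=np.int8)
        gm = GenotypeMatrix(calls, marker_ids=["m"], genotype_ids=list("abcd"))
        dm = markers.impute_naive({"A": gm})["A"]
        np.testing.assert_allclose(dm.values[:, 0], [0, 2, 4 / 3, 2])

    def test_complete_matrix_unchanged(self):
        calls = np.array([[0, 2], [2, 1]], dtype=np.int8)
        gm = GenotypeMatrix(calls, marker_ids=["m1", "m2"],
                            genotype_ids=["a", "b"])
        dm = markers.impute_naive({"A": gm})["A"]
        np.testing.assert_array_equal(dm.values, calls.T)

    def test_imputation_degrades_prediction_gracefully(self):
        # 10% MCAR missingness should cost little predictive ability
        rng = np.random.default_rng(42)
        n, p = 150, 400
        dos = rng.choice([0, 2], size=(p, n), p=[0.5, 0.5]).astype(np.int8)
        effects = rng.normal(size=60)
        qtl = rng.choice(p, 60, replace=False)
        yv = effects @ dos[qtl].astype(float)
        y = pd.Series(
            yv + rng.normal(0, np.std(yv) * 0.5, n),
            index=[f"g{i}" for i in range(n)],
        )
        masked = dos.copy()
        masked[rng.random(dos.shape) < 0.10] = -1
        gmap_ids = [f"g{i}" for i in range(n)]

        def ability(calls):
            gm = GenotypeMatrix(calls, marker_ids=[f"m{j}" for j in range(p)],
                                genotype_ids=gmap_ids)
            dm = markers.impute_naive({"A": gm})["A"]
            Z = dm.to_frame()
            train, test = gmap_ids[:110], gmap_ids[110:]
            model = solve_rrblup(y.loc[train], Z.loc[train])
            pred = predict_new(model, Z.loc[test])
            return np.corrcoef(pred, y.loc[test])[0, 1]

        r_full = ability(dos)
        r_masked = ability(masked)
        assert r_full - r_masked <= 0.05


class TestMergeAndInvariance:
    def make_groups(self, seed=1, n_groups=3, n=40, p=60):
        cfg = simulate.SimConfig(
            population=simulate.PopulationConfig(
                group_sizes={f"G{k}": n for k in range(n_groups)},
                n_markers=p, fst=0.2,
            ),
            seed=seed,
        )
        gm, gmap, _ = simulate.simulate_population(cfg)
        per = markers.qc_per_group(gm, gmap, level="subgroup")
        return markers.impute_naive(per)

    def test_single_group_reduces_to_filter(self):
        dosages = self.make_groups(n_groups=1)
        merged = markers.maf_filter_and_merge(dosages, maf_thr=0.05)
        dm = dosages["G0"]
        freq = dm.values.mean(axis=0) / 2
        expected = [m for m, f in zip(dm.marker_ids,
                                      np.minimum(freq, 1 - freq))
                    if f >= 0.05]
        assert merged.marker_ids == expected

    def test_merged_set_matches_set_operation_oracle(self):
        dosages = self.make_groups(n_groups=3)
        merged = markers.maf_filter_and_merge(dosages, maf_thr=0.05)
        survive = []
        for dm in dosages.values():
            freq = dm.values.mean(axis=0) / 2
            maf = np.minimum(freq, 1 - freq)
            survive.append(
                {m for m, f in zip(dm.marker_ids, maf) if f >= 0.05}
            )
        oracle = set.intersection(*survive)
        assert set(merged.marker_ids) == oracle
        assert len(merged.genotype_ids) == sum(
            len(d.genotype_ids) for d in dosages.values()
        )

    def test_marker_absent_from_one_group_is_dropped(self):
        a = markers.DosageMatrix(
            np.array([[0.0, 2.0], [2.0, 0.0]]), ["g1", "g2"], ["m1", "m2"]
        )
        b = markers.DosageMatrix(
            np.array([[0.0], [2.0]]), ["g3", "g4"], ["m1"]
        )
        merged = markers.maf_filter_and_merge({"A": a, "B": b}, maf_thr=0.0)
        assert merged.marker_ids == ["m1"]

    def test_empty_intersection_reports_counts(self):
        a = markers.DosageMatrix(np.array([[0.0], [2.0]]), ["g1", "g2"], ["m1"])
        b = markers.DosageMatrix(np.array([[0.0], [2.0]]), ["g3", "g4"], ["m2"])
        with pytest.raises(PhenopredError, match="survivors"):
            markers.maf_filter_and_merge({"A": a, "B": b}, maf_thr=0.0)

    def test_allele_flip_leaves_predictions_unchanged(self):
        rng = np.random.default_rng(7)
        n, p = 60, 80
        Z = pd.DataFrame(
            rng.choice([0.0, 1.0, 2.0], size=(n, p)),
            index=[f"g{i}" for i in range(n)],
        )
        y = pd.Series(rng.normal(size=n), index=Z.index)
        flipped = 2.0 - Z
        m1 = solve_rrblup(y.iloc[:40], Z.iloc[:40])
        m2 = solve_rrblup(y.iloc[:40], flipped.iloc[:40])
        p1 = predict_new(m1, Z.iloc[40:])
        p2 = predict_new(m2, flipped.iloc[40:])
        # residual deviation reflects the variance-ratio optimizer tolerance
        np.testing.assert_allclose(p1, p2, atol=1e-6 * y.std())
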