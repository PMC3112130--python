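"""Dataset I/O, prevalence tables and prevalence-difference tests."""

import math

import numpy as np
import pytest

from twinliab.twin_io import (FormatError, TwinDataset, TwinPairRecord,
                              compare_prevalence, percent_ever,
                              prevalence_table, read_dataset, write_dataset)


def _rec(group="MZM", cohort="c1", p1=1, p2=0, fid="f1"):
    return TwinPairRecord(family_id=fid, group=group, cohort=cohort,
                          pheno1=p1, pheno2=p2)


class TestRecordsAndDataset:
    def test_counting_pairs_and_singletons(self):
        ds = TwinDataset.from_records([
            _rec(fid="a"), _rec(fid="b"),
            _rec(group="DZF", fid="c", p1=None, p2=1),
        ])
        assert ds.n_records == 3
        assert ds.n_pairs == 2
        assert ds.n_singletons == 1
        assert ds.n_individuals == 5

    def test_invalid_records_rejected(self):
        with pytest.raises(ValueError):
            _rec(group="XX")
        with pytest.raises(ValueError):
            _rec(p1=None, p2=None)
        with pytest.raises(ValueError):
            _rec(p1=2)

    def test_dos_sex_convention_and_override(self):
        rec = _rec(group="DOS")
        assert rec.sexes == ("M", "F")
        rec = TwinPairRecord("f", "DOS", "c1", 1, 0, sex1="F", sex2="M")
        assert rec.sexes == ("F", "M")


class TestReadWrite:
    def test_round_trip(self, tmp_path, preset_dataset):
        path = tmp_path / "ds.csv"
        write_dataset(preset_dataset, path)
        again = read_dataset(path)
        assert again.cohorts == preset_dataset.cohorts
        assert [
            (r.family_id, r.group, r.cohort, r.pheno1, r.pheno2)
            for r in again.records
        ] == [
            (r.family_id, r.group, r.cohort, r.pheno1, r.pheno2)
            for r in preset_dataset.records
        ]

    def test_unknown_group_excluded_and_counted(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "family_id,group,cohort,pheno1,pheno2\n"
            "f1,MZM,c1,1,0\nf2,XX,c1,1,1\nf3,DZF,c1,,NA\nf4,MZF,c1,1,\n"
        )
        ds = read_dataset(path)
        assert ds.n_records == 2
        assert ds.read_log.n_excluded_unknown_group == 1
        assert ds.read_log.n_excluded_missing_both == 1

    def test_missing_column_raises(self, tmp_path):
        path = tmp_path / "cols.csv"
        path.write_text("family_id,group,pheno1,pheno2\nf1,MZM,1,0\n")
        with pytest.raises(FormatError):
            read_dataset(path)


class TestPrevalenceTable:
    @pytest.mark.parametrize(
        "k, n, pct", [(592, 1162, 50.9), (175, 768, 22.8), (352, 1573, 22.4),
                      (1, 8, 12.5), (1, 16, 6.3)]  # half-up at the half-point
    )
    def test_percent_round_half_up(self, k, n, pct):
        assert percent_ever(k, n) == pct

    def test_counts_each_individual_once(self, preset_dataset):
        table = prevalence_table(preset_dataset)
        for cohort in preset_dataset.cohorts:
            cells = table[(table.cohort == cohort) & (table.zyg_class != "Total")]
            assert cells.n_total.sum() == preset_dataset.subset(cohort=cohort).n_individuals

    def test_totals_are_row_sums(self, preset_dataset):
        table = prevalence_table(preset_dataset)
        for (sex, cohort), sub in table.groupby(["sex", "cohort"]):
            tot = sub[sub.zyg_class == "Total"]
            cells = sub[sub.zyg_class != "Total"]
            assert int(tot.n_total.iloc[0]) == cells.n_total.sum()
            assert int(tot.n_ever.iloc[0]) == cells.n_ever.sum()

    def test_all_zero_phenotypes(self):
        ds = TwinDataset.from_records(
            [_rec(p1=0, p2=0, fid=str(i)) for i in range(5)]
        )
        table = prevalence_table(ds)
        assert (table.dropna().percent == 0.0).all()

    def test_empty_dataset_errors(self):
        with pytest.raises(ValueError):
            prevalence_table(TwinDataset.from_records([]))

    def test_converges_to_generator_cell_probabilities(self):
        # 1e5 individuals per cell; MC error bound 3 SE
        from twinliab.simulate import GroupCounts, SimConfig, simulate

        prev = 0.35
        cfg = SimConfig(
            cohorts=("c1",),
            counts={("c1", "MZM"): GroupCounts(50_000, 0)},
            shares={("M", "c1"): (0.5, 0.3, 0.2), ("F", "c1"): (0.5, 0.3, 0.2)},
            rcdos={"c1": 1.0},
            prevalence={(s, z, "c1"): prev for s in "MF" for z in ("MZ", "DZ")},
        )
        table = prevalence_table(simulate(cfg, seed=5))
        cell = table[(table.sex == "M") & (table.zyg_class == "MZ")].iloc[0]
        se = math.sqrt(prev * (1 - prev) / cell.n_total)
        assert abs(cell.n_ever / cell.n_total - prev) < 3 * se


class TestComparePrevalence:
    def _dataset_from_counts(self, spec):
        """spec: list of (group, cohort, n_affected, n_total) singleton cells."""
        recs = []
        i = 0
        for group, cohort, k, n in spec:
            for j in range(n):
                recs.append(TwinPairRecord(
                    family_id=f"f{i}", group=group, cohort=cohort,
                    pheno1=1 if j < k else 0, pheno2=None))
                i += 1
        return TwinDataset.from_records(recs)

    def test_published_male_cohort_difference(self):
        # individual-level 2x2 of the printed male totals: 592/1162 vs 175/768
        ds = self._dataset_from_counts([
            ("DZM", "c1", 592, 1162), ("DZM", "c2", 175, 768),
        ])
        res = compare_prevalence(ds, "cohort", "M")
        # frozen from scipy.stats.chi2_contingency (correction=False)
        assert res.chi2 == pytest.approx(153.1160079, abs=1e-3)
        assert res.chi2_p < 0.001
        assert res.lrt_p < 0.001

    def test_published_male_zygosity_difference(self):
        # MZ 44/301 vs pooled DZ 131/467 in the later cohort
        ds = self._dataset_from_counts([
            ("MZM", "c2", 44, 301), ("DZM", "c2", 69, 239),
            ("DOS", "c2", 62, 228),
        ])
        res = compare_prevalence(ds, "zygosity", "M", cohort="c2")
        assert res.counts == ((44, 301), (131, 467))
        assert res.chi2_p < 0.001

    def test_identical_proportions(self):
        ds = self._dataset_from_counts([
            ("MZM", "c1", 10, 40), ("MZM", "c2", 10, 40),
        ])
        res = compare_prevalence(ds, "cohort", "M")
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.chi2_p == pytest.approx(1.0)
        assert res.lrt == pytest.approx(0.0, abs=1e-12)

    def test_pearson_matches_scipy(self):
        from scipy.stats import chi2_contingency

        ds = self._dataset_from_counts([
            ("MZF", "c1", 224, 658), ("MZF", "c2", 128, 728),
        ])
        res = compare_prevalence(ds, "cohort", "F", zyg_class="MZ")
        ref = chi2_contingency(
            [[224, 658 - 224], [128, 728 - 128]], correction=False
        )
        assert res.chi2 == pytest.approx(ref.statistic, abs=1e-10)
        assert res.chi2_p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_chi2_and_lrt_agree_on_null_data(self):
        # both tests should reach the same accept/reject decision at alpha=.01
        rng = np.random.default_rng(21)
        agree = 0
        n_sim = 200
        for _ in range(n_sim):
            k1 = rng.binomial(400, 0.3)
            k2 = rng.binomial(500, 0.3)
            ds = self._dataset_from_counts([
                ("DZF", "c1", int(k1), 400), ("DZF", "c2", int(k2), 500),
            ])
            res = compare_prevalence(ds, "cohort", "F")
            agree += (res.chi2_p < 0.01) == (res.lrt_p < 0.01)
        assert agree >= 0.95 * n_sim

    def test_zero_denominator_errors(self):
        ds = self._dataset_from_counts([("MZM", "c1", 5, 10), ("MZM", "c2", 5, 10)])
        with pytest.raises(ValueError):
            compare_prevalence(ds, "zygosity", "M", cohort="c1")  # no DZ rows
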