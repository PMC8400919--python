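"""Peak I/O, noise filtering, alignment and adduct grouping."""

import numpy as np
import pandas as pd
import pytest

from metabrobust.features import (
    ADDUCT_OFFSETS,
    FeatureTable,
    PeakList,
    PeakListError,
    align_features,
    annotate_adduct_groups,
    noise_filter,
    read_feature_table,
    read_peak_lists,
    write_feature_table,
    write_peak_lists,
)


def pl(sample_id, rows, **meta):
    return PeakList(
        sample_id=sample_id,
        peaks=pd.DataFrame(rows, columns=["mz", "rt", "abundance"]),
        **meta,
    )


class TestPeakIO:
    def test_round_trip(self, tmp_path):
        lists = [
            pl("s1", [(100.0, 1.0, 500.0), (200.0, 2.0, 300.0)], role="study", method="A"),
            pl("s2", [(100.0001, 1.01, 450.0)], role="blank"),
        ]
        write_peak_lists(lists, tmp_path / "p.csv", tmp_path / "m.csv")
        back = read_peak_lists(tmp_path / "p.csv", tmp_path / "m.csv")
        assert [b.sample_id for b in back] == ["s1", "s2"]
        assert back[0].method == "A" and back[1].role == "blank"
        pd.testing.assert_frame_equal(back[0].peaks, lists[0].peaks)

    def test_negative_abundance_reported_with_line_number(self, tmp_path):
        (tmp_path / "p.csv").write_text(
            "sample_id,mz,rt,abundance\ns1,100.0,1.0,500\ns1,101.0,1.0,-5\n"
        )
        (tmp_path / "m.csv").write_text("sample_id,role\ns1,study\n")
        with pytest.raises(PeakListError, match="line 3"):
            read_peak_lists(tmp_path / "p.csv", tmp_path / "m.csv")

    def test_metadata_missing_sample_named_in_error(self, tmp_path):
        (tmp_path / "p.csv").write_text("sample_id,mz,rt,abundance\norphan,100.0,1.0,500\n")
        (tmp_path / "m.csv").write_text("sample_id,role\ns1,study\n")
        with pytest.raises(PeakListError, match="orphan"):
            read_peak_lists(tmp_path / "p.csv", tmp_path / "m.csv")

    def test_duplicate_sample_ids_rejected(self, tmp_path):
        (tmp_path / "p.csv").write_text("sample_id,mz,rt,abundance\ns1,100.0,1.0,500\n")
        (tmp_path / "m.csv").write_text("sample_id,role\ns1,study\ns1,blank\n")
        with pytest.raises(PeakListError, match="duplicate"):
            read_peak_lists(tmp_path / "p.csv", tmp_path / "m.csv")


class TestNoiseFilter:
    @pytest.mark.parametrize("abundance,kept", [(150.0, False), (200.0, True), (250.0, True)])
    def test_strictly_below_threshold_is_noise(self, abundance, kept):
        out = noise_filter(pl("s", [(100.0, 1.0, abundance)]))
        assert (len(out) == 1) is kept

    def test_empty_list_passes_through(self):
        assert len(noise_filter(pl("s", []))) == 0


class TestAlignment:
    def test_peaks_within_both_tolerances_form_one_feature(self):
        # 14.8 ppm apart in mass, 0.10 min apart in RT: both inside 15 ppm / 0.15 min
        t = align_features([
            pl("s1", [(500.0000, 10.00, 1000.0)]),
            pl("s2", [(500.0074, 10.10, 900.0)]),
        ])
        assert t.n_features == 1
        assert t.abundance.notna().sum().sum() == 2

    def test_mass_gap_beyond_ppm_tolerance_splits(self):
        # 16 ppm apart at equal RT
        t = align_features([
            pl("s1", [(500.0000, 10.00, 1000.0)]),
            pl("s2", [(500.0080, 10.00, 900.0)]),
        ])
        assert t.n_features == 2

    def test_rt_gap_beyond_tolerance_splits(self):
        t = align_features([
            pl("s1", [(500.0, 10.00, 1000.0)]),
            pl("s2", [(500.0, 10.20, 900.0)]),
        ])
        assert t.n_features == 2

    def test_one_peak_per_sample_per_feature(self):
        # two same-sample peaks cannot share a feature even when coincident
        t = align_features([pl("s1", [(500.0, 10.0, 1000.0), (500.0, 10.0, 900.0)])])
        assert t.n_features == 2

    def test_consensus_is_abundance_weighted(self):
        t = align_features([
            pl("s1", [(500.0000, 10.0, 3000.0)]),
            pl("s2", [(500.0040, 10.0, 1000.0)]),
        ])
        assert t.features["mz"].iloc[0] == pytest.approx(500.0010, abs=1e-6)

    def test_sample_order_does_not_change_memberships(self, rng):
        lists = []
        seeds = [(150.0, 1.0), (150.01, 2.0), (400.0, 3.0), (800.0, 1.5)]
        for s in range(4):
            rows = [
                (mz * (1 + rng.uniform(-5e-6, 5e-6)), rt + rng.uniform(-0.05, 0.05),
                 float(rng.uniform(500, 5000)))
                for mz, rt in seeds
            ]
            lists.append(pl(f"s{s}", rows))
        t1 = align_features(lists)
        t2 = align_features(lists[::-1])
        pd.testing.assert_frame_equal(t1.abundance, t2.abundance)

    def test_recovers_planted_seed_count_with_half_tolerance_jitter(self, rng):
        k, n_samples = 40, 6
        # generous mass separation so the only valid grouping is by seed
        mzs = np.linspace(100, 1000, k)
        rts = rng.uniform(1, 30, k)
        lists = []
        for s in range(n_samples):
            rows = [
                (mz * (1 + rng.uniform(-7.5e-6, 7.5e-6)),
                 rt + rng.uniform(-0.075, 0.075), float(rng.uniform(300, 3000)))
                for mz, rt in zip(mzs, rts)
            ]
            lists.append(pl(f"s{s}", rows))
        t = align_features(lists)
        assert t.n_features == k

    def test_tolerances_must_be_positive(self):
        with pytest.raises(ValueError):
            align_features([pl("s1", [(100.0, 1.0, 10.0)])], ppm_tol=0)


class TestAdductGroups:
    def _table(self, mzs, rts):
        lists = [pl("s1", [(mz, rt, 1000.0) for mz, rt in zip(mzs, rts)])]
        return align_features(lists)

    def test_sodium_for_proton_difference_groups(self):
        t = self._table([501.00728, 522.98922], [5.0, 5.0])
        out = annotate_adduct_groups(t, "positive")
        assert out.features["adduct_group"].nunique() == 1

    def test_water_loss_groups(self):
        t = self._table([501.00728, 482.99671], [5.0, 5.0])
        out = annotate_adduct_groups(t, "positive")
        assert out.features["adduct_group"].nunique() == 1

    def test_different_rt_does_not_group(self):
        t = self._table([501.00728, 522.98922], [5.0, 9.0])
        out = annotate_adduct_groups(t, "positive")
        assert out.features["adduct_group"].nunique() == 2

    def test_grouping_is_transitive(self):
        # A(M+H) ~ B(M+Na) and B ~ C(M+K): all three in one group
        m = 500.0
        offs = ADDUCT_OFFSETS["positive"]
        t = self._table([m + offs["[M+H]+"], m + offs["[M+Na]+"], m + offs["[M+K]+"]],
                        [5.0, 5.0, 5.0])
        out = annotate_adduct_groups(t, "positive")
        assert out.features["adduct_group"].nunique() == 1

    def test_single_feature_is_singleton_group(self):
        out = annotate_adduct_groups(self._table([400.0], [2.0]), "negative")
        assert out.features["adduct_group"].tolist() == [1]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            annotate_adduct_groups(self._table([400.0], [2.0]), "both")


def test_feature_table_round_trip_preserves_missing_cells(tmp_path):
    t = align_features([
        pl("s1", [(500.0, 10.0, 1000.0), (600.0, 12.0, 800.0)]),
        pl("s2", [(500.0, 10.0, 1100.0)]),
    ])
    write_feature_table(t, tmp_path / "ft.csv")
    text = (tmp_path / "ft.csv").read_text()
    assert ",," in text or text.rstrip().endswith(",")  # missing cell stays empty
    back = read_feature_table(tmp_path / "ft.csv")
    assert back.n_features == 2
    assert back.abundance.isna().sum().sum() == 1
    np.testing.assert_allclose(
        back.abundance.to_numpy(float), t.abundance.to_numpy(float)
    )
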