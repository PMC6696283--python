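"""Feature extraction, trend classification, suspect matching, intensity
classes and occurrence tables."""

import numpy as np
import pytest

from tpscreen.chemcore import AdductIon, Formula, adduct_mz
from tpscreen.screening import (
    Feature,
    ScanSeries,
    SpeciesDef,
    classify_features,
    classify_trend,
    extract_features,
    format_occurrence,
    intensity_class,
    match_suspects,
    occurrence_table,
    read_peaks_csv,
    write_peaks_csv,
)
from tpscreen.synthdata import (
    HYDROLYSIS_SPECIES,
    KineticSpec,
    MON_A,
    MON_B,
    NoiseModel,
    SpeciesSpec,
    default_ec_species,
    generate_hydrolysis_series,
    generate_voltammogram,
)
from tpscreen.tpmapper import suspect_list


def make_series(traces, mzs, axis=None):
    """Build a ScanSeries from per-species intensity traces at fixed m/z."""
    axis = np.arange(len(next(iter(traces)))) if axis is None \
        else np.asarray(axis, float)
    peaks = []
    for i in range(len(axis)):
        peaks.append((np.asarray(mzs, float),
                      np.asarray([t[i] for t in traces], float)))
    return ScanSeries("potential", axis, peaks)


class TestExtractFeatures:
    def test_single_constant_peak_single_feature(self):
        series = make_series([[100.0] * 10], [500.0])
        feats = extract_features(series, min_scans=5)
        assert len(feats) == 1
        assert feats[0].mz == pytest.approx(500.0)
        assert np.all(feats[0].trace == 100.0)

    def test_na_nh4_pair_never_merged(self):
        """4.9554 Da is three orders of magnitude above a 10 ppm window
        near m/z 690."""
        series = make_series([[100.0] * 10, [300.0] * 10],
                             [688.4630, 693.4184])
        feats = extract_features(series, mz_tol=10.0, min_scans=5)
        assert len(feats) == 2

    def test_min_scans_filter(self):
        series = make_series([[100.0] * 10], [500.0])
        # a one-scan interloper peak far from the persistent feature
        mzs, intens = series.peaks[3]
        series.peaks[3] = (np.append(mzs, 800.0), np.append(intens, 50.0))
        feats = extract_features(series, min_scans=5)
        assert [round(f.mz) for f in feats] == [500]

    def test_synthetic_run_feature_count_is_species_times_adducts(self):
        series, manifest = generate_voltammogram(seed=1)
        feats = extract_features(series)
        assert len(feats) == 2 * len(manifest["species"])

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            ScanSeries("potential", np.array([]), [])


class TestClassifyTrend:
    def test_strictly_increasing_is_product(self):
        f = Feature(500.0, np.arange(10.0))
        assert classify_trend(f, np.arange(10)) == "product"
        assert f.trend_statistic == pytest.approx(1.0)

    def test_strictly_decreasing_is_precursor(self):
        f = Feature(500.0, np.arange(10.0)[::-1].copy())
        assert classify_trend(f, np.arange(10)) == "precursor"
        assert f.trend_statistic == pytest.approx(-1.0)

    def test_constant_trace_is_flat_zero(self):
        f = Feature(500.0, np.full(10, 7.0))
        assert classify_trend(f, np.arange(10)) == "flat"
        assert f.trend_statistic == 0.0

    def test_too_few_scans_rejected(self):
        with pytest.raises(ValueError):
            classify_trend(Feature(500.0, np.ones(3)), np.arange(3))

    def test_noisy_sigmoid_rise_is_product(self):
        """A sigmoid-rise trace with 5% multiplicative noise classifies as
        product in at least 95 of 100 replicates."""
        rng = np.random.default_rng(7)
        axis = np.linspace(0, 2.5, 51)
        clean = 1e5 / (1.0 + np.exp(-(axis - 1.5) / 0.15))
        hits = 0
        for _ in range(100):
            trace = clean * rng.lognormal(0.0, 0.05, size=axis.size)
            f = Feature(500.0, trace)
            if classify_trend(f, axis) == "product":
                hits += 1
        assert hits >= 95


class TestIntensityClass:
    @pytest.mark.parametrize("ratio,expected", [
        (0.65, "s"), (0.60, "s"), (0.45, "ms"), (0.30, "ms"),
        (0.15, "w"), (0.10, "w"), (0.05, "vw"), (0.0, "vw"),
    ])
    def test_half_open_bins(self, ratio, expected):
        assert intensity_class(ratio * 1e6, 1e6) == expected

    def test_zero_parent_rejected(self):
        with pytest.raises(ValueError):
            intensity_class(10.0, 0.0)


class TestMatchSuspects:
    def test_dehydration_product_matched(self, mon_a):
        suspects = suspect_list([mon_a], max_steps=1, adducts=("+Na",))
        f = Feature(675.4079, np.arange(10.0))
        classify_trend(f, np.arange(10))
        records, unknowns = match_suspects([f], suspects)
        assert len(records) == 1 and not unknowns
        assert str(records[0].formula) == "C36H60O10"
        assert records[0].path_label == "DEHYDRATION"

    def test_empty_feature_list(self, mon_a):
        suspects = suspect_list([mon_a], max_steps=1)
        assert match_suspects([], suspects) == ([], [])

    def test_unmatched_product_is_unknown(self, mon_a):
        suspects = suspect_list([mon_a], max_steps=1, adducts=("+Na",))
        f = Feature(444.4444, np.arange(10.0))
        classify_trend(f, np.arange(10))
        records, unknowns = match_suspects([f], suspects)
        assert not records and unknowns == [f]

    def test_full_synthetic_run_recovers_all_seeded_formulas(self):
        series, manifest = generate_voltammogram(seed=1)
        feats = extract_features(series)
        classify_features(series, feats)
        suspects = suspect_list([MON_A, MON_B])
        records, unknowns = match_suspects(feats, suspects)
        seeded_products = {s["formula"] for s in manifest["species"]
                           if s["curve"] == "rise"}
        assert {str(r.formula) for r in records} == seeded_products
        assert not unknowns
        assert all(r.paired_adducts for r in records)


class TestOccurrenceTable:
    def test_parent_present_everywhere(self):
        series_by_ph, _ = generate_hydrolysis_series(seed=3)
        table = occurrence_table(series_by_ph, list(HYDROLYSIS_SPECIES))
        for ph in (3.0, 4.0, 5.0):
            assert table.loc[(ph, "MON")].all()

    def test_threshold_above_max_gives_all_absent_tps(self):
        series_by_ph, _ = generate_hydrolysis_series(seed=3)
        table = occurrence_table(series_by_ph, list(HYDROLYSIS_SPECIES),
                                 detect_threshold=1e9)
        tps = table.loc[~table.index.get_level_values("species")
                        .isin(["MON"])]
        assert not tps.any().any()

    def test_appearance_order_and_ph_monotonicity(self):
        """Diastereomer before ring-opened before dehydrated; first days
        never decrease as pH rises (acid catalysis)."""
        series_by_ph, _ = generate_hydrolysis_series(seed=3)
        table = occurrence_table(series_by_ph, list(HYDROLYSIS_SPECIES))

        def first_day(ph, name):
            import pandas as pd
            row = table.loc[(ph, name)]
            days = [d for d in row.index
                    if not pd.isna(row[d]) and bool(row[d])]
            return min(days) if days else np.inf

        for ph in (3.0, 4.0, 5.0):
            assert first_day(ph, "TP10") <= first_day(ph, "TP11")
            assert first_day(ph, "TP11") < first_day(ph, "TP12")
        for name in ("TP10", "TP11", "TP12"):
            days = [first_day(ph, name) for ph in (3.0, 4.0, 5.0)]
            assert days == sorted(days)

    def test_presence_is_monotone_in_time(self):
        """With monotone kinetics a species never disappears again."""
        series_by_ph, _ = generate_hydrolysis_series(seed=3)
        table = occurrence_table(series_by_ph, list(HYDROLYSIS_SPECIES))
        import pandas as pd
        for _, row in table.iterrows():
            seen = False
            for day in row.index:
                if not pd.isna(row[day]) and bool(row[day]):
                    seen = True
                else:
                    assert not seen

    def test_format_marks(self):
        series_by_ph, _ = generate_hydrolysis_series(seed=3)
        table = occurrence_table(series_by_ph, list(HYDROLYSIS_SPECIES))
        marks = format_occurrence(table)
        assert set(np.unique(marks.values)) <= {"x", "", "n.m."}


class TestPeaksCsvRoundTrip:
    def test_voltammogram_round_trip(self, tmp_path):
        series, _ = generate_voltammogram(seed=5)
        path = tmp_path / "peaks.csv"
        write_peaks_csv(series, path)
        back = read_peaks_csv(path)
        assert back.axis_kind == "potential"
        assert np.allclose(back.axis, series.axis)
        assert back.n_scans == series.n_scans
        for a, b in zip(series.peaks, back.peaks):
            assert np.allclose(a[0], b[0], atol=1e-5)

    def test_hydrolysis_round_trip_keeps_rt_and_ph(self, tmp_path):
        series_by_ph, _ = generate_hydrolysis_series(seed=5)
        path = tmp_path / "ph3.csv"
        write_peaks_csv(series_by_ph[3.0], path)
        back = read_peaks_csv(path)
        assert back.ph == 3.0
        assert back.has_rt

    def test_deterministic_output(self, tmp_path):
        """Identical seed and config produce byte-identical CSV files."""
        for i in (1, 2):
            series, _ = generate_voltammogram(seed=11)
            write_peaks_csv(series, tmp_path / f"run{i}.csv")
        assert (tmp_path / "run1.csv").read_bytes() == \
            (tmp_path / "run2.csv").read_bytes()

    def test_false_positive_control_parent_only(self):
        """A parent-only run yields no product-classified feature."""
        species = [SpeciesSpec("MON A", MON_A, "decay", 1.2, 0.25, 1e6)]
        series, _ = generate_voltammogram(species=species, seed=13)
        feats = extract_features(series)
        classify_features(series, feats)
        assert all(f.trend_class != "product" for f in feats)
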