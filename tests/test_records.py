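import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pollenscale.errors import FormatError
from pollenscale.records import (
    PollenRecord,
    filter_records,
    infer_region,
    load_records,
    sqrt_transform,
    to_proportions,
    write_records,
)


def make_record(site_id="s1", lat=55.0, n=8, ages=None, seed=0):
    rng = np.random.default_rng(seed)
    if ages is None:
        ages = 2000.0 + 600.0 * np.arange(n)
    counts = rng.integers(1, 50, size=(len(ages), 3))
    # taxa in sorted order so the write -> load round trip is order-stable
    return PollenRecord(
        site_id=site_id, lat=lat, lon=12.0, times=np.asarray(ages, float),
        taxa=["Betula", "Pinus", "Poaceae"], counts=counts,
    )


class TestValidation:
    def test_decreasing_ages_rejected(self):
        with pytest.raises(FormatError, match="strictly increasing"):
            make_record(ages=[3000.0, 2000.0, 4000.0])

    def test_zero_total_sample_rejected(self):
        with pytest.raises(FormatError, match="zero total"):
            PollenRecord(
                site_id="z", lat=50, lon=0, times=np.array([1.0, 2.0]),
                taxa=["a"], counts=np.array([[5], [0]]),
            )

    @pytest.mark.parametrize(
        "lon,region",
        [(-100.0, "N_America"), (10.0, "W_Eurasia"), (59.9, "W_Eurasia"),
         (60.0, "E_Eurasia"), (120.0, "E_Eurasia")],
    )
    def test_region_from_longitude(self, lon, region):
        assert infer_region(lon) == region


class TestIO:
    def test_round_trip(self, tmp_path):
        recs = [make_record("a", seed=1), make_record("b", seed=2)]
        write_records(recs, tmp_path / "c.csv", tmp_path / "m.csv")
        back = load_records(tmp_path / "c.csv", tmp_path / "m.csv")
        assert len(back) == 2
        for orig, rt in zip(recs, back):
            assert orig.equals(rt)

    def test_missing_column_named(self, tmp_path):
        pd.DataFrame({"site_id": ["a"], "age_bp": [100], "taxon": ["Pinus"]}) \
            .to_csv(tmp_path / "c.csv", index=False)
        pd.DataFrame({"site_id": ["a"], "lat": [50], "lon": [0]}) \
            .to_csv(tmp_path / "m.csv", index=False)
        with pytest.raises(FormatError, match="count"):
            load_records(tmp_path / "c.csv", tmp_path / "m.csv")

    def test_site_missing_from_meta_listed(self, tmp_path):
        pd.DataFrame({"site_id": ["a", "b"], "age_bp": [100, 100],
                      "taxon": ["Pinus", "Pinus"], "count": [5, 5]}) \
            .to_csv(tmp_path / "c.csv", index=False)
        pd.DataFrame({"site_id": ["a"], "lat": [50], "lon": [0]}) \
            .to_csv(tmp_path / "m.csv", index=False)
        with pytest.raises(FormatError, match="b"):
            load_records(tmp_path / "c.csv", tmp_path / "m.csv")

    def test_duplicate_rows_summed_and_taxon_map_merges(self, tmp_path):
        pd.DataFrame({
            "site_id": ["a"] * 3,
            "age_bp": [100.0] * 3,
            "taxon": ["Picea_sp", "Picea", "Picea"],
            "count": [3, 4, 5],
        }).to_csv(tmp_path / "c.csv", index=False)
        pd.DataFrame({"site_id": ["a"], "lat": [50], "lon": [0]}) \
            .to_csv(tmp_path / "m.csv", index=False)
        rec, = load_records(tmp_path / "c.csv", tmp_path / "m.csv",
                            taxon_map={"Picea_sp": "Picea"})
        assert rec.taxa == ["Picea"]
        assert rec.counts.tolist() == [[12]]

    def test_class_columns_attached(self, tmp_path):
        write_records([make_record("a")], tmp_path / "c.csv", tmp_path / "m.csv")
        meta = pd.read_csv(tmp_path / "m.csv")
        meta["olson_class"] = "BorF"
        meta.to_csv(tmp_path / "m.csv", index=False)
        rec, = load_records(tmp_path / "c.csv", tmp_path / "m.csv")
        assert rec.class_labels == {"olson_class": "BorF"}


class TestTransforms:
    def test_proportions_direct_division(self):
        rec = PollenRecord("p", 50, 0, np.array([1.0]), ["a", "b"],
                           np.array([[3, 1]]))
        props = to_proportions(rec)
        assert np.allclose(props.values, [[0.75, 0.25]])

    def test_single_taxon_gives_ones(self):
        rec = PollenRecord("p", 50, 0, np.array([1.0, 2.0]), ["a"],
                           np.array([[7], [3]]))
        assert np.allclose(to_proportions(rec).values, 1.0)

    def test_sqrt_values_and_closure(self):
        rec = PollenRecord("p", 50, 0, np.array([1.0]), ["a", "b"],
                           np.array([[1, 3]]))
        sq = sqrt_transform(to_proportions(rec))
        assert np.allclose(sq.values, [[0.5, np.sqrt(0.75)]])
        assert np.allclose((sq.values**2).sum(axis=1), 1.0, atol=1e-12)

    def test_double_sqrt_rejected(self):
        rec = make_record()
        sq = sqrt_transform(to_proportions(rec))
        with pytest.raises(FormatError):
            sqrt_transform(sq)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_rows_sum_to_one_and_zeros_preserved(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 40, size=(6, 5))
        counts[:, 0] += 1  # keep row totals positive
        rec = PollenRecord("h", 50, 0, np.arange(6, dtype=float),
                           [f"t{i}" for i in range(5)], counts)
        props = to_proportions(rec)
        assert np.allclose(props.values.sum(axis=1), 1.0, atol=1e-12)
        sq = sqrt_transform(props)
        assert np.allclose((sq.values**2).sum(axis=1), 1.0, atol=1e-12)
        assert np.array_equal(sq.values == 0, counts == 0)


class TestFiltering:
    def _engineered(self):
        recs = []
        # 3 fail latitude only
        for i in range(3):
            recs.append(make_record(f"lat{i}", lat=20.0, n=8, seed=i))
        # 3 fail the in-window sample minimum only (5 in-window samples)
        for i in range(3):
            ages = np.concatenate([[500.0], 2100.0 + 500.0 * np.arange(5)])
            recs.append(make_record(f"few{i}", ages=ages, seed=10 + i))
        # 4 pass both
        for i in range(4):
            recs.append(make_record(f"ok{i}", n=8, seed=20 + i))
        return recs

    def test_rule_counts_and_survivors(self):
        kept, report = filter_records(self._engineered())
        assert report.n_input == 10
        assert report.n_fail_lat == 3
        assert report.n_fail_min_samples == 3
        assert report.n_kept == 4
        assert all(r.lat > 25 for r in kept)
        assert all(r.n_samples >= 6 for r in kept)

    def test_out_of_window_samples_dropped_first(self):
        ages = np.concatenate([[100.0, 9000.0], 2100.0 + 500.0 * np.arange(6)])
        rec = make_record("w", ages=np.sort(ages))
        kept, _ = filter_records([rec])
        assert len(kept) == 1
        assert kept[0].times.min() >= 2000 and kept[0].times.max() <= 8000
        assert kept[0].n_samples == 6

    def test_idempotent(self):
        kept, _ = filter_records(self._engineered())
        again, report = filter_records(kept)
        assert report.n_kept == len(kept)
        for a, b in zip(kept, again):
            assert a.equals(b)
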