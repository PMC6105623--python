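"""Track data model, CSV round-trips, recentering and volume splitting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import lymphtrack as lt

from conftest import make_track


def tracksets_equal(a: lt.TrackSet, b: lt.TrackSet) -> bool:
    if len(a) != len(b):
        return False
    for ta, tb in zip(a, b):
        if ta.track_id != tb.track_id:
            return False
        if not (np.array_equal(ta.t, tb.t) and np.array_equal(ta.xyz, tb.xyz)):
            return False
    return True


class TestTrackValidation:
    def test_rejects_non_increasing_timestamps(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            lt.Track("t", [0.0, 30.0, 30.0], np.zeros((3, 3)), 30.0)

    def test_rejects_gaps_not_multiple_of_dt(self):
        with pytest.raises(ValueError, match="integer multiples"):
            lt.Track("t", [0.0, 45.0], np.zeros((2, 3)), 30.0)

    def test_gap_is_retained_not_interpolated(self):
        tr = make_track("t", np.zeros((3, 3)), frames=[0, 1, 3])
        assert tr.has_gaps
        disp, start = tr.step_vectors()
        assert len(disp) == 1 and start.tolist() == [0]

    def test_duplicate_track_ids_rejected(self):
        tr = make_track("x", np.zeros((2, 3)))
        with pytest.raises(ValueError, match="duplicate"):
            lt.TrackSet((tr, tr))


class TestReadWrite:
    def test_two_track_roundtrip(self, tmp_path):
        ts = lt.TrackSet((
            make_track("a", [[0, 0, 0], [1, 2, 3]]),
            make_track("b", [[5, 5, 5], [6, 6, 6], [7, 7, 7]]),
        ))
        path = tmp_path / "t.csv"
        lt.write_tracks(ts, path)
        assert tracksets_equal(lt.read_tracks(path), ts)

    def test_empty_set_writes_header_only(self, tmp_path):
        path = tmp_path / "t.csv"
        lt.write_tracks(lt.TrackSet(()), path)
        assert path.read_text().strip() == "track_id,t_s,x_um,y_um,z_um"

    def test_duplicate_time_row_error_names_row(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "track_id,t_s,x_um,y_um,z_um\n1,0,0,0,0\n1,0,1,1,1\n")
        with pytest.raises(ValueError, match=r"track_id='1' t=0"):
            lt.read_tracks(path)

    def test_non_numeric_field_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("track_id,t_s,x_um,y_um,z_um\n1,0,oops,0,0\n")
        with pytest.raises(ValueError):
            lt.read_tracks(path)

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            lt.read_tracks(tmp_path / "x.csv", dialect="nope")

    def test_imaris_twin_fixture_matches_plain(self, tmp_path):
        """The same content in both dialects parses to the same TrackSet."""
        ts, _ = lt.make_tracks(lt.TPMScenario(
            model=lt.BrownianModel(5.0), n_cells=10, frames=10, seed=3,
            localisation_sd=0.0, dropout_rate=0.0))
        plain, imaris = tmp_path / "plain.csv", tmp_path / "imaris.csv"
        lt.write_tracks(ts, plain)
        lt.write_tracks(ts, imaris, dialect="imaris_position")
        assert tracksets_equal(
            lt.read_tracks(plain), lt.read_tracks(imaris, dialect="imaris_position"))

    @given(st.data())
    def test_roundtrip_property(self, tmp_path_factory, data):
        """read(write(ts)) is the identity for arbitrary valid track sets."""
        n_tracks = data.draw(st.integers(1, 6))
        coords = st.floats(-1e5, 1e5, allow_nan=False, width=64)
        tracks = []
        for i in range(n_tracks):
            n = data.draw(st.integers(1, 8))
            frames = sorted(data.draw(
                st.sets(st.integers(0, 20), min_size=n, max_size=n)))
            xyz = np.array(data.draw(
                st.lists(st.tuples(coords, coords, coords), min_size=n, max_size=n)))
            tracks.append(make_track(f"tr{i}", xyz, frames=frames))
        ts = lt.TrackSet(tuple(tracks))
        path = tmp_path_factory.mktemp("rt") / "t.csv"
        lt.write_tracks(ts, path)
        assert tracksets_equal(lt.read_tracks(path, nominal_dt=30.0), ts)


class TestRecenter:
    def test_series_start_at_origin_along_one_axis(self):
        tr = make_track("s", [[10.0 + 2 * k, 5.0, 1.0] for k in range(5)])
        (series,) = lt.recenter_tracks(lt.TrackSet((tr,)))
        assert np.array_equal(series[0], [0.0, 0.0])
        assert np.allclose(series[:, 1], 0.0)

    def test_subsamples_exactly_max_tracks(self, rng):
        tracks = tuple(
            make_track(f"t{i}", rng.normal(size=(4, 3))) for i in range(781))
        out = lt.recenter_tracks(lt.TrackSet(tracks), max_tracks=40)
        assert len(out) == 40

    def test_closed_track_returns_to_origin(self):
        tr = make_track("c", [[1, 1, 0], [2, 1, 0], [1, 1, 0.0]][:2] + [[1, 1, 0]])
        (series,) = lt.recenter_tracks(lt.TrackSet((tr,)))
        assert np.array_equal(series[-1], [0.0, 0.0])

    def test_translation_invariance(self, rng):
        tracks = tuple(make_track(f"t{i}", rng.normal(size=(6, 3))) for i in range(10))
        shifted = tuple(
            lt.Track(tr.track_id, tr.t, tr.xyz + [123.0, -45.0, 7.0], tr.nominal_dt)
            for tr in tracks)
        a = lt.recenter_tracks(lt.TrackSet(tracks), 5)
        b = lt.recenter_tracks(lt.TrackSet(shifted), 5)
        for sa, sb in zip(a, b):
            assert np.allclose(sa, sb)

    def test_max_tracks_below_one_rejected(self):
        with pytest.raises(ValueError):
            lt.recenter_tracks(lt.TrackSet((make_track("a", np.zeros((2, 3))),)), 0)


class TestSplitAtVolume:
    VOL = lt.ImagingVolume((0.0, 0.0, 0.0), (100.0, 100.0, 100.0))

    def test_inside_track_unchanged(self):
        tr = make_track("in", [[10, 10, 10], [20, 20, 20]])
        out = lt.split_at_volume(lt.TrackSet((tr,)), self.VOL)
        assert len(out) == 1 and out[0].track_id == "in"

    def test_out_and_back_yields_two_fragments(self):
        xyz = [[10, 10, 10], [20, 10, 10], [150, 10, 10], [30, 10, 10], [40, 10, 10]]
        out = lt.split_at_volume(lt.TrackSet((make_track("x", xyz),)), self.VOL)
        assert [tr.track_id for tr in out] == ["x#0", "x#1"]
        assert [len(tr) for tr in out] == [2, 2]

    def test_fragment_count_matches_brute_force_runs(self, rng):
        """Fragment count equals a brute-force count of maximal in-box runs."""
        n_expected = 0
        tracks = []
        for i in range(30):
            xyz = np.cumsum(rng.normal(scale=25.0, size=(40, 3)), axis=0) + 50.0
            tracks.append(make_track(f"w{i}", xyz))
            inside = [bool(np.all((p >= 0) & (p <= 100))) for p in xyz]
            prev = False
            for flag in inside:
                if flag and not prev:
                    n_expected += 1
                prev = flag
        out = lt.split_at_volume(lt.TrackSet(tuple(tracks)), self.VOL)
        assert len(out) == n_expected

    def test_conserves_in_volume_points_and_creates_none_outside(self, rng):
        tracks = tuple(
            make_track(f"w{i}", np.cumsum(rng.normal(scale=30.0, size=(25, 3)), axis=0) + 50.0)
            for i in range(10))
        ts = lt.TrackSet(tracks)
        out = lt.split_at_volume(ts, self.VOL)
        for tr in out:
            assert lt.split_at_volume(lt.TrackSet((tr,)), self.VOL)[0] is not None
            assert self.VOL.contains(tr.xyz).all()
        kept = sorted(map(tuple, np.vstack([tr.xyz for tr in out]))) if len(out) else []
        expect = sorted(
            tuple(p) for tr in ts for p in tr.xyz if self.VOL.contains(p[None, :])[0])
        assert kept == expect
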