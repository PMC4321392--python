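"""Soma status, total/isolated ratio, group comparison, bright exclusion."""

import numpy as np
import pandas as pd
import pytest

from assemblyscope.connectivity import (ConnectivityParams, Soma, SomaAnnotationSet,
                                        auto_exclude_bright, compare_groups,
                                        connectivity_ratio, soma_status)
from assemblyscope.synth import generate_soma_scene, render_soma_phase_image


def somaset(positions, radius=5.0, links=(), excluded=()):
    somas = [Soma(id=i, row=r, col=c, radius=radius, excluded=i in excluded)
             for i, (r, c) in enumerate(positions)]
    return SomaAnnotationSet(somas=somas, dendrite_links=list(links))


class TestSomaStatus:
    def test_halo_proximity_connects(self):
        # boundary gap 5 px < 10 px threshold
        ann = somaset([(100, 100), (100, 115)], radius=5)
        assert set(soma_status(ann).values()) == {"connected"}

    def test_distant_unlinked_soma_is_isolated(self):
        ann = somaset([(100, 100), (100, 160)], radius=5)   # gap 50 px
        assert set(soma_status(ann).values()) == {"isolated"}

    def test_dendrite_link_connects_across_distance(self):
        ann = somaset([(100, 100), (100, 300)], radius=5, links=[(0, 1)])
        assert set(soma_status(ann).values()) == {"connected"}

    def test_distance_is_boundary_referenced(self):
        # centroid distance 25 px but radii 10+10 leave a 5-px boundary gap
        ann = somaset([(50, 50), (50, 75)], radius=10)
        assert set(soma_status(ann).values()) == {"connected"}

    def test_excluded_somas_ignored(self):
        ann = somaset([(100, 100), (100, 112)], radius=5, excluded={1})
        status = soma_status(ann)
        assert status == {0: "isolated"}

    def test_link_to_excluded_soma_ignored_with_warning(self):
        ann = somaset([(100, 100), (100, 300)], radius=5, links=[(0, 1)], excluded={1})
        with pytest.warns(UserWarning, match="excluded"):
            status = soma_status(ann)
        assert status[0] == "isolated"

    def test_adding_link_never_increases_isolation(self):
        ann, _ = generate_soma_scene(20, 5, seed=2)
        before = connectivity_ratio(soma_status(ann)).n_isolated
        iso = [sid for sid, st in soma_status(ann).items() if st == "isolated"]
        ann.dendrite_links.append((iso[0], iso[1]))
        after = connectivity_ratio(soma_status(ann)).n_isolated
        assert after <= before

    @pytest.mark.parametrize("seed", range(8))
    def test_ground_truth_isolated_set_recovered(self, seed):
        ann, truth = generate_soma_scene(40, 15, seed=seed)
        status = soma_status(ann)
        assert {sid for sid, st in status.items() if st == "isolated"} == truth.isolated_ids


class TestConnectivityRatio:
    def test_forty_total_ten_isolated_gives_four(self):
        ann, _ = generate_soma_scene(40, 15, seed=1)
        res = connectivity_ratio(soma_status(ann))
        assert (res.n_total, res.n_isolated, res.ratio) == (40, 10, 4.0)

    def test_all_isolated_gives_unity(self):
        ann, _ = generate_soma_scene(12, 0, min_sep_px=20, seed=3)
        res = connectivity_ratio(soma_status(ann))
        assert res.n_isolated == 12 and res.ratio == 1.0

    def test_fully_connected_field_flagged_undefined(self):
        ann, _ = generate_soma_scene(4, 2, seed=4)
        res = connectivity_ratio(soma_status(ann))
        assert res.n_isolated == 0 and res.ratio is None

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            connectivity_ratio({})

    def test_ratio_at_least_one_when_defined(self):
        for seed in range(5):
            ann, _ = generate_soma_scene(30, 10, seed=seed)
            res = connectivity_ratio(soma_status(ann))
            if res.ratio is not None:
                assert res.ratio >= 1.0


class TestAutoExcludeBright:
    def test_dead_cells_excluded_from_phase_image(self):
        ann, truth = generate_soma_scene(20, 5, seed=6, n_dead=3)
        img = render_soma_phase_image(ann, truth)
        out = auto_exclude_bright(img, ann)
        assert {s.id for s in out.somas if s.excluded} == truth.dead_ids

    def test_moderate_intensities_leave_set_unchanged(self):
        ann, truth = generate_soma_scene(10, 2, seed=7)
        img = render_soma_phase_image(ann, truth)      # no dead cells, max 0.5
        out = auto_exclude_bright(img, ann)
        assert not any(s.excluded for s in out.somas)

    def test_floor_of_one_excludes_only_exact_maximum(self):
        ann = somaset([(2, 2), (6, 6)])
        img = np.zeros((10, 10))
        img[2, 2] = 1.0
        img[6, 6] = 0.999
        out = auto_exclude_bright(img, ann, ConnectivityParams(bright_floor=1.0))
        assert [s.excluded for s in out.somas] == [True, False]


class TestCompareGroups:
    @staticmethod
    def table(control, treated, tp=24.0):
        rows = [("control", tp, v) for v in control] + [("treated", tp, v) for v in treated]
        return pd.DataFrame(rows, columns=["group", "time_point_h", "ratio"])

    def test_percent_change_arithmetic(self):
        out = compare_groups(self.table([4.0, 4.0], [2.68, 2.68]))
        assert out.percent_change[0] == pytest.approx(33.0, abs=0.5)

    def test_identical_groups_null_result(self):
        out = compare_groups(self.table([3.0, 4.0, 5.0], [3.0, 4.0, 5.0]))
        assert out.percent_change[0] == pytest.approx(0.0)
        assert out.p_value[0] == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        a = 4.0 + 0.1 * rng.standard_normal(10)
        b = 2.0 + 0.1 * rng.standard_normal(10)
        out = compare_groups(self.table(a, b))
        assert out.p_value[0] < 0.05

    def test_single_replicate_flags_missing_p(self):
        out = compare_groups(self.table([4.0], [2.0]))
        assert out.flag[0] == "insufficient_replicates"
        assert np.isnan(out.p_value[0])

    def test_one_row_per_time_point(self):
        df = pd.concat([self.table([4, 4.2], [3, 3.1], tp=t) for t in (0, 2, 4, 6, 24)])
        out = compare_groups(df)
        assert list(out.time_point_h) == [0, 2, 4, 6, 24]


class TestAnnotationSet:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            SomaAnnotationSet(somas=[Soma(1, 0, 0, 5), Soma(1, 9, 9, 5)])

    def test_link_to_unknown_id_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            SomaAnnotationSet(somas=[Soma(1, 0, 0, 5)], dendrite_links=[(1, 2)])

    def test_csv_roundtrip(self, tmp_path):
        ann, _ = generate_soma_scene(10, 3, seed=9)
        ann.to_frame().to_csv(tmp_path / "somas.csv", index=False)
        pd.DataFrame(ann.dendrite_links, columns=["id_a", "id_b"]).to_csv(
            tmp_path / "links.csv", index=False)
        back = SomaAnnotationSet.from_csv(tmp_path / "somas.csv", tmp_path / "links.csv")
        assert soma_status(back) == soma_status(ann)
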