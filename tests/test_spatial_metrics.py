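import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatimmune import (
    g_curve,
    mh_features,
    morisita_horn,
    quadrat_counts,
    simulate_pair_pattern,
    sps,
    sps_features,
)
from spatimmune.spatial_metrics import default_radii

from conftest import make_cells


# -- quadrat counting -------------------------------------------------------

def brute_force_quadrats(points, window, square):
    nx = max(int(np.ceil(window[0] / square)), 1)
    ny = max(int(np.ceil(window[1] / square)), 1)
    counts = np.zeros((ny, nx), dtype=int)
    for x, y in points:
        ix = min(int(x // square), nx - 1)
        iy = min(int(y // square), ny - 1)
        counts[iy, ix] += 1
    return counts


def test_single_point_lands_in_origin_square():
    counts = quadrat_counts(np.array([[50.0, 50.0]]), (400, 400), 200)
    assert counts[0, 0] == 1
    assert counts.sum() == 1


def test_half_open_boundary_convention():
    # a point at exactly x = 200 belongs to column index 1
    counts = quadrat_counts(np.array([[200.0, 0.0]]), (400, 400), 200)
    assert counts[0, 1] == 1


def test_every_point_counted_once(rng):
    pts = rng.uniform([0, 0], [600, 450], size=(10_000, 2))
    counts = quadrat_counts(pts, (600, 450), 200)
    assert counts.sum() == 10_000


def test_quadrat_matches_brute_force(rng):
    pts = rng.uniform([0, 0], [610, 430], size=(1000, 2))
    fast = quadrat_counts(pts, (610, 430), 200)
    slow = brute_force_quadrats(pts, (610, 430), 200)
    np.testing.assert_array_equal(fast, slow)


def test_point_outside_window_rejected():
    with pytest.raises(ValueError, match="outside"):
        quadrat_counts(np.array([[700.0, 10.0]]), (600, 450), 200)


# -- Morisita-Horn ----------------------------------------------------------

@pytest.mark.parametrize("a,b,expected", [
    ((3, 0, 2), (3, 0, 2), 1.0),   # identical patterns -> fully colocalized
    ((5, 0), (0, 7), 0.0),         # disjoint supports -> fully segregated
    ((2, 1), (1, 2), 0.8),         # hand evaluation of the formula
])
def test_mh_reference_values(a, b, expected):
    assert morisita_horn(a, b) == pytest.approx(expected, abs=1e-12)


def test_mh_errors():
    with pytest.raises(ValueError, match="positive total"):
        morisita_horn([0, 0], [1, 2])
    with pytest.raises(ValueError, match="nonnegative"):
        morisita_horn([-1, 2], [1, 2])
    with pytest.raises(ValueError, match="equal length"):
        morisita_horn([1, 2, 3], [1, 2])


@settings(deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50)),
                min_size=1, max_size=30))
def test_mh_symmetric_and_bounded(pairs):
    a = [p[0] for p in pairs]
    b = [p[1] for p in pairs]
    if sum(a) == 0 or sum(b) == 0:
        return
    mh_ab = morisita_horn(a, b)
    mh_ba = morisita_horn(b, a)
    assert mh_ab == pytest.approx(mh_ba, rel=1e-12)
    assert -1e-12 <= mh_ab <= 1.0 + 1e-12


def test_mh_vegan_cross_check(tmp_path, rng):
    """Independent oracle: R vegan's 'horn' dissimilarity equals 1 - MH."""
    import subprocess

    a = rng.integers(0, 30, size=12)
    b = rng.integers(0, 30, size=12)
    a[0] += 1
    b[1] += 1
    script = tmp_path / "mh.R"
    script.write_text(
        "suppressMessages(library(vegan))\n"
        f"m <- rbind(c({','.join(map(str, a))}), c({','.join(map(str, b))}))\n"
        'cat(sprintf("%.12f", 1 - vegdist(m, method="horn")[1]))\n'
    )
    out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
    assert out.returncode == 0, out.stderr
    assert morisita_horn(a, b) == pytest.approx(float(out.stdout), abs=1e-9)


def test_mh_pooling_single_roi_reduces_to_direct_evaluation(rng):
    recs = []
    for i in range(60):
        recs.append({"patient_id": "PT1", "roi_id": "R1", "panel": "P1",
                     "x_um": float(rng.uniform(0, 600)),
                     "y_um": float(rng.uniform(0, 450)),
                     "phenotype": "Tm" if i < 30 else "T"})
    table = make_cells(recs)
    feats = mh_features(table)
    xy = table.cells[["x_um", "y_um"]].to_numpy()
    tm = table.cells["phenotype"] == "Tm"
    direct = morisita_horn(
        quadrat_counts(xy[tm], (600, 450), 200).ravel(),
        quadrat_counts(xy[~tm], (600, 450), 200).ravel(),
    )
    assert feats.loc["PT1", "Tm_T"] == pytest.approx(direct, abs=1e-12)


def test_mh_minimum_cell_rule():
    recs = [{"patient_id": "PT1", "roi_id": "R1", "panel": "P1",
             "x_um": 10.0 * i, "y_um": 10.0, "phenotype": "Tm"} for i in range(20)]
    recs += [{"patient_id": "PT1", "roi_id": "R1", "panel": "P1",
              "x_um": 5.0, "y_um": 5.0, "phenotype": "T"}]  # only 1 T cell
    feats = mh_features(make_cells(recs))
    assert np.isnan(feats.loc["PT1", "Tm_T"])


# -- G(r) and SPS -----------------------------------------------------------

def brute_force_g(a_points, b_points, radii):
    d = np.sqrt(((a_points[:, None, :] - b_points[None, :, :]) ** 2).sum(-1))
    nn = d.min(axis=1)
    return np.array([(nn <= r).mean() for r in radii])


def test_g_coincident_points_is_one():
    pts = np.array([[1.0, 1.0], [5.0, 5.0]])
    curve = g_curve(pts, pts)
    assert np.all(curve.g == 1.0)


def test_g_two_cell_hand_geometry():
    a = np.array([[0.0, 0.0], [100.0, 0.0]])
    b = np.array([[10.0, 0.0], [130.0, 0.0]])  # nearest distances 10 and 30
    curve = g_curve(a, b)
    assert np.all(curve.g[curve.radii < 10] == 0.0)
    assert np.all(curve.g[(curve.radii >= 10)] == 0.5)


def test_g_no_b_cells_is_zero():
    curve = g_curve(np.array([[1.0, 1.0]]), np.empty((0, 2)))
    assert np.all(curve.g == 0.0)
    with pytest.raises(ValueError, match="no a-cells"):
        g_curve(np.empty((0, 2)), np.array([[1.0, 1.0]]))


def test_g_matches_brute_force_oracle(rng):
    a = rng.uniform(0, 300, size=(500, 2))
    b = rng.uniform(0, 300, size=(500, 2))
    radii = default_radii()
    curve = g_curve(a, b, radii)
    np.testing.assert_allclose(curve.g, brute_force_g(a, b, radii), atol=0)


def test_g_monotone_nondecreasing(rng):
    a = rng.uniform(0, 200, size=(80, 2))
    b = rng.uniform(0, 200, size=(40, 2))
    curve = g_curve(a, b)
    assert np.all(np.diff(curve.g) >= 0)


def test_sps_two_cell_example_is_quarter():
    # step function: 0 below 10 um, 0.5 from 10 to 20 um -> AUC 5 um / 20 um
    a = np.array([[0.0, 0.0], [100.0, 0.0]])
    b = np.array([[10.0, 0.0], [130.0, 0.0]])
    score = sps([g_curve(a, b)])
    assert score == pytest.approx(0.25, abs=1e-2)


def test_sps_maximal_and_empty_cases():
    pts = np.array([[1.0, 1.0]])
    assert sps([g_curve(pts, pts), g_curve(pts, pts)]) == 1.0
    assert sps([g_curve(pts, np.empty((0, 2)))]) == 0.0
    with pytest.raises(ValueError, match="no defined"):
        sps([])


def test_sps_increases_when_distances_shrink(rng):
    a = rng.uniform(0, 300, size=(50, 2))
    b = a + rng.normal(scale=8.0, size=a.shape)
    far = sps([g_curve(a, a + (b - a) * 2)])
    near = sps([g_curve(a, b)])
    assert near > far


def test_sps_features_directionality(rng):
    # 1 Tm surrounded by many T within 20um: Tm_T.SPS high, T_Tm.SPS mixed
    recs = [{"patient_id": "PT1", "roi_id": "R1", "panel": "P1",
             "x_um": 100.0, "y_um": 100.0, "phenotype": "Tm"}]
    for i in range(10):
        recs.append({"patient_id": "PT1", "roi_id": "R1", "panel": "P1",
                     "x_um": 100.0 + 5.0 * np.cos(i), "y_um": 100.0 + 5.0 * np.sin(i),
                     "phenotype": "T"})
    recs += [{"patient_id": "PT1", "roi_id": "R1", "panel": "P1",
              "x_um": 400.0 + i, "y_um": 400.0, "phenotype": "T"} for i in range(5)]
    feats = sps_features(make_cells(recs))
    assert feats.loc["PT1", "Tm_T.SPS"] > 0.7
    assert feats.loc["PT1", "T_Tm.SPS"] < feats.loc["PT1", "Tm_T.SPS"]


# -- simulation-backed ground truth ----------------------------------------

def test_segregated_halves_give_zero_mh_when_grid_aligns():
    # 800-wide window: halves split at 400, aligned with 200 um squares
    a, b = simulate_pair_pattern(200, 200, (800, 400), "segregated", seed=5)
    mh = morisita_horn(
        quadrat_counts(a, (800, 400), 200).ravel(),
        quadrat_counts(b, (800, 400), 200).ravel(),
    )
    assert mh == 0.0
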