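"""ReHo (Kendall's W) and fALFF maps against first-principles oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nibabel as nib

from restingstop import (
    BandSpec,
    SpectralBands,
    VolumeSeries,
    bandpass,
    falff_map,
    kcc,
    reho_map,
    standardize_map,
)
from conftest import make_series


def brute_force_kcc(matrix):
    """Kendall's W from first principles: explicit per-series ranking,
    explicit rank sums, textbook formula. Assumes no ties."""
    k = len(matrix)
    n = len(matrix[0])
    rank_rows = []
    for row in matrix:
        order = sorted(range(n), key=lambda i: row[i])
        ranks = [0] * n
        for rank_minus_1, idx in enumerate(order):
            ranks[idx] = rank_minus_1 + 1
        rank_rows.append(ranks)
    r_i = [sum(rank_rows[j][i] for j in range(k)) for i in range(n)]
    rbar = k * (n + 1) / 2
    s = sum((ri - rbar) ** 2 for ri in r_i)
    return 12 * s / (k**2 * (n**3 - n))


def test_kcc_hand_example():
    """Three series with rank sums (6, 7, 8, 9) give W = 5/45."""
    m = np.array([[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]], dtype=float)
    assert kcc(m) == pytest.approx(5 / 45, abs=1e-12)


def test_kcc_perfect_concordance():
    base = np.array([0.3, 1.7, 2.2, 5.0, 9.1])
    m = np.tile(base, (27, 1))
    assert kcc(m) == pytest.approx(1.0, abs=1e-12)


def test_kcc_perfect_discordance_two_series():
    m = np.array([[1, 2, 3, 4], [4, 3, 2, 1]], dtype=float)
    assert kcc(m) == pytest.approx(0.0, abs=1e-12)


def test_kcc_rejects_constant_series():
    m = np.array([[1, 2, 3], [5, 5, 5]], dtype=float)
    with pytest.raises(ValueError, match="constant"):
        kcc(m)


def test_kcc_matches_brute_force_on_random_instances(rng):
    for _ in range(200):
        k = int(rng.integers(2, 31))
        n = int(rng.integers(2, 51))
        m = rng.standard_normal((k, n))
        assert kcc(m) == pytest.approx(brute_force_kcc(m), abs=1e-12)


@given(st.integers(0, 2**31 - 1))
@settings(deadline=None, derandomize=True, max_examples=25)
def test_kcc_invariant_under_monotone_transform_of_one_series(seed):
    """W is rank-based: exp() applied to one series changes nothing."""
    r = np.random.default_rng(seed)
    m = r.standard_normal((5, 12))
    m2 = m.copy()
    m2[2] = np.exp(m2[2])
    assert kcc(m2) == pytest.approx(kcc(m), abs=1e-12)


def test_reho_is_one_when_all_voxels_share_a_series(rng):
    base = rng.standard_normal(32)
    data = np.tile(base, (6, 6, 6, 1))
    m = reho_map(make_series(data))
    assert np.allclose(m.values[1:5, 1:5, 1:5], 1.0, atol=1e-12)


def test_reho_near_zero_for_independent_noise(rng):
    data = rng.standard_normal((10, 10, 10, 240))
    m = reho_map(make_series(data))
    assert np.nanmean(m.values) < 0.1


def test_reho_matches_kcc_at_interior_and_truncated_edge(rng):
    data = rng.standard_normal((5, 5, 5, 20))
    m = reho_map(make_series(data))
    interior = data[1:4, 1:4, 1:4].reshape(27, -1)
    assert m.values[2, 2, 2] == pytest.approx(kcc(interior), abs=1e-12)
    corner = data[0:2, 0:2, 0:2].reshape(8, -1)  # corner voxel has K = 8
    assert m.values[0, 0, 0] == pytest.approx(kcc(corner), abs=1e-12)


@pytest.mark.parametrize(
    "neighborhood,picks",
    [
        # 7-rule at the corner: center + the 3 in-grid face neighbors
        (7, [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)]),
        # 19-rule: additionally the 3 in-grid edge neighbors
        (19, [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1),
              (1, 1, 0), (1, 0, 1), (0, 1, 1)]),
        # 26-rule: the full 2x2x2 corner block
        (27, [(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)]),
    ],
)
def test_reho_neighborhood_sizes_at_corner(rng, neighborhood, picks):
    """At a grid corner the usable neighborhood shrinks with the rule."""
    data = rng.standard_normal((4, 4, 4, 10))
    m = reho_map(make_series(data), neighborhood=neighborhood)
    sub = np.stack([data[i] for i in picks], axis=0)
    assert m.values[0, 0, 0] == pytest.approx(kcc(sub), abs=1e-12)


def test_reho_synchrony_region_beats_background(rng):
    """A shared-signal region has clearly higher KCC than iid background."""
    from scipy import stats as sps

    data = rng.standard_normal((10, 10, 10, 96))
    common = rng.standard_normal(96)
    rho = 0.9
    region = np.s_[3:7, 3:7, 3:7]
    data[region] = np.sqrt(rho) * common + np.sqrt(1 - rho) * data[region]
    m = reho_map(make_series(data))
    region_mask = np.zeros((10, 10, 10), dtype=bool)
    region_mask[4:6, 4:6, 4:6] = True  # interior of the region
    bg_mask = np.zeros_like(region_mask)
    bg_mask[1:3, 1:3, 1:3] = True
    t, p = sps.ttest_ind(m.values[region_mask], m.values[bg_mask], alternative="greater")
    assert p < 0.001
    assert np.nanmean(m.values[region_mask]) > 0.5


def test_reho_respects_mask_and_flags_isolated_voxels(rng):
    mask = np.zeros((6, 6, 6), dtype=bool)
    mask[5, 5, 5] = True  # isolated voxel, no in-mask neighbor: K = 1 < 2
    mask[0:2, 0:2, 0:2] = True
    data = rng.standard_normal((6, 6, 6, 12))
    m = reho_map(make_series(data, mask=mask))
    assert np.isnan(m.values[5, 5, 5])
    assert np.isnan(m.values[3, 3, 3])  # outside mask
    assert np.isfinite(m.values[0, 0, 0])


def _sinusoid_series(freqs_amps, n_t=240, tr=2.0):
    t = np.arange(n_t) * tr
    sig = sum(a * np.sin(2 * np.pi * f * t + 0.3) for f, a in freqs_amps)
    return make_series(sig[None, None, None, :], tr_s=tr)


def _falff_oracle(x, tr, bands=SpectralBands()):
    freqs = np.fft.rfftfreq(len(x), d=tr)
    amp = np.abs(np.fft.rfft(x))
    num = amp[(freqs >= bands.num_low_hz) & (freqs < bands.num_high_hz) & (freqs > 0)].sum()
    den = amp[(freqs >= bands.den_low_hz) & (freqs < bands.den_high_hz) & (freqs > 0)].sum()
    return num / den


# frequencies sit exactly on the 240-point / TR 2 s FFT grid (bins 20 and
# 96 of 1/480 Hz) so the fALFF of a pure tone is leakage-free
IN_BAND_HZ = 20 / 480.0  # ~0.042 Hz, inside 0.01-0.08
OUT_BAND_HZ = 96 / 480.0  # 0.20 Hz, outside the numerator band


@pytest.mark.parametrize(
    "freqs_amps,target",
    [
        ([(IN_BAND_HZ, 1.0)], 1.0),
        ([(OUT_BAND_HZ, 1.0)], 0.0),
        ([(IN_BAND_HZ, 1.0), (OUT_BAND_HZ, 1.0)], 0.5),
    ],
)
def test_falff_analytic_sinusoid_cases(freqs_amps, target):
    series = _sinusoid_series(freqs_amps)
    m = falff_map(series)
    oracle = _falff_oracle(series.data[0, 0, 0], series.tr_s)
    assert m.values[0, 0, 0] == pytest.approx(oracle, abs=1e-12)
    assert abs(m.values[0, 0, 0] - target) < 0.02


def test_falff_scale_invariant(rng):
    data = rng.standard_normal((3, 3, 3, 128))
    m1 = falff_map(make_series(data))
    m2 = falff_map(make_series(1000.0 * data))
    assert np.allclose(m1.values, m2.values, atol=1e-12)


def test_falff_values_in_unit_interval(rng):
    m = falff_map(make_series(rng.standard_normal((4, 4, 4, 96))))
    assert np.all((m.values >= 0) & (m.values <= 1))


def test_falff_zero_series_undefined(rng):
    data = rng.standard_normal((3, 3, 3, 64))
    data[0, 0, 0] = 0.0
    m = falff_map(make_series(data))
    assert np.isnan(m.values[0, 0, 0])
    assert np.isfinite(m.values[1, 1, 1])


def test_falff_rejects_denominator_beyond_nyquist(rng):
    series = make_series(rng.standard_normal((2, 2, 2, 64)), tr_s=3.0)
    with pytest.raises(ValueError, match="Nyquist"):
        falff_map(series)


def test_maps_identical_between_array_and_nifti_path(rng, tmp_path):
    """Round-tripping the 4D series through a NIfTI file changes nothing."""
    data = rng.standard_normal((6, 6, 6, 64)).astype(np.float32)
    series = make_series(data)
    f = tmp_path / "bold.nii.gz"
    nib.save(nib.Nifti1Image(data, series.affine), f)
    reloaded = VolumeSeries(
        data=np.asarray(nib.load(f).dataobj),
        mask=series.mask,
        affine=series.affine,
        tr_s=series.tr_s,
    )
    band = BandSpec()
    r1 = reho_map(bandpass(series, band))
    r2 = reho_map(bandpass(reloaded, band))
    assert np.array_equal(r1.values, r2.values, equal_nan=True)
    f1 = falff_map(series)
    f2 = falff_map(reloaded)
    assert np.array_equal(f1.values, f2.values, equal_nan=True)


def test_standardize_constant_map_becomes_one(rng):
    m = falff_map(make_series(rng.standard_normal((3, 3, 3, 64))))
    m.values[:] = 4.2
    out = standardize_map(m)
    assert np.allclose(out.values, 1.0)


def test_standardize_scale_invariant_and_unit_mean(rng):
    m = falff_map(make_series(rng.standard_normal((4, 4, 4, 64))))
    s1 = standardize_map(m)
    m2 = falff_map(make_series(rng.standard_normal((4, 4, 4, 64))))
    m2.values = 2.0 * m.values
    s2 = standardize_map(m2)
    assert np.allclose(s1.values, s2.values, atol=1e-12)
    assert np.nanmean(s1.values[s1.mask]) == pytest.approx(1.0, abs=1e-12)


def test_standardize_rejects_nonpositive_mean(rng):
    m = falff_map(make_series(rng.standard_normal((3, 3, 3, 64))))
    m.values[:] = -1.0
    with pytest.raises(ValueError, match="positive"):
        standardize_map(m)
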