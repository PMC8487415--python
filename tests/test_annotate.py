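"""Annotation chain: PERCIST threshold, sphere statistics, candidate
detection and gradient-edge boundary refinement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from dotapet.annotate import (AnnotateConfig, BackgroundStats, Candidate3D,
                              annotate_study, detect_candidates,
                              gradient_edge_refine, percist_threshold,
                              place_background_spheres)
from dotapet.evaluate import lesion_components_3d, match_lesions, pooled_metrics
from dotapet.phantom import (OrganMask, PhantomSpec, PlacementError,
                             SliceStack, generate_study)


def _stats(mu, sigma):
    return BackgroundStats(((0, 0, 0), (0, 0, 1), (0, 0, 2)), 30.0,
                           mu, sigma, 10)


# --------------------------------------------------------------------------
# threshold formula
# --------------------------------------------------------------------------

@pytest.mark.parametrize("mu, sigma, expected", [
    (10.0, 2.0, 19.0),
    (0.0, 0.0, 0.0),
    (4.0, 1.0, 8.0),
])
def test_percist_threshold_known_values(mu, sigma, expected):
    assert percist_threshold(_stats(mu, sigma)).value == expected


@settings(max_examples=200, deadline=None, derandomize=True)
@given(mu=st.floats(0, 1e6, allow_nan=False),
       sigma=st.floats(0, 1e5, allow_nan=False))
def test_percist_threshold_exact_formula(mu, sigma):
    """value − (1.5μ + 2σ) is exactly zero, not merely close."""
    thr = percist_threshold(_stats(mu, sigma))
    assert thr.value - (1.5 * mu + 2.0 * sigma) == 0.0


# --------------------------------------------------------------------------
# background spheres
# --------------------------------------------------------------------------

def _uniform_liver_study(value=50.0, shape=(12, 48, 48)):
    vox = np.zeros(shape)
    liver = np.zeros(shape, bool)
    rr, cc = np.mgrid[0:shape[1], 0:shape[2]]
    ell = ((rr - shape[1] / 2) / (0.4 * shape[1])) ** 2 \
        + ((cc - shape[2] / 2) / (0.45 * shape[2])) ** 2 <= 1
    liver[:] = ell
    vox[liver] = value
    return SliceStack(vox, 4.0), OrganMask(liver)


def test_uniform_liver_gives_exact_mean_zero_sd():
    stack, liver = _uniform_liver_study(50.0)
    stats = place_background_spheres(stack, liver)
    assert stats.mean_activity == 50.0
    assert stats.sd_activity == 0.0
    assert len(stats.sphere_centers) == 3


def test_sphere_placement_error_in_tiny_liver():
    vox = np.full((3, 10, 10), 5.0)
    liver = np.zeros((3, 10, 10), bool)
    liver[:, 4:6, 4:6] = True            # far too small for three 30 mm spheres
    with pytest.raises(PlacementError):
        place_background_spheres(SliceStack(vox, 4.0), OrganMask(liver))


def test_pooled_sd_recovers_noise_sigma():
    """Pooled sphere SD within 10% of the injected noise SD; cross-checked
    against the all-liver-pixels sample SD of a lesion-free phantom."""
    spec = PhantomSpec(grid_shape=(64, 64), n_slices_range=(20, 24), seed=0)
    for seed in range(10):
        stack, liver, _ = generate_study(spec, abnormal=False, seed=seed)
        stats = place_background_spheres(stack, liver)
        assert abs(stats.sd_activity - spec.noise_sigma) < 0.1 * spec.noise_sigma
        # oracle: interior liver pixels (eroded past the PSF edge ramp)
        interior = ndimage.binary_erosion(liver.mask,
                                          np.ones((1, 5, 5), bool))
        oracle_sd = stack.voxels[interior].std(ddof=1)
        assert abs(stats.sd_activity - oracle_sd) < 0.1 * oracle_sd


def test_spheres_respect_exclusion_map(noiseless_spec):
    stack, liver, lesions = generate_study(noiseless_spec, True, seed=1)
    stats = place_background_spheres(stack, liver, exclusion=lesions)
    # all sampled pixels at pure background level: no lesion contamination
    assert stats.mean_activity < 1.2 * noiseless_spec.background_mean


# --------------------------------------------------------------------------
# candidate detection
# --------------------------------------------------------------------------

def _flood_fill_3d(mask):
    """Brute-force 26-connected labeling oracle."""
    mask = mask.astype(bool)
    labels = np.zeros(mask.shape, int)
    current = 0
    offsets = [(dz, dr, dc) for dz in (-1, 0, 1) for dr in (-1, 0, 1)
               for dc in (-1, 0, 1) if (dz, dr, dc) != (0, 0, 0)]
    for start in map(tuple, np.argwhere(mask)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            z, r, c = stack.pop()
            for dz, dr, dc in offsets:
                p = (z + dz, r + dr, c + dc)
                if all(0 <= p[i] < mask.shape[i] for i in range(3)) \
                        and mask[p] and not labels[p]:
                    labels[p] = current
                    stack.append(p)
    return labels, current


def test_candidates_empty_when_all_below_threshold():
    stack, liver = _uniform_liver_study(50.0)
    thr = percist_threshold(_stats(50.0, 0.0))   # threshold 75 > everything
    assert detect_candidates(stack, liver, thr) == []


def test_candidate_components_match_flood_fill_oracle(rng):
    """Two non-confluent hot spots → two components; touching → one; the
    grouping agrees with a brute-force 26-connected flood fill."""
    for trial in range(20):
        vox = np.full((6, 24, 24), 10.0)
        liver = np.ones(vox.shape, bool)
        hot = rng.random(vox.shape) > 0.9
        vox[hot] = 100.0
        thr = percist_threshold(_stats(10.0, 0.0))  # 15
        comps = detect_candidates(SliceStack(vox, 4.0), OrganMask(liver), thr)
        oracle_labels, n = _flood_fill_3d(hot)
        assert len(comps) == n
        got = {frozenset(map(tuple, c.coords)) for c in comps}
        want = {frozenset(map(tuple, np.argwhere(oracle_labels == k)))
                for k in range(1, n + 1)}
        assert got == want


def test_two_lesions_two_components_merged_one():
    vox = np.full((1, 20, 20), 10.0)
    liver = np.ones(vox.shape, bool)
    vox[0, 2:5, 2:5] = 100.0
    vox[0, 10:13, 10:13] = 100.0
    thr = percist_threshold(_stats(10.0, 0.0))
    assert len(detect_candidates(SliceStack(vox, 4.0), OrganMask(liver), thr)) == 2
    vox[0, 5:10, 5:10] = 100.0           # bridge them
    assert len(detect_candidates(SliceStack(vox, 4.0), OrganMask(liver), thr)) == 1


# --------------------------------------------------------------------------
# gradient edge refinement
# --------------------------------------------------------------------------

def _disk_candidate(radius, center=(24.0, 24.0), inside=50.0, outside=10.0,
                    shape=(48, 48)):
    img = np.full((1,) + shape, outside)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    disk = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2
    img[0][disk] = inside
    coords = np.argwhere(np.broadcast_to(disk, img.shape))
    cand = Candidate3D(1, coords, tuple(coords[0]), inside)
    return SliceStack(img, 4.0), disk, cand


@pytest.mark.parametrize("radius", [3.0, 4.7, 6.2, 7.8, 9.1, 10.4])
@pytest.mark.parametrize("center", [(24.0, 24.0), (23.6, 24.3)])
def test_hard_disk_refined_exactly(radius, center):
    """Step-edge lesion: the maximum gradient sits on the step, so the
    refined mask reproduces the pixel set exactly."""
    stack, disk, cand = _disk_candidate(radius, center)
    mask, warns = gradient_edge_refine(stack, cand, background_level=12.0)
    assert np.array_equal(mask[0], disk)
    assert warns == []


def test_blurred_disk_boundary_matches_1d_profile_oracle():
    """Per-ray boundary radius within 1 px of the argmax-gradient radius of
    the 1D blurred-step profile."""
    radius, sigma_b = 6.0, 1.5
    n = 64
    rr, cc = np.mgrid[0:n, 0:n]
    disk = (rr - 32) ** 2 + (cc - 32) ** 2 <= radius ** 2
    img = ndimage.gaussian_filter(np.where(disk, 50.0, 10.0), sigma_b)
    stack = SliceStack(img[None], 4.0)
    hot = img > 30.0
    coords = np.argwhere(hot[None])
    cand = Candidate3D(1, coords, (0, 32, 32), float(img.max()))
    mask, _ = gradient_edge_refine(stack, cand, background_level=12.0)
    # 1D oracle: blurred step d/dx argmax on a fine grid
    x = np.linspace(0, 20, 20001)
    from scipy.special import erf
    profile = 10.0 + 40.0 * 0.5 * (1 - erf((x - radius) / (np.sqrt(2) * sigma_b)))
    oracle_radius = x[np.argmax(np.abs(np.gradient(profile, x)))]
    got = mask[0]
    # effective mask radius along the two axes from center
    for axis_r in (np.nonzero(got[32, 32:])[0].max(),
                   np.nonzero(got[32:, 32])[0].max()):
        assert abs(axis_r - oracle_radius) <= 1.0


def test_single_pixel_component_returned_with_warning():
    vox = np.full((1, 16, 16), 5.0)
    vox[0, 8, 8] = 50.0
    cand = Candidate3D(1, np.array([[0, 8, 8]]), (0, 8, 8), 50.0)
    mask, warns = gradient_edge_refine(SliceStack(vox, 4.0), cand, 6.0)
    assert mask.sum() == 1 and mask[0, 8, 8]
    assert len(warns) == 1


def test_peak_always_inside_refined_mask(rng):
    """Contract: the peak pixel belongs to the refined mask, random cases."""
    for _ in range(100):
        radius = rng.uniform(2.5, 9.0)
        ctr = (rng.uniform(18, 30), rng.uniform(18, 30))
        stack, disk, cand = _disk_candidate(radius, ctr)
        blurred = ndimage.gaussian_filter(stack.voxels, (0, 1.0, 1.0))
        stack2 = SliceStack(blurred, 4.0)
        mask, _ = gradient_edge_refine(stack2, cand, background_level=12.0)
        assert mask[cand.peak]


# --------------------------------------------------------------------------
# full annotation
# --------------------------------------------------------------------------

def test_noiseless_annotation_recovers_all_lesions(noiseless_spec):
    matches = []
    for seed in range(6):
        stack, liver, lesions = generate_study(noiseless_spec, True, seed)
        result = annotate_study(stack, liver)
        matches.append(match_lesions(
            lesion_components_3d(result.lesion_map.labels),
            lesion_components_3d(lesions.labels)))
    ppv, sens, _ = pooled_metrics(matches)
    assert ppv == 1.0 and sens == 1.0


def test_normal_study_annotates_nothing(noiseless_spec):
    stack, liver, _ = generate_study(noiseless_spec, False, seed=3)
    result = annotate_study(stack, liver)
    assert not result.lesion_map.mask.any()
    assert result.per_lesion_peak == {}


def test_subthreshold_lesion_absent_from_annotation():
    """A lesion below 1.5×background never enters the gold standard."""
    spec = PhantomSpec(grid_shape=(64, 64), n_slices_range=(24, 26),
                       noise_sigma=0.0, lesion_contrast_range=(1.2, 1.3),
                       enforce_detectable=False, seed=0)
    stack, liver, lesions = generate_study(spec, True, seed=2)
    assert lesions.mask.any()
    result = annotate_study(stack, liver)
    assert not result.lesion_map.mask.any()


def test_annotation_monotone_under_contrast():
    """Raising a lesion's uptake never removes it from the annotation."""
    base = np.full((8, 48, 48), 100.0)
    liver = np.ones(base.shape, bool)
    rr, cc = np.mgrid[0:48, 0:48]
    disk = (rr - 24) ** 2 + (cc - 24) ** 2 <= 3.0 ** 2
    counts = []
    for contrast in (2.0, 2.5, 3.5, 5.0):
        vox = base.copy()
        vox[2:6, disk] = contrast * 100.0
        vox = ndimage.gaussian_filter(vox, (0.6, 0.6, 0.6))
        result = annotate_study(SliceStack(vox, 4.0), OrganMask(liver))
        counts.append(len(result.per_lesion_peak))
    assert counts[0] >= 1
    assert all(c == counts[0] for c in counts)


def test_every_annotated_lesion_has_supra_threshold_peak(small_spec):
    stack, liver, _ = generate_study(small_spec, True, seed=9)
    result = annotate_study(stack, liver)
    for peak in result.per_lesion_peak.values():
        assert peak > result.threshold.value
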