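"""First-order and texture features against brute-force oracles."""

import numpy as np
import pytest

from perturbrad import ImageVolume, ROIMask, extract_all, first_order
from perturbrad.features import CLASS_COUNTS, FEATURES_PER_FILTER
from perturbrad.filters import DiscretizedROI, discretize
from perturbrad.texture import (GLCM_NAMES, OFFSETS_13, OFFSETS_26, build_glcm,
                                build_gldm, build_glrlm, build_glszm,
                                build_ngtdm, glcm_features, texture_features)

from conftest import make_ellipsoid_mask


def make_disc(levels, mask=None, n_bins=None):
    levels = np.asarray(levels, dtype=np.int32)
    if mask is None:
        mask = np.ones(levels.shape, dtype=bool)
    if n_bins is None:
        n_bins = int(levels.max()) + 1
    lv = np.where(mask, levels, -1).astype(np.int32)
    return DiscretizedROI(levels=lv, mask=mask, n_bins=n_bins,
                          roi_min=0.0, roi_max=float(n_bins - 1))


# ---------------------------------------------------------------------------
# first-order
# ---------------------------------------------------------------------------

class TestFirstOrder:
    def test_constant_roi_limits(self):
        disc = make_disc(np.zeros((5, 5, 2)), n_bins=32)
        fo = first_order(disc, np.full(50, 4.0))
        assert fo["Entropy"] == 0.0
        assert fo["Uniformity"] == 1.0
        assert fo["Variance"] == 0.0
        assert fo["Skewness"] == 0.0 and fo["Kurtosis"] == 0.0

    def test_two_equal_bins(self):
        """Half the voxels in each of two bins: entropy 1 bit, uniformity 0.5."""
        levels = np.zeros((4, 4, 2), dtype=int)
        levels[:2] = 1
        disc = make_disc(levels, n_bins=32)
        fo = first_order(disc, np.repeat([0.0, 10.0], 16))
        assert fo["Entropy"] == pytest.approx(1.0)
        assert fo["Uniformity"] == pytest.approx(0.5)

    def test_matches_naive_oracle(self, rng):
        """All 18 statistics agree with a direct-summation oracle to 1e-10."""
        n = 500
        vals = rng.normal(50.0, 12.0, size=n)
        vals[0] = vals.max() + 30.0  # ensure a strict max
        shape = (10, 10, 5)
        vox = np.zeros(shape)
        vox.reshape(-1)[:n] = vals
        mask = np.zeros(shape, dtype=bool)
        mask.reshape(-1)[:n] = True
        vol = ImageVolume(vox, spacing=(0.98, 0.98, 5.0))
        roi = ROIMask(mask.astype(np.uint8), spacing=(0.98, 0.98, 5.0))
        disc = discretize(vol, roi, n_bins=32)
        fo = first_order(disc, vals, vol.voxel_volume_mm3)

        # independent naive-loop oracle
        mean = sum(vals) / n
        m2 = sum((v - mean) ** 2 for v in vals) / n
        m3 = sum((v - mean) ** 3 for v in vals) / n
        m4 = sum((v - mean) ** 4 for v in vals) / n
        counts = [0] * 32
        lo, hi = min(vals), max(vals)
        width = (hi - lo) / 32
        for v in vals:
            counts[min(int((v - lo) / width), 31)] += 1
        probs = [c / n for c in counts]
        entropy = -sum(p * np.log2(p) for p in probs if p > 0)
        p10, p25, p75, p90 = np.percentile(vals, [10, 25, 75, 90])
        robust = [v for v in vals if p10 <= v <= p90]
        rmean = sum(robust) / len(robust)
        expected = {
            "Energy": sum(v ** 2 for v in vals),
            "TotalEnergy": 0.98 * 0.98 * 5.0 * sum(v ** 2 for v in vals),
            "Entropy": entropy,
            "Minimum": lo, "Maximum": hi, "Range": hi - lo,
            "10Percentile": p10, "90Percentile": p90,
            "Mean": mean, "Median": float(np.median(vals)),
            "InterquartileRange": p75 - p25,
            "MeanAbsoluteDeviation": sum(abs(v - mean) for v in vals) / n,
            "RobustMeanAbsoluteDeviation":
                sum(abs(v - rmean) for v in robust) / len(robust),
            "RootMeanSquared": np.sqrt(sum(v ** 2 for v in vals) / n),
            "Skewness": m3 / m2 ** 1.5,
            "Kurtosis": m4 / m2 ** 2,
            "Variance": m2,
            "Uniformity": sum(p ** 2 for p in probs),
        }
        for key, val in expected.items():
            assert fo[key] == pytest.approx(val, rel=1e-10), key


# ---------------------------------------------------------------------------
# texture matrices vs brute-force enumeration
# ---------------------------------------------------------------------------

def brute_glcm(levels, mask, ng):
    """Pairwise enumeration oracle: one symmetrized matrix per direction."""
    mats = np.zeros((13, ng, ng))
    nx, ny, nz = levels.shape
    for d, (ox, oy, oz) in enumerate(OFFSETS_13):
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    if not mask[x, y, z]:
                        continue
                    q = (x + ox, y + oy, z + oz)
                    if (0 <= q[0] < nx and 0 <= q[1] < ny and 0 <= q[2] < nz
                            and mask[q]):
                        mats[d, levels[x, y, z], levels[q]] += 1
        mats[d] += mats[d].T.copy()
    return mats


def brute_glrlm(levels, mask, ng, lmax):
    mats = np.zeros((13, ng, lmax))
    nx, ny, nz = levels.shape
    lab = np.where(mask, levels, -1)
    for d, off in enumerate(OFFSETS_13):
        starts = [(x, y, z) for x in range(nx) for y in range(ny)
                  for z in range(nz)
                  if not (0 <= x - off[0] < nx and 0 <= y - off[1] < ny
                          and 0 <= z - off[2] < nz)]
        for sx, sy, sz in starts:
            run_level, run_len = -1, 0
            x, y, z = sx, sy, sz
            while 0 <= x < nx and 0 <= y < ny and 0 <= z < nz:
                lvl = lab[x, y, z]
                if lvl == run_level:
                    run_len += 1
                else:
                    if run_level >= 0:
                        mats[d, run_level, run_len - 1] += 1
                    run_level, run_len = lvl, 1
                x, y, z = x + off[0], y + off[1], z + off[2]
            if run_level >= 0:
                mats[d, run_level, run_len - 1] += 1
    return mats


def brute_gldm(levels, mask, ng):
    mat = np.zeros((ng, 27))
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                dep = 0
                for ox, oy, oz in OFFSETS_26:
                    q = (x + ox, y + oy, z + oz)
                    if (0 <= q[0] < nx and 0 <= q[1] < ny and 0 <= q[2] < nz
                            and mask[q] and levels[q] == levels[x, y, z]):
                        dep += 1
                mat[levels[x, y, z], dep] += 1
    return mat


def brute_ngtdm(levels, mask, ng):
    mat = np.zeros((ng, 2))
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                nb = [levels[x + ox, y + oy, z + oz] + 1
                      for ox, oy, oz in OFFSETS_26
                      if 0 <= x + ox < nx and 0 <= y + oy < ny
                      and 0 <= z + oz < nz and mask[x + ox, y + oy, z + oz]]
                if not nb:
                    continue
                mat[levels[x, y, z], 0] += 1
                mat[levels[x, y, z], 1] += abs(
                    levels[x, y, z] + 1 - sum(nb) / len(nb))
    return mat


@pytest.fixture()
def random_disc(rng):
    shape = (6, 5, 4)
    levels = rng.integers(0, 5, size=shape)
    mask = rng.random(shape) < 0.8
    mask[0, 0, 0] = True  # nonempty
    return make_disc(levels, mask, n_bins=5)


class TestMatrixBuilders:
    def test_glcm_hand_example(self):
        """2x2x1 ROI with levels [[0,0],[1,1]]: offset (1,0,0) pairs (0,0)
        and (1,1) exactly once each before symmetrization."""
        levels = np.array([[0, 0], [1, 1]]).reshape(2, 2, 1)
        disc = make_disc(levels, n_bins=2)
        tm = build_glcm(disc)
        d_100 = OFFSETS_13.index((1, 0, 0))
        # symmetrized: each unordered pair counted twice
        np.testing.assert_array_equal(tm.matrix[d_100],
                                      np.array([[0.0, 2.0], [2.0, 0.0]]))
        d_010 = OFFSETS_13.index((0, 1, 0))
        np.testing.assert_array_equal(tm.matrix[d_010],
                                      np.array([[2.0, 0.0], [0.0, 2.0]]))

    def test_glcm_counts_all_valid_pairs(self, random_disc):
        """Sum of each direction matrix equals 2x the valid in-mask pairs."""
        tm = build_glcm(random_disc)
        ref = brute_glcm(random_disc.levels, random_disc.mask, 5)
        np.testing.assert_array_equal(tm.matrix, ref)

    def test_glrlm_matches_brute_force(self, random_disc):
        tm = build_glrlm(random_disc)
        ref = brute_glrlm(random_disc.levels, random_disc.mask, 5,
                          tm.matrix.shape[2])
        np.testing.assert_array_equal(tm.matrix, ref)

    def test_gldm_matches_brute_force(self, random_disc):
        tm = build_gldm(random_disc)
        ref = brute_gldm(random_disc.levels, random_disc.mask, 5)
        np.testing.assert_array_equal(tm.matrix, ref)

    def test_ngtdm_matches_brute_force(self, random_disc):
        tm = build_ngtdm(random_disc)
        ref = brute_ngtdm(random_disc.levels, random_disc.mask, 5)
        np.testing.assert_allclose(tm.matrix, ref, atol=1e-10)

    def test_glszm_constant_roi_single_zone(self):
        """A constant ROI is one 26-connected zone of size |ROI| at level 0."""
        mask = np.zeros((6, 6, 3), dtype=bool)
        mask[1:5, 1:5, :] = True
        disc = make_disc(np.zeros((6, 6, 3), dtype=int), mask, n_bins=32)
        tm = build_glszm(disc)
        assert tm.matrix.sum() == 1
        assert tm.matrix[0, mask.sum() - 1] == 1

    def test_glszm_two_separate_zones(self):
        levels = np.zeros((7, 3, 1), dtype=int)
        levels[0:2] = 1  # zone of 6 at level 1
        levels[5:7] = 1  # zone of 6 at level 1, separated by level-0 band
        disc = make_disc(levels, n_bins=2)
        tm = build_glszm(disc)
        assert tm.matrix[1, 5] == 2  # two zones of size 6
        assert tm.matrix[0, 8] == 1  # one zone of size 9


# ---------------------------------------------------------------------------
# GLCM scalar features vs a hand-coded direct-formula oracle
# ---------------------------------------------------------------------------

def glcm_feature_oracle(counts):
    """Loop-based transcription of the 24 co-occurrence formulas."""
    ng = counts.shape[0]
    p = counts / counts.sum()
    i_vals = np.arange(1, ng + 1)
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i, j] for i in range(ng)) for j in range(ng)]
    mux = sum(i_vals[i] * px[i] for i in range(ng))
    muy = sum(i_vals[j] * py[j] for j in range(ng))
    sigx = np.sqrt(sum((i_vals[i] - mux) ** 2 * px[i] for i in range(ng)))
    sigy = np.sqrt(sum((i_vals[j] - muy) ** 2 * py[j] for j in range(ng)))
    psum = {}
    pdiff = {}
    for i in range(ng):
        for j in range(ng):
            psum[i + j + 2] = psum.get(i + j + 2, 0.0) + p[i, j]
            pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + p[i, j]
    log2 = np.log2
    ent = lambda q: -sum(v * log2(v) for v in q if v > 0)
    hxy = ent(p.ravel())
    hx, hy = ent(px), ent(py)
    hxy1 = -sum(p[i, j] * log2(px[i] * py[j]) for i in range(ng)
                for j in range(ng) if p[i, j] > 0 and px[i] * py[j] > 0)
    hxy2 = -sum(px[i] * py[j] * log2(px[i] * py[j]) for i in range(ng)
                for j in range(ng) if px[i] * py[j] > 0)
    da = sum(k * v for k, v in pdiff.items())
    keep = [i for i in range(ng) if px[i] > 0]
    q = np.zeros((len(keep), len(keep)))
    for a, i in enumerate(keep):
        for b, j in enumerate(keep):
            q[a, b] = sum(p[i, k] * p[j, k] / (px[i] * py[k])
                          for k in range(ng) if py[k] > 0)
    eig = sorted(np.abs(np.linalg.eigvals(q)))
    out = {
        "Autocorrelation": sum(i_vals[i] * i_vals[j] * p[i, j]
                               for i in range(ng) for j in range(ng)),
        "JointAverage": mux,
        "ClusterProminence": sum((i_vals[i] + i_vals[j] - mux - muy) ** 4 * p[i, j]
                                 for i in range(ng) for j in range(ng)),
        "ClusterShade": sum((i_vals[i] + i_vals[j] - mux - muy) ** 3 * p[i, j]
                            for i in range(ng) for j in range(ng)),
        "ClusterTendency": sum((i_vals[i] + i_vals[j] - mux - muy) ** 2 * p[i, j]
                               for i in range(ng) for j in range(ng)),
        "Contrast": sum((i_vals[i] - i_vals[j]) ** 2 * p[i, j]
                        for i in range(ng) for j in range(ng)),
        "Correlation": (sum(i_vals[i] * i_vals[j] * p[i, j] for i in range(ng)
                            for j in range(ng)) - mux * muy) / (sigx * sigy),
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(pdiff.values()),
        "DifferenceVariance": sum((k - da) ** 2 * v for k, v in pdiff.items()),
        "Id": sum(v / (1 + k) for k, v in pdiff.items()),
        "Idm": sum(v / (1 + k ** 2) for k, v in pdiff.items()),
        "Idmn": sum(v / (1 + (k / ng) ** 2) for k, v in pdiff.items()),
        "Idn": sum(v / (1 + k / ng) for k, v in pdiff.items()),
        "Imc1": (hxy - hxy1) / max(hx, hy),
        "Imc2": np.sqrt(1 - np.exp(-2 * (hxy2 - hxy))),
        "InverseVariance": sum(v / k ** 2 for k, v in pdiff.items() if k > 0),
        "JointEnergy": sum(v ** 2 for v in p.ravel()),
        "JointEntropy": hxy,
        "MCC": np.sqrt(eig[-2]),
        "MaximumProbability": p.max(),
        "SumAverage": sum(k * v for k, v in psum.items()),
        "SumEntropy": ent(psum.values()),
        "SumSquares": sum((i_vals[i] - mux) ** 2 * px[i] for i in range(ng)),
    }
    return out


class TestGLCMFeatures:
    def test_toy_roi_matches_formula_oracle(self, rng):
        """Every GLCM feature on a 4x4x2 toy ROI matches the loop oracle."""
        levels = rng.integers(0, 4, size=(4, 4, 2))
        disc = make_disc(levels, n_bins=4)
        tm = build_glcm(disc)
        ours = glcm_features(tm)
        per_dir = [glcm_feature_oracle(tm.matrix[d]) for d in range(13)]
        for name in GLCM_NAMES:
            expected = np.mean([f[name] for f in per_dir])
            assert ours[name] == pytest.approx(expected, rel=1e-10, abs=1e-12), name

    def test_constant_roi_degenerate_limits(self):
        """Single-cell matrix: max probability 1, joint entropy 0."""
        disc = make_disc(np.zeros((4, 4, 2), dtype=int), n_bins=32)
        feats = glcm_features(build_glcm(disc))
        assert feats["MaximumProbability"] == 1.0
        assert feats["JointEntropy"] == 0.0
        assert feats["Correlation"] == 0.0  # documented degenerate limit


class TestFeatureCounts:
    def test_class_counts(self, random_disc):
        for cls, builder in [("glcm", build_glcm), ("gldm", build_gldm),
                             ("glrlm", build_glrlm), ("glszm", build_glszm),
                             ("ngtdm", build_ngtdm)]:
            feats = texture_features(builder(random_disc))
            assert len(feats) == CLASS_COUNTS[cls], cls
        assert FEATURES_PER_FILTER == 93

    def test_extract_all_1302_and_deterministic(self, ct_volume, ctv_mask):
        fv1 = extract_all(ct_volume, ctv_mask)
        fv2 = extract_all(ct_volume, ctv_mask)
        assert len(fv1) == 1302
        assert all(np.isfinite(v) for v in fv1.values.values())
        assert fv1.values == fv2.values

    def test_histogram_features_permutation_invariant(self, rng):
        """Shuffling in-ROI voxels preserves entropy/uniformity but not
        texture features."""
        shape = (8, 8, 4)
        vox = rng.normal(size=shape)
        mask = make_ellipsoid_mask(shape, (3.5, 3.5, 1.5), (3.4, 3.4, 1.6),
                                   spacing=(1, 1, 1))
        m = mask.as_bool()
        shuffled = vox.copy()
        vals = shuffled[m]
        rng.shuffle(vals)
        shuffled[m] = vals
        v1 = ImageVolume(vox, spacing=(1, 1, 1))
        v2 = ImageVolume(shuffled, spacing=(1, 1, 1))
        d1, d2 = discretize(v1, mask), discretize(v2, mask)
        fo1 = first_order(d1, v1.voxels[m])
        fo2 = first_order(d2, v2.voxels[m])
        assert fo1["Entropy"] == pytest.approx(fo2["Entropy"], rel=1e-12)
        assert fo1["Uniformity"] == pytest.approx(fo2["Uniformity"], rel=1e-12)
        t1 = texture_features(build_glcm(d1))
        t2 = texture_features(build_glcm(d2))
        assert t1["JointEntropy"] != pytest.approx(t2["JointEntropy"], rel=1e-6)
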