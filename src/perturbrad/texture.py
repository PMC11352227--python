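"""Gray-level texture matrices and their scalar features.

Implements the five texture-matrix families (GLCM, GLDM, GLRLM, GLSZM,
NGTDM) on a fixed-bin-number discretized ROI, following the IBSI-standard
conventions of the mainstream radiomics toolchain: Chebyshev distance 1,
13 unique 3D directions for co-occurrence and runs (feature values averaged
over directions), 26-connected neighborhoods for dependence and gray-tone
difference, 26-connected zones for size-zone.  Gray levels enter the
formulas as ``i = level + 1`` (1..Ng) so the lowest bin is not
zero-weighted.  Degenerate matrices (a single occupied cell, vanishing
denominators) return documented limits instead of NaN and set a quality
flag upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage

from .filters import DiscretizedROI

_EPS = np.spacing(1.0)

#: 13 unique direction offsets at Chebyshev distance 1 (half of the 26)
OFFSETS_13 = tuple(
    d for d in product((-1, 0, 1), repeat=3) if d > (0, 0, 0)
)
OFFSETS_26 = tuple(d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0))

GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn", "Idn",
    "Imc1", "Imc2", "InverseVariance", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)
GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)
GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage",
    "GrayLevelVariance", "RunVariance", "RunEntropy",
    "LowGrayLevelRunEmphasis", "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis", "LongRunHighGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage",
    "GrayLevelVariance", "ZoneVariance", "ZoneEntropy",
    "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis", "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis", "LargeAreaHighGrayLevelEmphasis",
)
NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

CLASS_NAMES = {
    "glcm": GLCM_NAMES,
    "gldm": GLDM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
}


@dataclass
class TextureMatrix:
    """A texture matrix (or a per-direction stack of them)."""

    kind: str
    matrix: np.ndarray     # GLCM/GLRLM: (n_dir, ...); others: 2D
    n_levels: int
    n_voxels: int          # in-ROI voxel count, for percentage features


def _crop_to_roi(disc: DiscretizedROI) -> tuple[np.ndarray, np.ndarray]:
    """Bounding-box crop (levels, mask) — texture work scales with the ROI."""
    idx = np.nonzero(disc.mask)
    sl = tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)
    return disc.levels[sl], disc.mask[sl]


def _shift_pairs(arr: np.ndarray, off):
    """Index slices selecting (center, neighbor) overlap for an offset."""
    src, dst = [], []
    for o, n in zip(off, arr.shape):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------------------
# matrix builders
# ---------------------------------------------------------------------------

def build_glcm(disc: DiscretizedROI) -> TextureMatrix:
    """Symmetrized co-occurrence counts, one matrix per direction."""
    levels, mask = _crop_to_roi(disc)
    ng = disc.n_bins
    mats = np.zeros((len(OFFSETS_13), ng, ng))
    for d, off in enumerate(OFFSETS_13):
        src, dst = _shift_pairs(levels, off)
        a = levels[src]
        b = levels[dst]
        valid = mask[src] & mask[dst]
        np.add.at(mats[d], (a[valid], b[valid]), 1.0)
        mats[d] += mats[d].T.copy()
    return TextureMatrix("GLCM", mats, ng, int(mask.sum()))


def build_gldm(disc: DiscretizedROI) -> TextureMatrix:
    """Dependence matrix: 26-neighborhood, alpha = 0 (equal-level neighbors).

    Dependence j = 1 + number of in-mask 26-neighbors sharing the center's
    gray level, so j runs 1..27 and every in-ROI voxel contributes.
    """
    levels, mask = _crop_to_roi(disc)
    ng = disc.n_bins
    dep = np.zeros(levels.shape, dtype=np.int32)
    for off in OFFSETS_26:
        src, dst = _shift_pairs(levels, off)
        eq = (levels[src] == levels[dst]) & mask[src] & mask[dst]
        dep[src] += eq
    mat = np.zeros((ng, 27))
    np.add.at(mat, (levels[mask], dep[mask]), 1.0)
    return TextureMatrix("GLDM", mat, ng, int(mask.sum()))


def build_glrlm(disc: DiscretizedROI) -> TextureMatrix:
    """Run-length counts per direction (13 directions, runs broken by the mask)."""
    levels, mask = _crop_to_roi(disc)
    ng = disc.n_bins
    lmax = max(levels.shape)
    lab = np.where(mask, levels, -1)
    mats = np.zeros((len(OFFSETS_13), ng, lmax))
    shape = np.asarray(lab.shape)
    for d, off in enumerate(OFFSETS_13):
        offv = np.asarray(off)
        # start voxels: predecessor along the direction is out of bounds
        coords = np.indices(lab.shape).reshape(3, -1)
        prev = coords - offv[:, None]
        starts = ((prev < 0) | (prev >= shape[:, None])).any(axis=0)
        pos = coords[:, starts]
        cur_level = np.full(pos.shape[1], -1, dtype=np.int64)
        cur_len = np.zeros(pos.shape[1], dtype=np.int64)
        while pos.shape[1] > 0:
            inb = ((pos >= 0) & (pos < shape[:, None])).all(axis=0)
            exited = ~inb & (cur_level >= 0)
            if exited.any():  # lines leaving the array flush their open run
                np.add.at(mats[d], (cur_level[exited], cur_len[exited] - 1), 1.0)
            pos = pos[:, inb]
            cur_level = cur_level[inb]
            cur_len = cur_len[inb]
            if pos.shape[1] == 0:
                break
            lvl = lab[tuple(pos)]
            ending = (lvl != cur_level) & (cur_level >= 0)
            if ending.any():
                np.add.at(mats[d], (cur_level[ending], cur_len[ending] - 1), 1.0)
            cont = lvl == cur_level
            cur_len = np.where(cont, cur_len + 1, 1)
            cur_level = lvl
            pos = pos + offv[:, None]
    return TextureMatrix("GLRLM", mats, ng, int(mask.sum()))


def build_glszm(disc: DiscretizedROI) -> TextureMatrix:
    """Size-zone counts: 26-connected zones of equal gray level."""
    levels, mask = _crop_to_roi(disc)
    ng = disc.n_bins
    structure = np.ones((3, 3, 3), dtype=int)
    pairs = []
    present = np.unique(levels[mask])
    for g in present:
        lab, n = ndimage.label((levels == g) & mask, structure=structure)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            pairs.extend((int(g), int(s)) for s in sizes)
    smax = max(s for _, s in pairs)
    mat = np.zeros((ng, smax))
    for g, s in pairs:
        mat[g, s - 1] += 1.0
    return TextureMatrix("GLSZM", mat, ng, int(mask.sum()))


def build_ngtdm(disc: DiscretizedROI) -> TextureMatrix:
    """Neighborhood gray-tone difference sums s_i and occupancy counts n_i.

    Stored as an (Ng, 2) array of columns ``[n_i, s_i]`` over voxels having
    at least one valid 26-neighbor; gray values are ``level + 1``.
    """
    levels, mask = _crop_to_roi(disc)
    ng = disc.n_bins
    gray = np.where(mask, levels + 1, 0).astype(np.float64)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nb_sum = ndimage.correlate(gray, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.correlate(mask.astype(np.float64), kernel,
                               mode="constant", cval=0.0)
    valid = mask & (nb_cnt > 0)
    abar = np.zeros_like(gray)
    abar[valid] = nb_sum[valid] / nb_cnt[valid]
    diff = np.abs((levels + 1) - abar)
    mat = np.zeros((ng, 2))
    np.add.at(mat[:, 0], levels[valid], 1.0)
    np.add.at(mat[:, 1], levels[valid], diff[valid])
    return TextureMatrix("NGTDM", mat, ng, int(valid.sum()))


def build_texture_matrix(disc: DiscretizedROI, kind: str) -> TextureMatrix:
    """Dispatch on matrix family name (case-insensitive)."""
    builders = {"glcm": build_glcm, "gldm": build_gldm, "glrlm": build_glrlm,
                "glszm": build_glszm, "ngtdm": build_ngtdm}
    return builders[kind.lower()](disc)


# ---------------------------------------------------------------------------
# feature formulas
# ---------------------------------------------------------------------------

def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with 0 log 0 = 0."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _glcm_single(counts: np.ndarray) -> dict[str, float]:
    ng = counts.shape[0]
    total = counts.sum()
    if total == 0:
        return {k: 0.0 for k in GLCM_NAMES}
    p = counts / total
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = float((i * px).sum())
    muy = float((i * py).sum())
    sigx = float(np.sqrt(((i - mux) ** 2 * px).sum()))
    sigy = float(np.sqrt(((i - muy) ** 2 * py).sum()))

    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(k_sum.size)
    k_diff = np.arange(0, ng, dtype=np.float64)
    p_diff = np.zeros(k_diff.size)
    np.add.at(p_sum, (ii + jj - 2).astype(int), p)
    np.add.at(p_diff, np.abs(ii - jj).astype(int), p)

    hxy = float(-_xlogx(p).sum())
    hx = float(-_xlogx(px).sum())
    hy = float(-_xlogx(py).sum())
    pxy = np.outer(px, py)
    nz = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxy[nz])).sum())
    hxy2 = float(-_xlogx(pxy).sum())

    out = {}
    out["Autocorrelation"] = float((ii * jj * p).sum())
    out["JointAverage"] = mux
    csum = ii + jj - mux - muy
    out["ClusterProminence"] = float((csum ** 4 * p).sum())
    out["ClusterShade"] = float((csum ** 3 * p).sum())
    out["ClusterTendency"] = float((csum ** 2 * p).sum())
    out["Contrast"] = float(((ii - jj) ** 2 * p).sum())
    if sigx > _EPS and sigy > _EPS:
        out["Correlation"] = float(((ii * jj * p).sum() - mux * muy) / (sigx * sigy))
    else:
        out["Correlation"] = 0.0  # documented limit for a degenerate matrix
    da = float((k_diff * p_diff).sum())
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = float(-_xlogx(p_diff).sum())
    out["DifferenceVariance"] = float(((k_diff - da) ** 2 * p_diff).sum())
    out["Id"] = float((p_diff / (1.0 + k_diff)).sum())
    out["Idm"] = float((p_diff / (1.0 + k_diff ** 2)).sum())
    out["Idmn"] = float((p_diff / (1.0 + (k_diff / ng) ** 2)).sum())
    out["Idn"] = float((p_diff / (1.0 + k_diff / ng)).sum())
    denom = max(hx, hy)
    out["Imc1"] = float((hxy - hxy1) / denom) if denom > _EPS else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    out["Imc2"] = float(np.sqrt(max(arg, 0.0)))
    inv = p_diff[1:] / k_diff[1:] ** 2
    out["InverseVariance"] = float(inv.sum())
    out["JointEnergy"] = float((p ** 2).sum())
    out["JointEntropy"] = hxy
    out["MCC"] = _glcm_mcc(p, px, py)
    out["MaximumProbability"] = float(p.max())
    out["SumAverage"] = float((k_sum * p_sum).sum())
    out["SumEntropy"] = float(-_xlogx(p_sum).sum())
    out["SumSquares"] = float(((i - mux) ** 2 * px).sum())
    return out


def _glcm_mcc(p, px, py) -> float:
    keep = px > 0
    if keep.sum() < 2:
        return 1.0  # single occupied level: perfect correlation limit
    ps = p[np.ix_(keep, keep)]
    pxs = px[keep]
    pys = py[keep]
    # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
    q = (ps / pxs[:, None]) @ (ps / pys[None, :]).T
    eig = np.linalg.eigvals(q)
    eig = np.sort(np.abs(eig))
    second = eig[-2]
    return float(np.sqrt(max(second, 0.0)))


def glcm_features(tm: TextureMatrix) -> dict[str, float]:
    """Per-direction features averaged feature-wise over the 13 directions."""
    per_dir = [_glcm_single(tm.matrix[d]) for d in range(tm.matrix.shape[0])]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_NAMES}


def _weighted_stats(mat: np.ndarray):
    """(p_ij, i gray values, j second-index values, marginals) for 2D matrices."""
    total = mat.sum()
    p = mat / total if total > 0 else mat
    i = np.arange(1, mat.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, mat.shape[1] + 1, dtype=np.float64)
    return p, i, j


def gldm_features(tm: TextureMatrix) -> dict[str, float]:
    mat = tm.matrix
    nz = mat.sum()
    p, i, j = _weighted_stats(mat)
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    ii = i[:, None]
    jj = j[None, :]
    mu_i = float((i * pi).sum())
    mu_j = float((j * pj).sum())
    out = {
        "SmallDependenceEmphasis": float((p / jj ** 2).sum()),
        "LargeDependenceEmphasis": float((p * jj ** 2).sum()),
        "GrayLevelNonUniformity": float((mat.sum(axis=1) ** 2).sum() / nz),
        "DependenceNonUniformity": float((mat.sum(axis=0) ** 2).sum() / nz),
        "DependenceNonUniformityNormalized": float(
            (mat.sum(axis=0) ** 2).sum() / nz ** 2),
        "GrayLevelVariance": float(((i - mu_i) ** 2 * pi).sum()),
        "DependenceVariance": float(((j - mu_j) ** 2 * pj).sum()),
        "DependenceEntropy": float(-_xlogx(p).sum()),
        "LowGrayLevelEmphasis": float((p / ii ** 2).sum()),
        "HighGrayLevelEmphasis": float((p * ii ** 2).sum()),
        "SmallDependenceLowGrayLevelEmphasis": float((p / (ii ** 2 * jj ** 2)).sum()),
        "SmallDependenceHighGrayLevelEmphasis": float((p * ii ** 2 / jj ** 2).sum()),
        "LargeDependenceLowGrayLevelEmphasis": float((p * jj ** 2 / ii ** 2).sum()),
        "LargeDependenceHighGrayLevelEmphasis": float((p * ii ** 2 * jj ** 2).sum()),
    }
    return out


def _rlm_single(mat: np.ndarray, n_voxels: int, names) -> dict[str, float]:
    """Shared run-length / size-zone formulas (j = run length or zone size)."""
    nr = mat.sum()
    if nr == 0:
        return {k: 0.0 for k in names}
    p, i, j = _weighted_stats(mat)
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    ii = i[:, None]
    jj = j[None, :]
    mu_i = float((i * pi).sum())
    mu_j = float((j * pj).sum())
    vals = [
        float((p / jj ** 2).sum()),                       # short emphasis
        float((p * jj ** 2).sum()),                       # long emphasis
        float((mat.sum(axis=1) ** 2).sum() / nr),         # GLN
        float((mat.sum(axis=1) ** 2).sum() / nr ** 2),    # GLNN
        float((mat.sum(axis=0) ** 2).sum() / nr),         # RLN / SZN
        float((mat.sum(axis=0) ** 2).sum() / nr ** 2),    # RLNN / SZNN
        float(nr / n_voxels),                             # percentage
        float(((i - mu_i) ** 2 * pi).sum()),              # gray level variance
        float(((j - mu_j) ** 2 * pj).sum()),              # run/zone variance
        float(-_xlogx(p).sum()),                          # entropy
        float((p / ii ** 2).sum()),
        float((p * ii ** 2).sum()),
        float((p / (ii ** 2 * jj ** 2)).sum()),
        float((p * ii ** 2 / jj ** 2).sum()),
        float((p * jj ** 2 / ii ** 2).sum()),
        float((p * ii ** 2 * jj ** 2).sum()),
    ]
    return dict(zip(names, vals))


def glrlm_features(tm: TextureMatrix) -> dict[str, float]:
    per_dir = [_rlm_single(tm.matrix[d], tm.n_voxels, GLRLM_NAMES)
               for d in range(tm.matrix.shape[0])]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_NAMES}


def glszm_features(tm: TextureMatrix) -> dict[str, float]:
    return _rlm_single(tm.matrix, tm.n_voxels, GLSZM_NAMES)


def ngtdm_features(tm: TextureMatrix) -> dict[str, float]:
    n = tm.matrix[:, 0]
    s = tm.matrix[:, 1]
    nvp = n.sum()
    if nvp == 0:
        return {k: 0.0 for k in NGTDM_NAMES}
    p = n / nvp
    i = np.arange(1, tm.n_levels + 1, dtype=np.float64)
    nzmask = p > 0
    ngp = int(nzmask.sum())
    ps = float((p * s).sum())

    out = {}
    out["Coarseness"] = float(1.0 / ps) if ps > _EPS else 1e6  # flat-image limit
    if ngp > 1:
        iv = i[nzmask]
        pv = p[nzmask]
        sv = s[nzmask]
        di = iv[:, None] - iv[None, :]
        out["Contrast"] = float(
            (pv[:, None] * pv[None, :] * di ** 2).sum()
            / (ngp * (ngp - 1)) * (s.sum() / nvp))
        denom = np.abs(iv[:, None] * pv[:, None] - iv[None, :] * pv[None, :]).sum()
        out["Busyness"] = float(ps / denom) if denom > _EPS else 0.0
        num = np.abs(di) * (pv[:, None] * sv[:, None] + pv[None, :] * sv[None, :])
        out["Complexity"] = float(
            (num / (pv[:, None] + pv[None, :])).sum() / nvp)
        st = ((pv[:, None] + pv[None, :]) * di ** 2).sum()
        out["Strength"] = float(st / s.sum()) if s.sum() > _EPS else 0.0
    else:
        out["Contrast"] = 0.0
        out["Busyness"] = 0.0
        out["Complexity"] = 0.0
        out["Strength"] = 0.0
    return out


_FEATURE_FUNCS = {
    "glcm": (build_glcm, glcm_features),
    "gldm": (build_gldm, gldm_features),
    "glrlm": (build_glrlm, glrlm_features),
    "glszm": (build_glszm, glszm_features),
    "ngtdm": (build_ngtdm, ngtdm_features),
}


def texture_features(tm: TextureMatrix) -> dict[str, float]:
    """Scalar features for a built matrix, dispatched on its kind."""
    funcs = {"GLCM": glcm_features, "GLDM": gldm_features,
             "GLRLM": glrlm_features, "GLSZM": glszm_features,
             "NGTDM": ngtdm_features}
    return funcs[tm.kind](tm)


def all_texture_features(disc: DiscretizedROI) -> dict[str, float]:
    """All five classes on one discretized ROI, keys ``<class>_<name>``."""
    out = {}
    for cls, (build, feats) in _FEATURE_FUNCS.items():
        tm = build(disc)
        for name, val in feats(tm).items():
            out[f"{cls}_{name}"] = val
    return out
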