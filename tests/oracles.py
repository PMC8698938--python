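"""Naive, loop-based reference implementations of the texture families.

Everything here is written with explicit Python loops from the matrix and
feature definitions, deliberately sharing no code with the package, so that
agreement with the vectorized implementations is evidence of correctness.
Conventions mirror the package's documented choices: merged 3D matrices
over the 13 unique direction pairs (Chebyshev distance 1), GLRLM run
percentage normalized by ``n_voxels * 13``, GLSZM zone percentage by
``n_voxels``, and NGLDM dependence "length" equal to the count of same-level
26-neighbours plus one (the voxel itself), capped at 27 columns.
"""

import math

import numpy as np

OFFSETS_26 = [(dx, dy, dz)
              for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
              if (dx, dy, dz) != (0, 0, 0)]
DIRECTIONS_13 = [o for o in OFFSETS_26 if o > (0, 0, 0)]


def _inside(shape, x, y, z):
    return 0 <= x < shape[0] and 0 <= y < shape[1] and 0 <= z < shape[2]


def glcm_brute(bins, mask, n_levels):
    """Symmetric merged co-occurrence counts: every ordered in-mask pair at
    Chebyshev distance 1 counted once (equals M + M.T over 13 directions)."""
    M = np.zeros((n_levels, n_levels))
    shape = bins.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                for dx, dy, dz in OFFSETS_26:
                    u, v, w = x + dx, y + dy, z + dz
                    if _inside(shape, u, v, w) and mask[u, v, w]:
                        M[bins[x, y, z] - 1, bins[u, v, w] - 1] += 1
    return M


def glrlm_brute(bins, mask, n_levels):
    """Run counts by extracting every full grid line along each of the 13
    directions and run-length-encoding the in-mask stretches."""
    shape = bins.shape
    runs = {}
    for d in DIRECTIONS_13:
        starts = []
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    if not _inside(shape, x - d[0], y - d[1], z - d[2]):
                        starts.append((x, y, z))
        for x, y, z in starts:
            seq = []
            while _inside(shape, x, y, z):
                seq.append(bins[x, y, z] if mask[x, y, z] else None)
                x, y, z = x + d[0], y + d[1], z + d[2]
            g_prev, length = None, 0
            for g in seq + [None]:
                if g is not None and g == g_prev:
                    length += 1
                else:
                    if g_prev is not None and length:
                        runs[(g_prev, length)] = runs.get((g_prev, length), 0) + 1
                    g_prev, length = g, (1 if g is not None else 0)
    max_len = max((r for (_, r) in runs), default=1)
    M = np.zeros((n_levels, max_len))
    for (g, r), c in runs.items():
        M[g - 1, r - 1] = c
    return M


def glszm_brute(bins, mask, n_levels):
    """Zone counts via breadth-first flood fill with 26-connectivity."""
    shape = bins.shape
    seen = np.zeros(shape, dtype=bool)
    zones = {}
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z] or seen[x, y, z]:
                    continue
                g = bins[x, y, z]
                stack, size = [(x, y, z)], 0
                seen[x, y, z] = True
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx, dy, dz in OFFSETS_26:
                        u, v, w = cx + dx, cy + dy, cz + dz
                        if _inside(shape, u, v, w) and mask[u, v, w] \
                                and not seen[u, v, w] and bins[u, v, w] == g:
                            seen[u, v, w] = True
                            stack.append((u, v, w))
                zones[(g, size)] = zones.get((g, size), 0) + 1
    max_size = max((s for (_, s) in zones), default=1)
    M = np.zeros((n_levels, max_size))
    for (g, s), c in zones.items():
        M[g - 1, s - 1] = c
    return M


def ngtdm_brute(bins, mask, n_levels):
    shape = bins.shape
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                vals = [bins[x + dx, y + dy, z + dz]
                        for dx, dy, dz in OFFSETS_26
                        if _inside(shape, x + dx, y + dy, z + dz)
                        and mask[x + dx, y + dy, z + dz]]
                if not vals:
                    continue
                g = bins[x, y, z]
                n_i[g - 1] += 1
                s_i[g - 1] += abs(g - sum(vals) / len(vals))
    return {"n": n_i, "s": s_i}


def ngldm_brute(bins, mask, n_levels):
    shape = bins.shape
    M = np.zeros((n_levels, 27))
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                g = bins[x, y, z]
                k = sum(1 for dx, dy, dz in OFFSETS_26
                        if _inside(shape, x + dx, y + dy, z + dz)
                        and mask[x + dx, y + dy, z + dz]
                        and bins[x + dx, y + dy, z + dz] == g)
                M[g - 1, k] += 1
    return M


# --------------------------------------------------------------------------
# Loop-based feature formulas
# --------------------------------------------------------------------------

def _ent(values):
    return -sum(v * math.log2(v) for v in values if v > 0)


def glcm_features_brute(M):
    n = M.shape[0]
    total = M.sum()
    if total == 0:
        M = np.array([[1.0]])
        total, n = 1.0, 1
    p = M / total
    pi = [sum(p[i, j] for j in range(n)) for i in range(n)]
    mu = sum((i + 1) * p[i, j] for i in range(n) for j in range(n))
    mu_r = sum((i + 1) * pi[i] for i in range(n))
    sd2 = sum((i + 1 - mu_r) ** 2 * pi[i] for i in range(n))
    p_minus = [sum(p[i, j] for i in range(n) for j in range(n)
                   if abs(i - j) == k) for k in range(n)]
    p_plus = [sum(p[i, j] for i in range(n) for j in range(n)
                  if i + j + 2 == k) for k in range(2, 2 * n + 1)]
    da = sum(k * p_minus[k] for k in range(n))
    sa = sum(k * p_plus[k - 2] for k in range(2, 2 * n + 1))
    hxy = _ent(p.ravel())
    hxy1 = -sum(p[i, j] * math.log2(pi[i] * pi[j])
                for i in range(n) for j in range(n)
                if p[i, j] > 0 and pi[i] * pi[j] > 0)
    hx = _ent(pi)
    hxy2 = _ent([pi[i] * pi[j] for i in range(n) for j in range(n)])
    corr = (sum((i + 1) * (j + 1) * p[i, j] for i in range(n)
                for j in range(n)) - mu_r ** 2) / sd2 if sd2 > 0 else 1.0
    out = {
        "glcm_joint_max": p.max(),
        "glcm_joint_average": mu,
        "glcm_joint_variance": sum((i + 1 - mu) ** 2 * p[i, j]
                                   for i in range(n) for j in range(n)),
        "glcm_joint_entropy": hxy,
        "glcm_difference_average": da,
        "glcm_difference_variance": sum((k - da) ** 2 * p_minus[k]
                                        for k in range(n)),
        "glcm_difference_entropy": _ent(p_minus),
        "glcm_sum_average": sa,
        "glcm_sum_variance": sum((k - sa) ** 2 * p_plus[k - 2]
                                 for k in range(2, 2 * n + 1)),
        "glcm_sum_entropy": _ent(p_plus),
        "glcm_energy": sum(v ** 2 for v in p.ravel()),
        "glcm_contrast": sum((i - j) ** 2 * p[i, j]
                             for i in range(n) for j in range(n)),
        "glcm_dissimilarity": sum(abs(i - j) * p[i, j]
                                  for i in range(n) for j in range(n)),
        "glcm_inverse_difference": sum(p[i, j] / (1 + abs(i - j))
                                       for i in range(n) for j in range(n)),
        "glcm_inverse_difference_norm":
            sum(p[i, j] / (1 + abs(i - j) / n)
                for i in range(n) for j in range(n)),
        "glcm_inverse_difference_moment":
            sum(p[i, j] / (1 + (i - j) ** 2)
                for i in range(n) for j in range(n)),
        "glcm_inverse_difference_moment_norm":
            sum(p[i, j] / (1 + (i - j) ** 2 / n ** 2)
                for i in range(n) for j in range(n)),
        "glcm_inverse_variance": sum(p[i, j] / (i - j) ** 2
                                     for i in range(n) for j in range(n)
                                     if i != j),
        "glcm_correlation": corr,
        "glcm_autocorrelation": sum((i + 1) * (j + 1) * p[i, j]
                                    for i in range(n) for j in range(n)),
        "glcm_cluster_tendency": sum((i + j + 2 - 2 * mu) ** 2 * p[i, j]
                                     for i in range(n) for j in range(n)),
        "glcm_cluster_shade": sum((i + j + 2 - 2 * mu) ** 3 * p[i, j]
                                  for i in range(n) for j in range(n)),
        "glcm_cluster_prominence": sum((i + j + 2 - 2 * mu) ** 4 * p[i, j]
                                       for i in range(n) for j in range(n)),
        "glcm_information_correlation_1":
            (hxy - hxy1) / hx if hx > 0 else 0.0,
        "glcm_information_correlation_2":
            math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))),
    }
    return out


def run_family_features_brute(M, prefix, axis_name, percentage_denominator):
    Ns = M.sum()
    if Ns == 0:
        M = np.array([[1.0]])
        Ns = 1.0
    ng, nr = M.shape
    mi = [sum(M[i, r] for r in range(nr)) for i in range(ng)]
    mr = [sum(M[i, r] for i in range(ng)) for r in range(nr)]
    mu_i = sum((i + 1) * mi[i] for i in range(ng)) / Ns
    mu_r = sum((r + 1) * mr[r] for r in range(nr)) / Ns
    f = {
        f"{prefix}_short_{axis_name}_emphasis":
            sum(mr[r] / (r + 1) ** 2 for r in range(nr)) / Ns,
        f"{prefix}_long_{axis_name}_emphasis":
            sum(mr[r] * (r + 1) ** 2 for r in range(nr)) / Ns,
        f"{prefix}_low_grey_emphasis":
            sum(mi[i] / (i + 1) ** 2 for i in range(ng)) / Ns,
        f"{prefix}_high_grey_emphasis":
            sum(mi[i] * (i + 1) ** 2 for i in range(ng)) / Ns,
        f"{prefix}_short_{axis_name}_low_grey_emphasis":
            sum(M[i, r] / ((i + 1) ** 2 * (r + 1) ** 2)
                for i in range(ng) for r in range(nr)) / Ns,
        f"{prefix}_short_{axis_name}_high_grey_emphasis":
            sum(M[i, r] * (i + 1) ** 2 / (r + 1) ** 2
                for i in range(ng) for r in range(nr)) / Ns,
        f"{prefix}_long_{axis_name}_low_grey_emphasis":
            sum(M[i, r] * (r + 1) ** 2 / (i + 1) ** 2
                for i in range(ng) for r in range(nr)) / Ns,
        f"{prefix}_long_{axis_name}_high_grey_emphasis":
            sum(M[i, r] * (i + 1) ** 2 * (r + 1) ** 2
                for i in range(ng) for r in range(nr)) / Ns,
        f"{prefix}_grey_nonuniformity": sum(m ** 2 for m in mi) / Ns,
        f"{prefix}_grey_nonuniformity_norm": sum(m ** 2 for m in mi) / Ns ** 2,
        f"{prefix}_{axis_name}_nonuniformity": sum(m ** 2 for m in mr) / Ns,
        f"{prefix}_{axis_name}_nonuniformity_norm":
            sum(m ** 2 for m in mr) / Ns ** 2,
        f"{prefix}_{axis_name}_percentage": Ns / percentage_denominator,
        f"{prefix}_grey_variance":
            sum((i + 1 - mu_i) ** 2 * mi[i] for i in range(ng)) / Ns,
        f"{prefix}_{axis_name}_variance":
            sum((r + 1 - mu_r) ** 2 * mr[r] for r in range(nr)) / Ns,
        f"{prefix}_{axis_name}_entropy": _ent((M / Ns).ravel()),
        f"{prefix}_{axis_name}_energy": sum(v ** 2 for v in (M / Ns).ravel()),
    }
    return f


def ngtdm_features_brute(table):
    n_i, s_i = table["n"], table["s"]
    N = n_i.sum()
    names = ("ngtdm_coarseness", "ngtdm_contrast", "ngtdm_busyness",
             "ngtdm_complexity", "ngtdm_strength")
    if N == 0:
        return {k: 0.0 for k in names}
    ng = len(n_i)
    p = [n / N for n in n_i]
    present = [i for i in range(ng) if p[i] > 0]
    ngp = len(present)
    ps = sum(p[i] * s_i[i] for i in range(ng))
    coarseness = 1.0 / ps if ps > 0 else 1e6
    if ngp > 1:
        contrast = sum(p[i] * p[j] * (i - j) ** 2
                       for i in present for j in present) \
            / (ngp * (ngp - 1)) * sum(s_i) / N
        denom = sum(abs((i + 1) * p[i] - (j + 1) * p[j])
                    for i in present for j in present)
        busyness = ps / denom if denom > 0 else 0.0
        complexity = sum(abs(i - j) * (p[i] * s_i[i] + p[j] * s_i[j])
                         / (p[i] + p[j])
                         for i in present for j in present) / N
        strength = sum((p[i] + p[j]) * (i - j) ** 2
                       for i in present for j in present) / sum(s_i) \
            if sum(s_i) > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {"ngtdm_coarseness": coarseness, "ngtdm_contrast": contrast,
            "ngtdm_busyness": busyness, "ngtdm_complexity": complexity,
            "ngtdm_strength": strength}


def all_texture_features_brute(bins, mask, n_levels, n_voxels):
    """Full brute-force texture feature dictionary for one discretized mask
    (same naming and trimming conventions as the package)."""
    out = {}
    out.update(glcm_features_brute(glcm_brute(bins, mask, n_levels)))
    glrlm = run_family_features_brute(
        glrlm_brute(bins, mask, n_levels), "glrlm", "run",
        percentage_denominator=n_voxels * 13)
    glrlm.pop("glrlm_run_energy")
    out.update(glrlm)
    glszm = run_family_features_brute(
        glszm_brute(bins, mask, n_levels), "glszm", "zone",
        percentage_denominator=n_voxels)
    glszm.pop("glszm_zone_energy")
    out.update(glszm)
    out.update(ngtdm_features_brute(ngtdm_brute(bins, mask, n_levels)))
    out.update(run_family_features_brute(
        ngldm_brute(bins, mask, n_levels), "ngldm", "dependence",
        percentage_denominator=n_voxels))
    return out
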