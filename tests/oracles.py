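"""Independent reference implementations used only to check the package.

Each oracle deliberately takes a different computational route from the
implementation it validates: quaternion (Horn) superposition instead of the
SVD Kabsch form, scipy's align_vectors inside the exhaustive TM-score seed
search, a direct four-atom torsion formula, and a plain quadratic-time scan
for register overlap.
"""

import numpy as np
from scipy.spatial.transform import Rotation


def quaternion_superpose_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Optimal-superposition RMSD via Horn's quaternion eigenvalue method."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    am = a - a.mean(axis=0)
    bm = b - b.mean(axis=0)
    sxx, sxy, sxz = (am[:, 0] @ bm[:, 0], am[:, 0] @ bm[:, 1], am[:, 0] @ bm[:, 2])
    syx, syy, syz = (am[:, 1] @ bm[:, 0], am[:, 1] @ bm[:, 1], am[:, 1] @ bm[:, 2])
    szx, szy, szz = (am[:, 2] @ bm[:, 0], am[:, 2] @ bm[:, 1], am[:, 2] @ bm[:, 2])
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    g = (am ** 2).sum() + (bm ** 2).sum()
    return float(np.sqrt(max(0.0, g - 2.0 * lam) / a.shape[0]))


def torsion_reference(p1, p2, p3, p4) -> float:
    """Signed dihedral via plane normals and a sign from the scalar triple
    product, in degrees."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = (n1 @ n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if np.cross(n1, n2) @ b2 < 0:
        ang = -ang
    return float(ang)


def tm_score_exhaustive(a: np.ndarray, b: np.ndarray, l_ref: int) -> float:
    """Brute-force TM-score: every contiguous fragment of every length >= 4
    seeds an iterative superposition/selection refinement.

    Superpositions use scipy Rotation.align_vectors, keeping the oracle
    independent of the package's Kabsch implementation.
    """
    n = a.shape[0]
    d0 = max(0.5, 1.24 * np.cbrt(l_ref - 15.0) - 1.8)
    d0_search = min(max(d0, 4.5), 8.0)
    best = 0.0
    for lf in range(4, n + 1):
        for start in range(0, n - lf + 1):
            idx = np.arange(start, start + lf)
            prev = None
            for _ in range(40):
                rot, _ = Rotation.align_vectors(b[idx] - b[idx].mean(axis=0),
                                                a[idx] - a[idx].mean(axis=0))
                moved = rot.apply(a - a[idx].mean(axis=0)) + b[idx].mean(axis=0)
                d = np.linalg.norm(moved - b, axis=1)
                best = max(best, float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_ref))
                cut = d0_search
                sel = np.nonzero(d < cut)[0]
                while sel.size < 3 and cut < 30.0:
                    cut += 0.5
                    sel = np.nonzero(d < cut)[0]
                if prev is not None and np.array_equal(sel, prev):
                    break
                prev = sel
                idx = sel
    return best


def rio_brute_force(placed_res, crystal_res, match_distance=1.5):
    """Direct register-overlap count: (in_register, out_of_register, total).

    placed_res / crystal_res: lists of (seq_id, CA position); single copy,
    single chain.  Runs require consecutive placed numbering matched to
    crystal residues stepping +1 or -1, length >= 3.
    """
    matches = []
    for sid, pos in placed_res:
        cand = [(np.linalg.norm(pos - cpos), cid) for cid, cpos in crystal_res]
        cand.sort()
        matches.append(cand[0][1] if cand and cand[0][0] <= match_distance else None)
    in_reg = out_reg = 0
    i = 0
    n = len(placed_res)
    while i < n:
        if matches[i] is None:
            i += 1
            continue
        j = i + 1
        step = None
        while j < n and matches[j] is not None \
                and placed_res[j][0] == placed_res[j - 1][0] + 1:
            s = matches[j] - matches[j - 1]
            if s not in (1, -1) or (step is not None and s != step):
                break
            step = s
            j += 1
        run = list(range(i, j))
        if len(run) >= 3:
            if all(matches[k] == placed_res[k][0] for k in run):
                in_reg += len(run)
            else:
                out_reg += len(run)
        i = j
    return in_reg, out_reg, n
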