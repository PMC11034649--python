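"""Brute-force reference implementations used only as test oracles.

Deliberately simple and slow: boundary extraction by explicit neighbour
checks, distances by an all-pairs scan. The package implementation must
agree with these exactly on small masks.
"""

import numpy as np


def brute_boundary(mask):
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    pts = []
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ny, nx = y + dy, x + dx
                if not (0 <= ny < h and 0 <= nx < w) or not mask[ny, nx]:
                    pts.append((y, x))
                    break
    return pts


def brute_surface_distances(pred, gt):
    bp, bg = brute_boundary(pred), brute_boundary(gt)
    d_pg = [min(np.hypot(p[0] - g[0], p[1] - g[1]) for g in bg) for p in bp]
    d_gp = [min(np.hypot(p[0] - g[0], p[1] - g[1]) for p in bp) for g in bg]
    return np.array(d_pg), np.array(d_gp)


def brute_hd95(pred, gt):
    d_pg, d_gp = brute_surface_distances(pred, gt)
    return float(np.percentile(np.concatenate([d_pg, d_gp]), 95))


def brute_asd(pred, gt):
    d_pg, d_gp = brute_surface_distances(pred, gt)
    return float(np.concatenate([d_pg, d_gp]).mean())


def brute_dice(pred, gt):
    pred, gt = np.asarray(pred, bool), np.asarray(gt, bool)
    s = pred.sum() + gt.sum()
    return 1.0 if s == 0 else 2.0 * (pred & gt).sum() / s


def brute_jaccard(pred, gt):
    pred, gt = np.asarray(pred, bool), np.asarray(gt, bool)
    u = (pred | gt).sum()
    return 1.0 if u == 0 else (pred & gt).sum() / u
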