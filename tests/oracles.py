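"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain double loops and textbook formulas,
deliberately sharing no code with the package.
"""

import math

import numpy as np

BG, BE, B = 0, 127, 255


def area_loop(mask, cls):
    n = 0
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c] == cls:
                n += 1
    return n


def iou_loop(a, b, cls):
    inter = union = 0
    for r in range(a.shape[0]):
        for c in range(a.shape[1]):
            pa, pb = a[r, c] == cls, b[r, c] == cls
            if pa and pb:
                inter += 1
            if pa or pb:
                union += 1
    return 1.0 if union == 0 else inter / union


def pearson_formula(a, b):
    x = [float(v) for v in np.asarray(a).ravel()]
    y = [float(v) for v in np.asarray(b).ravel()]
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    sxx = sum((xi - mx) ** 2 for xi in x)
    syy = sum((yi - my) ** 2 for yi in y)
    return sxy / math.sqrt(sxx * syy)


def r_squared_arith(pred, ref):
    ref = [float(v) for v in ref]
    pred = [float(v) for v in pred]
    mean_ref = sum(ref) / len(ref)
    ss_res = sum((p - r) ** 2 for p, r in zip(pred, ref))
    ss_tot = sum((r - mean_ref) ** 2 for r in ref)
    return 1.0 - ss_res / ss_tot


def flood_fill_components(mask, connectivity=8):
    """BFS flood fill over berry-class pixels; returns lists of (r, c) sets."""
    h, w = mask.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = set()
    comps = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] != B or (r, c) in seen:
                continue
            queue = [(r, c)]
            seen.add((r, c))
            comp = set()
            while queue:
                cr, cc = queue.pop()
                comp.add((cr, cc))
                for dr, dc in nbrs:
                    nr, nc = cr + dr, cc + dc
                    if 0 <= nr < h and 0 <= nc < w and (nr, nc) not in seen \
                            and mask[nr, nc] == B:
                        seen.add((nr, nc))
                        queue.append((nr, nc))
            comps.append(comp)
    return comps


def axes_from_moments(comp):
    """Equivalent-ellipse full axis lengths with the 1/12 pixel term."""
    if len(comp) == 1:
        return 1.0, 1.0
    pts = sorted(comp)
    mr = sum(p[0] for p in pts) / len(pts)
    mc = sum(p[1] for p in pts) / len(pts)
    srr = sum((p[0] - mr) ** 2 for p in pts) / len(pts) + 1.0 / 12.0
    scc = sum((p[1] - mc) ** 2 for p in pts) / len(pts) + 1.0 / 12.0
    src = sum((p[0] - mr) * (p[1] - mc) for p in pts) / len(pts)
    tr, det = srr + scc, srr * scc - src * src
    disc = math.sqrt(max(tr * tr / 4.0 - det, 0.0))
    lam1, lam2 = tr / 2.0 + disc, tr / 2.0 - disc
    major = 4.0 * math.sqrt(max(lam1, 0.0))
    minor = 4.0 * math.sqrt(max(lam2, 0.0))
    major = max(major, 1.0)
    minor = max(min(minor, major), 1.0)
    return major, minor


def count_with_predicates(mask, min_area=25, min_ratio=0.3, fill_frac=0.5,
                          edge_frac=0.5, connectivity=8):
    """Full counting oracle: flood fill, then evaluate all four predicates."""
    h, w = mask.shape
    kept = 0
    for comp in flood_fill_components(mask, connectivity):
        area = len(comp)
        if area < min_area:
            continue
        major, minor = axes_from_moments(comp)
        if minor / major < min_ratio:
            continue
        radius = (minor + major) / 4.0
        if area < fill_frac * math.pi * radius ** 2:
            continue
        boundary = [p for p in comp
                    if any((p[0] + dr, p[1] + dc) not in comp
                           for dr, dc in [(-1, 0), (1, 0), (0, -1), (0, 1)])]
        near_edge = 0
        for (r, c) in boundary:
            found = False
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    nr, nc = r + dr, c + dc
                    if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] == BE:
                        found = True
            if found:
                near_edge += 1
        if not boundary or near_edge / len(boundary) < edge_frac:
            continue
        kept += 1
    return kept
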