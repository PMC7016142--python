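"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written with plain Python loops and no
image-processing or spatial libraries, so a defect in the implementation
path cannot hide in a shared dependency.
"""

from __future__ import annotations

import math

import numpy as np

SQRT2 = math.sqrt(2.0)

# weight of a border pixel given its (orthogonal, diagonal) border-neighbour
# counts; the weighted boundary-pixel perimeter estimator
_PERIMETER_WEIGHTS = {
    (2, 0): 1.0, (3, 0): 1.0, (2, 1): 1.0, (3, 1): 1.0, (2, 2): 1.0, (3, 2): 1.0,
    (0, 2): SQRT2, (1, 3): SQRT2,
    (1, 1): (1.0 + SQRT2) / 2.0, (1, 2): (1.0 + SQRT2) / 2.0,
}

ORTH = [(-1, 0), (1, 0), (0, -1), (0, 1)]
DIAG = [(-1, -1), (-1, 1), (1, -1), (1, 1)]


def flood_fill_label(mask: np.ndarray) -> np.ndarray:
    """8-connected component labelling by breadth-first flood fill."""
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    next_label = 0
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or labels[sy, sx]:
                continue
            next_label += 1
            queue = [(sy, sx)]
            labels[sy, sx] = next_label
            while queue:
                y, x = queue.pop()
                for dy, dx in ORTH + DIAG:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not labels[ny, nx]:
                        labels[ny, nx] = next_label
                        queue.append((ny, nx))
    return labels


def weighted_perimeter(mask: np.ndarray) -> float:
    """Weighted boundary-pixel perimeter of a binary mask, by per-pixel loops.

    A border pixel is a foreground pixel with at least one orthogonal
    neighbour outside the mask (image borders count as background).  Its
    weight depends on how many of its orthogonal/diagonal neighbours are
    themselves border pixels.
    """
    mask = np.asarray(mask, bool)
    h, w = mask.shape

    def is_fg(y: int, x: int) -> bool:
        return 0 <= y < h and 0 <= x < w and mask[y, x]

    border = np.zeros((h, w), dtype=bool)
    for y in range(h):
        for x in range(w):
            if mask[y, x] and any(not is_fg(y + dy, x + dx) for dy, dx in ORTH):
                border[y, x] = True

    total = 0.0
    for y in range(h):
        for x in range(w):
            if not border[y, x]:
                continue
            n_orth = sum(
                1 for dy, dx in ORTH
                if 0 <= y + dy < h and 0 <= x + dx < w and border[y + dy, x + dx]
            )
            n_diag = sum(
                1 for dy, dx in DIAG
                if 0 <= y + dy < h and 0 <= x + dx < w and border[y + dy, x + dx]
            )
            total += _PERIMETER_WEIGHTS.get((n_orth, n_diag), 0.0)
    return total


def region_stats(
    mask: np.ndarray,
    min_area: int,
    circularity_range: tuple[float, float],
    image: np.ndarray | None = None,
) -> list[dict]:
    """Brute-force per-region measurements with the same filters.

    Returns one dict per surviving region with keys area, perimeter,
    circularity, centroid (y, x) and mean_intensity, sorted by centroid.
    """
    labels = flood_fill_label(mask)
    lo, hi = circularity_range
    out = []
    for lab in range(1, labels.max() + 1):
        region = labels == lab
        area = int(region.sum())
        if area < min_area:
            continue
        perim = weighted_perimeter(region)
        circ = 0.0 if perim <= 0 else min(1.0, 4.0 * math.pi * area / perim**2)
        if not (lo <= circ <= hi):
            continue
        ys, xs = np.nonzero(region)
        out.append(
            {
                "area": area,
                "perimeter": perim,
                "circularity": circ,
                "centroid": (float(ys.mean()), float(xs.mean())),
                "mean_intensity": float(image[region].mean()) if image is not None else None,
            }
        )
    return sorted(out, key=lambda r: r["centroid"])


def intermeans_threshold_pixels(pixels: np.ndarray, max_iter: int = 500) -> float:
    """Fixed point of t <- (mean_below(t) + mean_above(t)) / 2 on raw pixels."""
    x = np.asarray(pixels, float).ravel()
    t = float(x.mean())
    for _ in range(max_iter):
        below, above = x[x <= t], x[x > t]
        if below.size == 0 or above.size == 0:
            break
        t_new = 0.5 * (float(below.mean()) + float(above.mean()))
        if abs(t_new - t) < 1e-12 * (x.max() - x.min() + 1e-30):
            return t_new
        t = t_new
    return t


def brute_force_gaps(
    centres: np.ndarray,
    radii: np.ndarray,
    mode: str = "nearest_neighbour",
    cutoff: float = 20.0,
) -> list[float]:
    """All surface-to-surface gaps by explicit double loop."""
    n = len(radii)
    gaps = []
    if mode == "nearest_neighbour":
        for i in range(n):
            best = math.inf
            for j in range(n):
                if i == j:
                    continue
                d = math.dist(centres[i], centres[j]) - radii[i] - radii[j]
                best = min(best, d)
            gaps.append(best)
    elif mode == "all_pairs":
        for i in range(n):
            for j in range(i + 1, n):
                d = math.dist(centres[i], centres[j]) - radii[i] - radii[j]
                if d <= cutoff:
                    gaps.append(d)
    else:
        raise ValueError(mode)
    return gaps


def brute_force_overlap_check(centres: np.ndarray, radii: np.ndarray) -> bool:
    """True if no pair of spheres overlaps (all gaps >= 0)."""
    n = len(radii)
    for i in range(n):
        for j in range(i + 1, n):
            if math.dist(centres[i], centres[j]) < radii[i] + radii[j]:
                return False
    return True


def shell_counts(
    centres: np.ndarray, centre: np.ndarray, n_shells: int, rmax: float
) -> list[int]:
    """Count centres per equal-width spherical shell (outer edge inclusive)."""
    counts = [0] * n_shells
    width = rmax / n_shells
    for c in centres:
        d = math.dist(c, centre)
        idx = min(int(d / width), n_shells - 1)
        counts[idx] += 1
    return counts
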