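"""Statistics on segmented vesicle sphere clouds from cryo-electron tomograms.

The input abstraction is a table of manually segmented spheres (3D centres
in nm plus radii in nm).  Three analyses are provided:

* surface-to-surface gap statistics — ``gap(i, j) = ||c_i - c_j|| - r_i - r_j``,
  either per-vesicle nearest neighbour or all pairs within a cutoff;
* radius distribution (mean, SEM, histogram);
* radial density profile relative to the condensate centre, which reports
  how vesicle concentration falls off toward the phase border.

Overlapping spheres (negative gaps) can occur in manual segmentations; they
are retained and flagged rather than silently dropped, with an explicit
``exclude_overlaps`` switch for the summary statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger("condensate_metrics")

__all__ = [
    "VesicleSet",
    "GapStats",
    "surface_gaps",
    "radius_stats",
    "radial_density_profile",
]


@dataclass
class VesicleSet:
    """A cloud of spheres: centres (n, 3) in nm, radii (n,) in nm."""

    centres: np.ndarray
    radii: np.ndarray
    tomogram_id: str = ""

    def __post_init__(self) -> None:
        self.centres = np.atleast_2d(np.asarray(self.centres, dtype=float))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if self.centres.shape != (len(self.radii), 3):
            raise ValueError("centres must be (n, 3) matching radii length n")
        if not np.all(np.isfinite(self.centres)):
            raise ValueError("centres must be finite")
        if np.any(self.radii <= 0) or not np.all(np.isfinite(self.radii)):
            raise ValueError("radii must be positive and finite")

    def __len__(self) -> int:
        return len(self.radii)

    @classmethod
    def from_table(cls, table: pd.DataFrame, tomogram_id: str = "") -> "VesicleSet":
        """Build from a table with columns x_nm, y_nm, z_nm, radius_nm."""
        centres = table[["x_nm", "y_nm", "z_nm"]].to_numpy(float)
        return cls(centres=centres, radii=table["radius_nm"].to_numpy(float),
                   tomogram_id=tomogram_id or str(table.get("tomogram_id", "")))

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tomogram_id": self.tomogram_id,
                "x_nm": self.centres[:, 0],
                "y_nm": self.centres[:, 1],
                "z_nm": self.centres[:, 2],
                "radius_nm": self.radii,
            }
        )


@dataclass
class GapStats:
    """Summary of surface-to-surface gaps.

    ``mode`` is ``"nearest_neighbour"`` (one gap per vesicle) or
    ``"all_pairs"`` (every unordered pair with gap <= cutoff).  Negative
    gaps mark overlapping segmented spheres; ``n_negative`` counts them.
    SEM is the n−1 sample standard deviation over sqrt(n).
    """

    gaps_nm: np.ndarray
    mean_nm: float
    sem_nm: float | None
    n: int
    mode: str
    cutoff_nm: float | None = None
    n_negative: int = 0
    pairs: np.ndarray | None = field(default=None, repr=False)


def _summary(gaps: np.ndarray) -> tuple[float, float | None]:
    mean = float(gaps.mean())
    sem = float(gaps.std(ddof=1) / np.sqrt(gaps.size)) if gaps.size > 1 else None
    return mean, sem


def surface_gaps(
    vs: VesicleSet,
    mode: str = "nearest_neighbour",
    cutoff_nm: float = 20.0,
    exclude_overlaps: bool = False,
) -> GapStats:
    """Surface-to-surface gap statistics of a sphere cloud.

    Parameters
    ----------
    vs
        At least two vesicles.
    mode
        ``"nearest_neighbour"``: per vesicle, the minimum gap to any other
        vesicle (n = vesicle count).  ``"all_pairs"``: every unordered pair
        with gap <= ``cutoff_nm``.
    exclude_overlaps
        Drop negative gaps from the summary mean/SEM (they remain counted
        in ``n_negative``); by default they are retained to avoid biasing
        the mean.
    """
    n = len(vs)
    if n < 2:
        raise ValueError("surface gaps need at least 2 vesicles")
    dist = cdist(vs.centres, vs.centres)
    gap_matrix = dist - vs.radii[:, None] - vs.radii[None, :]
    np.fill_diagonal(gap_matrix, np.inf)

    if mode == "nearest_neighbour":
        gaps = gap_matrix.min(axis=1)
        pairs = np.column_stack([np.arange(n), gap_matrix.argmin(axis=1)])
    elif mode == "all_pairs":
        iu, ju = np.triu_indices(n, k=1)
        sel = gap_matrix[iu, ju] <= cutoff_nm
        gaps = gap_matrix[iu, ju][sel]
        pairs = np.column_stack([iu[sel], ju[sel]])
    else:
        raise ValueError("mode must be 'nearest_neighbour' or 'all_pairs'")

    n_negative = int((gaps < 0).sum())
    if n_negative:
        logger.warning("%d overlapping sphere pair(s) (negative gaps) in %s",
                       n_negative, vs.tomogram_id or "vesicle set")
    kept = gaps[gaps >= 0] if exclude_overlaps else gaps
    if kept.size == 0:
        raise ValueError("no gaps left to summarise")
    mean, sem = _summary(kept)
    return GapStats(
        gaps_nm=gaps,
        mean_nm=mean,
        sem_nm=sem,
        n=int(kept.size),
        mode=mode,
        cutoff_nm=cutoff_nm if mode == "all_pairs" else None,
        n_negative=n_negative,
        pairs=pairs,
    )


def radius_stats(
    vs: VesicleSet, bin_width_nm: float = 0.5
) -> tuple[float, float | None, int, pd.DataFrame]:
    """Mean radius, SEM (None for a single vesicle), n, and a histogram.

    The histogram uses equal-width bins of ``bin_width_nm`` spanning the
    data; returned as a table with columns bin_left_nm, bin_right_nm, count.
    """
    r = vs.radii
    mean = float(r.mean())
    sem = float(r.std(ddof=1) / np.sqrt(r.size)) if r.size > 1 else None
    lo = np.floor(r.min() / bin_width_nm) * bin_width_nm
    hi = np.ceil(r.max() / bin_width_nm) * bin_width_nm
    n_bins = max(1, int(round((hi - lo) / bin_width_nm)))
    counts, edges = np.histogram(r, bins=n_bins, range=(lo, hi))
    hist = pd.DataFrame(
        {"bin_left_nm": edges[:-1], "bin_right_nm": edges[1:], "count": counts}
    )
    return mean, sem, int(r.size), hist


def radial_density_profile(
    vs: VesicleSet,
    centre: np.ndarray | str = "auto",
    n_shells: int = 10,
) -> pd.DataFrame:
    """Vesicle count and number density in concentric spherical shells.

    Shells are ``n_shells`` equal-width bands from ``centre`` (``"auto"`` =
    centroid of the sphere centres) out to the maximal centre distance.
    Density is count per shell volume (nm^-3).  Returns a table with
    columns shell_index, r_inner_nm, r_outer_nm, count, density_per_nm3.

    Raises
    ------
    ValueError
        If all centres coincide (no radial extent to profile) — except for
        a single vesicle, where the shells span its own radius.
    """
    if n_shells < 2:
        raise ValueError("n_shells must be >= 2")
    if isinstance(centre, str):
        if centre != "auto":
            raise ValueError("centre must be coordinates or 'auto'")
        c = vs.centres.mean(axis=0)
    else:
        c = np.asarray(centre, float)
    d = np.linalg.norm(vs.centres - c, axis=1)
    rmax = float(d.max())
    if rmax == 0.0:
        if len(vs) == 1:
            rmax = float(vs.radii[0])
        else:
            raise ValueError("degenerate vesicle set: all centres identical")
    edges = np.linspace(0.0, rmax, n_shells + 1)
    # the outer edge is inclusive so the farthest vesicle lands in the last shell
    idx = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_shells - 1)
    counts = np.bincount(idx, minlength=n_shells)
    volumes = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    return pd.DataFrame(
        {
            "shell_index": np.arange(n_shells),
            "r_inner_nm": edges[:-1],
            "r_outer_nm": edges[1:],
            "count": counts,
            "density_per_nm3": counts / volumes,
        }
    )
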