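"""Loop calling: cluster significant pixels, pick centres, merge resolutions.

Significant pixels are grouped with DBSCAN using a neighbourhood radius of 1
(Euclidean), which on the integer pixel lattice means two pixels are
neighbours only if they are 4-adjacent (diagonal neighbours are sqrt(2)
apart); every point is treated as a core point, so clusters are exactly the
4-connected components of the significant-pixel set.  Components smaller
than ``min_cluster`` are noise.  Each surviving cluster yields one loop
whose coordinates come from the cluster centre: the brightest pixel
(default, ties broken by smallest ``(i, j)``) or the per-axis arithmetic
mean rounded half-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .background import significant_pixel_mask
from .matrix import ContactMatrix, GenomicInterval, pixel_to_anchors
from .presets import Preset

__all__ = [
    "Cluster",
    "Loop",
    "LoopSet",
    "cluster_pixels",
    "cluster_center",
    "call_loops",
    "merge_resolutions",
]


@dataclass(frozen=True)
class Cluster:
    """A 4-connected component of significant pixels."""

    pixels: tuple[tuple[int, int], ...]

    @property
    def size(self) -> int:
        return len(self.pixels)


@dataclass
class Loop:
    """A called chromatin loop: two genomic anchors and the centre pixel."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    center: tuple[int, int]
    resolution: int
    q_adj: float = math.nan
    cluster_size: int = 0
    scores: dict = field(default_factory=dict)

    @property
    def chrom(self) -> str:
        return self.anchor1.chrom

    @property
    def span(self) -> tuple[int, int]:
        """1-D genomic span between the loop base points, half-open."""
        return self.anchor1.start, self.anchor2.end

    @property
    def distance(self) -> int:
        """Genomic separation between anchor midpoints, bp."""
        return int(self.anchor2.midpoint - self.anchor1.midpoint)


@dataclass
class LoopSet:
    """An ordered collection of loops plus calling provenance."""

    loops: list[Loop] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.loops)

    def __iter__(self):
        return iter(self.loops)

    def __getitem__(self, k: int) -> Loop:
        return self.loops[k]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for n, lp in enumerate(self.loops):
            rows.append(
                {
                    "chrom1": lp.anchor1.chrom,
                    "start1": lp.anchor1.start,
                    "end1": lp.anchor1.end,
                    "chrom2": lp.anchor2.chrom,
                    "start2": lp.anchor2.start,
                    "end2": lp.anchor2.end,
                    "name": f"loop_{n + 1}",
                    "q_adj": lp.q_adj,
                    "resolution": lp.resolution,
                    **lp.scores,
                }
            )
        return pd.DataFrame(rows)


def cluster_pixels(
    calls: pd.DataFrame,
    min_cluster: int = 3,
    connectivity: int = 4,
) -> list[Cluster]:
    """Group significant pixels into clusters of adjacent pixels.

    Parameters
    ----------
    calls
        Significant pixels with integer columns ``i`` and ``j``.
    min_cluster
        Minimum component size; smaller components are noise.
    connectivity
        4 (neighbour = Euclidean distance <= 1, the default geometry) or
        8 (distance <= sqrt(2), including diagonal neighbours).
    """
    if min_cluster < 1:
        raise ValueError("min_cluster must be >= 1")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if len(calls) == 0:
        return []
    coords = calls[["i", "j"]].to_numpy(dtype=float)
    eps = 1.0 if connectivity == 4 else math.sqrt(2.0) + 1e-9
    labels = DBSCAN(eps=eps, min_samples=1).fit_predict(coords)
    clusters = []
    ij = calls[["i", "j"]].to_numpy(dtype=int)
    for lab in np.unique(labels):
        members = ij[labels == lab]
        if len(members) >= min_cluster:
            members = members[np.lexsort((members[:, 1], members[:, 0]))]
            clusters.append(Cluster(tuple(map(tuple, members))))
    clusters.sort(key=lambda c: c.pixels[0])
    return clusters


def cluster_center(
    cluster: Cluster, cm: ContactMatrix, method: str = "brightest"
) -> tuple[int, int]:
    """Centre pixel of a cluster.

    ``brightest`` (default): the member with maximal intensity, ties broken
    by the lexicographically smallest ``(i, j)``.  ``mean``: per-axis
    arithmetic mean of member coordinates, rounded half-up to the nearest
    bin.
    """
    if cluster.size == 0:
        raise ValueError("empty cluster")
    if method == "brightest":
        best = max(
            cluster.pixels,
            key=lambda px: (cm.get(*px), (-px[0], -px[1])),
        )
        return best
    if method == "mean":
        arr = np.asarray(cluster.pixels, dtype=float)
        # round half-up, not banker's rounding
        ci, cj = (int(math.floor(x + 0.5)) for x in arr.mean(axis=0))
        return ci, cj
    raise ValueError(f"unknown centre method {method!r}")


def call_loops(cm: ContactMatrix, preset: Preset | None = None) -> LoopSet:
    """Call loops on one matrix: significance scan -> clustering -> centres.

    Scores (APA, PA, ...) are left unset; apply the filter stage separately.
    """
    preset = preset or Preset()
    result = significant_pixel_mask(
        cm,
        fit_quantile=preset.q,
        q_threshold=preset.q_value_trhd,
        scaling_threshold=preset.scaling_q_value_trhd,
        adjust=preset.adjust_by_scale,
        max_distance=preset.max_distance,
        include_zeros=preset.include_zeros,
        bh_scope=preset.bh_scope,
    )
    qmap = {
        (int(r.i), int(r.j)): float(r.q_adj)
        for r in result.calls.itertuples()
    }
    clusters = cluster_pixels(
        result.calls, preset.min_cluster, preset.connectivity
    )
    loops, seen = [], set()
    for cl in clusters:
        center = cluster_center(cl, cm, preset.center_method)
        if center in seen:  # possible only with the mean-centre rule
            continue
        seen.add(center)
        a1, a2 = pixel_to_anchors(cm, *center)
        loops.append(
            Loop(
                anchor1=a1,
                anchor2=a2,
                center=center,
                resolution=cm.resolution,
                q_adj=qmap.get(center, math.nan),
                cluster_size=cl.size,
            )
        )
    return LoopSet(
        loops=loops,
        provenance={
            "chrom": cm.chrom,
            "resolution": cm.resolution,
            "preset": preset.to_dict(),
            "n_significant_pixels": result.n_significant,
            "n_tested_pixels": result.n_tested,
        },
    )


def merge_resolutions(
    fine: LoopSet, coarse: LoopSet, frac: float = 0.7
) -> LoopSet:
    """Merge loop sets called at two resolutions, keeping the finer call
    wherever a fine and a coarse loop overlap reciprocally at >= ``frac``."""
    from .compare import reciprocal_overlap

    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    merged = list(fine.loops)
    for lc in coarse:
        if not any(reciprocal_overlap(lf, lc, frac) for lf in fine):
            merged.append(replace(lc))
    return LoopSet(
        loops=merged,
        provenance={
            "merged_from": [fine.provenance, coarse.provenance],
            "merge_frac": frac,
        },
    )
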