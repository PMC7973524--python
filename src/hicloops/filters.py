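"""Loop scoring and filtering.

Every called loop is scored on an 11 x 11 intensity window centred on its
pixel:

* **APA score** — centre intensity over the mean of a 3 x 3 corner patch of
  the window.  The default corner is the one pointing toward the matrix
  diagonal (shorter genomic distance), where the patch reflects the local
  expected background, as in aggregate peak analysis.
* **PA score** — mean, over the 8 pixels adjacent to the centre, of the
  ratio pixel / corner-patch mean.
* **zeros count** — number of zero pixels in the 3 x 3 neighbourhood of the
  centre (an artifact guard: loops sitting on unmappable patches are
  unreliable).
* **decay** — the radial profile must not increase: centre >= mean of the
  8-neighbour ring >= mean of the radius-2 ring.
* **random-distance enrichment** — centre intensity over the mean of
  ``n_random`` pixels sampled from the same diagonal (seeded).

Loops whose 11 x 11 window does not fit inside the matrix are *exempt* from
window-based filters (scored NaN) rather than dropped, to avoid biasing
against short-range loops near the matrix edge.  Filters are pure
conjunctive predicates: applying them is idempotent and order-independent,
and both scores are invariant under a global rescaling of the matrix.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .loops import Loop, LoopSet
from .matrix import ContactMatrix, extract_diagonal
from .presets import Preset

__all__ = [
    "FilterConfig",
    "apa_score",
    "pa_score",
    "zeros_count",
    "decay_check",
    "random_distance_enrichment",
    "apply_filters",
]

WINDOW_RADIUS = 5  # 11 x 11 window
CORNER_SIZE = 3

# slices of the 11x11 window array w[r, c] where w[r, c] = cm[i-5+r, j-5+c];
# "short" is the corner at max i / min j, i.e. toward the matrix diagonal
# (shorter genomic distance) -- the default background corner.
_CORNERS = {
    "short": (slice(8, 11), slice(0, 3)),
    "long": (slice(0, 3), slice(8, 11)),
    "low": (slice(8, 11), slice(8, 11)),
    "high": (slice(0, 3), slice(0, 3)),
}


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the loop filters; ``None`` disables a filter."""

    filter_APA: float | None = None
    filter_PA: float | None = None
    filter_intensity: float | None = None
    filter_zeros: int | None = None
    decay_required: bool = False
    random_enrichment_min: float | None = None
    n_random: int = 100
    seed: int = 0
    corner: str = "short"

    def __post_init__(self) -> None:
        for name in ("filter_APA", "filter_PA", "filter_intensity",
                     "random_enrichment_min"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.filter_zeros is not None and self.filter_zeros < 0:
            raise ValueError("filter_zeros must be >= 0")
        if self.corner not in _CORNERS:
            raise ValueError(f"corner must be one of {sorted(_CORNERS)}")

    @classmethod
    def from_preset(cls, preset: Preset, seed: int = 0) -> "FilterConfig":
        return cls(
            filter_APA=preset.filter_APA,
            filter_PA=preset.filter_PA,
            filter_intensity=preset.filter_intensity,
            filter_zeros=preset.filter_zeros,
            decay_required=preset.decay_required,
            random_enrichment_min=preset.random_enrichment_min,
            n_random=preset.n_random,
            seed=seed,
        )


def _corner_mean(window: np.ndarray, corner: str) -> float:
    return float(window[_CORNERS[corner]].mean())


def apa_score(cm: ContactMatrix, loop: Loop, corner: str = "short") -> float:
    """Centre intensity over the mean of the 3x3 background corner patch.

    NaN (exempt) when the window is clipped by the matrix edge or the
    corner mean is zero.
    """
    w = cm.window(*loop.center, WINDOW_RADIUS)
    if w is None:
        return math.nan
    bg = _corner_mean(w, corner)
    if bg == 0:
        return math.nan
    return float(w[WINDOW_RADIUS, WINDOW_RADIUS] / bg)


def pa_score(cm: ContactMatrix, loop: Loop, corner: str = "short") -> float:
    """Mean ratio of the 8 centre-adjacent pixels to the corner-patch mean."""
    w = cm.window(*loop.center, WINDOW_RADIUS)
    if w is None:
        return math.nan
    bg = _corner_mean(w, corner)
    if bg == 0:
        return math.nan
    c = WINDOW_RADIUS
    ring = w[c - 1 : c + 2, c - 1 : c + 2].copy()
    ring[1, 1] = np.nan
    return float(np.nanmean(ring) / bg)


def zeros_count(cm: ContactMatrix, loop: Loop) -> int:
    """Zero pixels in the 3x3 neighbourhood of the loop centre.

    Cells outside the matrix are not counted as zeros.
    """
    i, j = loop.center
    n = 0
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            r, c = i + di, j + dj
            if 0 <= r < cm.n_bins and 0 <= c < cm.n_bins:
                if cm.get(r, c) == 0:
                    n += 1
    return n


def _ring_mean(w: np.ndarray, radius: int) -> float:
    c = WINDOW_RADIUS
    sub = w[c - radius : c + radius + 1, c - radius : c + radius + 1]
    inner = (2 * radius - 1) ** 2
    return float((sub.sum() - w[c - radius + 1 : c + radius, c - radius + 1 : c + radius].sum()) / (sub.size - inner))


def decay_check(cm: ContactMatrix, loop: Loop) -> bool:
    """Non-increasing radial profile: centre >= ring-1 mean >= ring-2 mean.

    Loops whose window is clipped are exempt (returns True).
    """
    w = cm.window(*loop.center, WINDOW_RADIUS)
    if w is None:
        return True
    c = WINDOW_RADIUS
    center = float(w[c, c])
    ring1 = _ring_mean(w, 1)
    ring2 = _ring_mean(w, 2)
    return center >= ring1 >= ring2


def random_distance_enrichment(
    cm: ContactMatrix, loop: Loop, n_random: int = 100, seed: int = 0
) -> float:
    """Centre intensity over the mean of pixels sampled at the same distance.

    Samples ``n_random`` mappable pixels uniformly from the loop's diagonal
    (with replacement when the diagonal is shorter); deterministic under
    ``seed``.  NaN (exempt) when the diagonal has no mappable pixels or
    zero mean.
    """
    i, j = loop.center
    dv = extract_diagonal(cm, j - i)
    pool = dv.values[dv.mappable]
    if pool.size == 0:
        return math.nan
    rng = np.random.default_rng(seed)
    sample = rng.choice(pool, size=n_random, replace=n_random > pool.size)
    bg = float(sample.mean())
    if bg == 0:
        return math.nan
    return float(cm.get(i, j) / bg)


def _passes(score: float, threshold: float | None) -> bool:
    # NaN = exempt from window-based filters
    return threshold is None or math.isnan(score) or score >= threshold


def apply_filters(
    cm: ContactMatrix, loops: LoopSet, cfg: FilterConfig
) -> LoopSet:
    """Score every loop and keep those passing all enabled filters.

    All scores are attached to every loop (kept or not enabled alike);
    the surviving set is the conjunction of the enabled predicates and does
    not depend on the order of application.  Attrition counts per filter go
    into the result's provenance.
    """
    kept = []
    attrition = {k: 0 for k in
                 ("APA", "PA", "intensity", "zeros", "decay", "random")}
    for loop in loops:
        apa = apa_score(cm, loop, cfg.corner)
        pa = pa_score(cm, loop, cfg.corner)
        intensity = cm.get(*loop.center)
        zeros = zeros_count(cm, loop)
        decay = decay_check(cm, loop)
        rnd = random_distance_enrichment(cm, loop, cfg.n_random, cfg.seed)
        loop.scores.update(
            {
                "APA": apa,
                "PA": pa,
                "intensity": intensity,
                "zeros": zeros,
                "decay": decay,
                "random_enrichment": rnd,
                "edge_exempt": math.isnan(apa) and cm.window(*loop.center, WINDOW_RADIUS) is None,
            }
        )
        ok = True
        if not _passes(apa, cfg.filter_APA):
            attrition["APA"] += 1
            ok = False
        if not _passes(pa, cfg.filter_PA):
            attrition["PA"] += 1
            ok = False
        if cfg.filter_intensity is not None and intensity < cfg.filter_intensity:
            attrition["intensity"] += 1
            ok = False
        if cfg.filter_zeros is not None and zeros > cfg.filter_zeros:
            attrition["zeros"] += 1
            ok = False
        if cfg.decay_required and not decay:
            attrition["decay"] += 1
            ok = False
        if not _passes(rnd, cfg.random_enrichment_min):
            attrition["random"] += 1
            ok = False
        if ok:
            kept.append(loop)
    return LoopSet(
        loops=kept,
        provenance={
            **loops.provenance,
            "filter_config": asdict(cfg),
            "filter_attrition": attrition,
            "n_before_filters": len(loops),
        },
    )
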