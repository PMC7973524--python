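"""Loop-set comparison by reciprocal overlap.

Two loops overlap if the intersection of their 1-D spans (upstream-anchor
start to downstream-anchor end) covers at least a fraction ``frac`` of
*each* span (default 0.7).  An anchor-wise mode requiring both anchors to
overlap reciprocally is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

from .loops import Loop, LoopSet

__all__ = ["OverlapStats", "reciprocal_overlap", "compare_loop_sets"]


@dataclass(frozen=True)
class OverlapStats:
    n_a: int
    n_b: int
    n_overlap_a: int
    n_overlap_b: int

    @property
    def frac_a(self) -> float:
        return self.n_overlap_a / self.n_a if self.n_a else 0.0

    @property
    def frac_b(self) -> float:
        return self.n_overlap_b / self.n_b if self.n_b else 0.0


def _interval_reciprocal(a: tuple[int, int], b: tuple[int, int], frac: float) -> bool:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return False
    return inter >= frac * (a[1] - a[0]) and inter >= frac * (b[1] - b[0])


def reciprocal_overlap(
    a: Loop, b: Loop, frac: float = 0.7, mode: str = "span"
) -> bool:
    """True when the two loops overlap reciprocally at >= ``frac``.

    ``mode="span"`` (default) compares the full spans between loop base
    points; ``mode="anchors"`` requires both anchor pairs to overlap
    reciprocally.  Loops on different chromosomes never overlap.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    if a.chrom != b.chrom:
        return False
    if mode == "span":
        return _interval_reciprocal(a.span, b.span, frac)
    if mode == "anchors":
        return _interval_reciprocal(
            (a.anchor1.start, a.anchor1.end), (b.anchor1.start, b.anchor1.end), frac
        ) and _interval_reciprocal(
            (a.anchor2.start, a.anchor2.end), (b.anchor2.start, b.anchor2.end), frac
        )
    raise ValueError(f"unknown mode {mode!r}")


def compare_loop_sets(
    a: LoopSet, b: LoopSet, frac: float = 0.7, mode: str = "span"
) -> OverlapStats:
    """Fraction of each set matched by the other (any-counterpart rule).

    Each loop counts as overlapped if at least one loop of the other set
    satisfies :func:`reciprocal_overlap`; matches are not one-to-one.
    """
    hit_a = [False] * len(a)
    hit_b = [False] * len(b)
    for ia, la in enumerate(a):
        for ib, lb in enumerate(b):
            if hit_a[ia] and hit_b[ib]:
                continue
            if reciprocal_overlap(la, lb, frac, mode):
                hit_a[ia] = True
                hit_b[ib] = True
    return OverlapStats(
        n_a=len(a),
        n_b=len(b),
        n_overlap_a=sum(hit_a),
        n_overlap_b=sum(hit_b),
    )
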