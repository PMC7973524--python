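"""BEDPE / TSV readers and writers for loops and significant contacts.

Loops are written as standard 10-column BEDPE (chrom1 start1 end1 chrom2
start2 end2 name score strand1 strand2) followed by extra columns carrying
the q-value, APA, PA, centre intensity and calling resolution; anchor1 is
always the upstream anchor.  Floats are formatted to 6 significant digits,
which the round-trip reader restores exactly at that precision.  Header
lines start with ``#`` and echo the writer version; no timestamps, so a
repeated run is byte-identical.
"""

from __future__ import annotations

import math

import pandas as pd

from . import __version__
from .loops import Loop, LoopSet
from .matrix import GenomicInterval

__all__ = ["write_loops_bedpe", "read_loops_bedpe", "write_contacts_tsv"]

_EXTRA_COLS = ["q_adj", "APA", "PA", "intensity", "resolution"]


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "."
    if isinstance(x, bool):
        return str(int(x))
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def _bed_score(q: float) -> int:
    """Conventional 0-1000 BED score from the q-value (higher = stronger)."""
    if q is None or math.isnan(q) or q <= 0:
        return 1000
    return min(1000, int(round(-100.0 * math.log10(q)))) if q < 1 else 0


def write_loops_bedpe(loops: LoopSet, path: str, header: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# hicloops v{__version__} loops\n")
        for k, v in (header or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write(
            "# chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore\t"
            "strand1\tstrand2\t" + "\t".join(_EXTRA_COLS) + "\n"
        )
        for n, lp in enumerate(loops):
            extra = [
                _fmt(lp.q_adj),
                _fmt(lp.scores.get("APA", math.nan)),
                _fmt(lp.scores.get("PA", math.nan)),
                _fmt(lp.scores.get("intensity", math.nan)),
                str(lp.resolution),
            ]
            fields = [
                lp.anchor1.chrom,
                str(lp.anchor1.start),
                str(lp.anchor1.end),
                lp.anchor2.chrom,
                str(lp.anchor2.start),
                str(lp.anchor2.end),
                f"loop_{n + 1}",
                str(_bed_score(lp.q_adj)),
                ".",
                ".",
                *extra,
            ]
            fh.write("\t".join(fields) + "\n")


def _parse_float(tok: str) -> float:
    return math.nan if tok == "." else float(tok)


def read_loops_bedpe(path: str) -> LoopSet:
    loops = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            t = line.split("\t")
            a1 = GenomicInterval(t[0], int(t[1]), int(t[2]))
            a2 = GenomicInterval(t[3], int(t[4]), int(t[5]))
            resolution = int(t[14]) if len(t) > 14 else len(a1)
            loop = Loop(
                anchor1=a1,
                anchor2=a2,
                center=(a1.start // resolution, a2.start // resolution),
                resolution=resolution,
                q_adj=_parse_float(t[10]) if len(t) > 10 else math.nan,
            )
            if len(t) > 13:
                loop.scores = {
                    "APA": _parse_float(t[11]),
                    "PA": _parse_float(t[12]),
                    "intensity": _parse_float(t[13]),
                }
            loops.append(loop)
    return LoopSet(loops=loops, provenance={"path": path})


def write_contacts_tsv(contacts: pd.DataFrame, path: str, header: dict | None = None) -> None:
    """Significant contacts (or EP interactions) as a commented TSV."""
    with open(path, "w") as fh:
        fh.write(f"# hicloops v{__version__} contacts\n")
        for k, v in (header or {}).items():
            fh.write(f"# {k}={v}\n")
        contacts.to_csv(fh, sep="\t", index=False, float_format="%.6g")
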