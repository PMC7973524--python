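"""Balanced Hi-C contact matrices: loading, diagonal access, coordinate mapping.

A :class:`ContactMatrix` holds one intrachromosomal, balanced (bias-corrected)
contact map at a fixed bin resolution, stored as a sparse upper-triangular
matrix together with a per-bin validity mask (bins whose balancing weight is
non-finite are unmappable and excluded from all statistics).

Two container formats are supported:

* cooler-schema HDF5 containers — single-resolution ``.cool`` files and
  multi-resolution ``.mcool`` files addressed as ``path::/resolutions/<res>``,
  read and written directly through :mod:`h5py`;
* a plain-text sparse-triplet fallback (``bin1 bin2 value`` rows with a
  ``#``-comment header carrying chrom / resolution / n_bins), so that fixtures
  need no binary dependencies.

Coordinates follow the BED convention throughout: bins are 0-based, genomic
intervals are 0-based half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import scipy.sparse as sp

__all__ = [
    "GenomicInterval",
    "DiagonalValues",
    "ContactMatrix",
    "MissingResourceError",
    "MatrixConfigError",
    "load_matrix",
    "extract_diagonal",
    "pixel_to_anchors",
    "write_cool",
    "write_text_matrix",
]


class MissingResourceError(KeyError):
    """A named resource (chromosome, dataset) is absent from the container."""


class MatrixConfigError(ValueError):
    """The container cannot satisfy the requested configuration
    (missing resolution, unbalanced data requested as balanced, ...)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom`` (0-based bp)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        """At least 1 bp of overlap (same chromosome)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class DiagonalValues:
    """Pixel intensities along one diagonal of a contact matrix.

    ``values[k]`` is the intensity of pixel ``(k, k + d)``; entries absent
    from sparse storage are reported as zero.  Two masks qualify the entries:

    * ``mappable`` — both bins have finite balancing weights (structural
      validity).  Unmappable entries never enter any statistic.
    * ``valid`` — mappable *and* non-zero.  This is the default fitting mask;
      whether mappable zeros enter the background fit is controlled by the
      background module's ``include_zeros`` switch.
    """

    d: int
    values: np.ndarray
    mappable: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mappable = np.asarray(self.mappable, dtype=bool)
        if self.values.shape != self.mappable.shape:
            raise ValueError("values and mappable mask differ in length")

    @property
    def valid(self) -> np.ndarray:
        return self.mappable & (self.values > 0)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ContactMatrix:
    """Balanced intrachromosomal contact map at a fixed resolution.

    Storage is upper-triangular (``i <= j``); access is symmetric, i.e.
    querying ``(j, i)`` returns the ``(i, j)`` value.
    """

    chrom: str
    resolution: int
    n_bins: int
    matrix: sp.csr_matrix
    bin_valid: np.ndarray
    balanced: bool = True
    provenance: dict = field(default_factory=dict)

    @classmethod
    def from_pixels(
        cls,
        chrom: str,
        resolution: int,
        n_bins: int,
        bin1: np.ndarray,
        bin2: np.ndarray,
        values: np.ndarray,
        bin_valid: np.ndarray | None = None,
        balanced: bool = True,
    ) -> "ContactMatrix":
        bin1 = np.asarray(bin1, dtype=np.int64)
        bin2 = np.asarray(bin2, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        lo = np.minimum(bin1, bin2)
        hi = np.maximum(bin1, bin2)
        if lo.size and (lo.min() < 0 or hi.max() >= n_bins):
            raise ValueError("pixel indices out of range")
        keep = np.isfinite(values) & (values != 0)
        mat = sp.coo_matrix(
            (values[keep], (lo[keep], hi[keep])), shape=(n_bins, n_bins)
        ).tocsr()
        if bin_valid is None:
            bin_valid = np.ones(n_bins, dtype=bool)
        return cls(
            chrom=chrom,
            resolution=resolution,
            n_bins=n_bins,
            matrix=mat,
            bin_valid=np.asarray(bin_valid, dtype=bool),
            balanced=balanced,
        )

    @classmethod
    def from_dense(
        cls,
        dense: np.ndarray,
        chrom: str = "chrS",
        resolution: int = 10_000,
        bin_valid: np.ndarray | None = None,
        balanced: bool = True,
    ) -> "ContactMatrix":
        """Build from a dense array; only the upper triangle is stored."""
        dense = np.asarray(dense, dtype=float)
        n = dense.shape[0]
        if dense.shape != (n, n):
            raise ValueError("dense matrix must be square")
        iu, ju = np.triu_indices(n)
        return cls.from_pixels(
            chrom, resolution, n, iu, ju, dense[iu, ju], bin_valid, balanced
        )

    def get(self, i: int, j: int) -> float:
        """Symmetric pixel access."""
        if i > j:
            i, j = j, i
        if not (0 <= i <= j < self.n_bins):
            raise IndexError(f"pixel ({i}, {j}) out of range")
        return float(self.matrix[i, j])

    def dense(self) -> np.ndarray:
        """Full symmetric dense array (small matrices only)."""
        upper = self.matrix.toarray()
        return upper + np.triu(upper, 1).T

    def window(self, i: int, j: int, radius: int) -> np.ndarray | None:
        """Square ``(2r+1)``-sized symmetric-access patch centred on (i, j).

        Returns ``None`` when the patch does not fit inside the matrix.
        """
        if (
            i - radius < 0
            or j - radius < 0
            or i + radius >= self.n_bins
            or j + radius >= self.n_bins
        ):
            return None
        rows = np.arange(i - radius, i + radius + 1)
        cols = np.arange(j - radius, j + radius + 1)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        lo = np.minimum(rr, cc)
        hi = np.maximum(rr, cc)
        return np.asarray(self.matrix[lo.ravel(), hi.ravel()]).reshape(rr.shape)

    def pixels(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Stored upper-triangular pixels as ``(bin1, bin2, value)`` arrays."""
        coo = self.matrix.tocoo()
        return coo.row, coo.col, coo.data


def extract_diagonal(cm: ContactMatrix, d: int) -> DiagonalValues:
    """Values along diagonal ``d`` (genomic separation ``d * resolution``).

    Entry ``k`` corresponds to pixel ``(k, k + d)``; absent pixels are zeros,
    and entries touching an unmappable bin are masked.
    """
    if not (0 <= d < cm.n_bins):
        raise IndexError(f"diagonal {d} out of range for {cm.n_bins} bins")
    values = cm.matrix.diagonal(k=d)
    mappable = cm.bin_valid[: cm.n_bins - d] & cm.bin_valid[d:]
    return DiagonalValues(d=d, values=values, mappable=mappable)


def pixel_to_anchors(
    cm: ContactMatrix, i: int, j: int
) -> tuple[GenomicInterval, GenomicInterval]:
    """Genomic anchor intervals of pixel ``(i, j)`` (upper triangle, i <= j)."""
    if i > j:
        raise ValueError(f"expected i <= j (upper triangle), got ({i}, {j})")
    if j >= cm.n_bins or i < 0:
        raise IndexError(f"pixel ({i}, {j}) out of range")
    res = cm.resolution
    return (
        GenomicInterval(cm.chrom, i * res, (i + 1) * res),
        GenomicInterval(cm.chrom, j * res, (j + 1) * res),
    )


# ---------------------------------------------------------------------------
# cooler-schema HDF5 containers
# ---------------------------------------------------------------------------

def _split_uri(path: str) -> tuple[str, str]:
    """Split ``file.mcool::/resolutions/10000`` into (file, group)."""
    if "::" in path:
        fpath, group = path.split("::", 1)
        return fpath, group or "/"
    return path, "/"


def _open_cooler_group(path: str, resolution: int | None):
    fpath, group = _split_uri(path)
    if not os.path.exists(fpath):
        raise FileNotFoundError(fpath)
    f = h5py.File(fpath, "r")
    try:
        if group != "/":
            if group not in f:
                raise MatrixConfigError(f"group {group!r} not in {fpath}")
            grp = f[group]
        elif "pixels" in f:
            grp = f["/"]
        elif "resolutions" in f:
            # multi-resolution container addressed without an explicit group
            if resolution is None:
                raise MatrixConfigError(
                    "multi-resolution container requires a resolution"
                )
            key = f"resolutions/{resolution}"
            if key not in f:
                avail = sorted(int(k) for k in f["resolutions"])
                raise MatrixConfigError(
                    f"resolution {resolution} not in container "
                    f"(available: {avail})"
                )
            grp = f[key]
        else:
            raise MatrixConfigError(f"{fpath} is not a cooler-schema container")
    except Exception:
        f.close()
        raise
    return f, grp


def _load_cooler(
    path: str, chrom: str, resolution: int | None, balanced: bool
) -> ContactMatrix:
    f, grp = _open_cooler_group(path, resolution)
    with f:
        binsize = int(grp.attrs.get("bin-size", 0)) or None
        if binsize is None:
            starts = grp["bins/start"][:2]
            binsize = int(starts[1] - starts[0]) if len(starts) > 1 else 1
        if resolution is not None and binsize != resolution:
            raise MatrixConfigError(
                f"container resolution {binsize} != requested {resolution}"
            )
        chrom_names = [
            c.decode() if isinstance(c, bytes) else str(c)
            for c in grp["chroms/name"][:]
        ]
        if chrom not in chrom_names:
            raise MissingResourceError(
                f"chromosome {chrom!r} not in container (has {chrom_names})"
            )
        cix = chrom_names.index(chrom)
        chrom_offset = grp["indexes/chrom_offset"][:]
        lo, hi = int(chrom_offset[cix]), int(chrom_offset[cix + 1])
        n_bins = hi - lo

        bin1_offset = grp["indexes/bin1_offset"][:]
        plo, phi = int(bin1_offset[lo]), int(bin1_offset[hi])
        bin1 = grp["pixels/bin1_id"][plo:phi]
        bin2 = grp["pixels/bin2_id"][plo:phi]
        count = grp["pixels/count"][plo:phi].astype(float)
        cis = (bin2 >= lo) & (bin2 < hi)
        bin1, bin2, count = bin1[cis] - lo, bin2[cis] - lo, count[cis]

        has_weights = "weight" in grp["bins"]
        if balanced:
            if not has_weights:
                raise MatrixConfigError(
                    "balanced matrix requested but container has no "
                    "'weight' column; pass balanced=False for raw counts"
                )
            w = grp["bins/weight"][lo:hi].astype(float)
            bin_valid = np.isfinite(w)
            wsafe = np.where(bin_valid, w, 0.0)
            values = count * wsafe[bin1] * wsafe[bin2]
        else:
            bin_valid = np.ones(n_bins, dtype=bool)
            values = count

    cm = ContactMatrix.from_pixels(
        chrom, binsize, n_bins, bin1, bin2, values, bin_valid, balanced
    )
    cm.provenance = {"path": path, "format": "cooler"}
    return cm


def write_cool(
    cm: ContactMatrix,
    path: str,
    weights: np.ndarray | None = None,
    chrom_length: int | None = None,
    group: str | None = None,
) -> None:
    """Write a single-chromosome cooler-schema ``.cool`` container.

    The stored pixel values are divided out of the written counts so that
    ``count * w_i * w_j`` reproduces the balanced values exactly; by default
    unit weights are used (NaN on invalid bins).  Passing
    ``group="/resolutions/<res>"`` appends the matrix into a
    multi-resolution (``.mcool``-style) container instead of overwriting.
    """
    n = cm.n_bins
    if weights is None:
        weights = np.ones(n, dtype=float)
    weights = np.where(cm.bin_valid, weights, np.nan)
    if chrom_length is None:
        chrom_length = n * cm.resolution
    bin1, bin2, values = cm.pixels()
    order = np.lexsort((bin2, bin1))
    bin1, bin2, values = bin1[order], bin2[order], values[order]
    wprod = weights[bin1] * weights[bin2]
    counts = np.where(np.isfinite(wprod) & (wprod > 0), values / wprod, 0.0)

    bin1_offset = np.searchsorted(bin1, np.arange(n + 1))
    mode = "w" if group is None else "a"
    with h5py.File(path, mode) as root:
        if group is None:
            f = root
        else:
            root.attrs["format"] = "HDF5::MCOOL"
            f = root.require_group(group)
        f.attrs["format"] = "HDF5::Cooler"
        f.attrs["format-version"] = 3
        f.attrs["bin-size"] = cm.resolution
        f.attrs["bin-type"] = "fixed"
        f.attrs["nbins"] = n
        f.attrs["nchroms"] = 1
        f.attrs["nnz"] = len(values)
        g = f.create_group("chroms")
        g.create_dataset("name", data=np.array([cm.chrom.encode()]))
        g.create_dataset("length", data=np.array([chrom_length], dtype=np.int64))
        g = f.create_group("bins")
        g.create_dataset("chrom", data=np.zeros(n, dtype=np.int32))
        starts = np.arange(n, dtype=np.int64) * cm.resolution
        g.create_dataset("start", data=starts)
        g.create_dataset(
            "end", data=np.minimum(starts + cm.resolution, chrom_length)
        )
        g.create_dataset("weight", data=weights)
        g = f.create_group("pixels")
        g.create_dataset("bin1_id", data=bin1.astype(np.int64))
        g.create_dataset("bin2_id", data=bin2.astype(np.int64))
        g.create_dataset("count", data=counts)
        g = f.create_group("indexes")
        g.create_dataset("chrom_offset", data=np.array([0, n], dtype=np.int64))
        g.create_dataset("bin1_offset", data=bin1_offset.astype(np.int64))


# ---------------------------------------------------------------------------
# plain-text sparse-triplet fallback
# ---------------------------------------------------------------------------

def write_text_matrix(cm: ContactMatrix, path: str) -> None:
    """Write the text-triplet fallback format (``bin1 bin2 value`` rows)."""
    bin1, bin2, values = cm.pixels()
    with open(path, "w") as fh:
        fh.write(
            f"# chrom={cm.chrom} resolution={cm.resolution} "
            f"n_bins={cm.n_bins} balanced={int(cm.balanced)}\n"
        )
        if not cm.bin_valid.all():
            bad = ",".join(map(str, np.flatnonzero(~cm.bin_valid)))
            fh.write(f"# invalid_bins={bad}\n")
        for i, j, v in zip(bin1, bin2, values):
            fh.write(f"{i} {j} {v:.10g}\n")


def _load_text(path: str, chrom: str | None, balanced: bool) -> ContactMatrix:
    header: dict[str, str] = {}
    b1, b2, vals = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        header[k] = v
                continue
            parts = line.split()
            b1.append(int(parts[0]))
            b2.append(int(parts[1]))
            vals.append(float(parts[2]))
    if "n_bins" not in header or "resolution" not in header:
        raise MatrixConfigError(
            f"{path}: text matrix header must carry resolution and n_bins"
        )
    file_chrom = header.get("chrom", "unknown")
    if chrom is not None and chrom != file_chrom:
        raise MissingResourceError(
            f"chromosome {chrom!r} not in file (file has {file_chrom!r})"
        )
    n_bins = int(header["n_bins"])
    bin_valid = np.ones(n_bins, dtype=bool)
    if "invalid_bins" in header and header["invalid_bins"]:
        bin_valid[[int(x) for x in header["invalid_bins"].split(",")]] = False
    cm = ContactMatrix.from_pixels(
        file_chrom,
        int(header["resolution"]),
        n_bins,
        np.array(b1, dtype=np.int64),
        np.array(b2, dtype=np.int64),
        np.array(vals, dtype=float),
        bin_valid,
        balanced=balanced,
    )
    cm.provenance = {"path": path, "format": "text"}
    return cm


def load_matrix(
    path: str,
    chrom: str | None = None,
    resolution: int | None = None,
    balanced: bool = True,
) -> ContactMatrix:
    """Load one intrachromosomal contact matrix.

    ``path`` may be a ``.cool`` file, an ``.mcool`` URI
    (``file.mcool::/resolutions/10000`` or plain path + ``resolution``),
    or a text-triplet fallback file.
    """
    fpath, _ = _split_uri(path)
    if os.path.exists(fpath) and h5py.is_hdf5(fpath):
        if chrom is None:
            raise ValueError("chrom is required for cooler containers")
        return _load_cooler(path, chrom, resolution, balanced)
    return _load_text(path, chrom, balanced)
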