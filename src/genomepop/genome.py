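"""Genome segmentation and nuclear geometry.

The diploid genome is represented as a chain of spherical chromatin domains
("beads"): each chromosome is segmented into fixed-size genomic bins (default
200 kb) and every bin of every homologous copy becomes one bead.  The nucleus
is a sphere or an ellipsoid centered at the origin; all coordinates are in
nanometres.  This module holds the index bookkeeping (haploid bin index *I*
versus diploid bead index *i*) and all radial / envelope arithmetic used by
the restraint engine and the feature calculators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomePopError",
    "GenomeSegmentation",
    "NuclearGeometry",
    "BeadGeometry",
    "segment_genome",
    "bead_radius_from_occupancy",
    "radial_norm",
    "distance_to_envelope",
]


class GenomePopError(ValueError):
    """Base error for invalid inputs anywhere in the package."""


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSegmentation:
    """Diploid binning of a genome into fixed-size chromatin domains.

    Haploid bins are enumerated chromosome by chromosome in input order; the
    diploid bead index enumerates copy 0 of every bin first, then copy 1 (two
    contiguous haploid blocks).  For a chromosome with copy number 1 only the
    copy-0 block contains its beads.

    Attributes
    ----------
    chromosomes:
        List of ``(name, length_bp, copy_number)``.
    bin_size:
        Bin size in base pairs.
    haploid_bins:
        List of ``(chrom, start, end)`` half-open 0-based intervals tiling
        each chromosome; the last bin of a chromosome may be short.
    """

    chromosomes: tuple[tuple[str, int, int], ...]
    bin_size: int
    haploid_bins: tuple[tuple[str, int, int], ...]
    # diploid bead i -> (haploid bin I, copy)
    copy_map: tuple[tuple[int, int], ...] = field(repr=False)

    @property
    def H(self) -> int:
        """Number of haploid genomic bins."""
        return len(self.haploid_bins)

    @property
    def N(self) -> int:
        """Number of diploid beads (sum of copy numbers over bins)."""
        return len(self.copy_map)

    def copy_number(self, haploid_index: int) -> int:
        chrom = self.haploid_bins[haploid_index][0]
        return self._cn_by_chrom[chrom]

    @property
    def _cn_by_chrom(self) -> dict[str, int]:
        return {name: cn for name, _, cn in self.chromosomes}

    @property
    def chrom_of_bin(self) -> np.ndarray:
        """Integer chromosome id per haploid bin (input chromosome order)."""
        order = {name: k for k, (name, _, _) in enumerate(self.chromosomes)}
        return np.array([order[c] for c, _, _ in self.haploid_bins], dtype=np.int64)

    @property
    def chrom_of_bead(self) -> np.ndarray:
        """Integer chromosome id per diploid bead."""
        cb = self.chrom_of_bin
        return cb[np.array([I for I, _ in self.copy_map], dtype=np.int64)]

    @property
    def bin_of_bead(self) -> np.ndarray:
        """Haploid bin index per diploid bead."""
        return np.array([I for I, _ in self.copy_map], dtype=np.int64)

    @property
    def copy_of_bead(self) -> np.ndarray:
        return np.array([c for _, c in self.copy_map], dtype=np.int64)

    def beads_of_bin(self, haploid_index: int) -> list[int]:
        """Diploid bead indices (one per copy, copy order) of a haploid bin."""
        return sorted(
            self._beads_by_bin[haploid_index],
            key=lambda i: self.copy_map[i][1],
        )

    @property
    def _beads_by_bin(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for i, (I, _) in enumerate(self.copy_map):
            out.setdefault(I, []).append(i)
        return out

    def bin_index(self, chrom: str, start: int) -> int:
        """Haploid bin index for a ``chrom:start`` locus token."""
        try:
            return self._bin_lookup[(chrom, start)]
        except KeyError:
            raise GenomePopError(
                f"locus {chrom}:{start} does not match any bin boundary"
            ) from None

    @property
    def _bin_lookup(self) -> dict[tuple[str, int], int]:
        return {(c, s): I for I, (c, s, _) in enumerate(self.haploid_bins)}

    def checksum(self) -> str:
        """Stable digest of the segmentation, used to guard file round trips."""
        import hashlib

        h = hashlib.sha1()
        h.update(str(self.bin_size).encode())
        for name, length, cn in self.chromosomes:
            h.update(f"{name}:{length}:{cn};".encode())
        return h.hexdigest()


def segment_genome(
    chrom_sizes: dict[str, int],
    bin_size: int = 200_000,
    ploidy: dict[str, int] | None = None,
) -> GenomeSegmentation:
    """Tile each chromosome with half-open ``bin_size`` bins and build the
    diploid bead index.

    Parameters
    ----------
    chrom_sizes:
        Mapping chromosome name -> length in bp (order is preserved).
    bin_size:
        Genomic bin size in bp (default 200 kb).
    ploidy:
        Mapping chromosome name -> copy number; default 2 everywhere.
    """
    if bin_size <= 0:
        raise GenomePopError(f"bin_size must be positive, got {bin_size}")
    ploidy = dict(ploidy or {})
    chroms: list[tuple[str, int, int]] = []
    bins: list[tuple[str, int, int]] = []
    for name, length in chrom_sizes.items():
        if length <= 0:
            raise GenomePopError(f"chromosome {name!r} has non-positive length {length}")
        cn = int(ploidy.get(name, 2))
        if cn < 1:
            raise GenomePopError(f"chromosome {name!r} has copy number {cn} < 1")
        chroms.append((name, int(length), cn))
        for start in range(0, length, bin_size):
            bins.append((name, start, min(start + bin_size, length)))
    # two contiguous haploid blocks: all copy-0 beads, then all copy-1 beads
    copy_map: list[tuple[int, int]] = []
    cn_of = {name: cn for name, _, cn in chroms}
    max_cn = max(cn_of.values())
    for copy in range(max_cn):
        for I, (chrom, _, _) in enumerate(bins):
            if copy < cn_of[chrom]:
                copy_map.append((I, copy))
    return GenomeSegmentation(
        chromosomes=tuple(chroms),
        bin_size=int(bin_size),
        haploid_bins=tuple(bins),
        copy_map=tuple(copy_map),
    )


# ---------------------------------------------------------------------------
# Nuclear geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NuclearGeometry:
    """Spherical or ellipsoidal nuclear envelope centered at the origin.

    ``semiaxes = (a, b, c)`` in nm with ``a >= b >= c > 0``; a sphere is
    ``a == b == c``.
    """

    semiaxes: tuple[float, float, float]

    def __post_init__(self) -> None:
        a, b, c = self.semiaxes
        if not (a >= b >= c > 0):
            raise GenomePopError(f"semiaxes must satisfy a >= b >= c > 0, got {self.semiaxes}")

    @classmethod
    def sphere(cls, radius: float) -> "NuclearGeometry":
        return cls((float(radius),) * 3)

    @property
    def shape(self) -> str:
        a, b, c = self.semiaxes
        return "sphere" if a == b == c else "ellipsoid"

    @property
    def volume(self) -> float:
        a, b, c = self.semiaxes
        return 4.0 / 3.0 * np.pi * a * b * c

    def axes_array(self) -> np.ndarray:
        return np.asarray(self.semiaxes, dtype=float)


@dataclass(frozen=True)
class BeadGeometry:
    """Excluded-volume bead radius and target genome volume occupancy."""

    r0: float
    occupancy: float

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise GenomePopError(f"bead radius must be positive, got {self.r0}")
        if not 0 < self.occupancy < 1:
            raise GenomePopError(f"occupancy must be in (0, 1), got {self.occupancy}")


def bead_radius_from_occupancy(
    geometry: NuclearGeometry, N: int, occupancy: float = 0.40
) -> float:
    """Bead radius r0 (nm) such that N beads occupy ``occupancy`` of the
    nuclear volume: ``r0 = (phi * V_nucleus / (N * 4/3 pi))^(1/3)``.
    """
    if N < 1:
        raise GenomePopError(f"N must be >= 1, got {N}")
    if not 0 < occupancy < 1:
        raise GenomePopError(f"occupancy must be in (0, 1), got {occupancy}")
    return float((occupancy * geometry.volume / (N * 4.0 / 3.0 * np.pi)) ** (1.0 / 3.0))


def radial_norm(points: np.ndarray, geometry: NuclearGeometry) -> np.ndarray | float:
    """Semiaxis-scaled radial coordinate: 0 at the center, 1 on the envelope.

    ``r = sqrt((x/a)^2 + (y/b)^2 + (z/c)^2)``; accepts a single 3-vector or
    an ``(..., 3)`` array.
    """
    p = np.asarray(points, dtype=float)
    scaled = p / geometry.axes_array()
    r = np.sqrt(np.sum(scaled * scaled, axis=-1))
    return float(r) if p.ndim == 1 else r


def distance_to_envelope(points: np.ndarray, geometry: NuclearGeometry) -> np.ndarray | float:
    """Radial approximation of the distance from an interior point to the
    nuclear envelope: ``d = (1/sqrt(kappa) - 1) * ||x||`` with
    ``kappa = (x/a)^2 + (y/b)^2 + (z/c)^2``.

    For a sphere this is exactly ``R - ||x||``.  At the exact center (kappa
    = 0) the formula is singular; by convention the smallest semiaxis ``c``
    is returned as a conservative lower bound.
    """
    p = np.asarray(points, dtype=float)
    single = p.ndim == 1
    p2 = np.atleast_2d(p)
    kappa = radial_norm(p2, geometry) ** 2
    norm = np.linalg.norm(p2, axis=-1)
    c = geometry.semiaxes[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (1.0 / np.sqrt(kappa) - 1.0) * norm
    d = np.where(kappa == 0.0, c, d)
    return float(d[0]) if single else d
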