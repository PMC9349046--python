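"""Data tensors for the four input modalities and the structure population
container, with plain-text readers/writers and an HDF5 population file.

Dialects
--------
* Hi-C: tidy TSV ``chrom1  start1  chrom2  start2  prob`` (symmetric fill).
* Lamina DamID: bedGraph ``chrom  start  end  value``.
* FISH: TSV with a ``#units=<nm|radial>`` header, then one row per
  (target, max|min) distribution: locus token(s), the literal ``max`` or
  ``min``, and the sorted distance list.
* SPRITE: one cluster per line, whitespace-separated ``chrom:start`` tokens.
* Population: HDF5 with datasets ``/coordinates`` (float32, S x N x 3, nm),
  ``/radii`` and ``/index`` plus attributes (semiaxes, bin size, seed,
  schedule step, segmentation checksum).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomePopError, GenomeSegmentation, NuclearGeometry

__all__ = [
    "ContactProbabilityMatrix",
    "LaminaContactProfile",
    "RadialDistributionSet",
    "PairwiseDistributionSet",
    "SpriteClusterSet",
    "StructurePopulation",
    "LatentAssignments",
    "InputBundle",
    "load_hic",
    "write_hic",
    "load_damid",
    "write_damid",
    "load_fish_radial",
    "write_fish_radial",
    "load_fish_pairwise",
    "write_fish_pairwise",
    "load_sprite",
    "write_sprite",
    "load_ab_labels",
    "read_chrom_sizes",
    "write_population",
    "read_population",
]

_PROB_EPS = 1e-9


def _check_prob(value: float, where: str) -> float:
    if value < -_PROB_EPS or value > 1.0 + _PROB_EPS:
        raise GenomePopError(f"probability {value} outside [0, 1] at {where}")
    return float(min(max(value, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ContactProbabilityMatrix:
    """Symmetric H x H contact probability matrix A = (a_IJ)."""

    matrix: np.ndarray
    segmentation: GenomeSegmentation

    def __post_init__(self) -> None:
        A = np.asarray(self.matrix, dtype=float)
        H = self.segmentation.H
        if A.shape != (H, H):
            raise GenomePopError(f"Hi-C matrix shape {A.shape} != ({H}, {H})")
        if not np.allclose(A, A.T):
            raise GenomePopError("Hi-C matrix is not symmetric")
        if A.min() < -_PROB_EPS or A.max() > 1.0 + _PROB_EPS:
            raise GenomePopError("Hi-C probabilities outside [0, 1]")
        self.matrix = np.clip(A, 0.0, 1.0)


@dataclass
class LaminaContactProfile:
    """Length-H vector E = (e_I) of lamina contact probabilities."""

    values: np.ndarray
    segmentation: GenomeSegmentation

    def __post_init__(self) -> None:
        e = np.asarray(self.values, dtype=float)
        if e.shape != (self.segmentation.H,):
            raise GenomePopError(
                f"DamID profile length {e.shape} != H={self.segmentation.H}"
            )
        if e.min() < -_PROB_EPS or e.max() > 1.0 + _PROB_EPS:
            raise GenomePopError("DamID probabilities outside [0, 1]")
        self.values = np.clip(e, 0.0, 1.0)


def _check_sorted_pair(zmax: np.ndarray, zmin: np.ndarray, where: str) -> None:
    if np.any(np.diff(zmax) < 0) or np.any(np.diff(zmin) < 0):
        raise GenomePopError(f"distance lists not sorted ascending for {where}")
    if len(zmax) != len(zmin):
        raise GenomePopError(f"max/min lists of different length for {where}")
    if np.any(zmax < zmin):
        raise GenomePopError(f"Z^max < Z^min after rank alignment for {where}")


@dataclass
class RadialDistributionSet:
    """Sorted per-locus radial distance distributions Z_I^max / Z_I^min.

    ``units`` is ``"radial"`` (semiaxis-normalized, dimensionless) or
    ``"nm"`` (Euclidean distance to the nuclear center).
    """

    distributions: dict[int, tuple[np.ndarray, np.ndarray]]
    units: str
    segmentation: GenomeSegmentation

    def __post_init__(self) -> None:
        if self.units not in ("nm", "radial"):
            raise GenomePopError(f"unknown units {self.units!r}")
        for I, (zmax, zmin) in self.distributions.items():
            _check_sorted_pair(np.asarray(zmax), np.asarray(zmin), f"locus {I}")


@dataclass
class PairwiseDistributionSet:
    """Sorted per-pair distance distributions Z_IJ^max / Z_IJ^min (nm)."""

    distributions: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]]
    units: str
    segmentation: GenomeSegmentation

    def __post_init__(self) -> None:
        if self.units != "nm":
            raise GenomePopError("pairwise FISH distances must be in nm")
        for (I, J), (zmax, zmin) in self.distributions.items():
            if I == J:
                raise GenomePopError(f"pairwise distribution with I == J == {I}")
            _check_sorted_pair(np.asarray(zmax), np.asarray(zmin), f"pair {I}-{J}")


@dataclass
class SpriteClusterSet:
    """SPRITE clusters: tuples of haploid bin ids, n >= 2 members each."""

    clusters: list[tuple[int, ...]]
    segmentation: GenomeSegmentation
    presence: np.ndarray | None = None

    def __post_init__(self) -> None:
        for k, members in enumerate(self.clusters):
            if len(members) < 2:
                raise GenomePopError(f"SPRITE cluster {k} has n={len(members)} < 2")
            if len(set(members)) != len(members):
                raise GenomePopError(f"SPRITE cluster {k} contains duplicate bins")


@dataclass
class StructurePopulation:
    """The model X: S diploid genome structures with bead coordinates in nm."""

    coordinates: np.ndarray  # (S, N, 3)
    radii: np.ndarray  # (N,)
    segmentation: GenomeSegmentation
    geometry: NuclearGeometry
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        X = np.asarray(self.coordinates)
        if X.ndim != 3 or X.shape[2] != 3:
            raise GenomePopError(f"coordinates must be (S, N, 3), got {X.shape}")
        if X.shape[0] == 0:
            raise GenomePopError("empty population (S = 0)")
        if X.shape[1] != self.segmentation.N:
            raise GenomePopError(
                f"coordinate bead count {X.shape[1]} != segmentation N={self.segmentation.N}"
            )
        if not np.all(np.isfinite(X)):
            raise GenomePopError("non-finite coordinates in population")
        self.coordinates = X
        self.radii = np.asarray(self.radii, dtype=float)
        if self.radii.shape != (self.segmentation.N,):
            raise GenomePopError("radii length does not match bead count")

    @property
    def S(self) -> int:
        return self.coordinates.shape[0]

    @property
    def N(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class LatentAssignments:
    """Sparse activation records produced by the A-step.

    * ``contacts``: int array (K, 3) of (structure s, bead i, bead j).
    * ``lamina``: int array (K, 2) of (structure s, bead i).
    * ``radial``: per-row (s, bead, target, tolerance) with ``radial_units``.
    * ``pairs``: per-row (s, bead i, bead j, target nm, tolerance).
    * ``clusters``: list of (structure s, bead tuple, cluster radius r_c nm).
    """

    contacts: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=np.int64))
    lamina: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    radial_idx: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    radial_target: np.ndarray = field(default_factory=lambda: np.empty(0))
    radial_tol: np.ndarray = field(default_factory=lambda: np.empty(0))
    radial_units: str = "radial"
    pair_idx: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=np.int64))
    pair_target: np.ndarray = field(default_factory=lambda: np.empty(0))
    pair_tol: np.ndarray = field(default_factory=lambda: np.empty(0))
    clusters: list[tuple[int, tuple[int, ...], float]] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {
            "contact": len(self.contacts),
            "lamina": len(self.lamina),
            "radial": len(self.radial_idx),
            "pair_distance": len(self.pair_idx),
            "cluster": len(self.clusters),
        }


@dataclass
class InputBundle:
    """The four data modalities handed to the modeling pipeline."""

    hic: ContactProbabilityMatrix | None = None
    damid: LaminaContactProfile | None = None
    fish_radial: RadialDistributionSet | None = None
    fish_pairwise: PairwiseDistributionSet | None = None
    sprite: SpriteClusterSet | None = None


# ---------------------------------------------------------------------------
# Plain-text readers / writers
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> dict[str, int]:
    """Read a UCSC-style two-column ``chrom<TAB>length_bp`` file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise GenomePopError(f"{path}:{ln}: expected 'chrom length'")
            sizes[parts[0]] = int(parts[1])
    return sizes


def _parse_locus(token: str, segmentation: GenomeSegmentation, where: str) -> int:
    try:
        chrom, start = token.rsplit(":", 1)
        start_bp = int(start)
    except ValueError:
        raise GenomePopError(f"{where}: malformed locus token {token!r}") from None
    known = {name for name, _, _ in segmentation.chromosomes}
    if chrom not in known:
        raise GenomePopError(f"{where}: unknown chromosome {chrom!r}")
    return segmentation.bin_index(chrom, start_bp)


def load_hic(path, segmentation: GenomeSegmentation) -> ContactProbabilityMatrix:
    """Read a tidy Hi-C TSV into a symmetric contact probability matrix."""
    H = segmentation.H
    A = np.zeros((H, H))
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 5:
                raise GenomePopError(f"{path}:{ln}: expected 5 columns")
            where = f"{path}:{ln}"
            I = _parse_locus(f"{parts[0]}:{parts[1]}", segmentation, where)
            J = _parse_locus(f"{parts[2]}:{parts[3]}", segmentation, where)
            p = _check_prob(float(parts[4]), where)
            A[I, J] = p
            A[J, I] = p
    return ContactProbabilityMatrix(A, segmentation)


def write_hic(hic: ContactProbabilityMatrix, path) -> None:
    seg = hic.segmentation
    with open(path, "w") as fh:
        fh.write("# chrom1\tstart1\tchrom2\tstart2\tprob\n")
        I_idx, J_idx = np.nonzero(np.triu(hic.matrix, k=1))
        for I, J in zip(I_idx, J_idx):
            c1, s1, _ = seg.haploid_bins[I]
            c2, s2, _ = seg.haploid_bins[J]
            fh.write(f"{c1}\t{s1}\t{c2}\t{s2}\t{float(hic.matrix[I, J])!r}\n")


def load_damid(path, segmentation: GenomeSegmentation) -> LaminaContactProfile:
    """Read a bedGraph lamina contact track into a length-H profile."""
    e = np.zeros(segmentation.H)
    last_key: tuple[str, int] | None = None
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise GenomePopError(f"{path}:{ln}: expected 4 bedGraph columns")
            where = f"{path}:{ln}"
            chrom, start = parts[0], int(parts[1])
            I = _parse_locus(f"{chrom}:{start}", segmentation, where)
            key = (chrom, start)
            if last_key is not None and key[0] == last_key[0] and key[1] <= last_key[1]:
                raise GenomePopError(f"{where}: non-monotone bins within chromosome")
            last_key = key
            e[I] = _check_prob(float(parts[3]), where)
    return LaminaContactProfile(e, segmentation)


def write_damid(profile: LaminaContactProfile, path) -> None:
    seg = profile.segmentation
    with open(path, "w") as fh:
        for I, (chrom, start, end) in enumerate(seg.haploid_bins):
            fh.write(f"{chrom}\t{start}\t{end}\t{float(profile.values[I])!r}\n")


def _read_fish(path, segmentation, n_locus_tokens):
    units = None
    rows: dict = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#units="):
                units = line.split("=", 1)[1].strip()
                continue
            if line.startswith("#"):
                continue
            parts = line.split()
            where = f"{path}:{ln}"
            if len(parts) < n_locus_tokens + 2:
                raise GenomePopError(f"{where}: too few columns")
            key_bins = tuple(
                _parse_locus(tok, segmentation, where) for tok in parts[:n_locus_tokens]
            )
            kind = parts[n_locus_tokens]
            if kind not in ("max", "min"):
                raise GenomePopError(f"{where}: expected 'max' or 'min', got {kind!r}")
            values = np.array([float(v) for v in parts[n_locus_tokens + 1:]])
            key = key_bins[0] if n_locus_tokens == 1 else key_bins
            rows.setdefault(key, {})[kind] = values
    if units is None:
        raise GenomePopError(f"{path}: missing '#units=' header")
    dists = {}
    for key, kinds in rows.items():
        if "max" not in kinds or "min" not in kinds:
            raise GenomePopError(f"{path}: target {key} missing max or min row")
        dists[key] = (kinds["max"], kinds["min"])
    return dists, units


def load_fish_radial(path, segmentation: GenomeSegmentation) -> RadialDistributionSet:
    dists, units = _read_fish(path, segmentation, n_locus_tokens=1)
    return RadialDistributionSet(dists, units, segmentation)


def write_fish_radial(rad: RadialDistributionSet, path) -> None:
    seg = rad.segmentation
    with open(path, "w") as fh:
        fh.write(f"#units={rad.units}\n")
        for I, (zmax, zmin) in rad.distributions.items():
            chrom, start, _ = seg.haploid_bins[I]
            for kind, z in (("max", zmax), ("min", zmin)):
                vals = " ".join(repr(float(v)) for v in z)
                fh.write(f"{chrom}:{start}\t{kind}\t{vals}\n")


def load_fish_pairwise(path, segmentation: GenomeSegmentation) -> PairwiseDistributionSet:
    dists, units = _read_fish(path, segmentation, n_locus_tokens=2)
    return PairwiseDistributionSet(dists, units, segmentation)


def write_fish_pairwise(pw: PairwiseDistributionSet, path) -> None:
    seg = pw.segmentation
    with open(path, "w") as fh:
        fh.write(f"#units={pw.units}\n")
        for (I, J), (zmax, zmin) in pw.distributions.items():
            c1, s1, _ = seg.haploid_bins[I]
            c2, s2, _ = seg.haploid_bins[J]
            for kind, z in (("max", zmax), ("min", zmin)):
                vals = " ".join(repr(float(v)) for v in z)
                fh.write(f"{c1}:{s1}\t{c2}:{s2}\t{kind}\t{vals}\n")


def load_sprite(path, segmentation: GenomeSegmentation) -> SpriteClusterSet:
    clusters: list[tuple[int, ...]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            members = tuple(
                _parse_locus(tok, segmentation, f"{path}:{ln}") for tok in line.split()
            )
            clusters.append(members)
    return SpriteClusterSet(clusters, segmentation)


def write_sprite(sprite: SpriteClusterSet, path) -> None:
    seg = sprite.segmentation
    with open(path, "w") as fh:
        for members in sprite.clusters:
            toks = []
            for I in members:
                chrom, start, _ = seg.haploid_bins[I]
                toks.append(f"{chrom}:{start}")
            fh.write(" ".join(toks) + "\n")


def load_ab_labels(path, segmentation: GenomeSegmentation) -> np.ndarray:
    """Read ``chrom start end {A|B}`` rows into a length-H label array.

    Bins absent from the file get the empty label ``""``.
    """
    labels = np.full(segmentation.H, "", dtype="U1")
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4 or parts[3] not in ("A", "B"):
                raise GenomePopError(f"{path}:{ln}: expected 'chrom start end A|B'")
            I = _parse_locus(f"{parts[0]}:{parts[1]}", segmentation, f"{path}:{ln}")
            labels[I] = parts[3]
    return labels


# ---------------------------------------------------------------------------
# Population container (HDF5)
# ---------------------------------------------------------------------------

def write_population(population: StructurePopulation, path) -> None:
    """Write a population to the HDF5 container (coordinates as float32)."""
    import h5py

    seg = population.segmentation
    with h5py.File(path, "w") as h5:
        h5.create_dataset(
            "coordinates", data=np.asarray(population.coordinates, dtype=np.float32)
        )
        h5.create_dataset("radii", data=np.asarray(population.radii, dtype=np.float64))
        index = np.array(
            [
                (seg.haploid_bins[I][0], seg.haploid_bins[I][1], seg.haploid_bins[I][2], c)
                for I, c in seg.copy_map
            ],
            dtype=[("chrom", "S32"), ("start", "i8"), ("end", "i8"), ("copy", "i1")],
        )
        h5.create_dataset("index", data=index)
        h5.attrs["semiaxes"] = np.asarray(population.geometry.semiaxes)
        h5.attrs["bin_size"] = seg.bin_size
        h5.attrs["segmentation_checksum"] = seg.checksum()
        h5.attrs["chromosomes"] = "\n".join(
            f"{n}\t{l}\t{cn}" for n, l, cn in seg.chromosomes
        )
        for key in ("seed", "schedule_step"):
            if key in population.provenance:
                h5.attrs[key] = population.provenance[key]


def read_population(path, segmentation: GenomeSegmentation | None = None) -> StructurePopulation:
    """Read a population container; the segmentation is rebuilt from the file
    metadata, or validated against ``segmentation`` if given."""
    import h5py

    from .genome import segment_genome

    with h5py.File(path, "r") as h5:
        coords = h5["coordinates"][...]
        radii = h5["radii"][...]
        chrom_rows = [r.split("\t") for r in h5.attrs["chromosomes"].split("\n")]
        sizes = {name: int(length) for name, length, _ in chrom_rows}
        ploidy = {name: int(cn) for name, _, cn in chrom_rows}
        seg = segment_genome(sizes, int(h5.attrs["bin_size"]), ploidy)
        if h5.attrs["segmentation_checksum"] != seg.checksum():
            raise GenomePopError(f"{path}: segmentation checksum mismatch")
        if segmentation is not None and segmentation.checksum() != seg.checksum():
            raise GenomePopError(f"{path}: population does not match expected segmentation")
        geometry = NuclearGeometry(tuple(float(v) for v in h5.attrs["semiaxes"]))
        provenance = {
            key: h5.attrs[key] for key in ("seed", "schedule_step") if key in h5.attrs
        }
    return StructurePopulation(coords, radii, segmentation or seg, geometry, provenance)
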