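"""Coordinate-based prediction of inter-label distance distributions.

An accessible-volume surrogate for nitroxide (MTSSL-type) spin labeling:
candidate spin-centre positions are sampled uniformly in a spherical shell
5-9 A around the labeled residue's C-alpha (restricted to the C-alpha ->
C-beta hemisphere when a C-beta exists), and candidates clashing with any
heavy atom of the rest of the structure are rejected.  The surviving cloud
of centres plays the role of the rotamer ensemble; pairwise distances
between two clouds, lightly smeared, give the predicted inter-spin distance
distribution that can be compared directly with a DEER-derived one.

This deliberately omits rotamer-library dihedral chemistry and conformer
weighting: the shell radii reproduce the typical backbone-to-NO-midpoint
offset of the label, and the clash rejection reproduces its excluded-volume
sensitivity, which is what the cross-validation needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from io import StringIO

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.spatial.distance import cdist

from .dipolar_model import DistanceDistribution, DistanceGrid
from .errors import (
    BuriedSiteError,
    EmptyStructureError,
    InvalidParameterError,
    OutOfGridWarning,
    PDBParseError,
)

_WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    element: str
    name: str
    resname: str
    chain: str
    resnum: int
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class Structure:
    """Heavy-atom coordinate set keyed by (chain, residue number, atom name)."""

    atoms: tuple[AtomRecord, ...]

    def __post_init__(self):
        keys = [(a.chain, a.resnum, a.name, a.altloc) for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise InvalidParameterError("duplicate (chain, resnum, atom, altloc) keys")
        for a in self.atoms:
            if not np.isfinite([a.x, a.y, a.z]).all():
                raise InvalidParameterError(f"non-finite coordinates at atom {a.serial}")

    @property
    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms])

    def atom(self, chain: str, resnum: int, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.chain == chain and a.resnum == resnum and a.name == name:
                return a
        return None

    def to_pdb(self) -> str:
        from .io import structure_to_pdb

        return structure_to_pdb(self.atoms)


@dataclass(frozen=True)
class RotamerCloud:
    """Accessible spin-centre positions (A) for one labeled site."""

    site: tuple[str, int]
    centers: np.ndarray
    n_attempts: int
    n_accepted: int

    def __post_init__(self):
        c = np.asarray(self.centers, float).reshape(-1, 3)
        object.__setattr__(self, "centers", c)
        if self.n_accepted != len(c) or self.n_accepted > self.n_attempts:
            raise InvalidParameterError("inconsistent rotamer-cloud counts")


def read_structure(pdb_text: str) -> Structure:
    """Parse PDB-format text into a heavy-atom :class:`Structure`.

    Keeps ATOM records of the first model with altloc '' or 'A'; hydrogens
    and waters are dropped.  HETATM records other than water are kept (they
    are potential clash partners).
    """
    import biotite.structure.io.pdb as pdb

    if not any(line.startswith(("ATOM", "HETATM")) for line in pdb_text.splitlines()):
        raise EmptyStructureError("no usable ATOM records in PDB text")
    try:
        pdb_file = pdb.PDBFile.read(StringIO(pdb_text))
        arr = pdb_file.get_structure(
            model=1, altloc="all", extra_fields=["atom_id", "occupancy"]
        )
    except Exception as exc:  # malformed records: locate the offending line
        for i, line in enumerate(pdb_text.splitlines(), start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except ValueError:
                    raise PDBParseError(f"malformed coordinate field at line {i}") from exc
        raise PDBParseError(f"could not parse PDB text: {exc}") from exc

    atoms = []
    altlocs = (
        arr.get_annotation("altloc_id")
        if "altloc_id" in arr.get_annotation_categories()
        else np.full(arr.array_length(), "")
    )
    for i in range(arr.array_length()):
        alt = str(altlocs[i]).strip()
        if alt not in ("", "A"):
            continue
        element = str(arr.element[i]).strip().upper()
        resname = str(arr.res_name[i]).strip()
        if element == "H" or resname in _WATER_RESNAMES:
            continue
        x, y, z = (float(c) for c in arr.coord[i])
        atoms.append(
            AtomRecord(
                serial=int(arr.atom_id[i]),
                element=element,
                name=str(arr.atom_name[i]).strip(),
                resname=resname,
                chain=str(arr.chain_id[i]).strip(),
                resnum=int(arr.res_id[i]),
                x=x,
                y=y,
                z=z,
                occupancy=float(arr.occupancy[i]),
                altloc="" if alt == "" else alt,
            )
        )
    if not atoms:
        raise EmptyStructureError("no usable ATOM records in PDB text")
    return Structure(tuple(atoms))


@dataclass(frozen=True)
class LabelParams:
    """Accessible-volume sampling parameters (all lengths in A)."""

    r_min: float = 5.0
    r_max: float = 9.0
    clash_cutoff: float = 2.5
    n_samples: int = 2000

    def __post_init__(self):
        if not 0 < self.r_min < self.r_max:
            raise InvalidParameterError("need 0 < r_min < r_max")
        if self.clash_cutoff < 0 or self.n_samples < 1:
            raise InvalidParameterError("invalid clash cutoff or sample count")


def sample_shell_points(
    ca: np.ndarray,
    cb_direction: np.ndarray | None,
    r_min: float,
    r_max: float,
    n: int,
    seed: int,
) -> np.ndarray:
    """Deterministic uniform sample of n points in the shell [r_min, r_max].

    When ``cb_direction`` is given, points in the opposite hemisphere are
    reflected through ``ca`` so that the whole sample lies on the
    C-alpha -> C-beta side (uniform on the hemisphere shell).
    """
    rng = np.random.default_rng(seed)
    d = rng.standard_normal((n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    radius = (r_min**3 + rng.random(n) * (r_max**3 - r_min**3)) ** (1.0 / 3.0)
    if cb_direction is not None:
        u = np.asarray(cb_direction, float)
        u = u / np.linalg.norm(u)
        flip = d @ u < 0
        d[flip] *= -1.0
    return np.asarray(ca, float) + d * radius[:, None]


def attach_label(
    structure: Structure,
    site: tuple[str, int],
    params: LabelParams = LabelParams(),
    seed: int = 0,
) -> RotamerCloud:
    """Accessible-volume spin labeling of one site.

    Raises :class:`BuriedSiteError` when no candidate survives the clash
    filter (site fully enclosed by neighbouring atoms).
    """
    chain, resnum = site
    ca = structure.atom(chain, resnum, "CA")
    if ca is None:
        raise InvalidParameterError(f"site {chain}:{resnum} has no CA atom")
    cb = structure.atom(chain, resnum, "CB")
    cb_dir = cb.coord - ca.coord if cb is not None else None

    candidates = sample_shell_points(
        ca.coord, cb_dir, params.r_min, params.r_max, params.n_samples, seed
    )
    env = np.array(
        [
            [a.x, a.y, a.z]
            for a in structure.atoms
            if not (a.chain == chain and a.resnum == resnum)
        ]
    )
    if env.size:
        dmin = cdist(candidates, env).min(axis=1)
        accepted = candidates[dmin >= params.clash_cutoff]
    else:
        accepted = candidates
    if len(accepted) == 0:
        raise BuriedSiteError(
            f"site {chain}:{resnum} buried: 0/{params.n_samples} candidates accepted",
            n_attempts=params.n_samples,
        )
    return RotamerCloud(
        site=site,
        centers=accepted,
        n_attempts=params.n_samples,
        n_accepted=len(accepted),
    )


def pair_distance_histogram(
    a: RotamerCloud, b: RotamerCloud, grid: DistanceGrid
) -> tuple[np.ndarray, float]:
    """All-pairs distance histogram on the grid with linear (mass- and
    mean-preserving) assignment to the two bracketing grid points.

    Returns (unnormalized histogram, fraction of pair mass outside the grid).
    """
    d_nm = cdist(a.centers, b.centers).ravel() / 10.0
    r = grid.r
    hist = np.zeros(grid.n)
    inside = (d_nm >= r[0]) & (d_nm <= r[-1])
    clipped_fraction = 1.0 - inside.mean() if d_nm.size else 0.0
    d_in = d_nm[inside]
    pos = (d_in - r[0]) / grid.dr
    lo = np.minimum(np.floor(pos).astype(int), grid.n - 2)
    frac = pos - lo
    np.add.at(hist, lo, 1.0 - frac)
    np.add.at(hist, lo + 1, frac)
    return hist, float(clipped_fraction)


def predict_distance_distribution(
    a: RotamerCloud,
    b: RotamerCloud,
    grid: DistanceGrid,
    smear_sd: float = 0.1,
) -> DistanceDistribution:
    """Predicted inter-spin distance distribution from two rotamer clouds.

    All pairwise centre-centre distances are histogrammed on ``grid``,
    convolved with a Gaussian of standard deviation ``smear_sd`` (nm) and
    normalized.  Pair distances outside the grid raise an
    :class:`OutOfGridWarning` and their mass is clipped.
    """
    if a.n_accepted == 0 or b.n_accepted == 0:
        raise InvalidParameterError("both rotamer clouds must be non-empty")
    hist, clipped = pair_distance_histogram(a, b, grid)
    if clipped > 0:
        warnings.warn(
            f"{clipped:.1%} of pair distances outside the grid were clipped",
            OutOfGridWarning,
            stacklevel=2,
        )
    if smear_sd > 0:
        hist = gaussian_filter1d(hist, sigma=smear_sd / grid.dr, mode="constant")
    return DistanceDistribution.normalized(grid, hist)
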