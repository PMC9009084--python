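"""Molecular geometries with a two-fragment partition, XYZ and cube I/O.

Coordinates are stored in angstrom (as they appear in XYZ files) and
converted to bohr at the integral layer.  Ghost atoms carry basis
functions but no nuclear charge and no electrons; they are what the
counterpoise (Boys-Bernardi) correction is made of.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903
HARTREE_TO_KCAL = 627.5094740631

ELEMENTS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar",
]
ATOMIC_NUMBER = {sym: z for z, sym in enumerate(ELEMENTS)}

#: number of frozen-core spatial orbitals per element (standard chemical core:
#: none for H-He, the He shell for Li-Ne, the Ne shell for Na-Ar)
N_CORE_ORBITALS = {z: (0 if z <= 2 else 1 if z <= 10 else 5) for z in range(1, 19)}


class GeometryError(ValueError):
    """Malformed geometry, fragment spec or cube grid."""


@dataclass(frozen=True)
class FragmentedGeometry:
    """Atoms plus a two-fragment partition, total charge and multiplicity.

    ``fragment_of_atom[k]`` is ``"X"`` or ``"Y"``; ``is_ghost[k]`` marks
    counterpoise ghost centers.
    """

    symbols: tuple[str, ...]
    coords: np.ndarray                     # (n, 3) angstrom
    charge: int
    multiplicity: int
    fragment_of_atom: tuple[str, ...]
    is_ghost: tuple[bool, ...] = None      # type: ignore[assignment]
    name: str = ""

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "coords", coords)
        if self.is_ghost is None:
            object.__setattr__(self, "is_ghost", (False,) * len(self.symbols))
        n = len(self.symbols)
        if not (coords.shape[0] == len(self.fragment_of_atom) == len(self.is_ghost) == n):
            raise GeometryError("inconsistent atom counts")
        for sym in self.symbols:
            if sym not in ATOMIC_NUMBER or sym == "X":
                raise GeometryError(f"unknown element {sym!r}")
        for lab in self.fragment_of_atom:
            if lab not in ("X", "Y"):
                raise GeometryError(f"fragment label must be X or Y, got {lab!r}")
        if self.multiplicity < 1:
            raise GeometryError("multiplicity must be >= 1")
        nelec = self.n_electrons
        if nelec < 0:
            raise GeometryError("negative electron count")
        if (nelec - (self.multiplicity - 1)) % 2 != 0:
            raise GeometryError(
                f"multiplicity {self.multiplicity} inconsistent with "
                f"{nelec} electrons"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def atomic_numbers(self) -> np.ndarray:
        """Nuclear charges; zero for ghost centers."""
        return np.array(
            [0 if g else ATOMIC_NUMBER[s] for s, g in zip(self.symbols, self.is_ghost)],
            dtype=int,
        )

    @property
    def n_electrons(self) -> int:
        return int(self.atomic_numbers.sum()) - self.charge

    @property
    def n_alpha(self) -> int:
        return (self.n_electrons + self.multiplicity - 1) // 2

    @property
    def n_beta(self) -> int:
        return (self.n_electrons - self.multiplicity + 1) // 2

    @property
    def coords_bohr(self) -> np.ndarray:
        return self.coords * BOHR_PER_ANGSTROM

    @property
    def is_monomer(self) -> bool:
        """True when all non-ghost atoms sit in a single fragment."""
        real = {f for f, g in zip(self.fragment_of_atom, self.is_ghost) if not g}
        return len(real) < 2

    def atoms_of(self, fragment: str) -> list[int]:
        return [k for k, f in enumerate(self.fragment_of_atom) if f == fragment]

    @property
    def n_core(self) -> int:
        """Frozen-core spatial orbital count (real atoms only)."""
        return int(sum(N_CORE_ORBITALS[z] for z in self.atomic_numbers if z > 0))

    def nuclear_repulsion(self) -> float:
        z = self.atomic_numbers.astype(float)
        r = self.coords_bohr
        e = 0.0
        for i in range(len(z)):
            for j in range(i):
                if z[i] == 0 or z[j] == 0:
                    continue
                e += z[i] * z[j] / np.linalg.norm(r[i] - r[j])
        return e


# -- fragment spec ----------------------------------------------------------

def parse_fragment_spec(spec: str, n_atoms: int) -> tuple[str, ...]:
    """Parse ``"1-3:X,4:Y"`` (1-based, comma-separated ranges) into labels.

    Every atom must be assigned exactly once; exactly the labels X and/or Y
    may appear.
    """
    labels: dict[int, str] = {}
    for chunk in spec.split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        m = re.fullmatch(r"(\d+)(?:-(\d+))?\s*:\s*([XY])", chunk)
        if m is None:
            raise GeometryError(f"bad fragment spec chunk {chunk!r}")
        lo = int(m.group(1))
        hi = int(m.group(2) or m.group(1))
        lab = m.group(3)
        if lo < 1 or hi > n_atoms or lo > hi:
            raise GeometryError(f"atom range {lo}-{hi} outside 1..{n_atoms}")
        for k in range(lo - 1, hi):
            if k in labels:
                raise GeometryError(f"atom {k + 1} assigned twice")
            labels[k] = lab
    if len(labels) != n_atoms:
        missing = sorted(set(range(n_atoms)) - set(labels))
        raise GeometryError(f"atoms left unassigned: {[k + 1 for k in missing]}")
    return tuple(labels[k] for k in range(n_atoms))


def read_xyz_with_fragments(
    path, fragment_spec: str, charge: int = 0, multiplicity: int = 1
) -> FragmentedGeometry:
    """Read a standard XYZ file and attach the two-fragment partition."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GeometryError("empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise GeometryError("first XYZ line must be the atom count") from exc
    body = lines[2 : 2 + n]
    if len(body) < n:
        raise GeometryError(f"XYZ promises {n} atoms, found {len(body)}")
    symbols, coords = [], []
    for ln in body:
        parts = ln.split()
        if len(parts) < 4:
            raise GeometryError(f"malformed XYZ atom line: {ln!r}")
        symbols.append(parts[0].capitalize())
        try:
            coords.append([float(x) for x in parts[1:4]])
        except ValueError as exc:
            raise GeometryError(f"bad coordinate in line {ln!r}") from exc
    labels = parse_fragment_spec(fragment_spec, n)
    return FragmentedGeometry(
        symbols=tuple(symbols),
        coords=np.array(coords),
        charge=charge,
        multiplicity=multiplicity,
        fragment_of_atom=labels,
        name=lines[1].strip() if len(lines) > 1 else "",
    )


def write_xyz(geometry: FragmentedGeometry, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(geometry.symbols)}\n{comment}\n")
        for sym, (x, y, z) in zip(geometry.symbols, geometry.coords):
            fh.write(f"{sym:2s} {x:18.10f} {y:18.10f} {z:18.10f}\n")


def make_ghost_system(
    geometry: FragmentedGeometry,
    real_fragment: str,
    real_charge: int = 0,
    real_multiplicity: int = 1,
) -> FragmentedGeometry:
    """Counterpoise monomer: the other fragment's atoms become ghosts.

    Charge and multiplicity of the retained (real) fragment must be
    supplied by the caller; they cannot be inferred from the adduct.
    """
    if real_fragment not in ("X", "Y"):
        raise GeometryError("real_fragment must be 'X' or 'Y'")
    if geometry.is_monomer:
        raise GeometryError("cannot ghost a monomer input")
    ghosts = tuple(
        f != real_fragment or g
        for f, g in zip(geometry.fragment_of_atom, geometry.is_ghost)
    )
    return replace(
        geometry,
        is_ghost=ghosts,
        charge=real_charge,
        multiplicity=real_multiplicity,
        name=f"{geometry.name} [{real_fragment} real]".strip(),
    )


# -- cube files -------------------------------------------------------------

@dataclass(frozen=True)
class CubeGrid:
    """Regular 3-D lattice: ``origin`` (bohr), three orthogonal step
    vectors ``axes`` (bohr, rows) and point counts ``shape``."""

    origin: np.ndarray
    axes: np.ndarray       # (3, 3), row k is the step along grid axis k
    shape: tuple[int, int, int]

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, float).reshape(3))
        axes = np.asarray(self.axes, float).reshape(3, 3)
        object.__setattr__(self, "axes", axes)
        if abs(np.linalg.det(axes)) < 1e-14:
            raise GeometryError("grid axes are singular")
        gram = axes @ axes.T
        if np.max(np.abs(gram - np.diag(np.diag(gram)))) > 1e-10:
            raise GeometryError("grid axes must be orthogonal (regular lattice)")
        if any(s < 1 for s in self.shape):
            raise GeometryError("grid shape must be positive")

    def points(self) -> np.ndarray:
        """All lattice points, x index slowest / z fastest, shape (N, 3)."""
        nx, ny, nz = self.shape
        i, j, k = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([i.ravel(), j.ravel(), k.ravel()], axis=1).astype(float)
        return self.origin + idx @ self.axes

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.axes)))

    @classmethod
    def around(cls, geometry: FragmentedGeometry, margin: float = 4.0, spacing: float = 0.4):
        """Cartesian box enclosing the molecule (bohr units)."""
        r = geometry.coords_bohr
        lo = r.min(axis=0) - margin
        hi = r.max(axis=0) + margin
        shape = tuple(int(np.ceil((hi[d] - lo[d]) / spacing)) + 1 for d in range(3))
        return cls(origin=lo, axes=np.eye(3) * spacing, shape=shape)


def write_cube(
    grid_values: np.ndarray, geometry: FragmentedGeometry, grid: CubeGrid, path,
    comment: str = "generated by hfld",
) -> None:
    """Gaussian cube file; values ordered x slowest, z fastest."""
    vals = np.asarray(grid_values, float)
    if vals.shape != tuple(grid.shape):
        raise GeometryError(f"values shape {vals.shape} != grid shape {grid.shape}")
    zs = geometry.atomic_numbers
    with open(path, "w") as fh:
        fh.write(f"{comment}\nhfld cube: x slowest, z fastest\n")
        fh.write(
            f"{len(zs):5d} {grid.origin[0]:12.6f} {grid.origin[1]:12.6f} {grid.origin[2]:12.6f}\n"
        )
        for d in range(3):
            ax = grid.axes[d]
            fh.write(f"{grid.shape[d]:5d} {ax[0]:12.6f} {ax[1]:12.6f} {ax[2]:12.6f}\n")
        for sym, z, xyz in zip(geometry.symbols, zs, geometry.coords_bohr):
            znum = ATOMIC_NUMBER[sym]
            fh.write(
                f"{znum:5d} {float(z):12.6f} {xyz[0]:12.6f} {xyz[1]:12.6f} {xyz[2]:12.6f}\n"
            )
        flat = vals.reshape(grid.shape[0] * grid.shape[1], grid.shape[2])
        for row in flat:
            for start in range(0, len(row), 6):
                fh.write("".join(f"{v:13.5E}" for v in row[start : start + 6]) + "\n")


def read_cube(path) -> tuple[np.ndarray, CubeGrid, np.ndarray]:
    """Read back a cube file -> (values, grid, nuclear charges)."""
    with open(path) as fh:
        lines = fh.read().split("\n")
    natom = int(lines[2].split()[0])
    origin = np.array([float(x) for x in lines[2].split()[1:4]])
    shape, axes = [], []
    for d in range(3):
        parts = lines[3 + d].split()
        shape.append(int(parts[0]))
        axes.append([float(x) for x in parts[1:4]])
    charges = np.array([float(lines[6 + k].split()[1]) for k in range(natom)])
    data = []
    for ln in lines[6 + natom :]:
        data.extend(float(x) for x in ln.split())
    grid = CubeGrid(origin=origin, axes=np.array(axes), shape=tuple(shape))
    vals = np.array(data).reshape(grid.shape)
    return vals, grid, charges
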