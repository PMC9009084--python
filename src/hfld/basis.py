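"""Gaussian basis sets: parsing the built-in library and building the
shell list for a geometry (ghost atoms included).

Cartesian Gaussians are used throughout; a shell of angular momentum l
carries (l+1)(l+2)/2 components ordered lexicographically descending in
(lx, ly, lz).  Each component is individually normalized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .geometry import FragmentedGeometry

_ANGMOM = {"S": 0, "P": 1, "D": 2, "F": 3}


class BasisError(ValueError):
    pass


def _double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def cartesian_components(l: int) -> list[tuple[int, int, int]]:
    return [
        (lx, ly, l - lx - ly)
        for lx in range(l, -1, -1)
        for ly in range(l - lx, -1, -1)
    ]


@dataclass(frozen=True)
class Shell:
    """One contracted shell on one center."""

    l: int
    atom: int                 # index into the geometry
    center: np.ndarray        # bohr
    exps: np.ndarray
    coefs: np.ndarray         # includes primitive normalization, (l,0,0) convention

    @property
    def n_components(self) -> int:
        return (self.l + 1) * (self.l + 2) // 2


@dataclass(frozen=True)
class BasisSet:
    """Shells plus AO bookkeeping for one geometry."""

    name: str
    shells: tuple[Shell, ...]
    geometry: FragmentedGeometry

    @property
    def n_ao(self) -> int:
        return sum(sh.n_components for sh in self.shells)

    @property
    def ao_offsets(self) -> np.ndarray:
        off = np.zeros(len(self.shells) + 1, dtype=int)
        for k, sh in enumerate(self.shells):
            off[k + 1] = off[k] + sh.n_components
        return off

    @property
    def ao_atom(self) -> np.ndarray:
        """Atom index of every AO (the shell->atom map)."""
        out = np.empty(self.n_ao, dtype=int)
        off = self.ao_offsets
        for k, sh in enumerate(self.shells):
            out[off[k] : off[k + 1]] = sh.atom
        return out

    def ao_fragment_mask(self, fragment: str) -> np.ndarray:
        frag = np.array(self.geometry.fragment_of_atom)
        return frag[self.ao_atom] == fragment

    @property
    def component_scales(self) -> np.ndarray:
        """Per-AO factor turning (l,0,0)-normalized integrals into
        individually normalized cartesian components."""
        out = np.empty(self.n_ao)
        off = self.ao_offsets
        for k, sh in enumerate(self.shells):
            base = _double_factorial(2 * sh.l - 1)
            for c, (lx, ly, lz) in enumerate(cartesian_components(sh.l)):
                denom = (
                    _double_factorial(2 * lx - 1)
                    * _double_factorial(2 * ly - 1)
                    * _double_factorial(2 * lz - 1)
                )
                out[off[k] + c] = math.sqrt(base / denom)
        return out


# -- library parsing --------------------------------------------------------

def _load_library_text() -> str:
    return (resources.files("hfld") / "data" / "basis.gbs").read_text()


_LIBRARY_CACHE: dict[str, dict[str, list[tuple[int, np.ndarray, np.ndarray]]]] = {}


def _parse_library() -> dict[str, dict[str, list]]:
    if _LIBRARY_CACHE:
        return _LIBRARY_CACHE
    text = _load_library_text()
    current_name = None
    pending_includes: list[str] = []
    element_shells: dict[str, list] = {}
    cur_el, cur_l = None, None
    prims: list[tuple[float, float]] = []

    def flush_shell():
        nonlocal prims
        if cur_el is not None and prims:
            exps = np.array([p[0] for p in prims])
            coefs = np.array([p[1] for p in prims])
            element_shells.setdefault(cur_el, []).append((cur_l, exps, coefs))
        prims = []

    for raw in text.splitlines():
        line = raw.split("!")[0].strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("BASIS"):
            current_name = line.split('"')[1].lower()
            element_shells = {}
            pending_includes = []
            cur_el = cur_l = None
        elif upper == "END":
            flush_shell()
            cur_el = cur_l = None
            merged: dict[str, list] = {}
            for inc in pending_includes:
                if inc not in _LIBRARY_CACHE:
                    raise BasisError(f"INCLUDE {inc} before its definition")
                for el, shl in _LIBRARY_CACHE[inc].items():
                    merged.setdefault(el, []).extend(shl)
            for el, shl in element_shells.items():
                merged.setdefault(el, []).extend(shl)
            _LIBRARY_CACHE[current_name] = merged
        elif upper.startswith("INCLUDE"):
            pending_includes.append(line.split()[1].lower())
        else:
            parts = line.split()
            if parts[0][0].isalpha():
                flush_shell()
                cur_el = parts[0].capitalize()
                if parts[1].upper() not in _ANGMOM:
                    raise BasisError(f"unknown shell type {parts[1]!r}")
                cur_l = _ANGMOM[parts[1].upper()]
            else:
                prims.append((float(parts[0]), float(parts[1])))
    return _LIBRARY_CACHE


def available_bases() -> list[str]:
    return sorted(_parse_library().keys())


def _primitive_norm(l: int, a: float) -> float:
    # normalization of a cartesian primitive with (lx, ly, lz) = (l, 0, 0)
    return (
        (2 * a / math.pi) ** 0.75
        * (4 * a) ** (l / 2.0)
        / math.sqrt(_double_factorial(2 * l - 1))
    )


def _normalized_contraction(l: int, exps: np.ndarray, coefs: np.ndarray) -> np.ndarray:
    c = coefs * np.array([_primitive_norm(l, a) for a in exps])
    # self-overlap of the contracted (l,0,0) function
    ee = exps[:, None] + exps[None, :]
    s = (
        math.pi ** 1.5
        * _double_factorial(2 * l - 1)
        / 2.0 ** l
        * (c[:, None] * c[None, :] / ee ** (l + 1.5)).sum()
    )
    return c / math.sqrt(s)


def _resolve_basis_spec(basis_name: str) -> tuple[str, dict[str, str]]:
    """Parse ``"cc-pvdz"`` or ``"cc-pvdz;F=aug-cc-pvdz,O=..."`` into a
    default name plus per-element overrides."""
    parts = basis_name.lower().split(";")
    default = parts[0].strip()
    overrides: dict[str, str] = {}
    for chunk in parts[1:]:
        for item in chunk.split(","):
            item = item.strip()
            if not item:
                continue
            el, _, name = item.partition("=")
            if not name:
                raise BasisError(f"bad basis override {item!r}")
            overrides[el.strip().capitalize()] = name.strip()
    return default, overrides


def build_basis(geometry: FragmentedGeometry, basis_name: str) -> BasisSet:
    """Assemble the shell list; ghosts get the full basis of their element.

    ``basis_name`` may carry per-element overrides, e.g.
    ``"cc-pvdz;F=aug-cc-pvdz"`` augments fluorine only.
    """
    lib = _parse_library()
    default, overrides = _resolve_basis_spec(basis_name)
    for name in [default, *overrides.values()]:
        if name not in lib:
            raise BasisError(f"unknown basis {name!r}; have {available_bases()}")
    shells = []
    coords = geometry.coords_bohr
    for k, sym in enumerate(geometry.symbols):
        table = lib[overrides.get(sym, default)]
        if sym not in table:
            raise BasisError(f"basis {basis_name!r} has no element {sym}")
        for l, exps, coefs in table[sym]:
            shells.append(
                Shell(
                    l=l,
                    atom=k,
                    center=coords[k].copy(),
                    exps=exps.copy(),
                    coefs=_normalized_contraction(l, exps, coefs),
                )
            )
    return BasisSet(
        name=basis_name.lower(), shells=tuple(shells), geometry=geometry
    )
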