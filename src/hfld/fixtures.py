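"""Programmatic test systems and potential-energy scans.

All fixtures are rigid-monomer geometries built from standard
experimental monomer internals (r_OH = 0.9572 A, HOH = 104.52 deg;
triplet CH2: r_CH = 1.077 A, HCH = 134 deg; r_CO+ = 1.115 A;
methane r_CH = 1.087 A) placed at a requested fragment separation
along a documented approach axis.  They emulate the system classes of
the radical-solvent (TA13-like) and carbene (CARB10-like) benchmark
families at desk scale, and regenerate bit-identically from their
parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .geometry import FragmentedGeometry, HARTREE_TO_KCAL, make_ghost_system
from .integrals import build_ao_integrals
from .reference import counterpoise_interaction
from .led import hfld_interaction_energy, run_correlation_stage, _reference_energy_fn


R_OH = 0.9572
A_HOH = 104.52
R_CH_CARBENE = 1.077
A_HCH_TRIPLET = 134.0
R_CO_CATION = 1.115
R_CH_METHANE = 1.087


def _water_atoms(origin=np.zeros(3), axis=np.array([0.0, 0.0, 1.0])):
    """Water with O at ``origin``; the H's lie on the +axis side, so an
    approach along -axis meets the oxygen lone-pair region."""
    half = math.radians(A_HOH / 2.0)
    x = R_OH * math.sin(half)
    z = R_OH * math.cos(half)
    # build in the frame where axis = +z, then rotate
    atoms = np.array([[0.0, 0.0, 0.0], [x, 0.0, z], [-x, 0.0, z]])
    R = _rotation_to(np.array([0.0, 0.0, 1.0]), axis)
    return ["O", "H", "H"], atoms @ R.T + origin


def _rotation_to(a, b):
    """Rotation matrix taking unit vector a to unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    charge: int = 0
    multiplicity: int = 1
    fragment_charges: tuple = (0, 0)
    fragment_multiplicities: tuple = (1, 1)
    default_separation: float = 3.0


FIXTURES = {
    "he2": FixtureSpec("he2", default_separation=3.0),
    "ne2": FixtureSpec("ne2", default_separation=3.1),
    "h2o_h2o": FixtureSpec("h2o_h2o", default_separation=2.98),
    "li_h2o": FixtureSpec(
        "li_h2o", multiplicity=2, fragment_multiplicities=(2, 1),
        default_separation=1.90,
    ),
    "f_h2o": FixtureSpec(
        "f_h2o", multiplicity=2, fragment_multiplicities=(2, 1),
        default_separation=2.40,
    ),
    "co+_h2o": FixtureSpec(
        "co+_h2o", charge=1, multiplicity=2, fragment_charges=(1, 0),
        fragment_multiplicities=(2, 1), default_separation=2.30,
    ),
    "ch2_he": FixtureSpec(
        "ch2_he", multiplicity=3, fragment_multiplicities=(3, 1),
        default_separation=3.2,
    ),
    "ch4_3h2o": FixtureSpec("ch4_3h2o", default_separation=3.4),
}


def build_dimer(kind: str, separation: float | None = None) -> FragmentedGeometry:
    """Build a two-fragment fixture at the given fragment separation (A)."""
    kind = kind.lower()
    if kind not in FIXTURES:
        raise ValueError(f"unknown fixture {kind!r}; have {sorted(FIXTURES)}")
    spec = FIXTURES[kind]
    d = spec.default_separation if separation is None else float(separation)
    if d <= 0.5:
        raise ValueError("separation must exceed 0.5 A")
    syms: list[str] = []
    xyz: list = []
    frag: list[str] = []

    def add(s, pos, f):
        syms.extend(s)
        xyz.extend(np.atleast_2d(pos))
        frag.extend(f * len(s) if len(f) == 1 else f)

    if kind in ("he2", "ne2"):
        el = "He" if kind == "he2" else "Ne"
        add([el], [[0.0, 0.0, 0.0]], "X")
        add([el], [[0.0, 0.0, d]], "Y")
    elif kind == "li_h2o":
        add(["Li"], [[0.0, 0.0, -d]], "X")
        s, a = _water_atoms()
        add(s, a, "Y")
    elif kind == "f_h2o":
        # hemi-bond approach: F toward the oxygen lone pair along the C2 axis
        add(["F"], [[0.0, 0.0, -d]], "X")
        s, a = _water_atoms()
        add(s, a, "Y")
    elif kind == "co+_h2o":
        # carbon end toward the water oxygen
        add(["C", "O"], [[0.0, 0.0, -d], [0.0, 0.0, -d - R_CO_CATION]], "X")
        s, a = _water_atoms()
        add(s, a, "Y")
    elif kind == "ch2_he":
        half = math.radians(A_HCH_TRIPLET / 2.0)
        hx = R_CH_CARBENE * math.sin(half)
        hz = R_CH_CARBENE * math.cos(half)
        add(["C", "H", "H"], [[0, 0, 0], [hx, 0, hz], [-hx, 0, hz]], "X")
        add(["He"], [[0.0, 0.0, -d]], "Y")
    elif kind == "h2o_h2o":
        # donor OH points at the acceptor oxygen along +z
        s, a = _water_atoms()                       # acceptor at origin, H's up
        add(s, a, "X")
        od = np.array([0.0, 0.0, -d])
        h1 = od + np.array([0.0, 0.0, R_OH])        # donor H toward acceptor O
        ang = math.radians(A_HOH)
        h2 = od + R_OH * np.array([math.sin(ang), 0.0, math.cos(ang)])
        add(["O", "H", "H"], [od, h1, h2], "Y")
    elif kind == "ch4_3h2o":
        t = 1.0 / math.sqrt(3.0)
        dirs = np.array([[t, t, t], [-t, -t, t], [-t, t, -t], [t, -t, -t]])
        add(["C"], [[0.0, 0.0, 0.0]], "X")
        add(["H"] * 4, R_CH_METHANE * dirs, "X")
        for phi in (0.0, 2 * math.pi / 3, 4 * math.pi / 3):
            radial = np.array([math.cos(phi), math.sin(phi), 0.0])
            s, a = _water_atoms(origin=d * radial, axis=radial)
            add(s, a, "Y")
    geometry = FragmentedGeometry(
        symbols=tuple(syms),
        coords=np.array(xyz, float),
        charge=spec.charge,
        multiplicity=spec.multiplicity,
        fragment_of_atom=tuple(frag),
        name=f"{kind} d={d:.4f}",
    )
    return geometry


def fixture_config(kind: str, **overrides) -> RunConfig:
    """RunConfig with the fixture's fragment charges/multiplicities."""
    spec = FIXTURES[kind.lower()]
    cfg = dict(
        fragment_charges={"X": spec.fragment_charges[0], "Y": spec.fragment_charges[1]},
        fragment_multiplicities={
            "X": spec.fragment_multiplicities[0],
            "Y": spec.fragment_multiplicities[1],
        },
    )
    cfg.update(overrides)
    return RunConfig(**cfg)


def rigid_transform(
    geometry: FragmentedGeometry, seed: int
) -> FragmentedGeometry:
    """Seeded rigid rotation + translation (results must be invariant)."""
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    shift = rng.uniform(-1.0, 1.0, size=3)
    from dataclasses import replace

    return replace(geometry, coords=geometry.coords @ R.T + shift)


def scan_curve(
    kind: str,
    method: str,
    separations,
    config: RunConfig | None = None,
) -> list[tuple[float, float]]:
    """Counterpoise-corrected interaction-energy curve (kcal/mol).

    ``method``: "HF" (reference level only), "HFLD", or "CCSD" (full-pair
    coupled cluster on the restricted determinant).  Monomer geometries
    are frozen across the scan (only the separation changes).
    """
    method = method.upper()
    config = config or fixture_config(kind)
    out = []
    for d in separations:
        geometry = build_dimer(kind, d)
        base_ao = build_ao_integrals(geometry, config.basis_name)
        if method == "HF":
            cp = counterpoise_interaction(
                geometry, _reference_energy_fn(config, base_ao=base_ao),
                config.fragment_charges, config.fragment_multiplicities,
            )
            de = cp.delta_e
        elif method == "HFLD":
            de = hfld_interaction_energy(geometry, config, ao=base_ao).de_hfld
        elif method == "CCSD":
            # internally consistent total CCSD energies on the restricted
            # determinant: E = E_ref_det + E_corr for each sub-system
            def total(g):
                ao = build_ao_integrals(g, config.basis_name, reuse=base_ao)
                st = run_correlation_stage(g, config, "all", ao=ao)
                return st.reference.energy + st.cc.e_corr

            e_ad = total(geometry)
            e_mono = {}
            for f in ("X", "Y"):
                mono = make_ghost_system(
                    geometry, f, config.fragment_charges[f],
                    config.fragment_multiplicities[f],
                )
                e_mono[f] = total(mono)
            de = e_ad - e_mono["X"] - e_mono["Y"]
        else:
            raise ValueError("method must be HF, HFLD or CCSD")
        out.append((float(d), de * HARTREE_TO_KCAL))
    return out
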