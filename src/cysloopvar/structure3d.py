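"""Structure I/O and pore geometry for pentameric ligand-gated ion channels.

The ion-conduction pathway of a Cys-loop receptor runs along the approximate
five-fold axis of the transmembrane bundle.  The pore profile computed here is
HOLE/PoreWalker-like: at evenly spaced stations along the pore axis (3 Å by
default), the in-plane center is refined to maximize clearance and the radius
of the largest sphere avoiding all atomic van der Waals spheres is recorded.
Constriction radii are interpreted against the Pauling ionic radius of Cl⁻
(1.81 Å) and the hydrated Cl⁻ radius (3.2 Å): a constriction below 1.81 Å is
non-conductive, between the two it passes only dehydrated chloride, above
3.2 Å hydrated chloride fits.

Also here: residue-level van der Waals / hydrogen-bond contact detection,
inter-residue distances under both Cα and minimum-heavy-atom conventions, and
Kabsch least-squares superposition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure3D",
    "PoreStep",
    "PoreProfile",
    "Contact",
    "ContactSet",
    "IonConstants",
    "VDW_RADII",
    "read_structure",
    "pore_axis",
    "pore_profile",
    "classify_permeation",
    "compare_profiles",
    "contacts",
    "residue_distance",
    "kabsch_rmsd",
]

#: Bondi van der Waals radii (Å); hydrogens are dropped on input
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}
DEFAULT_VDW = 1.70


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


@dataclass(frozen=True)
class IonConstants:
    """Chloride radii used to classify pore constrictions."""

    cl_pauling_radius: float = 1.81
    cl_hydrated_radius: float = 3.2


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    altloc: str = ""


@dataclass
class Residue:
    number: int
    name: str
    atoms: list[Atom]

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    chain_id: str
    subunit_role: str
    residues: list[Residue]

    def residue(self, number: int) -> Residue | None:
        for r in self.residues:
            if r.number == number:
                return r
        return None


@dataclass
class Structure3D:
    """Chains, residues and atoms of one model, with subunit-role labels."""

    structure_id: str
    chains: list[Chain]
    hetero: list[tuple[str, Residue]] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in {self.structure_id}")

    def atom_table(self) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int, str, str]]]:
        """Coordinates (n,3), vdW radii (n,) and (chain, resnum, resname, atom) labels."""
        coords, radii, labels = [], [], []
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    coords.append(a.xyz)
                    radii.append(vdw_radius(a.element))
                    labels.append((c.chain_id, r.number, r.name, a.name))
        if not coords:
            raise ValueError(f"{self.structure_id}: no atoms")
        return np.asarray(coords, dtype=float), np.asarray(radii, dtype=float), labels

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure3D":
        """A rigidly moved copy: x -> x @ R + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        new_chains = []
        for c in self.chains:
            new_res = [
                Residue(
                    r.number,
                    r.name,
                    [
                        Atom(a.name, a.element, a.xyz @ rotation + translation, a.occupancy, a.altloc)
                        for a in r.atoms
                    ],
                )
                for r in c.residues
            ]
            new_chains.append(Chain(c.chain_id, c.subunit_role, new_res))
        return Structure3D(self.structure_id, new_chains, list(self.hetero))


def read_structure(
    path: str | Path,
    fmt: Literal["pdb", "mmcif", "auto"] = "auto",
    chain_roles: Mapping[str, str] | None = None,
) -> Structure3D:
    """Read a PDB/mmCIF file into a Structure3D.

    Hydrogens and waters are dropped, only the highest-occupancy altloc of
    each atom is kept, hetero/ligand residues are separated from the polymer,
    and only the first model of a multi-model file is used (with a warning).
    ``chain_roles`` maps chain ids to subunit roles (e.g. ``{"A": "α1"}``);
    naming a chain absent from the file is an error.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    st = (
        gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        if fmt == "mmcif"
        else gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    )
    st.setup_entities()
    if len(st) > 1:
        warnings.warn(f"{path.name}: {len(st)} models; using the first", stacklevel=2)
    model = st[0]
    known_chains = {ch.name for ch in model}
    if chain_roles:
        unknown = set(chain_roles) - known_chains
        if unknown:
            raise ValueError(f"{path.name}: chain-role map names unknown chains {sorted(unknown)}")
    chains: list[Chain] = []
    hetero: list[tuple[str, Residue]] = []
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            if res.is_water():
                continue
            best: dict[str, Atom] = {}
            for at in res:
                if at.element.is_hydrogen:
                    continue
                a = Atom(
                    name=at.name,
                    element=at.element.name.upper(),
                    xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=at.occ,
                    altloc=at.altloc,
                )
                prev = best.get(at.name)
                if prev is None or a.occupancy > prev.occupancy:
                    best[at.name] = a
            if not best:
                continue
            out = Residue(number=res.seqid.num, name=res.name, atoms=list(best.values()))
            if res.het_flag == "H":
                hetero.append((ch.name, out))
            else:
                residues.append(out)
        if residues:
            role = (chain_roles or {}).get(ch.name, "")
            chains.append(Chain(chain_id=ch.name, subunit_role=role, residues=residues))
    if not chains:
        raise ValueError(f"{path.name}: no polymer chains")
    return Structure3D(structure_id=path.stem, chains=chains, hetero=hetero)


def _tm_ca_coords(
    s: Structure3D, tm_selection: Mapping[str, Sequence[tuple[int, int]]] | None
) -> tuple[np.ndarray, int]:
    """Cα coordinates of the transmembrane selection and #chains contributing."""
    coords = []
    n_chains = 0
    for c in s.chains:
        spans = None if tm_selection is None else tm_selection.get(c.chain_id)
        if tm_selection is not None and spans is None:
            continue
        got = False
        for r in c.residues:
            if spans is not None and not any(lo <= r.number <= hi for lo, hi in spans):
                continue
            ca = r.atom("CA")
            at = ca if ca is not None else (r.atoms[0] if r.atoms else None)
            if at is not None:
                coords.append(at.xyz)
                got = True
        n_chains += got
    return np.asarray(coords, dtype=float), n_chains


def pore_axis(
    s: Structure3D,
    tm_selection: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    extracellular_point: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pore axis as (origin, unit direction) from the TM bundle's principal axis.

    The axis passes through the centroid of the transmembrane Cα atoms along
    their dominant principal direction.  The direction is oriented
    extracellular→cytoplasmic: if ``extracellular_point`` is given, the axis
    points away from it; otherwise the raw principal direction is returned
    with a deterministic sign (positive z component).
    """
    coords, n_chains = _tm_ca_coords(s, tm_selection)
    if n_chains < 3:
        raise ValueError(f"pore axis needs >= 3 chains with TM residues, got {n_chains}")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    u, sv, vt = np.linalg.svd(centered, full_matrices=False)
    if sv[2] <= 1e-9 * sv[0] or len(coords) < 4:
        raise ValueError("degenerate TM geometry: atoms do not span three dimensions")
    direction = vt[0]
    if extracellular_point is not None:
        if np.dot(centroid - np.asarray(extracellular_point, float), direction) < 0:
            direction = -direction
    elif direction[2] < 0 or (direction[2] == 0 and direction[0] < 0):
        direction = -direction
    return centroid, direction / np.linalg.norm(direction)


@dataclass(frozen=True)
class PoreStep:
    s: float  # distance along the axis from the profile origin, Å
    center: tuple[float, float, float]  # refined sphere center, absolute coordinates
    radius: float  # Å; 0 when blocked
    blocked: bool
    defined: bool  # False when no atoms lie near this station


@dataclass(frozen=True)
class PoreProfile:
    origin: tuple[float, float, float]
    direction: tuple[float, float, float]
    step_size: float
    steps: tuple[PoreStep, ...]

    def radii(self) -> np.ndarray:
        return np.array([st.radius if st.defined else np.nan for st in self.steps])

    def s_values(self) -> np.ndarray:
        return np.array([st.s for st in self.steps])

    def min_radius(self) -> tuple[float, float]:
        """(radius, s) of the narrowest defined station."""
        radii = self.radii()
        if np.all(np.isnan(radii)):
            raise ValueError("profile has no defined steps")
        i = int(np.nanargmin(radii))
        return float(radii[i]), float(self.steps[i].s)

    def to_frame(self, ions: IonConstants = IonConstants()) -> pd.DataFrame:
        rows = []
        for st in self.steps:
            rows.append(
                {
                    "step_A": st.s,
                    "center_x": st.center[0],
                    "center_y": st.center[1],
                    "center_z": st.center[2],
                    "radius_A": st.radius if st.defined else np.nan,
                    "blocked": st.blocked,
                    "defined": st.defined,
                    "permeation_class": (
                        classify_permeation(st.radius, ions) if st.defined else "undefined"
                    ),
                }
            )
        return pd.DataFrame(rows)


def _plane_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, direction)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(direction, helper)
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)
    return u, v


def pore_profile(
    s: Structure3D,
    axis: tuple[np.ndarray, np.ndarray],
    step_size: float = 3.0,
    refine_center: bool = True,
    search_radius: float = 2.0,
    grid_spacing: float = 0.5,
) -> PoreProfile:
    """Maximal inscribed-sphere radius at ``step_size`` stations along the axis.

    At each station the candidate sphere center moves in the plane normal to
    the axis (coarse ``grid_spacing`` grid within ``search_radius`` of the
    axis point, then local simplex refinement); the radius is the clearance
    ``min_i (‖center − xᵢ‖ − vdW(xᵢ))`` over nearby atoms.  The search disc
    is deliberately small: it compensates for a tilted or slightly off-center
    axis while keeping the sphere from escaping sideways out of the pore
    between the lining helices.  Negative clearances clamp to zero and flag
    the station blocked.  Stations with no atoms within one step along the
    axis are marked undefined.  With ``refine_center`` false the sphere stays
    on the axis (pure fixed-axis measurement).
    """
    origin, direction = np.asarray(axis[0], float), np.asarray(axis[1], float)
    direction = direction / np.linalg.norm(direction)
    coords, radii, _ = s.atom_table()
    t = (coords - origin) @ direction
    u, v = _plane_basis(direction)
    r_max = radii.max()
    s_start = np.floor(t.min() / step_size) * step_size
    stations = np.arange(s_start, t.max() + 0.5 * step_size, step_size)

    # precompute coarse grid offsets once
    g = np.arange(-search_radius, search_radius + 1e-9, grid_spacing)
    gx, gy = np.meshgrid(g, g)
    keep = gx**2 + gy**2 <= search_radius**2
    grid_uv = np.stack([gx[keep], gy[keep]], axis=1)

    steps: list[PoreStep] = []
    for s_val in stations:
        p0 = origin + s_val * direction
        near = np.abs(t - s_val) <= step_size
        if not near.any():
            steps.append(
                PoreStep(s=float(s_val), center=tuple(p0), radius=0.0, blocked=False, defined=False)
            )
            continue
        # only atoms close enough along the axis can touch a sphere of radius
        # <= search_radius centered in this plane
        slab = np.abs(t - s_val) <= search_radius + r_max
        sc, sr = coords[slab], radii[slab]

        def clearance_uv(uv: np.ndarray) -> float:
            c = p0 + uv[0] * u + uv[1] * v
            return float(np.min(np.linalg.norm(sc - c, axis=1) - sr))

        if refine_center:
            centers = p0[None, :] + grid_uv[:, :1] * u[None, :] + grid_uv[:, 1:2] * v[None, :]
            d = np.linalg.norm(sc[None, :, :] - centers[:, None, :], axis=2) - sr[None, :]
            clear = d.min(axis=1)
            best = int(np.argmax(clear))
            res = minimize(
                lambda uv: -clearance_uv(uv)
                + (1e3 if uv[0] ** 2 + uv[1] ** 2 > search_radius**2 else 0.0),
                grid_uv[best],
                method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 300},
            )
            best_uv = res.x
            best_clear = clearance_uv(best_uv)
            if best_clear < clear[best]:  # refinement never worsens the grid optimum
                best_uv, best_clear = grid_uv[best], float(clear[best])
        else:
            best_uv = np.zeros(2)
            best_clear = clearance_uv(best_uv)
        center = p0 + best_uv[0] * u + best_uv[1] * v
        blocked = best_clear < 0
        steps.append(
            PoreStep(
                s=float(s_val),
                center=tuple(float(x) for x in center),
                radius=max(best_clear, 0.0),
                blocked=bool(blocked),
                defined=True,
            )
        )
    return PoreProfile(
        origin=tuple(float(x) for x in origin),
        direction=tuple(float(x) for x in direction),
        step_size=float(step_size),
        steps=tuple(steps),
    )


def classify_permeation(radius: float, ions: IonConstants = IonConstants()) -> str:
    """Ion-passability class of a pore radius against the chloride radii.

    Below the Pauling Cl⁻ radius the constriction is blocked; between the
    Pauling and hydrated radii only dehydrated chloride passes; at or above
    the hydrated radius hydrated chloride fits.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    if radius < ions.cl_pauling_radius:
        return "blocked"
    if radius < ions.cl_hydrated_radius:
        return "dehydrated-Cl-only"
    return "hydrated-Cl-passable"


def compare_profiles(
    wt: PoreProfile,
    mutants: Mapping[str, PoreProfile] | Sequence[PoreProfile],
    report_threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-step radius changes of mutant profiles relative to the wild type.

    All profiles must share the wild type's axis registration (same stations,
    same step size).  Returns a long-format frame with columns mutant,
    step_A, wt_radius_A, mut_radius_A, delta_A, flagged.
    """
    if not isinstance(mutants, Mapping):
        mutants = {f"mutant_{i+1}": p for i, p in enumerate(mutants)}
    rows = []
    wt_s = wt.s_values()
    wt_r = wt.radii()
    for name, prof in mutants.items():
        if prof.step_size != wt.step_size or len(prof.steps) != len(wt.steps):
            raise ValueError(f"{name}: profile steps do not match the wild type")
        if not np.allclose(prof.s_values(), wt_s, atol=1e-6):
            raise ValueError(f"{name}: station coordinates differ from the wild type")
        mut_r = prof.radii()
        delta = mut_r - wt_r
        for s_val, wr, mr, d in zip(wt_s, wt_r, mut_r, delta):
            rows.append(
                {
                    "mutant": name,
                    "step_A": float(s_val),
                    "wt_radius_A": float(wr),
                    "mut_radius_A": float(mr),
                    "delta_A": float(d),
                    "flagged": bool(np.isfinite(d) and abs(d) >= report_threshold),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Contact:
    residue_a: tuple[str, int, str]  # (chain, number, name)
    residue_b: tuple[str, int, str]
    kind: Literal["vdw", "hbond"]
    distance: float
    inter_subunit: bool


@dataclass(frozen=True)
class ContactSet:
    contacts: tuple[Contact, ...]

    def __len__(self) -> int:
        return len(self.contacts)

    def between(self, res_a: tuple[str, int], res_b: tuple[str, int]) -> list[Contact]:
        out = []
        for c in self.contacts:
            pa, pb = c.residue_a[:2], c.residue_b[:2]
            if (pa, pb) == (res_a, res_b) or (pa, pb) == (res_b, res_a):
                out.append(c)
        return out


#: atom-name prefixes regarded as hydrogen-bond capable (N/O donors/acceptors)
_HBOND_ELEMENTS = {"N", "O"}
VDW_MARGIN = 0.5
HBOND_MAX = 3.5


def contacts(
    s: Structure3D,
    selection: Sequence[tuple[str, int]] | None = None,
) -> ContactSet:
    """Residue-level van der Waals and hydrogen-bond contacts.

    A vdW contact exists when two heavy atoms of different residues approach
    within the sum of their Bondi radii plus 0.5 Å; an H-bond when an N/O
    pair approaches within 3.5 Å (classified as hbond, which takes precedence
    for the pair of atoms involved).  Distances reported are the minimum over
    the atom pairs satisfying each rule.  ``selection`` restricts one side of
    every contact to the listed (chain, residue-number) pairs; the other side
    may be any residue.  Symmetric: each contact is stored once with both
    orientations retrievable.
    """
    coords, radii, labels = s.atom_table()
    elem = []
    for c in s.chains:
        for r in c.residues:
            for a in r.atoms:
                elem.append(a.element.upper())
    elem = np.array(elem)
    resname = {}
    for c in s.chains:
        for r in c.residues:
            resname[(c.chain_id, r.number)] = r.name
    tree = cKDTree(coords)
    cutoff = 2 * max(VDW_RADII.values()) + VDW_MARGIN
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    sel = set(selection) if selection is not None else None
    best: dict[tuple[tuple[str, int], tuple[str, int], str], float] = {}
    for i, j in pairs:
        ch_i, num_i = labels[i][0], labels[i][1]
        ch_j, num_j = labels[j][0], labels[j][1]
        if (ch_i, num_i) == (ch_j, num_j):
            continue
        if sel is not None and (ch_i, num_i) not in sel and (ch_j, num_j) not in sel:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        key_res = tuple(sorted([(ch_i, num_i), (ch_j, num_j)]))
        if elem[i] in _HBOND_ELEMENTS and elem[j] in _HBOND_ELEMENTS and d <= HBOND_MAX:
            kind = "hbond"
        elif d <= radii[i] + radii[j] + VDW_MARGIN:
            kind = "vdw"
        else:
            continue
        k = (key_res[0], key_res[1], kind)
        if k not in best or d < best[k]:
            best[k] = d
    out = []
    for (ra, rb, kind), d in sorted(best.items()):
        out.append(
            Contact(
                residue_a=(ra[0], ra[1], resname[ra]),
                residue_b=(rb[0], rb[1], resname[rb]),
                kind=kind,  # type: ignore[arg-type]
                distance=d,
                inter_subunit=ra[0] != rb[0],
            )
        )
    return ContactSet(contacts=tuple(out))


def residue_distance(
    s: Structure3D,
    res_a: tuple[str, int],
    res_b: tuple[str, int],
    convention: Literal["ca", "min-heavy"] = "ca",
) -> float:
    """Distance between two residues under the chosen atom convention.

    ``ca``: Cα–Cα distance.  ``min-heavy``: minimum over all heavy-atom
    pairs.  A residue compared against itself is 0 by convention.
    """
    if res_a == res_b:
        return 0.0
    ra = s.chain(res_a[0]).residue(res_a[1])
    rb = s.chain(res_b[0]).residue(res_b[1])
    missing = [str(r) for r, found in ((res_a, ra), (res_b, rb)) if found is None]
    if missing:
        raise ValueError(f"residues not found: {', '.join(missing)}")
    assert ra is not None and rb is not None
    if convention == "ca":
        ca_a, ca_b = ra.atom("CA"), rb.atom("CA")
        missing = [f"{r} CA" for r, a in ((res_a, ca_a), (res_b, ca_b)) if a is None]
        if missing:
            raise ValueError(f"missing atoms: {', '.join(missing)}")
        assert ca_a is not None and ca_b is not None
        return float(np.linalg.norm(ca_a.xyz - ca_b.xyz))
    if convention == "min-heavy":
        xa = np.array([a.xyz for a in ra.atoms])
        xb = np.array([a.xyz for a in rb.atoms])
        return float(np.min(np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)))
    raise ValueError(f"unknown convention {convention!r}")


def kabsch_rmsd(
    a: np.ndarray, b: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of paired coordinate sets.

    Returns ``(rmsd, rotation, translation)`` such that ``a @ rotation +
    translation`` best superposes onto ``b`` with a proper rotation
    (det = +1).  Requires n >= 3 non-collinear points.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must be paired (n, 3) arrays")
    n = a.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 paired points, got {n}")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    aa, bb = a - ca, b - cb
    sv_a = np.linalg.svd(aa, compute_uv=False)
    if sv_a[1] <= 1e-9 * max(sv_a[0], 1.0):
        raise ValueError("degenerate (collinear) coordinate set")
    h = aa.T @ bb
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, 1.0, d])
    rot = u @ corr @ vt
    t = cb - ca @ rot
    diff = aa @ rot - bb
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return rmsd, rot, t
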