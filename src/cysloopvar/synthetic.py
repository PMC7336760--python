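"""Synthetic benchmark data with known ground truth.

Three generators give every analysis stage a download-free test surface:

* :func:`gen_toy_pentamer` — C5-symmetric rings of atoms around a (possibly
  rigidly moved) axis, standing in for a pentameric channel.  Exact symmetry
  makes the pore radius closed-form — ring radius minus the ring element's
  van der Waals radius — at each ring's depth, at the cost of any backbone
  realism.
* :func:`gen_family` — descendants of a random ancestor sequence with
  recorded substitutions and indels, standing in for a divergent receptor
  paralog family; the true residue correspondence is returned, never inferred.
* :func:`gen_variant_table` — missense variant tables with controlled
  placement over (helix, region) categories, standing in for merged clinical
  variant sets.

Every generator is deterministic given its seed and returns its ground truth
alongside the data.  :func:`fixtures` exposes the packaged study data: the
seven GABRA2 variants, the published cross-receptor equivalence table, the
topology registry, and the chloride radii.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

from .seqmap import ProteinSequence
from .structure3d import Atom, Chain, IonConstants, Residue, Structure3D, vdw_radius
from .topology import HELIX_ORDER, HelixSpan, PrimeAnchor, TMTopology, packaged_topology
from .variantdb import VariantRecord, parse_hgvs_p

__all__ = [
    "ToyChannelSpec",
    "FamilySpec",
    "VariantTableSpec",
    "gen_toy_pentamer",
    "write_toy_pdb",
    "gen_family",
    "gen_variant_table",
    "make_toy_topology",
    "fixtures",
    "FixtureRegistry",
]

_DATA_DIR = Path(__file__).parent / "data"

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# toy pentameric channels


@dataclass(frozen=True)
class ToyChannelSpec:
    """A stack of C5-symmetric atom rings with analytically known pore radii."""

    ring_z: tuple[float, ...] = (0.0, 6.0, 12.0)
    ring_radius: tuple[float, ...] = (5.0, 3.5, 5.0)
    atoms_per_ring: int = 5
    elements: tuple[str, ...] | None = None  # default: all carbon
    mutation_mask: Mapping[int, float] = field(default_factory=dict)  # ring -> radius decrement
    rotation: tuple[tuple[float, float, float], ...] | None = None
    translation: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.ring_z) != len(self.ring_radius):
            raise ValueError("ring_z and ring_radius must have equal length")
        if any(b <= a for a, b in zip(self.ring_z, self.ring_z[1:])):
            raise ValueError("ring z positions must be strictly increasing")
        if self.atoms_per_ring < 3:
            raise ValueError("need at least 3 atoms per ring")
        for i, r in enumerate(self.effective_radii()):
            if r <= vdw_radius(self.element(i)):
                raise ValueError(
                    f"ring {i}: radius {r} must exceed the vdW radius of {self.element(i)}"
                )

    @property
    def n_rings(self) -> int:
        return len(self.ring_z)

    def element(self, ring: int) -> str:
        if self.elements is None:
            return "C"
        return self.elements[ring]

    def effective_radii(self) -> tuple[float, ...]:
        return tuple(
            r - self.mutation_mask.get(i, 0.0) for i, r in enumerate(self.ring_radius)
        )


def gen_toy_pentamer(spec: ToyChannelSpec) -> tuple[Structure3D, list[tuple[float, float]]]:
    """Build the toy channel and its analytic pore profile.

    Returns the structure (one chain per symmetry copy, one single-atom
    residue per ring) and ``[(z, radius), ...]`` where radius is the ring
    radius minus the ring element's van der Waals radius, in the channel's
    own axis coordinates (before any rigid move).
    """
    n = spec.atoms_per_ring
    chains = []
    radii = spec.effective_radii()
    for k in range(n):
        angle = 2.0 * np.pi * k / n
        residues = []
        for i, z in enumerate(spec.ring_z):
            xyz = np.array([radii[i] * np.cos(angle), radii[i] * np.sin(angle), z])
            residues.append(
                Residue(
                    number=i + 1,
                    name="RNG",
                    atoms=[Atom(name=f"{spec.element(i)}1", element=spec.element(i), xyz=xyz)],
                )
            )
        chains.append(Chain(chain_id="ABCDEFGHIJ"[k], subunit_role="toy", residues=residues))
    st = Structure3D(structure_id=f"toy_pentamer_seed{spec.seed}", chains=chains)
    if spec.rotation is not None or spec.translation is not None:
        rot = np.asarray(spec.rotation if spec.rotation is not None else np.eye(3), float)
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-8) or np.linalg.det(rot) < 0:
            raise ValueError("rotation must be a proper orthonormal matrix")
        tr = np.asarray(spec.translation if spec.translation is not None else np.zeros(3), float)
        st = st.transformed(rot, tr)
    analytic = [
        (float(z), float(radii[i] - vdw_radius(spec.element(i))))
        for i, z in enumerate(spec.ring_z)
    ]
    return st, analytic


def write_toy_pdb(st: Structure3D, path: str | Path) -> Path:
    """Write a toy structure as a PDB file (via gemmi) for file-interface tests."""
    gs = gemmi.Structure()
    gs.name = st.structure_id
    model = gemmi.Model("1")
    for c in st.chains:
        gc = gemmi.Chain(c.chain_id)
        for r in c.residues:
            gr = gemmi.Residue()
            gr.name = r.name
            gr.seqid = gemmi.SeqId(r.number, " ")
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.xyz)
                ga.occ = a.occupancy
                gr.add_atom(ga)
            gc.add_residue(gr)
        model.add_chain(gc)
    gs.add_model(model)
    gs.setup_entities()
    # the single-atom ring residues are chemically nonstandard; mark them as
    # ordinary polymer atoms so they round-trip as ATOM records
    for m in gs:
        for c in m:
            for r in c:
                r.het_flag = "A"
    path = Path(path)
    gs.write_pdb(str(path))
    return path


# ---------------------------------------------------------------------------
# divergent sequence families

#: indels are kept away from the sequence ends to keep local/global
#: alignment comparisons stable
_INDEL_MARGIN = 3


@dataclass(frozen=True)
class FamilySpec:
    ancestor_length: int = 200
    n_descendants: int = 4
    substitution_rate: float = 0.05
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ancestor_length < 2 * _INDEL_MARGIN + 1:
            raise ValueError("ancestor too short")
        for name in ("substitution_rate", "indel_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {rate}")


@dataclass(frozen=True)
class FamilyTruth:
    """Ground truth for one descendant: position map and substituted columns."""

    #: 1-based descendant position -> 1-based ancestor position (insertions absent)
    position_map: dict[int, int]
    #: ancestor columns carrying a substitution in this descendant
    substituted: frozenset[int]


def gen_family(
    spec: FamilySpec,
) -> tuple[ProteinSequence, list[ProteinSequence], list[FamilyTruth]]:
    """Evolve descendants from a random ancestor with recorded edits.

    Substitutions replace a residue with a different one at
    ``substitution_rate`` per column.  Indels (single-residue deletions or
    insertions, equal probability halves of ``indel_rate``) avoid the first
    and last three ancestor columns.  The returned truth gives, per
    descendant, the exact descendant→ancestor residue correspondence.
    """
    rng = np.random.default_rng(spec.seed)
    ancestor = "".join(rng.choice(list(AA20), size=spec.ancestor_length))
    ref = ProteinSequence(id="ancestor", residues=ancestor)
    descendants: list[ProteinSequence] = []
    truths: list[FamilyTruth] = []
    for d in range(spec.n_descendants):
        out: list[str] = []
        pos_map: dict[int, int] = {}
        substituted: set[int] = set()
        for col in range(1, spec.ancestor_length + 1):
            interior = _INDEL_MARGIN < col <= spec.ancestor_length - _INDEL_MARGIN
            if interior and rng.random() < spec.indel_rate / 2.0:
                continue  # deletion of this column
            residue = ancestor[col - 1]
            if rng.random() < spec.substitution_rate:
                choices = [c for c in AA20 if c != residue]
                residue = str(rng.choice(choices))
                substituted.add(col)
            out.append(residue)
            pos_map[len(out)] = col
            if interior and rng.random() < spec.indel_rate / 2.0:
                out.append(str(rng.choice(list(AA20))))  # insertion, unmapped
        descendants.append(ProteinSequence(id=f"desc{d + 1}", residues="".join(out)))
        truths.append(FamilyTruth(position_map=pos_map, substituted=frozenset(substituted)))
    return ref, descendants, truths


# ---------------------------------------------------------------------------
# variant tables with controlled enrichment


@dataclass(frozen=True)
class VariantTableSpec:
    """Placement weights for synthetic missense variants over helix regions.

    ``weights`` maps categories to non-negative weights.  A category is
    either a helix id (core positions), ``"flank"`` (any flank window) or
    ``"outside"``.
    """

    topology: TMTopology
    n_variants: int = 86
    weights: Mapping[str, float] = field(
        default_factory=lambda: {"M1": 1.0, "M2": 1.0, "M3": 1.0, "M4": 1.0}
    )
    protein_length: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        vals = list(self.weights.values())
        if any(w < 0 for w in vals) or sum(vals) == 0:
            raise ValueError("weights must be non-negative and not all zero")
        for k in self.weights:
            if k not in HELIX_ORDER and k not in ("flank", "outside"):
                raise ValueError(f"unknown category {k!r}")


def _category_pools(spec: VariantTableSpec) -> dict[str, list[int]]:
    top = spec.topology
    length = spec.protein_length or top.helices[-1].end + top.flank + 10
    pools: dict[str, list[int]] = {h: [] for h in HELIX_ORDER}
    pools["flank"] = []
    pools["outside"] = []
    from .topology import assign_helix  # local import to avoid cycle at module load

    for pos in range(1, length + 1):
        helix, region = assign_helix(top, pos)
        if region == "core" and helix is not None:
            pools[helix].append(pos)
        elif region == "flank":
            pools["flank"].append(pos)
        else:
            pools["outside"].append(pos)
    return pools


def gen_variant_table(
    spec: VariantTableSpec,
) -> tuple[list[VariantRecord], list[tuple[str | None, str]]]:
    """Place variants multinomially over the weighted categories.

    Returns the records and, aligned with them, the true (helix, region) of
    each placement — the ground truth for count recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    pools = _category_pools(spec)
    cats = [c for c, w in spec.weights.items() if w > 0]
    for c in cats:
        if not pools[c]:
            raise ValueError(f"category {c!r} has no positions available")
    probs = np.array([spec.weights[c] for c in cats], dtype=float)
    probs /= probs.sum()
    counts = rng.multinomial(spec.n_variants, probs)
    from .topology import assign_helix

    records: list[VariantRecord] = []
    truth: list[tuple[str | None, str]] = []
    for cat, k in zip(cats, counts):
        pool = pools[cat]
        for pos in rng.choice(pool, size=k, replace=True):
            pos = int(pos)
            ref_aa = str(rng.choice(list(AA20)))
            alt_aa = str(rng.choice([c for c in AA20 if c != ref_aa]))
            records.append(
                VariantRecord(
                    protein_id=spec.topology.protein_id,
                    pos=pos,
                    ref_aa=ref_aa,
                    alt_aa=alt_aa,
                    source="manual",
                    significance="pathogenic",
                )
            )
            truth.append(assign_helix(spec.topology, pos))
    return records, truth


def make_toy_topology(protein_id: str = "TOY1", flank: int = 5) -> TMTopology:
    """A compact four-helix topology for synthetic variant placement."""
    spans = [(11, 30), (41, 60), (71, 90), (101, 120)]
    helices = tuple(
        HelixSpan(h, lo, hi, "extracellular" if i % 2 == 0 else "cytoplasmic")
        for i, (h, (lo, hi)) in enumerate(zip(HELIX_ORDER, spans))
    )
    return TMTopology(
        protein_id=protein_id,
        helices=helices,  # type: ignore[arg-type]
        flank=flank,
        anchor=PrimeAnchor(protein_id=protein_id, anchor_pos=50, anchor_prime=9),
    )


# ---------------------------------------------------------------------------
# packaged fixtures


@dataclass(frozen=True)
class FixtureRegistry:
    """Paths and parsed objects for the packaged study data."""

    gabra2_variants_path: Path
    table1_path: Path
    topology_path: Path
    gabra2_variants: tuple[VariantRecord, ...]
    table1: pd.DataFrame
    topologies: Mapping[str, TMTopology]
    ion_constants: IonConstants


def fixtures() -> FixtureRegistry:
    """Load the packaged fixtures: study variants, equivalence table, topology.

    The variant fixture carries the seven GABRA2 missense variants under
    study; the equivalence table is the published set of pathogenic variants
    at equivalent or flanking positions in other Cys-loop receptors, with
    their positions already expressed in GABRA2 reference coordinates.
    """
    var_path = _DATA_DIR / "gabra2_variants.tsv"
    tbl_path = _DATA_DIR / "table1_equivalents.tsv"
    top_path = _DATA_DIR / "topology.toml"
    for p in (var_path, tbl_path, top_path):
        if not p.exists():
            raise FileNotFoundError(f"packaged fixture missing: {p}")
    vdf = pd.read_csv(var_path, sep="\t", dtype=str)
    records = []
    for _, row in vdf.iterrows():
        pos, ref, alt = parse_hgvs_p(row["hgvs_p"])
        records.append(
            VariantRecord(
                protein_id=row["protein_id"],
                pos=pos,
                ref_aa=ref,
                alt_aa=alt,
                source=row["source"],
                significance=row["significance"],
                gene=row["gene"],
                hgvs_c=None if row["hgvs_c"] == "." else row["hgvs_c"],
                hgvs_p=row["hgvs_p"],
            )
        )
    table1 = pd.read_csv(tbl_path, sep="\t", dtype={"equivalent_ref_pos": int})
    return FixtureRegistry(
        gabra2_variants_path=var_path,
        table1_path=tbl_path,
        topology_path=top_path,
        gabra2_variants=tuple(records),
        table1=table1,
        topologies=packaged_topology(),
        ion_constants=IonConstants(),
    )
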