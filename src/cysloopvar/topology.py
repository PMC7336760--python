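"""Transmembrane topology of Cys-loop receptor subunits.

Each subunit crosses the membrane four times (helices M1-M4), alternating
orientation: M1 enters from the extracellular side, M2 returns from the
cytoplasmic side, and so on.  The five M2 helices of a pentamer line the ion
pore, and the field indexes M2 positions with a family-wide "prime" numbering
(..., -2', -1', 1', ..., 9', ...) so that rings of equivalent side chains can
be compared across subunits and receptor families.  The 9' position is the
conserved activation-gate leucine; the -2' ring forms the narrowest
intracellular constriction (the desensitization gate).

Prime numbering here is defined by anchor arithmetic from the conserved 9'
leucine (GABRA2 Leu291 = 9' in the packaged config) rather than from the M2
start, so it does not drift with helix-boundary annotation releases.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

from .seqmap import ProteinSequence, align_pair, map_position

__all__ = [
    "HelixSpan",
    "TMTopology",
    "PrimeAnchor",
    "PrimeIndex",
    "load_topology",
    "packaged_topology",
    "assign_helix",
    "prime_index",
    "prime_index_foreign",
    "center_offset",
    "ring_identities",
]

HELIX_ORDER = ("M1", "M2", "M3", "M4")
#: membrane orientation alternates along the chain
EXPECTED_N_TERM_SIDE = {
    "M1": "extracellular",
    "M2": "cytoplasmic",
    "M3": "extracellular",
    "M4": "cytoplasmic",
}

Region = Literal["core", "flank", "outside"]


@dataclass(frozen=True)
class HelixSpan:
    helix_id: str
    start: int
    end: int
    n_term_side: Literal["extracellular", "cytoplasmic"]

    def __post_init__(self) -> None:
        if self.helix_id not in HELIX_ORDER:
            raise ValueError(f"unknown helix id {self.helix_id!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.helix_id}: start {self.start} must precede end {self.end}")
        if self.n_term_side not in ("extracellular", "cytoplasmic"):
            raise ValueError(f"bad orientation {self.n_term_side!r}")

    @property
    def center(self) -> int:
        # even-length helices have no single central residue; take the
        # N-terminal of the middle pair
        return (self.start + self.end) // 2

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class PrimeAnchor:
    """A known (residue, prime index) pair fixing M2 prime numbering."""

    protein_id: str
    anchor_pos: int
    anchor_prime: int


@dataclass(frozen=True)
class PrimeIndex:
    """An integer M2 prime position with the conventional prime rendering."""

    value: int

    def __str__(self) -> str:
        return f"{self.value}′"

    def __int__(self) -> int:
        return self.value


@dataclass(frozen=True)
class TMTopology:
    protein_id: str
    helices: tuple[HelixSpan, HelixSpan, HelixSpan, HelixSpan]
    flank: int = 5
    anchor: PrimeAnchor | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.helices) != 4:
            raise ValueError(f"{self.protein_id}: expected four helices, got {len(self.helices)}")
        ids = tuple(h.helix_id for h in self.helices)
        if ids != HELIX_ORDER:
            raise ValueError(f"{self.protein_id}: helices must be M1..M4 in order, got {ids}")
        for h in self.helices:
            if h.n_term_side != EXPECTED_N_TERM_SIDE[h.helix_id]:
                raise ValueError(
                    f"{self.protein_id} {h.helix_id}: orientation must be "
                    f"{EXPECTED_N_TERM_SIDE[h.helix_id]}, got {h.n_term_side}"
                )
        for prev, nxt in zip(self.helices, self.helices[1:]):
            if prev.end >= nxt.start:
                raise ValueError(
                    f"{self.protein_id}: {prev.helix_id} ({prev.start}-{prev.end}) overlaps or "
                    f"follows {nxt.helix_id} ({nxt.start}-{nxt.end})"
                )
        if self.flank < 0:
            raise ValueError(f"{self.protein_id}: flank must be >= 0, got {self.flank}")
        if self.anchor is not None:
            m2 = self.helix("M2")
            lo, hi = m2.start - self.flank, m2.end + self.flank
            if not lo <= self.anchor.anchor_pos <= hi:
                raise ValueError(
                    f"{self.protein_id}: prime anchor {self.anchor.anchor_pos} outside "
                    f"M2 span {m2.start}-{m2.end} ± {self.flank}"
                )

    def helix(self, helix_id: str) -> HelixSpan:
        for h in self.helices:
            if h.helix_id == helix_id:
                return h
        raise KeyError(helix_id)


def _parse_helix(helix_id: str, raw, where: str) -> HelixSpan:
    try:
        start, end = int(raw[0]), int(raw[1])
    except (TypeError, ValueError, IndexError) as exc:
        raise ValueError(f"{where}: helix {helix_id} must be a [start, end] pair: {exc}") from exc
    return HelixSpan(helix_id, start, end, EXPECTED_N_TERM_SIDE[helix_id])


def load_topology(config: str | Path) -> dict[str, TMTopology]:
    """Load and validate a topology registry from a TOML config file.

    Expected layout, one table per protein::

        [P47869]
        gene = "GABRA2"
        M1 = [253, 274]
        M2 = [280, 301]
        M3 = [315, 336]
        M4 = [420, 441]
        flank = 5
        anchor = [291, 9]      # residue Leu291 is the 9' gate leucine
    """
    path = Path(config)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    registry: dict[str, TMTopology] = {}
    for protein_id, entry in raw.items():
        if not isinstance(entry, dict):
            raise ValueError(f"{path}: top-level key {protein_id!r} is not a table")
        missing = [h for h in HELIX_ORDER if h not in entry]
        if missing:
            raise ValueError(f"{path}: [{protein_id}] missing helices {missing}")
        helices = tuple(
            _parse_helix(h, entry[h], f"{path} [{protein_id}]") for h in HELIX_ORDER
        )
        anchor = None
        if "anchor" in entry:
            apos, aprime = int(entry["anchor"][0]), int(entry["anchor"][1])
            anchor = PrimeAnchor(protein_id=protein_id, anchor_pos=apos, anchor_prime=aprime)
        registry[protein_id] = TMTopology(
            protein_id=protein_id,
            helices=helices,  # type: ignore[arg-type]
            flank=int(entry.get("flank", 5)),
            anchor=anchor,
        )
    if not registry:
        raise ValueError(f"{path}: no protein entries")
    return registry


def packaged_topology() -> dict[str, TMTopology]:
    """The versioned topology registry shipped with the package (GABRA2)."""
    return load_topology(Path(__file__).parent / "data" / "topology.toml")


def assign_helix(top: TMTopology, pos: int) -> tuple[str | None, Region]:
    """Assign a residue to a helix and region: core, flank, or outside.

    Core means inside the annotated span; flank means within ``top.flank``
    residues of a span boundary.  When the flank windows of adjacent helices
    overlap, the position goes to the nearer helix; an exact tie goes to the
    N-terminal-side helix.
    """
    if pos < 1:
        raise ValueError(f"residue index must be >= 1, got {pos}")
    candidates: list[tuple[int, int, str]] = []  # (distance, helix_rank, id)
    for rank, h in enumerate(top.helices):
        if pos in h:
            return h.helix_id, "core"
        dist = h.start - pos if pos < h.start else pos - h.end
        if dist <= top.flank:
            candidates.append((dist, rank, h.helix_id))
    if not candidates:
        return None, "outside"
    candidates.sort()  # nearest first; rank breaks exact ties N-terminally
    return candidates[0][2], "flank"


def prime_index(top: TMTopology, pos: int) -> PrimeIndex:
    """M2 prime index of a residue, by arithmetic from the packaged anchor.

    ``prime(pos) = pos - anchor_pos + anchor_prime``; defined only inside the
    M2 span plus flanks.
    """
    if top.anchor is None:
        raise ValueError(f"{top.protein_id}: no prime anchor configured")
    m2 = top.helix("M2")
    lo, hi = m2.start - top.flank, m2.end + top.flank
    if not lo <= pos <= hi:
        raise ValueError(
            f"prime numbering undefined: {top.protein_id} {pos} outside M2 "
            f"{m2.start}-{m2.end} ± {top.flank}"
        )
    return PrimeIndex(pos - top.anchor.anchor_pos + top.anchor.anchor_prime)


def prime_index_foreign(
    subunit: ProteinSequence,
    pos: int,
    ref: ProteinSequence,
    ref_top: TMTopology,
) -> PrimeIndex:
    """Prime index of a residue of another subunit, via mapping onto the reference.

    Aligns the subunit to the reference globally, maps ``pos`` into reference
    coordinates, then applies the reference's anchored prime arithmetic.
    """
    if subunit.id == ref.id and subunit.residues == ref.residues:
        return prime_index(ref_top, pos)
    aln = align_pair(subunit, ref, mode="global")
    m = map_position(aln, pos)
    if m.target_pos is None:
        raise ValueError(
            f"{subunit.id} position {pos} is unaligned against {ref.id}; "
            f"nearest mapped flanks: {m.flank_before}, {m.flank_after}"
        )
    return prime_index(ref_top, m.target_pos)


def center_offset(top: TMTopology, pos: int) -> int:
    """Signed residue offset from the central residue of the containing helix.

    Negative offsets are toward the extracellular side, positive toward the
    cytoplasm, regardless of the helix's chain orientation.
    """
    helix_id, region = assign_helix(top, pos)
    if region == "outside" or helix_id is None:
        raise ValueError(f"{top.protein_id} {pos} is outside every helix ± flank")
    h = top.helix(helix_id)
    raw = pos - h.center
    # for an N-in-from-extracellular helix the sequence runs outside -> inside,
    # so raw already has the convention's sign; cytoplasmic-N helices run the
    # other way and flip
    return raw if h.n_term_side == "extracellular" else -raw


def ring_identities(
    prime: PrimeIndex | int,
    subunits: list[ProteinSequence],
    ref: ProteinSequence,
    ref_top: TMTopology,
) -> dict[str, str | None]:
    """Residue letter each subunit contributes at a given M2 prime position.

    Subunits whose alignment leaves the ring position unmapped are reported
    with ``None`` rather than silently dropped.
    """
    if ref_top.anchor is None:
        raise ValueError(f"{ref_top.protein_id}: no prime anchor configured")
    prime_val = int(prime)
    ref_pos = ref_top.anchor.anchor_pos + (prime_val - ref_top.anchor.anchor_prime)
    out: dict[str, str | None] = {}
    for sub in subunits:
        if sub.id == ref.id and sub.residues == ref.residues:
            out[sub.id] = ref.residue_at(ref_pos)
            continue
        aln = align_pair(ref, sub, mode="global")
        m = map_position(aln, ref_pos)
        out[sub.id] = sub.residue_at(m.target_pos) if m.target_pos is not None else None
    return out
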