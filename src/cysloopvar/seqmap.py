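"""Pairwise sequence alignment and cross-paralog residue-position mapping.

Every residue-equivalence statement between two Cys-loop receptor subunits
(e.g. "GABRG2 Pro302 occupies the same pore position as GABRA2 Pro280") is a
single source-to-reference relation, so this module maps positions through
optimal pairwise alignments against a chosen reference sequence rather than
through a multiple alignment.  Alignments use BLOSUM62 with affine gap
penalties (open 10, extend 0.5, the EMBOSS-style defaults) and a deterministic
traceback, so a given pair of sequences always yields the same mapping.

All residue indices are 1-based, following UniProt and HGVS conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "ProteinSequence",
    "PairwiseAlignment",
    "ResidueMapping",
    "read_fasta",
    "align_pair",
    "map_position",
    "percent_identity",
    "conservation_profile",
    "write_mapping_table",
]

#: the 20 standard one-letter codes plus 'X' for unknown
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

GAP_OPEN = 10.0
GAP_EXTEND = 0.5


@dataclass(frozen=True)
class ProteinSequence:
    """An identified amino-acid sequence with 1-based residue indexing."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = [(i + 1, c) for i, c in enumerate(self.residues) if c not in VALID_RESIDUES]
        if bad:
            pos, c = bad[0]
            raise ValueError(
                f"illegal residue character {c!r} in record {self.id!r} at position {pos}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, pos: int) -> str:
        """One-letter code at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.residues):
            raise IndexError(f"position {pos} outside {self.id} (length {len(self.residues)})")
        return self.residues[pos - 1]


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped pairwise alignment between a query and a target sequence.

    ``aligned_query`` and ``aligned_target`` are equal-length gapped strings;
    for local mode they cover only the aligned region, whose 1-based inclusive
    spans on the original sequences are ``query_span`` / ``target_span``.
    """

    query_id: str
    target_id: str
    aligned_query: str
    aligned_target: str
    score: float
    mode: Literal["global", "local"]
    query_span: tuple[int, int]
    target_span: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_target):
            raise ValueError("gapped strings differ in length")
        for qc, tc in zip(self.aligned_query, self.aligned_target):
            if qc == "-" and tc == "-":
                raise ValueError("alignment contains a gap-in-both column")

    def columns(self) -> Iterable[tuple[int | None, int | None, str, str]]:
        """Yield (query_pos, target_pos, query_char, target_char) per column.

        Positions are 1-based on the full sequences; ``None`` marks a gap.
        """
        q = self.query_span[0] - 1
        t = self.target_span[0] - 1
        for qc, tc in zip(self.aligned_query, self.aligned_target):
            qp = tp = None
            if qc != "-":
                q += 1
                qp = q
            if tc != "-":
                t += 1
                tp = t
            yield qp, tp, qc, tc

    def transpose(self) -> "PairwiseAlignment":
        """The same alignment with query and target roles swapped."""
        return PairwiseAlignment(
            query_id=self.target_id,
            target_id=self.query_id,
            aligned_query=self.aligned_target,
            aligned_target=self.aligned_query,
            score=self.score,
            mode=self.mode,
            query_span=self.target_span,
            target_span=self.query_span,
        )


@dataclass(frozen=True)
class ResidueMapping:
    """Where one source residue lands on the target sequence.

    ``target_pos`` is ``None`` when the source position sits in a column that
    is gapped in the target; ``flank_before``/``flank_after`` then give the
    nearest mapped positions on either side (never a silent nearest guess).
    """

    source_pos: int
    target_pos: int | None
    column_identical: bool
    flank_before: tuple[int, int] | None = None
    flank_after: tuple[int, int] | None = None

    @property
    def unaligned(self) -> bool:
        return self.target_pos is None


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read protein sequences from a FASTA file, preserving record order.

    The header token before the first whitespace becomes the id.  Residues are
    upper-cased and validated against the 20 standard codes plus ``X``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [ProteinSequence(id=r.id, residues=str(r.seq).upper()) for r in records]


def _make_aligner(mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    aligner.mode = mode
    return aligner


def align_pair(
    a: ProteinSequence, b: ProteinSequence, mode: Literal["global", "local"] = "global"
) -> PairwiseAlignment:
    """Optimal affine-gap alignment of ``a`` (query) against ``b`` (target).

    Uses BLOSUM62 with gap open 10 / extend 0.5.  Ties among equal-score
    optima are broken by the aligner's canonical first traceback, so the
    result is deterministic for a given input pair.
    """
    if not a.residues or not b.residues:
        raise ValueError("cannot align an empty sequence")
    if mode not in ("global", "local"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    aligner = _make_aligner(mode)
    aln = aligner.align(a.residues, b.residues)[0]
    gapped_q, gapped_t = str(aln[0]), str(aln[1])
    qa, ta = aln.aligned
    if mode == "local":
        q_span = (int(qa[0][0]) + 1, int(qa[-1][1]))
        t_span = (int(ta[0][0]) + 1, int(ta[-1][1]))
    else:
        q_span = (1, len(a.residues))
        t_span = (1, len(b.residues))
    return PairwiseAlignment(
        query_id=a.id,
        target_id=b.id,
        aligned_query=gapped_q,
        aligned_target=gapped_t,
        score=float(aln.score),
        mode=mode,
        query_span=q_span,
        target_span=t_span,
    )


def map_position(aln: PairwiseAlignment, source_pos: int) -> ResidueMapping:
    """Map a 1-based query position through the alignment onto the target.

    If the position's column is a gap in the target, the mapping is flagged
    unaligned and the nearest mapped flanking positions are reported instead.
    """
    lo, hi = aln.query_span
    if not lo <= source_pos <= hi:
        raise IndexError(
            f"position {source_pos} outside aligned span {lo}..{hi} of {aln.query_id}"
        )
    cols = list(aln.columns())
    hit_idx = None
    for i, (qp, _tp, _qc, _tc) in enumerate(cols):
        if qp == source_pos:
            hit_idx = i
            break
    assert hit_idx is not None
    qp, tp, qc, tc = cols[hit_idx]
    if tp is not None:
        return ResidueMapping(source_pos=source_pos, target_pos=tp, column_identical=(qc == tc))
    before = after = None
    for qp2, tp2, _, _ in reversed(cols[:hit_idx]):
        if qp2 is not None and tp2 is not None:
            before = (qp2, tp2)
            break
    for qp2, tp2, _, _ in cols[hit_idx + 1 :]:
        if qp2 is not None and tp2 is not None:
            after = (qp2, tp2)
            break
    return ResidueMapping(
        source_pos=source_pos,
        target_pos=None,
        column_identical=False,
        flank_before=before,
        flank_after=after,
    )


def percent_identity(aln: PairwiseAlignment) -> float:
    """Identical columns divided by aligned (non-gap-pair) columns, in [0, 1]."""
    aligned = identical = 0
    for qp, tp, qc, tc in aln.columns():
        if qp is not None and tp is not None:
            aligned += 1
            identical += qc == tc
    if aligned == 0:
        raise ValueError("alignment has no aligned columns")
    return identical / aligned


def conservation_profile(
    ref: ProteinSequence, others: Sequence[ProteinSequence]
) -> np.ndarray:
    """Fraction of homologs identical to the reference at each position.

    Each homolog is globally aligned to the reference; a reference position
    whose column is gapped in the homolog counts as non-identical there.
    Returns an array of length ``ref.length`` with values in [0, 1].
    """
    if not others:
        raise ValueError("need at least one homolog")
    hits = np.zeros(ref.length, dtype=float)
    for other in others:
        aln = align_pair(ref, other, mode="global")
        for qp, tp, qc, tc in aln.columns():
            if qp is not None and tp is not None and qc == tc:
                hits[qp - 1] += 1.0
    return hits / len(others)


def write_mapping_table(
    path: str | Path,
    source: ProteinSequence,
    target: ProteinSequence,
    positions: Iterable[int],
    mode: Literal["global", "local"] = "global",
) -> None:
    """Write a tab-delimited residue-equivalence table for the given positions."""
    aln = align_pair(source, target, mode=mode)
    with open(path, "w") as fh:
        fh.write(
            "source_id\tsource_pos\tsource_aa\ttarget_id\ttarget_pos\ttarget_aa\tcolumn_identical\n"
        )
        for pos in positions:
            m = map_position(aln, pos)
            taa = target.residue_at(m.target_pos) if m.target_pos is not None else "-"
            tpos = m.target_pos if m.target_pos is not None else "NA"
            fh.write(
                f"{source.id}\t{pos}\t{source.residue_at(pos)}\t{target.id}\t"
                f"{tpos}\t{taa}\t{str(m.column_identical).lower()}\n"
            )
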