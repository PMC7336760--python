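"""Protein-level missense variant tables: parsing, merging, and equivalence reports.

Inputs are tab-delimited tables in two minimal dialects — a ClinVar-style one
(clinical significance vocabulary) and a Humsavar-style one (Disease /
Polymorphism / Unclassified).  Everything operates in protein coordinates on
the canonical sequence; genomic-to-protein lifting is out of scope.  Merging
follows the rule that a duplicate is the same amino-acid change at the same
position in the same protein, counted once, and that a variant whose key is
pathogenic-class in one source but benign/uncertain-class in the other is
dropped from both.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .seqmap import ProteinSequence, align_pair, map_position

__all__ = [
    "VariantRecord",
    "EquivalenceRow",
    "parse_hgvs_p",
    "codon_index",
    "load_variants",
    "merge_dedupe",
    "build_equivalence_table",
    "equivalence_frame",
]

logger = logging.getLogger(__name__)

AA3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}

#: closed significance vocabulary after normalization
SIGNIFICANCE_VOCAB = frozenset(
    {
        "pathogenic",
        "likely_pathogenic",
        "pathogenic/likely_pathogenic",
        "disease",
        "benign",
        "likely_benign",
        "uncertain",
        "polymorphism",
        "unclassified",
    }
)
#: labels that count as disease-causing when filtering / resolving conflicts
PATHOGENIC_CLASS = frozenset(
    {"pathogenic", "likely_pathogenic", "pathogenic/likely_pathogenic", "disease"}
)

_NORMALIZE = {
    "pathogenic": "pathogenic",
    "likely pathogenic": "likely_pathogenic",
    "likely_pathogenic": "likely_pathogenic",
    "pathogenic/likely pathogenic": "pathogenic/likely_pathogenic",
    "pathogenic/likely_pathogenic": "pathogenic/likely_pathogenic",
    "disease": "disease",
    "benign": "benign",
    "likely benign": "likely_benign",
    "likely_benign": "likely_benign",
    "uncertain significance": "uncertain",
    "uncertain": "uncertain",
    "vus": "uncertain",
    "polymorphism": "polymorphism",
    "unclassified": "unclassified",
}


@dataclass(frozen=True)
class VariantRecord:
    """A protein-level missense variant on a canonical sequence."""

    protein_id: str
    pos: int
    ref_aa: str
    alt_aa: str
    source: str  # clinvar | humsavar | manual | both
    significance: str
    gene: str = ""
    hgvs_c: str | None = None
    hgvs_p: str | None = None
    rsid: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"residue index must be >= 1, got {self.pos}")
        if self.ref_aa == self.alt_aa:
            raise ValueError(
                f"{self.protein_id} {self.ref_aa}{self.pos}{self.alt_aa}: not missense"
            )
        if self.significance not in SIGNIFICANCE_VOCAB:
            raise ValueError(f"significance {self.significance!r} outside closed vocabulary")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity for dedup: same change, same position, same protein."""
        return (self.protein_id, self.pos, self.ref_aa, self.alt_aa)

    @property
    def is_pathogenic(self) -> bool:
        return self.significance in PATHOGENIC_CLASS

    def short(self) -> str:
        return f"{self.ref_aa}{self.pos}{self.alt_aa}"


@dataclass(frozen=True)
class EquivalenceRow:
    """One pathogenic variant in another receptor matched to a query variant."""

    query: VariantRecord
    other_gene: str
    family: str
    other_variant: str
    equivalent_ref_pos: int
    relation: Literal["exact", "adjacent"]

    def __post_init__(self) -> None:
        delta = abs(self.query.pos - self.equivalent_ref_pos)
        expected = "exact" if delta == 0 else "adjacent" if delta == 1 else None
        if self.relation != expected:
            raise ValueError(
                f"relation {self.relation!r} inconsistent with positions "
                f"{self.query.pos} vs {self.equivalent_ref_pos}"
            )


_HGVS_P_RE = re.compile(r"^(?:p\.)?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")


def parse_hgvs_p(text: str) -> tuple[int, str, str]:
    """Parse a three-letter protein HGVS like ``p.Pro280Leu`` -> (280, 'P', 'L').

    Accepts the bare form without the ``p.`` prefix.  Nonsense, frameshift,
    synonymous and otherwise non-missense notations are rejected.
    """
    m = _HGVS_P_RE.match(text.strip())
    if not m:
        raise ValueError(f"not a missense protein HGVS: {text!r}")
    ref3, pos, alt3 = m.group(1), int(m.group(2)), m.group(3)
    if ref3 not in AA3TO1 or alt3 not in AA3TO1:
        raise ValueError(f"unknown amino-acid code in {text!r}")
    ref, alt = AA3TO1[ref3], AA3TO1[alt3]
    if ref == alt:
        raise ValueError(f"{text!r} is synonymous, not missense")
    if pos < 1:
        raise ValueError(f"bad residue index in {text!r}")
    return pos, ref, alt


def codon_index(c_pos: int, cds_length: int | None = None) -> int:
    """Residue index of the codon containing coding-nucleotide position ``c_pos``.

    E.g. c.839 lies in codon 280.  ``codon_index = ceil(c_pos / 3)``.
    """
    if c_pos < 1:
        raise ValueError(f"coding position must be >= 1, got {c_pos}")
    if cds_length is not None and c_pos > cds_length:
        raise ValueError(f"coding position {c_pos} beyond CDS length {cds_length}")
    return math.ceil(c_pos / 3)


def normalize_significance(label: str) -> str:
    key = label.strip().lower().replace("‐", "-")
    if key not in _NORMALIZE:
        raise ValueError(f"unrecognized significance label {label!r}")
    return _NORMALIZE[key]


# minimal column subsets per dialect; a column_map adapts real exports
_DIALECT_COLUMNS = {
    "clinvar": {"variant": "hgvs_p", "significance": "significance"},
    "humsavar": {"variant": "variant", "significance": "category"},
}


def load_variants(
    path: str | Path,
    dialect: Literal["clinvar", "humsavar"],
    column_map: Mapping[str, str] | None = None,
    pathogenic_only: bool = False,
) -> list[VariantRecord]:
    """Load missense variant records from a tab-delimited table.

    Both dialects need a protein HGVS column and a significance column plus
    ``gene`` and ``protein_id``; ``column_map`` overrides the default column
    names (keys ``variant`` and ``significance``).  Rows that are not
    parseable missense changes are logged and skipped, with the skip count
    reported at INFO level.
    """
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cols = dict(_DIALECT_COLUMNS[dialect])
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna(".")
    for logical, actual in cols.items():
        if actual not in df.columns:
            raise ValueError(f"{path}: missing required column {actual!r} ({logical})")
    records: list[VariantRecord] = []
    skipped = 0
    for i, row in df.iterrows():
        try:
            pos, ref, alt = parse_hgvs_p(row[cols["variant"]])
            sig = normalize_significance(row[cols["significance"]])
            rec = VariantRecord(
                protein_id=row.get("protein_id", "."),
                pos=pos,
                ref_aa=ref,
                alt_aa=alt,
                source=dialect,
                significance=sig,
                gene=row.get("gene", ""),
                hgvs_c=None if row.get("hgvs_c", ".") == "." else row.get("hgvs_c"),
                hgvs_p=row[cols["variant"]],
                rsid=None if row.get("rsid", ".") == "." else row.get("rsid"),
            )
        except ValueError as exc:
            logger.debug("%s row %d skipped: %s", path, i, exc)
            skipped += 1
            continue
        records.append(rec)
    if skipped:
        logger.info("%s: skipped %d unparseable/non-missense rows", path, skipped)
    if pathogenic_only:
        records = [r for r in records if r.is_pathogenic]
    return records


def merge_dedupe(
    a: Sequence[VariantRecord], b: Sequence[VariantRecord]
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Merge two sources into one pathogenic set with provenance counts.

    The same amino-acid change at the same position in the same protein is
    counted once (source becomes ``both``); a key that is pathogenic-class in
    one source but benign/uncertain-class in the other is a conflicting
    interpretation and is removed entirely.  Returns the merged pathogenic
    records (sorted by key for order-independence) and counts
    ``{"only_a": .., "only_b": .., "both": .., "conflicts_dropped": ..}``.
    """
    by_key_a = {r.key: r for r in a}
    by_key_b = {r.key: r for r in b}
    merged: list[VariantRecord] = []
    counts = {"only_a": 0, "only_b": 0, "both": 0, "conflicts_dropped": 0}
    for key in sorted(set(by_key_a) | set(by_key_b)):
        ra, rb = by_key_a.get(key), by_key_b.get(key)
        if ra is not None and rb is not None:
            if ra.is_pathogenic != rb.is_pathogenic:
                counts["conflicts_dropped"] += 1
                logger.debug("conflicting interpretations for %s; dropped", key)
                continue
            if ra.is_pathogenic:
                merged.append(replace(ra, source="both"))
                counts["both"] += 1
        elif ra is not None:
            if ra.is_pathogenic:
                merged.append(ra)
                counts["only_a"] += 1
        else:
            assert rb is not None
            if rb.is_pathogenic:
                merged.append(rb)
                counts["only_b"] += 1
    return merged, counts


def build_equivalence_table(
    query_variants: Sequence[VariantRecord],
    other_variants: Sequence[VariantRecord],
    sequences: Mapping[str, ProteinSequence] | None = None,
    ref: ProteinSequence | None = None,
    precomputed_ref_pos: Mapping[tuple[str, int], int] | None = None,
    families: Mapping[str, str] | None = None,
    window: int = 1,
) -> list[EquivalenceRow]:
    """Match query variants to pathogenic variants at equivalent positions.

    Each pathogenic variant in another receptor whose position, expressed in
    reference coordinates, lies within ``window`` residues of a query
    position is reported once, under its *nearest* query (``exact`` at
    distance 0, ``adjacent`` at 1; an exact-distance tie goes to the
    N-terminal query).  Assigning to the nearest query keeps each
    other-receptor variant in a single group even when two query variants
    are adjacent in sequence.  Reference coordinates come either from
    ``precomputed_ref_pos`` (keyed by ``(gene, pos)``) or from a global
    alignment of the other receptor's sequence to ``ref``.  Variants whose
    position cannot be expressed in reference coordinates are skipped with a
    log message.
    """
    if not 0 <= window <= 1:
        raise ValueError("window must be 0 (exact only) or 1 (exact + adjacent)")
    mapped: list[tuple[VariantRecord, int]] = []
    aln_cache: dict[str, object] = {}
    for ov in other_variants:
        if not ov.is_pathogenic:
            continue
        ref_pos: int | None = None
        if precomputed_ref_pos is not None and (ov.gene, ov.pos) in precomputed_ref_pos:
            ref_pos = precomputed_ref_pos[(ov.gene, ov.pos)]
        elif sequences is not None and ref is not None and ov.protein_id in sequences:
            if ov.protein_id not in aln_cache:
                aln_cache[ov.protein_id] = align_pair(sequences[ov.protein_id], ref, "global")
            m = map_position(aln_cache[ov.protein_id], ov.pos)  # type: ignore[arg-type]
            ref_pos = m.target_pos
        if ref_pos is None:
            logger.warning("cannot map %s %s to reference coordinates", ov.gene, ov.short())
            continue
        mapped.append((ov, ref_pos))
    rows: list[EquivalenceRow] = []
    for ov, ref_pos in mapped:
        candidates = [
            (abs(qv.pos - ref_pos), qv.pos, qv) for qv in query_variants
            if abs(qv.pos - ref_pos) <= window
        ]
        if not candidates:
            continue
        delta, _, qv = min(candidates, key=lambda c: (c[0], c[1]))
        rows.append(
            EquivalenceRow(
                query=qv,
                other_gene=ov.gene,
                family=(families or {}).get(ov.gene, ""),
                other_variant=ov.hgvs_p or ov.short(),
                equivalent_ref_pos=ref_pos,
                relation="exact" if delta == 0 else "adjacent",
            )
        )
    rows.sort(key=lambda r: (r.query.pos, r.other_gene, r.equivalent_ref_pos, r.other_variant))
    return rows


_EQUIVALENCE_COLUMNS = [
    "query_gene", "query_variant", "query_pos", "other_gene", "family",
    "other_variant", "equivalent_ref_pos", "relation",
]


def equivalence_frame(rows: Iterable[EquivalenceRow]) -> pd.DataFrame:
    """Long-format DataFrame of an equivalence report, ready for TSV export."""
    records = [
            {
                "query_gene": r.query.gene,
                "query_variant": r.query.hgvs_p or r.query.short(),
                "query_pos": r.query.pos,
                "other_gene": r.other_gene,
                "family": r.family,
                "other_variant": r.other_variant,
                "equivalent_ref_pos": r.equivalent_ref_pos,
                "relation": r.relation,
            }
            for r in rows
        ]
    if not records:
        return pd.DataFrame(columns=_EQUIVALENCE_COLUMNS)
    return pd.DataFrame(records, columns=_EQUIVALENCE_COLUMNS)
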