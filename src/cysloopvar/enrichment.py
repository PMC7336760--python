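"""Distribution of disease variants along the four transmembrane helices.

Disease variants of Cys-loop receptor subunits cluster in the pore-lining M2
helix.  This module counts variants per helix (optionally including ±flank
windows), tests the per-helix counts against an equal-expectation chi-square
goodness of fit (df 3), builds center-relative position histograms, and
reports helix positions never hit by a disease variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .topology import HELIX_ORDER, TMTopology, assign_helix, center_offset
from .variantdb import VariantRecord

__all__ = [
    "HelixCounts",
    "ChiSquareResult",
    "count_by_helix",
    "chisquare_uniform",
    "position_histogram",
    "zero_coverage_positions",
]


@dataclass(frozen=True)
class HelixCounts:
    """Disease-variant counts per helix, plus the excluded outside count."""

    counts: dict[str, int]
    flank_included: bool
    outside: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[h] for h in HELIX_ORDER], dtype=float)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: tuple[float, ...]


def count_by_helix(
    variants: Sequence[VariantRecord],
    topologies: Mapping[str, TMTopology],
    flank_included: bool = False,
) -> HelixCounts:
    """Count each variant once, in the helix its position falls in.

    With ``flank_included`` false only core-helix positions count; with it
    true, positions in the ±flank windows count toward their (nearer) helix.
    Variants outside every window are excluded but reported in ``outside``.
    A variant whose protein has no topology is an error, not a silent drop.
    """
    counts = {h: 0 for h in HELIX_ORDER}
    outside = 0
    for v in variants:
        top = topologies.get(v.protein_id)
        if top is None:
            raise KeyError(f"no topology for protein {v.protein_id!r}")
        helix, region = assign_helix(top, v.pos)
        in_scope = region == "core" or (flank_included and region == "flank")
        if in_scope and helix is not None:
            counts[helix] += 1
        else:
            outside += 1
    return HelixCounts(counts=counts, flank_included=flank_included, outside=outside)


def chisquare_uniform(
    counts: HelixCounts, expected: Sequence[float] | None = None
) -> ChiSquareResult:
    """Goodness of fit of the per-helix counts against expected frequencies.

    Default expectation is equal counts across M1-M4 ("expected by chance");
    pass helix lengths (or any weights) as ``expected`` for a
    length-proportional null instead.  The p-value uses the exact chi-square
    survival function with df 3.
    """
    observed = counts.as_array()
    total = observed.sum()
    if total <= 0:
        raise ValueError("no variants to test")
    if expected is None:
        exp = np.full(4, total / 4.0)
    else:
        w = np.asarray(expected, dtype=float)
        if w.shape != (4,) or (w <= 0).any():
            raise ValueError("expected weights must be four positive numbers")
        exp = total * w / w.sum()
    stat, p = stats.chisquare(observed, f_exp=exp)
    return ChiSquareResult(
        statistic=float(stat), df=3, p_value=float(p), expected=tuple(float(e) for e in exp)
    )


def position_histogram(
    variants: Sequence[VariantRecord],
    topologies: Mapping[str, TMTopology],
) -> pd.DataFrame:
    """Histogram of variant positions relative to each helix center.

    Offsets follow the membrane convention: negative toward the extracellular
    space, positive toward the cytosol.  Flank positions are tagged separately
    so core and flank contributions stay distinguishable.  Returns a
    long-format frame with columns helix, offset, region, count.
    """
    rows: list[tuple[str, int, str]] = []
    for v in variants:
        top = topologies.get(v.protein_id)
        if top is None:
            raise KeyError(f"no topology for protein {v.protein_id!r}")
        helix, region = assign_helix(top, v.pos)
        if region == "outside" or helix is None:
            continue
        rows.append((helix, center_offset(top, v.pos), region))
    if not rows:
        return pd.DataFrame(columns=["helix", "offset", "region", "count"])
    df = pd.DataFrame(rows, columns=["helix", "offset", "region"])
    out = (
        df.groupby(["helix", "offset", "region"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
        .sort_values(["helix", "offset", "region"], ignore_index=True)
    )
    return out


def zero_coverage_positions(
    variants: Sequence[VariantRecord],
    topology: TMTopology,
    helix_id: str,
) -> int:
    """Number of core positions of one helix with no disease variant.

    Positions are compared in center-offset space so that subunits of
    different lengths (sharing this topology's helix geometry) pool
    correctly.
    """
    h = topology.helix(helix_id)
    covered: set[int] = set()
    for v in variants:
        helix, region = assign_helix(topology, v.pos)
        if helix == helix_id and region == "core":
            covered.add(center_offset(topology, v.pos))
    return (h.end - h.start + 1) - len(covered)
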