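"""TCR clonotype frequency analysis.

A clonotype is identified by its CDR3 nucleotide sequence(s) plus V/D/J
gene calls; single-cell TCR capture frequently drops one chain, producing
"orphan" single-chain records of a clone that was in fact paired.  The
pooling rule implemented here merges a beta-only orphan into a paired
clonotype when the beta CDR3 nucleotide sequence AND all three V/D/J calls
match exactly — the strictest reading of the rule; nothing fuzzy.

Also provided: clone frequency tables, Shannon diversity / clonality, and
flow-cytometry Vbeta-panel time courses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from ._util import least_squares_slope, series_direction

__all__ = [
    "Clonotype",
    "RepertoireSample",
    "MergeReport",
    "clonotype_frequencies",
    "merge_orphan_chains",
    "merge_orphan_chains_with_report",
    "top_clone_fraction",
    "diversity",
    "vbeta_timecourse",
    "VbetaSeries",
]


@dataclass(frozen=True)
class Clonotype:
    """One clonotype with its cell count; either chain may be absent but
    not both."""

    alpha_nt: str | None = None
    beta_nt: str | None = None
    alpha_aa: str | None = None
    beta_aa: str | None = None
    v_beta: str | None = None
    d_beta: str | None = None
    j_beta: str | None = None
    cells: int = 1

    def __post_init__(self) -> None:
        if self.alpha_nt is None and self.beta_nt is None:
            raise ValueError("a clonotype needs at least one chain")
        if self.cells < 1:
            raise ValueError("cells must be >= 1")

    @property
    def is_paired(self) -> bool:
        return self.alpha_nt is not None and self.beta_nt is not None

    @property
    def is_beta_only(self) -> bool:
        return self.alpha_nt is None and self.beta_nt is not None

    @property
    def beta_key(self) -> tuple[str | None, str | None, str | None, str | None]:
        return (self.beta_nt, self.v_beta, self.d_beta, self.j_beta)


@dataclass(frozen=True)
class RepertoireSample:
    sample_id: str
    clonotypes: tuple[Clonotype, ...]
    timepoint: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "clonotypes", tuple(self.clonotypes))

    @property
    def total_cells(self) -> int:
        return sum(c.cells for c in self.clonotypes)


def clonotype_frequencies(
    s: RepertoireSample,
) -> list[tuple[Clonotype, int, float]]:
    """(clonotype, cells, fraction) rows sorted by descending cell count;
    fractions sum to 1."""
    total = s.total_cells
    if total == 0:
        raise ValueError("empty repertoire")
    rows = [(c, c.cells, c.cells / total) for c in s.clonotypes]
    rows.sort(key=lambda r: (-r[1], r[0].beta_nt or "", r[0].alpha_nt or ""))
    return rows


@dataclass(frozen=True)
class MergeReport:
    merged: tuple[tuple[Clonotype, Clonotype], ...] = ()  # (orphan, target)
    ambiguous: tuple[Clonotype, ...] = ()


def merge_orphan_chains_with_report(
    s: RepertoireSample,
) -> tuple[RepertoireSample, MergeReport]:
    """Pool beta-only orphan clonotypes into paired clonotypes with an
    identical beta chain.

    An orphan merges only when exactly one paired clonotype matches its
    (beta_nt, v_beta, d_beta, j_beta) key; with two or more paired
    candidates the orphan is left as-is and listed in the report.  Total
    cells are conserved.
    """
    paired_by_key: dict[tuple, list[int]] = {}
    for i, c in enumerate(s.clonotypes):
        if c.is_paired:
            paired_by_key.setdefault(c.beta_key, []).append(i)

    extra_cells: dict[int, int] = {}
    drop: set[int] = set()
    merged: list[tuple[Clonotype, Clonotype]] = []
    ambiguous: list[Clonotype] = []
    for i, c in enumerate(s.clonotypes):
        if not c.is_beta_only:
            continue
        targets = paired_by_key.get(c.beta_key, [])
        if len(targets) == 1:
            t = targets[0]
            extra_cells[t] = extra_cells.get(t, 0) + c.cells
            drop.add(i)
            merged.append((c, s.clonotypes[t]))
        elif len(targets) > 1:
            ambiguous.append(c)

    out: list[Clonotype] = []
    for i, c in enumerate(s.clonotypes):
        if i in drop:
            continue
        if i in extra_cells:
            c = replace(c, cells=c.cells + extra_cells[i])
        out.append(c)
    result = RepertoireSample(
        sample_id=s.sample_id, clonotypes=tuple(out), timepoint=s.timepoint
    )
    return result, MergeReport(merged=tuple(merged), ambiguous=tuple(ambiguous))


def merge_orphan_chains(s: RepertoireSample) -> RepertoireSample:
    """As :func:`merge_orphan_chains_with_report`, returning the pooled
    sample only."""
    return merge_orphan_chains_with_report(s)[0]


def top_clone_fraction(s: RepertoireSample) -> tuple[Clonotype, float]:
    """Largest clonotype and its cell fraction; ties break
    lexicographically on the beta CDR3 nucleotide sequence."""
    if not s.clonotypes:
        raise ValueError("empty repertoire")
    top = min(
        s.clonotypes, key=lambda c: (-c.cells, c.beta_nt or "", c.alpha_nt or "")
    )
    return top, top.cells / s.total_cells


def diversity(s: RepertoireSample) -> tuple[float, float]:
    """Shannon entropy (nats) over clone fractions and normalized
    clonality ``1 - H / ln(richness)``.

    Clonality is 0 for a perfectly even repertoire and approaches 1 for a
    repertoire dominated by one clone; a single-clone repertoire has H = 0
    and clonality 1 by convention.
    """
    total = s.total_cells
    if total == 0:
        raise ValueError("empty repertoire")
    fracs = [c.cells / total for c in s.clonotypes]
    h = -sum(p * math.log(p) for p in fracs if p > 0)
    richness = len(fracs)
    clonality = 1.0 if richness == 1 else 1.0 - h / math.log(richness)
    return h, clonality


@dataclass(frozen=True)
class VbetaSeries:
    family: str
    timepoints: tuple[str, ...]
    fractions: tuple[float, ...]
    direction: str
    slope_per_step: float | None = field(default=None)


def vbeta_timecourse(
    series: Mapping[str, Mapping[str, float]],
    family: str,
    *,
    timepoint_order: Iterable[str] | None = None,
) -> VbetaSeries:
    """Time course of one Vbeta antibody family's cell fraction.

    ``series`` maps timepoint -> {family -> fraction of CD4+ cells}; a
    24-antibody flow panel covers roughly 70% of the normal repertoire so
    per-timepoint fractions need not sum to 1.  Timepoints are taken in
    ``timepoint_order`` when given, else sorted.
    """
    tps = list(timepoint_order) if timepoint_order is not None else sorted(series)
    fracs = []
    for tp in tps:
        fam = series[tp]
        if family not in fam:
            raise KeyError(f"family {family!r} missing at timepoint {tp!r}")
        f = fam[family]
        if not 0.0 <= f <= 1.0:
            raise ValueError("panel fractions must be in [0, 1]")
        fracs.append(f)
    if not fracs:
        raise ValueError("empty panel series")
    return VbetaSeries(
        family=family,
        timepoints=tuple(tps),
        fractions=tuple(fracs),
        direction=series_direction(fracs),
        slope_per_step=least_squares_slope(range(len(fracs)), fracs),
    )
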