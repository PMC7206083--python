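"""Ultra-deep amplicon variant detection and longitudinal VAF tracking.

Amplicon sequencing at depths up to ~100,000x detects variants down to a
0.5% allele fraction.  Two rules separate a true low-frequency somatic
variant from sequencing noise at that depth:

* the variant base frequency (VAF) must reach 0.5% of all called reads at
  the position, and
* the *base quality frequency ratio* must be at least 0.9.  The ratio
  compares the variant reads' share of the position's quality mass with
  their share of the read count — equivalently, the mean base quality of
  variant-supporting reads relative to the mean base quality of all reads.
  Sequencing errors carry systematically lower base qualities, so genuine
  variants cluster near 1 while error pileups fall below the cutoff.

Both thresholds are inclusive, and the VAF threshold is applied to the
*reported* one-decimal VAF (the resolution at which amplicon tables are
printed and at which the 0.5% sensitivity claim operates).

The tracking helpers summarise calls across years (VAF trajectories),
across sorted cell fractions (lineage confinement) and across a patient
cohort (carrier prevalence).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from ._util import least_squares_slope, round_half_away, series_direction
from .somatic import QualityPileup

__all__ = [
    "AmpliconMeasurement",
    "AmpliconThresholds",
    "VafSeries",
    "CompartmentFlag",
    "base_quality_frequency_ratio",
    "call_amplicon_variant",
    "track_vaf",
    "confinement_report",
    "cohort_prevalence",
]

# guard against binary representation error at the inclusive ratio boundary
_RATIO_EPS = 1e-12


@dataclass(frozen=True)
class AmpliconThresholds:
    """Detection thresholds; defaults are the published amplicon rules
    (VAF >= 0.5% of called reads, base quality frequency ratio >= 0.9,
    both inclusive)."""

    min_vaf: float = 0.5
    min_freq_ratio: float = 0.9
    invert_ratio: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_vaf <= 100.0:
            raise ValueError("min_vaf is a percentage in [0, 100]")
        if self.min_freq_ratio < 0:
            raise ValueError("min_freq_ratio must be non-negative")


@dataclass(frozen=True)
class AmpliconMeasurement:
    """One amplicon assay of one variant in one sample: the mirror of a
    published amplicon-table row, plus the boolean call."""

    subject: str
    sample_year: int
    compartment: str
    gene: str
    chrom: str
    pos: int
    ref: str
    var: str
    call_depth: int
    ref_calls: int
    var_calls: int
    vaf: float  # percentage, one decimal
    freq_ratio: float | None
    called: bool

    def __post_init__(self) -> None:
        if self.ref_calls + self.var_calls != self.call_depth:
            raise ValueError("ref_calls + var_calls must equal call_depth")


def base_quality_frequency_ratio(
    p: QualityPileup, *, invert: bool = False
) -> float:
    """Base quality frequency ratio of a pileup.

    Computed as ``(qsum_var / qsum_all) / (var_calls / depth)`` — the mean
    quality of variant-supporting bases over the mean quality of all bases
    at the position.  1 means variant bases carry typical quality; values
    well below 1 flag low-quality (error-like) variant support.  ``invert``
    returns the reciprocal reading.
    """
    if p.var_calls == 0:
        raise ValueError("frequency ratio undefined with no variant calls")
    qsum_all = p.qsum_ref + p.qsum_var
    if qsum_all <= 0:
        raise ValueError("frequency ratio undefined with zero quality mass")
    ratio = (p.qsum_var / qsum_all) / (p.var_calls / p.depth)
    return 1.0 / ratio if invert else ratio


def call_amplicon_variant(
    p: QualityPileup,
    th: AmpliconThresholds | None = None,
    *,
    subject: str = "",
    sample_year: int = 0,
    compartment: str = "",
    gene: str = "",
) -> AmpliconMeasurement:
    """Apply the VAF and quality-ratio rules to one pileup.

    The VAF is reported to one decimal (half away from zero) and the call
    compares that reported value against ``min_vaf``; the ratio threshold
    is inclusive.  A pileup with no variant reads yields VAF 0.0, no
    ratio, and no call.
    """
    th = th or AmpliconThresholds()
    if p.depth == 0:
        raise ValueError("call_depth must be positive")
    vaf = round_half_away(100.0 * p.var_calls / p.depth, 1)
    if p.var_calls > 0 and (p.qsum_ref + p.qsum_var) > 0:
        ratio = base_quality_frequency_ratio(p, invert=th.invert_ratio)
    else:
        ratio = None
    called = (
        vaf >= th.min_vaf
        and ratio is not None
        and ratio >= th.min_freq_ratio - _RATIO_EPS
    )
    return AmpliconMeasurement(
        subject=subject,
        sample_year=sample_year,
        compartment=compartment,
        gene=gene,
        chrom=p.chrom,
        pos=p.pos,
        ref=p.ref_base,
        var=p.var_base,
        call_depth=p.depth,
        ref_calls=p.ref_calls,
        var_calls=p.var_calls,
        vaf=vaf,
        freq_ratio=ratio,
        called=called,
    )


@dataclass(frozen=True)
class VafSeries:
    """A year-ordered VAF trajectory with a descriptive trend summary."""

    subject: str
    gene: str
    compartment: str
    years: tuple[int, ...]
    vafs: tuple[float, ...]
    direction: str
    slope_pct_per_year: float | None


def track_vaf(
    measurements: Iterable[AmpliconMeasurement],
    subject: str,
    gene: str,
    compartment: str,
) -> VafSeries:
    """Longitudinal VAF series for one (subject, gene, compartment) key.

    The slope is an ordinary least-squares fit in percent per year, a
    descriptive summary only (no inference is attached).
    """
    rows = sorted(
        (
            m
            for m in measurements
            if m.subject == subject
            and m.gene == gene
            and m.compartment == compartment
        ),
        key=lambda m: m.sample_year,
    )
    if not rows:
        raise ValueError(
            f"no measurements for subject={subject!r} gene={gene!r} "
            f"compartment={compartment!r}"
        )
    years = tuple(m.sample_year for m in rows)
    vafs = tuple(m.vaf for m in rows)
    return VafSeries(
        subject=subject,
        gene=gene,
        compartment=compartment,
        years=years,
        vafs=vafs,
        direction=series_direction(vafs),
        slope_pct_per_year=least_squares_slope(years, vafs),
    )


@dataclass(frozen=True)
class CompartmentFlag:
    vaf: float
    flag: str  # carrier | shared | trace | absent
    ratio_to_max: float | None


def confinement_report(
    measurements: Iterable[AmpliconMeasurement],
    *,
    trace_factor: float = 0.5,
) -> dict[str, CompartmentFlag]:
    """Classify compartments of one subject/gene/year by VAF.

    The compartment with the maximum VAF is the ``carrier``; uncalled
    compartments are ``absent``; called compartments below
    ``trace_factor * max_vaf`` are ``trace`` (contamination-level signal,
    with the trace/max ratio reported); the remainder are ``shared``.
    """
    rows = list(measurements)
    if not rows:
        return {}
    max_vaf = max(m.vaf for m in rows)
    out: dict[str, CompartmentFlag] = {}
    for m in rows:
        ratio = (m.vaf / max_vaf) if max_vaf > 0 else None
        if not m.called:
            flag = "absent"
        elif m.vaf == max_vaf:
            flag = "carrier"
        elif m.vaf < trace_factor * max_vaf:
            flag = "trace"
        else:
            flag = "shared"
        out[m.compartment] = CompartmentFlag(vaf=m.vaf, flag=flag, ratio_to_max=ratio)
    return out


def cohort_prevalence(
    carrier_flags: Mapping[str, bool] | Sequence[bool],
) -> tuple[int, int, float]:
    """Carrier count, cohort size and percentage (one decimal)."""
    flags = (
        list(carrier_flags.values())
        if isinstance(carrier_flags, Mapping)
        else list(carrier_flags)
    )
    if not flags:
        raise ValueError("empty cohort")
    count = sum(bool(f) for f in flags)
    total = len(flags)
    return count, total, round_half_away(100.0 * count / total, 1)
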