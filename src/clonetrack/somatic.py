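"""Paired-fraction somatic variant calling from allele-count pileups.

The model is deliberately minimal and mirrors how targeted immunogene-panel
data are analysed in practice: each site is reduced to a biallelic
(reference, tracked-variant) count pair per sorted cell fraction, the
"normal" fraction (here the CD8+ cells) and the "tumor" fraction (the
clonally expanded CD4+ cells).  The somatic test is a one-tailed Fisher
exact test on the resulting 2x2 allele table: the probability, under the
hypergeometric null that variant reads distribute over fractions purely by
the sequencing-depth margins, of seeing at least the observed variant
support in the tumor fraction.  This is the convention VarScan-style
somatic callers use and it reproduces published panel p-values exactly.

Filters are applied in a fixed order (coverage, then VAF, then known
germline variants), so a site can carry only one failure label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import fisher_exact, hypergeom

from ._util import round_half_away

__all__ = [
    "QualityPileup",
    "SomaticCall",
    "CallerParams",
    "compute_vaf",
    "somatic_fisher_p",
    "call_paired_somatic",
    "write_vcf",
]


@dataclass(frozen=True)
class QualityPileup:
    """Biallelic allele counts plus per-allele base-quality sums at one site.

    Quality sums are in raw Phred units: the sum of the per-read base
    qualities over the reads supporting each allele.
    """

    chrom: str
    pos: int
    ref_base: str
    var_base: str
    ref_calls: int
    var_calls: int
    qsum_ref: float = 0.0
    qsum_var: float = 0.0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.ref_calls < 0 or self.var_calls < 0:
            raise ValueError("allele counts must be non-negative")
        if self.qsum_ref < 0 or self.qsum_var < 0:
            raise ValueError("quality sums must be non-negative")
        if self.var_calls == 0 and self.qsum_var != 0:
            raise ValueError("qsum_var must be 0 when var_calls is 0")

    @property
    def depth(self) -> int:
        return self.ref_calls + self.var_calls

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_base, self.var_base)


# Filter status labels, in the order the filters are applied.
CANDIDATE = "candidate"
FILTERED_LOW_COVERAGE = "filtered_low_coverage"
FILTERED_LOW_VAF = "filtered_low_vaf"
FILTERED_KNOWN_VARIANT = "filtered_known_variant"


@dataclass(frozen=True)
class SomaticCall:
    """One scored site of a paired-fraction comparison.

    VAFs are percentages rounded to two decimals (the panel-table display
    convention); the raw counts are retained for exact downstream use.
    """

    chrom: str
    pos: int
    ref_base: str
    var_base: str
    normal_ref: int
    normal_var: int
    tumor_ref: int
    tumor_var: int
    normal_vaf: float
    tumor_vaf: float
    somatic_p: float
    status: str
    gene: str | None = None
    effect: str | None = None
    normal_missing: bool = False


@dataclass(frozen=True)
class CallerParams:
    """Caller settings; the defaults are the published panel settings
    (min tumor coverage 6, min VAF 0.05, somatic p cutoff 1, purity 1).

    ``normal_purity`` is recorded for provenance but does not enter the
    count model.  ``known_variant_set`` holds (chrom, pos, var_base)
    tuples of known germline variants to exclude.
    """

    min_tumor_coverage: int = 6
    min_vaf: float = 0.05
    max_somatic_p: float = 1.0
    normal_purity: float = 1.0
    known_variant_set: frozenset[tuple[str, int, str]] = field(
        default_factory=frozenset
    )
    two_tailed: bool = False

    def __post_init__(self) -> None:
        if self.min_tumor_coverage < 0:
            raise ValueError("min_tumor_coverage must be >= 0")
        if not 0.0 <= self.min_vaf <= 1.0:
            raise ValueError("min_vaf is a fraction in [0, 1]")
        if not 0.0 < self.max_somatic_p <= 1.0:
            raise ValueError("max_somatic_p must be in (0, 1]")


def compute_vaf(ref_calls: int, var_calls: int, *, ndigits: int | None = 2) -> float:
    """Variant allele frequency as a percentage.

    Returns ``100 * var / (ref + var)``; by default rounded to two decimals
    (panel tables).  Pass ``ndigits=1`` for amplicon tables or ``None`` for
    the unrounded value.  Raises on a zero-depth site.
    """
    if ref_calls < 0 or var_calls < 0:
        raise ValueError("allele counts must be non-negative")
    total = ref_calls + var_calls
    if total == 0:
        raise ZeroDivisionError("VAF undefined at zero depth")
    vaf = 100.0 * var_calls / total
    return vaf if ndigits is None else round_half_away(vaf, ndigits)


def somatic_fisher_p(
    normal_ref: int,
    normal_var: int,
    tumor_ref: int,
    tumor_var: int,
    *,
    two_tailed: bool = False,
) -> float:
    """One-tailed Fisher exact somatic p-value of the 2x2 allele table.

    Returns P(X >= tumor_var) under the hypergeometric null with the
    observed margins: the chance that at least the observed variant support
    lands in the tumor fraction if variant reads carry no fraction signal.
    ``two_tailed=True`` gives the standard two-sided Fisher p instead
    (sensitivity analysis only; published panel values are one-tailed).
    """
    counts = (normal_ref, normal_var, tumor_ref, tumor_var)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    if sum(counts) == 0:
        raise ValueError("degenerate all-zero 2x2 table")
    if two_tailed:
        return float(
            fisher_exact(
                [[normal_ref, normal_var], [tumor_ref, tumor_var]],
                alternative="two-sided",
            ).pvalue
        )
    total = sum(counts)
    n_var = normal_var + tumor_var
    n_tumor = tumor_ref + tumor_var
    return float(hypergeom.sf(tumor_var - 1, total, n_var, n_tumor))


def call_paired_somatic(
    normal: Mapping[tuple[str, int, str, str], QualityPileup] | Iterable[QualityPileup],
    tumor: Mapping[tuple[str, int, str, str], QualityPileup] | Iterable[QualityPileup],
    params: CallerParams | None = None,
    *,
    genes: Mapping[tuple[str, int, str, str], str] | None = None,
) -> list[SomaticCall]:
    """Score every tumor site with variant support against the paired normal.

    Sites present in the tumor but absent from the normal are scored with
    normal counts (0, 0) and flagged ``normal_missing`` rather than raising.
    Filters apply in order: tumor depth < ``min_tumor_coverage`` ->
    ``filtered_low_coverage``; tumor VAF < ``min_vaf`` -> ``filtered_low_vaf``;
    site in ``known_variant_set`` -> ``filtered_known_variant``; otherwise
    ``candidate``.  The returned list holds candidates first, sorted by
    ascending somatic p, then filtered sites in the same order.
    """
    params = params or CallerParams()
    normal_map = _as_site_map(normal)
    tumor_map = _as_site_map(tumor)
    genes = genes or {}

    calls: list[SomaticCall] = []
    for site, tp in tumor_map.items():
        if tp.var_calls == 0:
            continue
        np_ = normal_map.get(site)
        missing = np_ is None
        n_ref, n_var = (0, 0) if missing else (np_.ref_calls, np_.var_calls)
        tumor_frac = tp.var_calls / tp.depth
        if tp.depth < params.min_tumor_coverage:
            status = FILTERED_LOW_COVERAGE
        elif tumor_frac < params.min_vaf:
            status = FILTERED_LOW_VAF
        elif (tp.chrom, tp.pos, tp.var_base) in params.known_variant_set:
            status = FILTERED_KNOWN_VARIANT
        else:
            status = CANDIDATE
        p = somatic_fisher_p(
            n_ref, n_var, tp.ref_calls, tp.var_calls, two_tailed=params.two_tailed
        )
        if status == CANDIDATE and p > params.max_somatic_p:
            continue  # p cutoff is 1.0 by default, i.e. report all
        calls.append(
            SomaticCall(
                chrom=tp.chrom,
                pos=tp.pos,
                ref_base=tp.ref_base,
                var_base=tp.var_base,
                normal_ref=n_ref,
                normal_var=n_var,
                tumor_ref=tp.ref_calls,
                tumor_var=tp.var_calls,
                normal_vaf=(
                    compute_vaf(n_ref, n_var) if (n_ref + n_var) > 0 else 0.0
                ),
                tumor_vaf=compute_vaf(tp.ref_calls, tp.var_calls),
                somatic_p=p,
                status=status,
                gene=genes.get(site),
                normal_missing=missing,
            )
        )
    calls.sort(key=lambda c: (c.status != CANDIDATE, c.somatic_p, c.chrom, c.pos))
    return calls


def _as_site_map(
    pileups: Mapping[tuple[str, int, str, str], QualityPileup] | Iterable[QualityPileup],
) -> dict[tuple[str, int, str, str], QualityPileup]:
    if isinstance(pileups, Mapping):
        return dict(pileups)
    return {p.site: p for p in pileups}


_VCF_FILTER_BY_STATUS = {
    CANDIDATE: "PASS",
    FILTERED_LOW_COVERAGE: "low_coverage",
    FILTERED_LOW_VAF: "low_vaf",
    FILTERED_KNOWN_VARIANT: "known_variant",
}

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=clonetrack
##FILTER=<ID=low_coverage,Description="Tumor depth below the minimum coverage">
##FILTER=<ID=low_vaf,Description="Tumor VAF below the minimum variant frequency">
##FILTER=<ID=known_variant,Description="Site present in the known-variant exclusion list">
##INFO=<ID=NR,Number=1,Type=Integer,Description="Normal reads supporting the reference allele">
##INFO=<ID=NV,Number=1,Type=Integer,Description="Normal reads supporting the variant allele">
##INFO=<ID=TR,Number=1,Type=Integer,Description="Tumor reads supporting the reference allele">
##INFO=<ID=TV,Number=1,Type=Integer,Description="Tumor reads supporting the variant allele">
##INFO=<ID=NVAF,Number=1,Type=Float,Description="Normal variant allele frequency, percent">
##INFO=<ID=TVAF,Number=1,Type=Float,Description="Tumor variant allele frequency, percent">
##INFO=<ID=SPV,Number=1,Type=Float,Description="One-tailed Fisher exact somatic p-value">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(calls: Sequence[SomaticCall], path: str) -> None:
    """Write calls as minimal VCF 4.2 with count/VAF/p INFO fields and a
    FILTER column mirroring the call status."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_VCF_HEADER)
        for c in calls:
            info = (
                f"NR={c.normal_ref};NV={c.normal_var};"
                f"TR={c.tumor_ref};TV={c.tumor_var};"
                f"NVAF={c.normal_vaf:g};TVAF={c.tumor_vaf:g};"
                f"SPV={c.somatic_p:.6g}"
            )
            if c.gene:
                info += f";GENE={c.gene}"
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref_base}\t{c.var_base}\t.\t"
                f"{_VCF_FILTER_BY_STATUS[c.status]}\t{info}\n"
            )
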