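"""Published worked-example data, packaged as in-code fixtures.

``PANEL_CALLS`` holds the 14 candidate somatic mutations found in the
index patient's CD4+ T cells by immunogene-panel sequencing (normal =
CD8+ fraction, tumor = CD4+ fraction), with the printed VAFs and somatic
p-values.  The two CD7 frameshift rows are carried as printed (the caller
itself models substitutions only); for those two rows the normal-side
counts were recovered by exact inversion of the printed p-values, since
the source rendering is ambiguous there.

``AMPLICON_ROWS`` holds the longitudinal ultra-deep amplicon validation
table for the mTOR P2229R and NFKB2 P882Q mutations across years,
compartments and biopsies.  ``consistent`` marks rows whose printed
one-decimal VAF equals the half-away-from-zero rounding of
``100 * var_calls / call_depth``; a handful of printed rows disagree with
their own counts and are excluded from numeric reproduction checks.

``index_repertoire()`` builds the index patient's two-part dominant
clonotype (paired 4669 cells + beta-only orphan 2038 cells of 14,111
total CD4+ cells) over a deterministic synthetic background.
"""

from __future__ import annotations

import os

import pandas as pd

from ._util import round_half_away
from .somatic import QualityPileup
from .synthetic import (
    KillingSimConfig,
    simulate_dose_response,
    simulate_impedance,
)
from .tcr import Clonotype, RepertoireSample

__all__ = [
    "PANEL_CALLS",
    "AMPLICON_ROWS",
    "COHORT_COUNTS",
    "panel_pileups",
    "amplicon_pileup",
    "index_repertoire",
    "make_fixtures",
]

# chrom, pos, ref, var, gene, effect, normal (CD8) ref/var, tumor (CD4)
# ref/var, printed tumor VAF %, printed somatic p
PANEL_CALLS: tuple[dict, ...] = (
    dict(chrom="1", pos=11182160, ref="G", var="C", gene="MTOR",
         effect="P2229R", normal=(179, 8), tumor=(157, 24),
         vaf=13.26, somatic_p=0.00178),
    dict(chrom="4", pos=154625732, ref="G", var="T", gene="TLR2",
         effect="W558L", normal=(116, 2), tumor=(104, 10),
         vaf=8.77, somatic_p=0.0145),
    dict(chrom="4", pos=144801662, ref="C", var="G", gene="GYPE",
         effect="G13A", normal=(150, 68), tumor=(147, 99),
         vaf=40.24, somatic_p=0.0266),
    dict(chrom="19", pos=50017643, ref="G", var="T", gene="FCGRT",
         effect="Q167H", normal=(28, 0), tumor=(14, 2),
         vaf=12.5, somatic_p=0.12685),
    dict(chrom="16", pos=31388150, ref="A", var="G", gene="ITGAX",
         effect="T847A", normal=(57, 0), tumor=(35, 2),
         vaf=5.41, somatic_p=0.15237),
    dict(chrom="11", pos=2415324, ref="G", var="T", gene="CD81",
         effect="splicing", normal=(58, 0), tumor=(36, 2),
         vaf=5.26, somatic_p=0.15417),
    dict(chrom="22", pos=37326772, ref="C", var="A", gene="CSF2RB",
         effect="H310Q", normal=(54, 0), tumor=(35, 2),
         vaf=5.41, somatic_p=0.16264),
    dict(chrom="3", pos=49936028, ref="A", var="C", gene="MST1R",
         effect="C548G", normal=(45, 0), tumor=(38, 2),
         vaf=5.0, somatic_p=0.21849),
    dict(chrom="10", pos=104162075, ref="C", var="A", gene="NFKB2",
         effect="P882Q", normal=(14, 0), tumor=(26, 3),
         vaf=10.34, somatic_p=0.29609),
    dict(chrom="10", pos=18112382, ref="G", var="T", gene="MRC1",
         effect="G134C", normal=(29, 0), tumor=(35, 2),
         vaf=5.41, somatic_p=0.31049),
    dict(chrom="17", pos=80274159, ref="G", var="GA", gene="CD7",
         effect="A175D_fs", normal=(8, 0), tumor=(16, 3),
         vaf=15.79, somatic_p=0.33128),
    dict(chrom="17", pos=80274183, ref="G", var="C", gene="CD7",
         effect="A167G", normal=(13, 0), tumor=(19, 2),
         vaf=9.52, somatic_p=0.37433),
    dict(chrom="12", pos=109017698, ref="G", var="A", gene="SELPLG",
         effect="T145M", normal=(46, 2), tumor=(35, 3),
         vaf=7.89, somatic_p=0.38939),
    dict(chrom="17", pos=80274161, ref="T", var="TG", gene="CD7",
         effect="fs", normal=(7, 0), tumor=(11, 2),
         vaf=15.38, somatic_p=0.41053),
)

_MTOR_SITE = dict(gene="mTOR", chrom="1", pos=11182160, ref="G", var="C")
_NFKB2_SITE = dict(gene="NFKB2", chrom="10", pos=104162075, ref="C", var="A")


def _amp(year, compartment, site, depth, ref_calls, var_calls, vaf, freq_ratio):
    row = dict(site)
    row.update(
        subject="index",
        sample_year=year,
        compartment=compartment,
        call_depth=depth,
        ref_calls=ref_calls,
        var_calls=var_calls,
        vaf=vaf,
        freq_ratio=freq_ratio,
    )
    row["consistent"] = (
        ref_calls + var_calls == depth
        and round_half_away(100.0 * var_calls / depth, 1) == vaf
    )
    return row


AMPLICON_ROWS: tuple[dict, ...] = (
    _amp(2013, "CD4", _MTOR_SITE, 7204, 5939, 1265, 17.3, 0.99757),
    _amp(2013, "CD4", _NFKB2_SITE, 52, 43, 9, 17.3, 0.67697),
    _amp(2015, "CD4", _MTOR_SITE, 1000004, 808220, 191784, 19.2, 1.00047),
    _amp(2015, "CD8", _MTOR_SITE, 1000003, 942683, 57320, 5.7, 0.9993),
    _amp(2015, "skin_biopsy", _MTOR_SITE, 8085, 7986, 99, 0.8, 0.96305),
    _amp(2015, "whole_blood", _MTOR_SITE, 719, 703, 16, 2.0, 1.02671),
    _amp(2015, "CD4", _NFKB2_SITE, 471375, 414821, 56554, 12.5, 1.0061),
    _amp(2015, "CD8", _NFKB2_SITE, 586903, 577283, 9620, 1.6, 1.00124),
    _amp(2016, "whole_blood", _MTOR_SITE, 2743, 2715, 28, 1.0, 1.01793),
    _amp(2017, "CD4", _MTOR_SITE, 7330, 5796, 1534, 20.5, 0.99141),
    _amp(2017, "CD4Vb20", _MTOR_SITE, 168592, 93183, 75409, 44.7, 0.99928),
    _amp(2017, "CD4CD8Vb20", _MTOR_SITE, 171728, 110670, 61058, 35.5, 0.99910),
    _amp(2017, "CD4", _NFKB2_SITE, 1436, 1236, 200, 12.5, 0.82101),
    _amp(2017, "CD4Vb20", _NFKB2_SITE, 26262, 20668, 5594, 21.3, 1.00395),
    _amp(2017, "CD4CD8Vb20", _NFKB2_SITE, 48654, 43822, 4832, 9.9, 1.00282),
    _amp(2019, "CD4", _MTOR_SITE, 6890, 5261, 1629, 23.4, 0.99281),
    _amp(2019, "CD4", _NFKB2_SITE, 82, 70, 12, 14.6, 1.00724),
)

# carrier counts from the published screening cohorts:
# (carriers, cohort size) per (mutation, cohort)
COHORT_COUNTS: dict[tuple[str, str], tuple[int, int]] = {
    ("mTOR_P2229R", "cGvHD"): (3, 135),
    ("TLR2_W558L", "cGvHD"): (21, 134),
    ("TLR2_W558L", "healthy"): (5, 54),
    ("mTOR_P2229R", "healthy"): (0, 54),
    ("mTOR_P2229R", "no_cGvHD_HSCT"): (0, 38),
}

# mean Phred quality used when synthesizing quality sums for count-only rows
_FIXTURE_Q = 36.0


def panel_pileups() -> tuple[
    dict[tuple, QualityPileup], dict[tuple, QualityPileup], dict[tuple, str]
]:
    """(normal map, tumor map, gene map) rebuilt from the panel rows.

    Quality sums are synthesized at a constant per-base Phred quality
    (the published panel rows carry no quality columns)."""
    normal: dict[tuple, QualityPileup] = {}
    tumor: dict[tuple, QualityPileup] = {}
    genes: dict[tuple, str] = {}
    for row in PANEL_CALLS:
        site = (row["chrom"], row["pos"], row["ref"], row["var"])
        genes[site] = row["gene"]
        for counts, dest in ((row["normal"], normal), (row["tumor"], tumor)):
            ref_calls, var_calls = counts
            dest[site] = QualityPileup(
                chrom=row["chrom"],
                pos=row["pos"],
                ref_base=row["ref"],
                var_base=row["var"],
                ref_calls=ref_calls,
                var_calls=var_calls,
                qsum_ref=_FIXTURE_Q * ref_calls,
                qsum_var=_FIXTURE_Q * var_calls,
            )
    return normal, tumor, genes


def amplicon_pileup(row: dict) -> QualityPileup:
    """Rebuild a pileup from one amplicon row, choosing quality sums that
    reproduce the printed base quality frequency ratio exactly:
    with mean overall quality q, ``qsum_var = ratio * var_calls * q``."""
    depth = row["call_depth"]
    qsum_all = _FIXTURE_Q * depth
    qsum_var = row["freq_ratio"] * (row["var_calls"] / depth) * qsum_all
    return QualityPileup(
        chrom=row["chrom"],
        pos=row["pos"],
        ref_base=row["ref"],
        var_base=row["var"],
        ref_calls=row["ref_calls"],
        var_calls=row["var_calls"],
        qsum_ref=qsum_all - qsum_var,
        qsum_var=qsum_var,
    )


# index patient's dominant clonotype: 4669 paired cells + 2038 beta-only
# orphan cells of 14,111 CD4+ cells passing QC
DOMINANT_PAIRED_CELLS = 4669
DOMINANT_ORPHAN_CELLS = 2038
INDEX_TOTAL_CELLS = 14111

_ALPHA_AA = "CLVGDIGNQGGKLIF"
_BETA_AA = "CAWSTGQANNSPLHF"
_ALPHA_NT = "TGTCTCGTGGGTGACATCGGCAACCAGGGAGGAAAGCTTATCTTC"
_BETA_NT = "TGTGCCTGGAGTACCGGGCAGGCTAACAATTCACCCCTCCACTTT"
_VDJ = ("TRBV30-01", "TRBD01-01", "TRBJ01-06")


def index_repertoire(n_background_clones: int = 24) -> RepertoireSample:
    """The two-part dominant clonotype over a deterministic background
    filling the remaining 7404 cells (synthetic background; the real data
    held ~3576 further clonotypes)."""
    v, d, j = _VDJ
    clones = [
        Clonotype(
            alpha_nt=_ALPHA_NT, beta_nt=_BETA_NT,
            alpha_aa=_ALPHA_AA, beta_aa=_BETA_AA,
            v_beta=v, d_beta=d, j_beta=j,
            cells=DOMINANT_PAIRED_CELLS,
        ),
        Clonotype(
            beta_nt=_BETA_NT, beta_aa=_BETA_AA,
            v_beta=v, d_beta=d, j_beta=j,
            cells=DOMINANT_ORPHAN_CELLS,
        ),
    ]
    rest = INDEX_TOTAL_CELLS - DOMINANT_PAIRED_CELLS - DOMINANT_ORPHAN_CELLS
    base = rest // n_background_clones
    sizes = [base] * n_background_clones
    sizes[0] += rest - base * n_background_clones
    bases = "ACGT"
    for i, size in enumerate(sizes):
        seed_nt = "".join(bases[(i + k) % 4] for k in range(45))
        clones.append(
            Clonotype(
                alpha_nt=seed_nt[::-1],
                beta_nt=seed_nt,
                v_beta=f"TRBV{(i % 29) + 1:02d}-01",
                d_beta="TRBD01-01",
                j_beta="TRBJ02-01",
                cells=size,
            )
        )
    return RepertoireSample(sample_id="index", clonotypes=tuple(clones))


def make_fixtures(outdir: str, seed: int = 0) -> list[str]:
    """Write every fixture as plain-text tables; returns the paths.

    Panel and amplicon tables are the published rows; repertoire, RTCA
    and plate inputs are small deterministic simulations.
    """
    os.makedirs(outdir, exist_ok=True)
    written: list[str] = []

    normal, tumor, genes = panel_pileups()
    for name, pmap in (("panel_normal.tsv", normal), ("panel_tumor.tsv", tumor)):
        df = pd.DataFrame(
            dict(
                chrom=p.chrom, pos=p.pos, ref=p.ref_base, var=p.var_base,
                ref_calls=p.ref_calls, var_calls=p.var_calls,
                qsum_ref=p.qsum_ref, qsum_var=p.qsum_var,
                gene=genes[site],
            )
            for site, p in pmap.items()
        )
        path = os.path.join(outdir, name)
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    amp = pd.DataFrame(AMPLICON_ROWS)[
        ["subject", "sample_year", "compartment", "gene", "chrom", "pos",
         "ref", "var", "call_depth", "ref_calls", "var_calls", "vaf",
         "freq_ratio", "consistent"]
    ]
    path = os.path.join(outdir, "amplicon_runs.tsv")
    amp.to_csv(path, sep="\t", index=False)
    written.append(path)

    rep = index_repertoire()
    rows = []
    for i, c in enumerate(rep.clonotypes):
        for chain, nt, aa in (
            ("TRA", c.alpha_nt, c.alpha_aa),
            ("TRB", c.beta_nt, c.beta_aa),
        ):
            if nt is None:
                continue
            rows.append(
                dict(
                    clone_id=f"clone{i:04d}", chain=chain, cdr3_nt=nt,
                    cdr3_aa=aa or "", v_call=c.v_beta if chain == "TRB" else "",
                    d_call=c.d_beta if chain == "TRB" else "",
                    j_call=c.j_beta if chain == "TRB" else "", count=c.cells,
                )
            )
        # beta-only rows still need their V/D/J; handled above
    path = os.path.join(outdir, "repertoire.tsv")
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    written.append(path)

    traces = simulate_impedance(KillingSimConfig(noise_sd=0.5, seed=seed))
    trace_rows, meta_rows = [], []
    for tr in traces:
        meta_rows.append(dict(well=tr.well, condition=tr.condition,
                              Zn=tr.zn, R0=tr.r0, t_add=24.0))
        for t, r in zip(tr.times, tr.resistance):
            trace_rows.append(dict(well=tr.well, condition=tr.condition,
                                   time_h=t, resistance=r))
    path = os.path.join(outdir, "rtca_traces.csv")
    pd.DataFrame(trace_rows).to_csv(path, index=False)
    written.append(path)
    path = os.path.join(outdir, "rtca_meta.csv")
    pd.DataFrame(meta_rows).to_csv(path, index=False)
    written.append(path)

    plate_rows = []
    for k, (name, ic50, slope, bottom_viab) in enumerate(
        (("drug_A", 30.0, 1.2, 5.0), ("drug_B", 300.0, 0.8, 20.0),
         ("drug_C", 5000.0, 1.5, 60.0))
    ):
        curve = simulate_dose_response(
            ic50, slope, top=100.0, bottom=bottom_viab,
            noise_sd=1.0, seed=seed + k, drug=name,
        )
        for dose, inh in zip(curve.doses, curve.inhibition):
            plate_rows.append(
                dict(drug=name, dose_nM=dose,
                     signal=round(1000.0 * (1.0 - inh / 100.0), 3),
                     control_signal=1000.0)
            )
    path = os.path.join(outdir, "plate.csv")
    pd.DataFrame(plate_rows).to_csv(path, index=False)
    written.append(path)
    return written
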