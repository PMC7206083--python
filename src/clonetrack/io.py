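"""Readers and writers for the plain-text table dialects the pipeline uses.

Formats (all headered, tab- or comma-separated):

* pileup TSV: ``chrom pos ref var ref_calls var_calls qsum_ref qsum_var``
  (+ optional ``gene``);
* amplicon TSV: ``subject sample_year compartment gene chrom pos ref var
  call_depth ref_calls var_calls [qsum_ref qsum_var | vaf freq_ratio]``;
* AIRR-style repertoire TSV: one row per chain,
  ``clone_id chain cdr3_nt cdr3_aa v_call d_call j_call count``;
* RTCA long CSV ``well condition time_h resistance`` plus a metadata CSV
  ``well condition Zn R0 t_add``;
* DSRT plate CSV ``drug dose_nM signal control_signal``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .amplicon import AmpliconMeasurement
from .rtca import ImpedanceTrace
from .somatic import QualityPileup, SomaticCall
from .tcr import Clonotype, RepertoireSample

__all__ = [
    "read_pileup_tsv",
    "write_pileup_tsv",
    "read_amplicon_tsv",
    "write_amplicon_tsv",
    "read_known_variants_tsv",
    "read_repertoire_tsv",
    "read_rtca_csv",
    "read_plate_csv",
    "write_calls_tsv",
]


def read_pileup_tsv(path: str) -> dict[tuple[str, int, str, str], QualityPileup]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = {}
    for row in df.itertuples(index=False):
        p = QualityPileup(
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref_base=str(row.ref),
            var_base=str(row.var),
            ref_calls=int(row.ref_calls),
            var_calls=int(row.var_calls),
            qsum_ref=float(getattr(row, "qsum_ref", 0.0)),
            qsum_var=float(getattr(row, "qsum_var", 0.0)),
        )
        out[p.site] = p
    return out


def read_pileup_genes(path: str) -> dict[tuple[str, int, str, str], str]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "gene" not in df.columns:
        return {}
    return {
        (str(r.chrom), int(r.pos), str(r.ref), str(r.var)): str(r.gene)
        for r in df.itertuples(index=False)
    }


def write_pileup_tsv(
    pileups: Sequence[QualityPileup] | dict, path: str
) -> None:
    items = list(pileups.values()) if isinstance(pileups, dict) else list(pileups)
    pd.DataFrame(
        dict(
            chrom=p.chrom, pos=p.pos, ref=p.ref_base, var=p.var_base,
            ref_calls=p.ref_calls, var_calls=p.var_calls,
            qsum_ref=p.qsum_ref, qsum_var=p.qsum_var,
        )
        for p in items
    ).to_csv(path, sep="\t", index=False)


def read_amplicon_tsv(path: str) -> pd.DataFrame:
    """Amplicon rows as a DataFrame (kept tabular: downstream helpers take
    either rows or :class:`AmpliconMeasurement` objects built from them)."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def amplicon_measurements_from_df(df: pd.DataFrame) -> list[AmpliconMeasurement]:
    """Interpret already-called amplicon rows (with ``vaf`` and ``called``
    or ``freq_ratio`` columns) as measurement records."""
    from .amplicon import AmpliconThresholds

    th = AmpliconThresholds()
    out = []
    for r in df.itertuples(index=False):
        ratio = float(r.freq_ratio) if hasattr(r, "freq_ratio") else None
        vaf = float(r.vaf)
        called = (
            bool(r.called)
            if hasattr(r, "called")
            else vaf >= th.min_vaf and ratio is not None
            and ratio >= th.min_freq_ratio - 1e-12
        )
        out.append(
            AmpliconMeasurement(
                subject=str(r.subject),
                sample_year=int(r.sample_year),
                compartment=str(r.compartment),
                gene=str(r.gene),
                chrom=str(r.chrom),
                pos=int(r.pos),
                ref=str(r.ref),
                var=str(r.var),
                call_depth=int(r.call_depth),
                ref_calls=int(r.ref_calls),
                var_calls=int(r.var_calls),
                vaf=vaf,
                freq_ratio=ratio,
                called=called,
            )
        )
    return out


def write_amplicon_tsv(measurements: Sequence[AmpliconMeasurement], path: str) -> None:
    pd.DataFrame(
        dict(
            subject=m.subject, sample_year=m.sample_year,
            compartment=m.compartment, gene=m.gene, chrom=m.chrom, pos=m.pos,
            ref=m.ref, var=m.var, call_depth=m.call_depth,
            ref_calls=m.ref_calls, var_calls=m.var_calls, vaf=m.vaf,
            freq_ratio=m.freq_ratio, called=m.called,
        )
        for m in measurements
    ).to_csv(path, sep="\t", index=False)


def read_known_variants_tsv(path: str) -> frozenset[tuple[str, int, str]]:
    """Known-variant exclusion list: TSV with ``chrom pos var`` columns
    (a tiny stand-in for a germline-variant database)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return frozenset(
        (str(r.chrom), int(r.pos), str(r.var)) for r in df.itertuples(index=False)
    )


def read_repertoire_tsv(path: str, sample_id: str | None = None) -> RepertoireSample:
    """Group per-chain rows by ``clone_id`` into clonotypes; the cell
    count is taken from the clone's rows (which must agree)."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    clones: list[Clonotype] = []
    for clone_id, grp in df.groupby("clone_id", sort=True):
        counts = set(int(c) for c in grp["count"])
        if len(counts) != 1:
            raise ValueError(f"conflicting counts for clone {clone_id!r}")
        fields: dict = dict(cells=counts.pop())
        for r in grp.itertuples(index=False):
            chain = str(r.chain).upper()
            if chain == "TRA":
                fields["alpha_nt"] = str(r.cdr3_nt)
                fields["alpha_aa"] = str(r.cdr3_aa) or None
            elif chain == "TRB":
                fields["beta_nt"] = str(r.cdr3_nt)
                fields["beta_aa"] = str(r.cdr3_aa) or None
                fields["v_beta"] = str(r.v_call) or None
                fields["d_beta"] = str(r.d_call) or None
                fields["j_beta"] = str(r.j_call) or None
            else:
                raise ValueError(f"unknown chain {chain!r}")
        clones.append(Clonotype(**fields))
    return RepertoireSample(
        sample_id=sample_id or path, clonotypes=tuple(clones)
    )


def read_rtca_csv(traces_path: str, meta_path: str) -> list[ImpedanceTrace]:
    traces = pd.read_csv(traces_path)
    meta = pd.read_csv(meta_path).set_index("well")
    out = []
    for well, grp in traces.groupby("well", sort=True):
        grp = grp.sort_values("time_h")
        m = meta.loc[well]
        out.append(
            ImpedanceTrace(
                well=str(well),
                condition=str(grp["condition"].iloc[0]),
                times=grp["time_h"].to_numpy(dtype=float),
                resistance=grp["resistance"].to_numpy(dtype=float),
                r0=float(m["R0"]),
                zn=float(m["Zn"]),
            )
        )
    return out


def read_plate_csv(path: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-drug (doses, inhibition %) with inhibition computed as
    ``100 * (1 - signal / control_signal)``."""
    df = pd.read_csv(path)
    out = {}
    for drug, grp in df.groupby("drug", sort=True):
        grp = grp.sort_values("dose_nM")
        doses = grp["dose_nM"].to_numpy(dtype=float)
        inhibition = 100.0 * (
            1.0 - grp["signal"].to_numpy(dtype=float)
            / grp["control_signal"].to_numpy(dtype=float)
        )
        out[str(drug)] = (doses, inhibition)
    return out


def write_calls_tsv(calls: Sequence[SomaticCall], path: str) -> None:
    """Panel-table-shaped TSV of somatic calls."""
    pd.DataFrame(
        dict(
            chrom=c.chrom, pos=c.pos, ref=c.ref_base, var=c.var_base,
            gene=c.gene or "", normal_ref=c.normal_ref, normal_var=c.normal_var,
            normal_vaf=c.normal_vaf, tumor_ref=c.tumor_ref,
            tumor_var=c.tumor_var, tumor_vaf=c.tumor_vaf,
            somatic_p=c.somatic_p, status=c.status,
        )
        for c in calls
    ).to_csv(path, sep="\t", index=False)
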