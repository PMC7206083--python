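"""Synthetic-data generators for every pipeline stage.

These generators emulate the statistical structure the analysis assumes —
not the raw instruments:

* ultra-deep amplicon/panel pileups: variant reads are binomial at
  ``true_vaf * (1 - e) + (1 - true_vaf) * e / 3`` (miscalls distribute
  uniformly over the three non-reference bases and only the tracked
  alternate base is counted), with Phred-like truncated-normal integer
  base qualities per allele class;
* paired sorted fractions: the clone lives in one carrier compartment at
  ``clone_vaf``; every other compartment sees ``contamination * clone_vaf``
  (cross-sort contamination, e.g. CD4+CD8+ double positives in a bead-
  sorted CD8 fraction);
* single-cell TCR repertoires: one dominant paired clonotype, part of
  which is emitted as a beta-only orphan with an identical beta chain
  (incomplete capture), over a geometric background of small clones;
* impedance traces: logistic target growth, effector-dependent
  exponential killing after the addition time, Gaussian resistance noise;
* dose-response plates: four-parameter logistic viability plus noise over
  a five-point, 10,000-fold concentration series.

All generators take an explicit seed; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .drug_response import DEFAULT_DOSES_NM, DoseResponseCurve, four_param_logistic
from .rtca import ImpedanceTrace
from .somatic import QualityPileup
from .tcr import Clonotype, RepertoireSample

__all__ = [
    "SeqSimConfig",
    "FractionSimConfig",
    "RepertoireSimConfig",
    "KillingSimConfig",
    "simulate_pileup",
    "simulate_paired_fractions",
    "simulate_repertoire",
    "simulate_impedance",
    "simulate_dose_response",
]


def _check_fraction(name: str, value: float, *, upper_open: bool = False) -> None:
    if not np.isfinite(value):
        raise ValueError(f"{name} must be finite")
    if upper_open:
        if not 0.0 <= value < 1.0:
            raise ValueError(f"{name} must be in [0, 1)")
    elif not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class SeqSimConfig:
    """One simulated amplicon/panel site.

    ``error_rate`` is the per-base miscall probability; 1e-3 is a generic
    post-alignment floor for this assay class, standing in for an error
    model the source data do not pin down.  Qualities are Phred-scale
    integers, truncated-normal per allele class, so the base-quality
    frequency-ratio statistic is exercisable (set ``q_var_mean`` below
    ``q_ref_mean`` to emulate error-like variant support).
    """

    true_vaf: float
    depth: int
    error_rate: float = 1e-3
    q_ref_mean: float = 36.0
    q_var_mean: float = 36.0
    q_sd: float = 4.0
    seed: int = 0
    chrom: str = "sim1"
    pos: int = 1
    ref_base: str = "G"
    var_base: str = "C"

    def __post_init__(self) -> None:
        _check_fraction("true_vaf", self.true_vaf)
        _check_fraction("error_rate", self.error_rate)
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.q_sd < 0 or not np.isfinite(self.q_sd):
            raise ValueError("q_sd must be a non-negative finite number")
        if self.q_ref_mean < 0 or self.q_var_mean < 0:
            raise ValueError("quality means must be non-negative")


def _quality_sum(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> float:
    """Sum of n truncated-normal Phred integer qualities in [2, 60]."""
    if n == 0:
        return 0.0
    q = np.rint(rng.normal(mean, sd, size=n)) if sd > 0 else np.full(n, round(mean))
    return float(np.clip(q, 2, 60).sum())


def simulate_pileup(cfg: SeqSimConfig) -> QualityPileup:
    """Draw one pileup: var_calls ~ Binomial(depth, v(1-e) + (1-v)e/3)."""
    rng = np.random.default_rng(cfg.seed)
    v, e = cfg.true_vaf, cfg.error_rate
    p_var = v * (1.0 - e) + (1.0 - v) * e / 3.0
    var_calls = int(rng.binomial(cfg.depth, p_var))
    ref_calls = cfg.depth - var_calls
    return QualityPileup(
        chrom=cfg.chrom,
        pos=cfg.pos,
        ref_base=cfg.ref_base,
        var_base=cfg.var_base,
        ref_calls=ref_calls,
        var_calls=var_calls,
        qsum_ref=_quality_sum(rng, ref_calls, cfg.q_ref_mean, cfg.q_sd),
        qsum_var=_quality_sum(rng, var_calls, cfg.q_var_mean, cfg.q_sd),
    )


@dataclass(frozen=True)
class FractionSimConfig:
    """A clone confined to one sorted compartment with small cross-sort
    contamination of every other compartment."""

    clone_vaf: float
    host_fractions: tuple[str, ...]
    carrier_fraction: str
    depths: dict[str, int]
    contamination: float = 0.02
    error_rate: float = 1e-3
    q_ref_mean: float = 36.0
    q_var_mean: float = 36.0
    q_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check_fraction("clone_vaf", self.clone_vaf)
        _check_fraction("contamination", self.contamination, upper_open=True)
        if self.carrier_fraction not in self.host_fractions:
            raise ValueError(
                f"carrier fraction {self.carrier_fraction!r} not among "
                f"host fractions {self.host_fractions}"
            )
        missing = set(self.host_fractions) - set(self.depths)
        if missing:
            raise ValueError(f"depths missing for fractions: {sorted(missing)}")


def simulate_paired_fractions(cfg: FractionSimConfig) -> dict[str, QualityPileup]:
    """One pileup per compartment; the carrier's expected VAF is
    ``clone_vaf``, all others' is ``contamination * clone_vaf``."""
    rng = np.random.default_rng(cfg.seed)
    out: dict[str, QualityPileup] = {}
    for frac in cfg.host_fractions:
        vaf = (
            cfg.clone_vaf
            if frac == cfg.carrier_fraction
            else cfg.contamination * cfg.clone_vaf
        )
        sub = SeqSimConfig(
            true_vaf=vaf,
            depth=cfg.depths[frac],
            error_rate=cfg.error_rate,
            q_ref_mean=cfg.q_ref_mean,
            q_var_mean=cfg.q_var_mean,
            q_sd=cfg.q_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out[frac] = simulate_pileup(sub)
    return out


@dataclass(frozen=True)
class RepertoireSimConfig:
    """One dominant paired clonotype (a fraction of which is emitted as a
    beta-only orphan with the same beta chain and V/D/J calls) over a
    geometric background of small clones."""

    n_cells: int
    expanded_clone_fraction: float
    n_background_clones: int = 50
    orphan_split_fraction: float = 0.0
    background_geometric_p: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        _check_fraction("expanded_clone_fraction", self.expanded_clone_fraction)
        _check_fraction("orphan_split_fraction", self.orphan_split_fraction)
        if self.expanded_clone_fraction < 1.0 and self.n_background_clones < 1:
            raise ValueError("need background clones unless the clone is everything")
        if not 0.0 < self.background_geometric_p <= 1.0:
            raise ValueError("background_geometric_p must be in (0, 1]")


_DOMINANT_ALPHA_NT = "TGTCTCGTGGGTGACATCGGCAACCAGGGAGGAAAGCTTATCTTC"
_DOMINANT_BETA_NT = "TGTGCCTGGAGTACCGGGCAGGCTAACAATTCACCCCTCCACTTT"
_DOMINANT_ALPHA_AA = "CLVGDIGNQGGKLIF"
_DOMINANT_BETA_AA = "CAWSTGQANNSPLHF"
_DOMINANT_VDJ = ("TRBV30-01", "TRBD01-01", "TRBJ01-06")

_NT = np.array(list("ACGT"))


def simulate_repertoire(cfg: RepertoireSimConfig) -> RepertoireSample:
    """Total cells equal ``n_cells`` exactly; background clone sizes are
    geometric, rescaled to the residual cell mass."""
    rng = np.random.default_rng(cfg.seed)
    expanded_cells = int(round(cfg.n_cells * cfg.expanded_clone_fraction))
    orphan_cells = int(round(expanded_cells * cfg.orphan_split_fraction))
    paired_cells = expanded_cells - orphan_cells
    background_cells = cfg.n_cells - expanded_cells

    clones: list[Clonotype] = []
    v, d, j = _DOMINANT_VDJ
    if paired_cells > 0:
        clones.append(
            Clonotype(
                alpha_nt=_DOMINANT_ALPHA_NT,
                beta_nt=_DOMINANT_BETA_NT,
                alpha_aa=_DOMINANT_ALPHA_AA,
                beta_aa=_DOMINANT_BETA_AA,
                v_beta=v,
                d_beta=d,
                j_beta=j,
                cells=paired_cells,
            )
        )
    if orphan_cells > 0:
        clones.append(
            Clonotype(
                beta_nt=_DOMINANT_BETA_NT,
                beta_aa=_DOMINANT_BETA_AA,
                v_beta=v,
                d_beta=d,
                j_beta=j,
                cells=orphan_cells,
            )
        )

    if background_cells > 0:
        k = cfg.n_background_clones
        sizes = rng.geometric(cfg.background_geometric_p, size=k).astype(float)
        sizes = np.maximum(
            1, np.rint(sizes * background_cells / sizes.sum())
        ).astype(int)
        # exact cell conservation: trim/pad the largest background clone
        sizes[np.argmax(sizes)] += background_cells - int(sizes.sum())
        sizes = sizes[sizes > 0]
        for i, size in enumerate(sizes):
            beta_nt = "".join(rng.choice(_NT, size=45))
            paired = rng.random() < 0.7
            clones.append(
                Clonotype(
                    alpha_nt=(
                        "".join(rng.choice(_NT, size=45)) if paired else None
                    ),
                    beta_nt=beta_nt,
                    v_beta=f"TRBV{rng.integers(1, 31):02d}-01",
                    d_beta=f"TRBD0{rng.integers(1, 3)}-01",
                    j_beta=f"TRBJ0{rng.integers(1, 3)}-0{rng.integers(1, 8)}",
                    cells=int(size),
                )
            )
    return RepertoireSample(sample_id=f"sim-{cfg.seed}", clonotypes=tuple(clones))


@dataclass(frozen=True)
class KillingSimConfig:
    """Impedance kinetics: logistic target growth to a fixed carrying
    capacity, with per-hour killing proportional to the effector:target
    ratio after the addition time."""

    baseline_growth_rate: float = 0.08  # per hour
    killing_rate: float = 0.012  # per hour per E:T unit
    et_ratios: tuple[float, ...] = (4.0, 8.0, 16.0)
    t_add: float = 24.0  # hours
    duration: float = 45.0  # hours: 24 h growth + 21 h co-culture readout
    dt: float = 0.5  # hours (instrument sampled every 30 min)
    noise_sd: float = 0.0  # resistance units (ohm)
    zn: float = 15.0
    r0: float = 10.0
    carrying_capacity: float = 10.0  # CI units
    ci0: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.t_add < self.duration:
            raise ValueError("t_add must precede the end of the run")
        if self.zn <= 0:
            raise ValueError("Zn must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if any(r <= 0 for r in self.et_ratios):
            raise ValueError("E:T ratios must be positive")


def simulate_impedance(cfg: KillingSimConfig) -> list[ImpedanceTrace]:
    """One control ("media") trace plus one trace per E:T ratio.

    Before ``t_add`` every well follows the same logistic growth; after
    it, effector wells additionally decay at ``killing_rate * ratio``.
    Resistance is ``r0 + Zn * CI(t)`` plus optional Gaussian noise.
    """
    rng = np.random.default_rng(cfg.seed)
    times = np.arange(0.0, cfg.duration + cfg.dt / 2, cfg.dt)
    traces: list[ImpedanceTrace] = []
    conditions = [("control", 0.0)] + [
        (f"E:T {r:g}:1", r) for r in cfg.et_ratios
    ]
    for idx, (label, ratio) in enumerate(conditions):
        ci = np.empty_like(times)
        c = cfg.ci0
        for i, t in enumerate(times):
            ci[i] = c
            growth = cfg.baseline_growth_rate * c * (1.0 - c / cfg.carrying_capacity)
            kill = cfg.killing_rate * ratio * c if t >= cfg.t_add else 0.0
            c = max(c + cfg.dt * (growth - kill), 0.0)
        resistance = cfg.r0 + cfg.zn * ci
        if cfg.noise_sd > 0:
            resistance = resistance + rng.normal(0.0, cfg.noise_sd, size=times.size)
        traces.append(
            ImpedanceTrace(
                well=f"W{idx + 1}",
                condition=label,
                times=times,
                resistance=resistance,
                r0=cfg.r0,
                zn=cfg.zn,
            )
        )
    return traces


def simulate_dose_response(
    ic50: float,
    hill_slope: float,
    top: float = 100.0,
    bottom: float = 0.0,
    doses: Sequence[float] = DEFAULT_DOSES_NM,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    drug: str = "sim-drug",
) -> DoseResponseCurve:
    """Viability follows a descending 4PL (``top`` at low dose falling to
    ``bottom``) plus Gaussian noise; the returned curve reports inhibition
    ``100 - viability``.  With ``top = bottom = 100`` the drug does
    nothing and inhibition is 0 everywhere.  The generating parameters
    are stored as the curve's parameters (on the inhibition scale), so a
    noise-free round trip through
    :func:`~clonetrack.drug_response.fit_dose_response` checks parameter
    recovery."""
    d = np.asarray(doses, dtype=float)
    if np.any(np.diff(d) <= 0):
        raise ValueError("doses must be strictly increasing")
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    # ascending 4PL on the inhibition scale == descending viability 4PL
    inh_top, inh_bottom = 100.0 - bottom, 100.0 - top
    y = np.asarray(
        four_param_logistic(d, ic50, hill_slope, inh_top, inh_bottom), dtype=float
    )
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=d.size)
    flat = bool(np.ptp(y) <= 1e-12)
    return DoseResponseCurve(
        drug=drug,
        doses=tuple(d),
        inhibition=tuple(y),
        top=float(inh_top),
        bottom=float(inh_bottom),
        ic50=None if flat else float(ic50),
        slope=None if flat else float(hill_slope),
        residual=0.0,
        flat=flat,
    )
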