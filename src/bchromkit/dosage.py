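"""B-chromosome copy-number calling from qPCR gene-dose ratios.

The quantitative marker targets a genomic region carried at low copy
number in the A complement but at high copy number on the B, so each
additional B adds a fixed increment of template.  With a single-copy
reference gene (HPRT) and 100% amplification efficiency, the gene dose
ratio GDR = 2^-(Ct_target - Ct_HPRT) is proportional to the target's copy
number; a 2B genome therefore shows roughly twice the GDR of a 1B genome.
Known 0B/1B/2B controls calibrate per-genotype GDR clusters in log2 space
and unknown samples take the genotype of the nearest cluster center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DoseEstimate",
    "Calibration",
    "CopyCall",
    "CalibrationError",
    "aggregate_ct",
    "gdr",
    "dose_table",
    "calibrate",
    "call_copies",
    "cohort_fold_change",
]

GENOTYPE_ORDER = ("0B", "1B", "2B")
DEFAULT_SD_FLAG = 0.5  # cycles; replicate triples noisier than this get flagged
DEFAULT_EPSILON = 0.25  # log2 units; ambiguity margin between cluster centers


class CalibrationError(ValueError):
    """Control clusters violate the monotone dose ordering 0B < 1B < 2B."""


@dataclass(frozen=True)
class DoseEstimate:
    sample_id: str
    ct_target_mean: float
    ct_target_sd: float
    ct_ref_mean: float
    ct_ref_sd: float
    flagged: bool

    @property
    def delta_ct(self) -> float:
        return self.ct_target_mean - self.ct_ref_mean

    @property
    def gdr(self) -> float:
        return 2.0 ** (-self.delta_ct)

    @property
    def gdr_interval(self) -> tuple[float, float]:
        """GDR at delta-Ct +/- the combined replicate SD."""
        sd = math.hypot(self.ct_target_sd, self.ct_ref_sd)
        return (2.0 ** (-(self.delta_ct + sd)), 2.0 ** (-(self.delta_ct - sd)))


@dataclass
class Calibration:
    """Per-genotype control GDR statistics and log2 cluster centers."""

    means: dict[str, float]
    sds: dict[str, float]
    log2_centers: dict[str, float]
    n_controls: dict[str, int]


@dataclass(frozen=True)
class CopyCall:
    sample_id: str
    genotype: str
    fold_change_vs_1b: float
    log2_distance: float
    ambiguous: bool


def aggregate_ct(replicates: Sequence[float], *, sd_flag: float = DEFAULT_SD_FLAG) -> tuple[float, float, bool]:
    """Mean and sample SD of replicate Ct values, with a noise flag.

    Requires >= 2 positive replicates; the flag marks triples whose SD
    exceeds ``sd_flag`` cycles (0.5 by default), the usual symptom of a
    pipetting or amplification problem.
    """
    values = np.asarray(list(replicates), dtype=float)
    if values.size < 2:
        raise ValueError("need at least two Ct replicates")
    if np.any(values <= 0) or not np.all(np.isfinite(values)):
        raise ValueError("Ct values must be positive and finite")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return mean, sd, sd > sd_flag


def gdr(
    sample_id: str,
    target_replicates: Sequence[float],
    ref_replicates: Sequence[float],
    *,
    sd_flag: float = DEFAULT_SD_FLAG,
) -> DoseEstimate:
    """Gene dose ratio 2^-(Ct_target - Ct_HPRT) for one sample."""
    t_mean, t_sd, t_flag = aggregate_ct(target_replicates, sd_flag=sd_flag)
    r_mean, r_sd, r_flag = aggregate_ct(ref_replicates, sd_flag=sd_flag)
    return DoseEstimate(
        sample_id=sample_id,
        ct_target_mean=t_mean,
        ct_target_sd=t_sd,
        ct_ref_mean=r_mean,
        ct_ref_sd=r_sd,
        flagged=t_flag or r_flag,
    )


def dose_table(ct: pd.DataFrame, *, sd_flag: float = DEFAULT_SD_FLAG) -> list[DoseEstimate]:
    """Per-sample dose estimates from a tidy Ct table.

    Expects columns ``sample_id, assay, ct`` with assay in
    {``target``, ``HPRT``}; every sample must carry both assays.
    """
    required = {"sample_id", "assay", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    estimates = []
    for sample_id, group in ct.groupby("sample_id", sort=False):
        by_assay = {assay: sub["ct"].tolist() for assay, sub in group.groupby("assay")}
        for assay in ("target", "HPRT"):
            if assay not in by_assay:
                raise ValueError(f"sample {sample_id!r} lacks the {assay} assay")
        estimates.append(
            gdr(str(sample_id), by_assay["target"], by_assay["HPRT"], sd_flag=sd_flag)
        )
    return estimates


def calibrate(
    estimates: Sequence[DoseEstimate], genotypes: Mapping[str, str]
) -> Calibration:
    """Fit per-genotype GDR clusters from known 0B/1B/2B controls.

    Requires at least one control per class and a strictly increasing
    mean GDR across 0B < 1B < 2B; an inversion invalidates dose
    discrimination and raises :class:`CalibrationError`.
    """
    by_class: dict[str, list[float]] = {g: [] for g in GENOTYPE_ORDER}
    for est in estimates:
        genotype = genotypes.get(est.sample_id)
        if genotype is None:
            continue
        if genotype not in by_class:
            raise ValueError(f"unknown genotype label {genotype!r}")
        by_class[genotype].append(est.gdr)
    missing = [g for g, vals in by_class.items() if not vals]
    if missing:
        raise ValueError(f"no controls for genotype class(es): {', '.join(missing)}")
    means = {g: float(np.mean(v)) for g, v in by_class.items()}
    if not means["0B"] < means["1B"] < means["2B"]:
        raise CalibrationError(
            "control GDR means are not ordered 0B < 1B < 2B: "
            + ", ".join(f"{g}={means[g]:.3g}" for g in GENOTYPE_ORDER)
        )
    return Calibration(
        means=means,
        sds={g: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for g, v in by_class.items()},
        log2_centers={g: float(np.mean(np.log2(v))) for g, v in by_class.items()},
        n_controls={g: len(v) for g, v in by_class.items()},
    )


def call_copies(
    estimate: DoseEstimate,
    calibration: Calibration,
    *,
    epsilon: float = DEFAULT_EPSILON,
) -> CopyCall:
    """Assign the genotype with the nearest log2 GDR cluster center.

    ``fold_change_vs_1b`` is GDR / mean control GDR of the 1B class; the
    call is flagged ambiguous when the two nearest centers differ by less
    than ``epsilon`` log2 units in distance.
    """
    log_gdr = math.log2(estimate.gdr)
    dists = sorted(
        (abs(log_gdr - center), g) for g, center in calibration.log2_centers.items()
    )
    best_dist, best_g = dists[0]
    ambiguous = len(dists) > 1 and (dists[1][0] - best_dist) < epsilon
    return CopyCall(
        sample_id=estimate.sample_id,
        genotype=best_g,
        fold_change_vs_1b=estimate.gdr / calibration.means["1B"],
        log2_distance=best_dist,
        ambiguous=ambiguous,
    )


def cohort_fold_change(
    gdr_2b: Sequence[float],
    gdr_1b: Sequence[float],
    *,
    n_boot: int = 1_000,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Ratio of mean GDRs, 2B over 1B, with a bootstrap percentile interval.

    Under the linear dose model with ``a`` A-complement copies and ``c``
    copies added per B this converges to (a + 2c) / (a + c), i.e. to 2 as
    c/a grows — the "two-fold in 2B" signature of a B-borne high-copy
    region.
    """
    x2 = np.asarray(list(gdr_2b), dtype=float)
    x1 = np.asarray(list(gdr_1b), dtype=float)
    if x2.size == 0 or x1.size == 0:
        raise ValueError("both genotype classes need at least one sample")
    ratio = float(x2.mean() / x1.mean())
    rng = np.random.default_rng(seed)
    idx2 = rng.integers(0, x2.size, size=(n_boot, x2.size))
    idx1 = rng.integers(0, x1.size, size=(n_boot, x1.size))
    boot = x2[idx2].mean(axis=1) / x1[idx1].mean(axis=1)
    lo, hi = np.quantile(boot, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return ratio, (float(lo), float(hi))
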