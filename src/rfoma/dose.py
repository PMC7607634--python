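"""Complex-ratio normalization, the delta-250kDa statistic, and the gene-dose model.

The strength of a restorer allele is measured on Blue Native blots as the
drop in the CMS-associated 250-kDa complex relative to the rf1rf1 baseline,
after normalizing each lane's 250-kDa signal by the 420-kDa COXI loading
complex:

    delta = baseline_mean - genotype_mean,   clamped to [0, baseline_mean].

The additive dose model says two restorer alleles contribute twice the
per-allele delta, but the realized drop saturates at the baseline (a signal
cannot fall below zero), leaving a residual = potential - realized.  qPCR
abundances come from 2^(ct_reference - ct_target) with efficiency 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class DoseError(ValueError):
    """Invalid densitometry/qPCR input for the dose analysis."""


@dataclass(frozen=True)
class ComplexRatio:
    """Replicated 250-kDa/420-kDa intensity ratio for one genotype."""

    genotype_label: str
    replicate_values: tuple[float, ...]
    mean: float
    sd: float
    detected: bool


@dataclass(frozen=True)
class DeltaStat:
    """Drop in 250-kDa accumulation relative to the rf1rf1 baseline."""

    genotype_label: str
    baseline_label: str
    delta: float
    baseline_mean: float


@dataclass(frozen=True)
class GenotypeDose:
    """Additive dose prediction with the detection-ceiling split."""

    genotype_label: str
    n_restoring_alleles: int
    per_allele_delta: float
    potential_delta: float
    realized_delta: float
    residual: float


@dataclass(frozen=True)
class QpcrQuant:
    """Relative transcript abundance for one genotype/stage/reference gene."""

    genotype_label: str
    stage: str
    reference_gene: str
    relative_abundance: float
    sd: float
    detected: bool


@dataclass(frozen=True)
class DoseCorrelation:
    """mRNA quantity vs delta: Pearson r and the least-squares line."""

    points: tuple[tuple[float, float], ...]
    pearson_r: float
    slope: float
    intercept: float


def complex_ratio(densitometry: pd.DataFrame, genotype_label: str) -> ComplexRatio:
    """Mean +- SD of the 250/420 ratio over a genotype's replicates.

    A genotype whose replicates are all zero is flagged not-detected (its
    band was invisible on the blot); a single replicate gets SD 0.
    """
    rows = densitometry.loc[densitometry["genotype"] == genotype_label]
    if rows.empty:
        raise DoseError(f"no densitometry rows for genotype {genotype_label!r}")
    values = rows["ratio_250_over_420"].to_numpy(dtype=float)
    if (values < 0).any():
        raise DoseError(f"negative intensity ratio for {genotype_label!r}")
    detected = bool((values > 0).any())
    mean = float(values.mean()) if detected else 0.0
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return ComplexRatio(
        genotype_label=genotype_label,
        replicate_values=tuple(float(v) for v in values),
        mean=mean,
        sd=sd,
        detected=detected,
    )


def delta_250(baseline: ComplexRatio, genotype: ComplexRatio) -> DeltaStat:
    """delta = baseline mean - genotype mean, clamped to [0, baseline mean].

    A not-detected genotype realizes the full baseline drop (the ceiling of
    the assay); a not-detected baseline leaves nothing to compare against.
    """
    if not baseline.detected:
        raise DoseError(
            f"baseline {baseline.genotype_label!r} has no detectable signal"
        )
    mean = 0.0 if not genotype.detected else genotype.mean
    delta = min(max(baseline.mean - mean, 0.0), baseline.mean)
    return DeltaStat(
        genotype_label=genotype.genotype_label,
        baseline_label=baseline.genotype_label,
        delta=delta,
        baseline_mean=baseline.mean,
    )


def dose_model(
    per_allele_delta: float,
    n_alleles: int,
    baseline_mean: float,
    genotype_label: str = "",
) -> GenotypeDose:
    """Additive dose with ceiling: realized = min(n * per-allele, baseline)."""
    if n_alleles not in (1, 2):
        raise DoseError("n_alleles must be 1 (heterozygote) or 2 (homozygote)")
    if per_allele_delta < 0 or baseline_mean < 0:
        raise DoseError("deltas and baseline must be non-negative")
    potential = n_alleles * per_allele_delta
    realized = min(potential, baseline_mean)
    return GenotypeDose(
        genotype_label=genotype_label,
        n_restoring_alleles=n_alleles,
        per_allele_delta=per_allele_delta,
        potential_delta=potential,
        realized_delta=realized,
        residual=potential - realized,
    )


def relative_expression(
    ct_target: float, ct_reference: float, efficiency: float = 2.0
) -> float:
    """efficiency^(ct_reference - ct_target); NaN target Ct (no
    amplification) maps to 0."""
    if ct_target is None or (isinstance(ct_target, float) and math.isnan(ct_target)):
        return 0.0
    return float(efficiency ** (ct_reference - ct_target))


def quantify_qpcr(
    qpcr: pd.DataFrame, efficiency: float = 2.0
) -> list[QpcrQuant]:
    """Collapse a Ct table into per-(genotype, stage, reference) abundances."""
    out: list[QpcrQuant] = []
    grouped = qpcr.groupby(["genotype", "stage", "reference_gene"], sort=False)
    for (genotype, stage, ref_gene), rows in grouped:
        abundances = [
            relative_expression(t, r, efficiency)
            for t, r in zip(rows["ct_target"], rows["ct_reference"])
        ]
        detected = any(a > 0 for a in abundances)
        out.append(
            QpcrQuant(
                genotype_label=genotype,
                stage=stage,
                reference_gene=ref_gene,
                relative_abundance=float(np.mean(abundances)) if detected else 0.0,
                sd=float(np.std(abundances, ddof=1)) if len(abundances) > 1 else 0.0,
                detected=detected,
            )
        )
    return out


def correlate_dose(
    quants: Sequence[QpcrQuant], deltas: Sequence[DeltaStat]
) -> DoseCorrelation:
    """Join abundances to deltas on genotype and fit the dose-response line."""
    delta_by_genotype = {d.genotype_label: d.delta for d in deltas}
    points = [
        (q.relative_abundance, delta_by_genotype[q.genotype_label])
        for q in quants
        if q.genotype_label in delta_by_genotype
    ]
    if len(points) < 3:
        raise DoseError(f"need >= 3 joined genotypes, got {len(points)}")
    x = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points])
    fit = stats.linregress(x, y)
    return DoseCorrelation(
        points=tuple(points),
        pearson_r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def plot_dose(correlation: DoseCorrelation, path: str) -> None:
    """Scatter of mRNA quantity vs delta with the fitted line (SVG/PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = [p[0] for p in correlation.points]
    y = [p[1] for p in correlation.points]
    fig, ax = plt.subplots(figsize=(4.2, 3.4))
    ax.scatter(x, y, color="black", zorder=3)
    xs = np.linspace(min(x), max(x), 50)
    ax.plot(xs, correlation.slope * xs + correlation.intercept, color="grey")
    ax.set_xlabel("200-kDa generative mRNA (relative)")
    ax.set_ylabel(r"$\Delta^{250\,\mathrm{kDa}}$")
    ax.set_title(f"r = {correlation.pearson_r:.2f}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
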