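"""Poisson quantification of droplet digital PCR counts and population
copy-number summaries.

In digital PCR the sample is partitioned into droplets; a droplet is
positive if it received at least one template molecule. Under Poisson
loading with mean ``lam`` molecules per droplet the positive fraction is
``1 - exp(-lam)``, so ``lam = -ln(1 - p)``. Copy number per diploid genome
is the target/reference concentration ratio scaled by the reference's
diploid copy count (2 for an autosomal single-copy reference such as
EIF2C1). Droplet volume cancels in the ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .simulate import SaturationError

__all__ = [
    "LambdaEstimate",
    "CopyNumberEstimate",
    "estimate_lambda",
    "estimate_copy_number",
    "quantify_table",
    "bin_copy_numbers",
    "population_summary",
    "DROPLET_VOLUME_NL",
]

# QX100/QX200 nominal droplet volume, used only for optional copies/uL output.
DROPLET_VOLUME_NL = 0.85


@dataclass
class LambdaEstimate:
    """Mean template molecules per droplet for one channel, with a 95% CI
    obtained by transforming a Wilson binomial interval on the positive
    fraction through -ln(1 - p)."""

    lam: float
    ci_low: float
    ci_high: float
    positives: int
    total: int

    @property
    def copies_per_ul(self) -> float:
        """Absolute concentration assuming the nominal droplet volume."""
        return self.lam / (DROPLET_VOLUME_NL * 1e-3)


@dataclass
class CopyNumberEstimate:
    sample_id: str
    population: str
    cn: float
    ci_low: float
    ci_high: float


def estimate_lambda(positives: int, total: int) -> LambdaEstimate:
    """Invert the Poisson loading model: lam = -ln(1 - positives/total)."""
    if total <= 0:
        raise ValueError("total droplet count must be positive")
    if positives < 0 or positives > total:
        raise ValueError(f"positives {positives} outside [0, {total}]")
    if positives == total:
        raise SaturationError(
            f"all {total} droplets positive: concentration not quantifiable"
        )
    p_hat = positives / total
    lam = -math.log1p(-p_hat)
    lo, hi = proportion_confint(positives, total, alpha=0.05, method="wilson")
    hi = min(hi, 1.0 - 1e-15)
    return LambdaEstimate(
        lam=lam,
        ci_low=-math.log1p(-float(lo)),
        ci_high=-math.log1p(-float(hi)),
        positives=positives,
        total=total,
    )


def estimate_copy_number(
    target: LambdaEstimate,
    reference: LambdaEstimate,
    reference_copies: int = 2,
    sample_id: str = "",
    population: str = "",
) -> CopyNumberEstimate:
    """cn = reference_copies * lam_target / lam_reference; the CI propagates
    the channel CIs as a ratio of bounds."""
    if reference.lam <= 0:
        raise ValueError("no reference signal (lambda == 0)")
    cn = reference_copies * target.lam / reference.lam
    ci_low = reference_copies * target.ci_low / reference.ci_high
    ci_high = (
        reference_copies * target.ci_high / reference.ci_low
        if reference.ci_low > 0
        else math.inf
    )
    return CopyNumberEstimate(sample_id, population, cn, ci_low, ci_high)


def quantify_table(droplets: pd.DataFrame, reference_copies: int = 2) -> list[CopyNumberEstimate]:
    """Per-sample copy-number estimates from a validated droplet table."""
    estimates = []
    for sample_id, group in droplets.groupby("sample_id", sort=True):
        by_channel = group.set_index("channel")
        lam = {
            channel: estimate_lambda(
                int(by_channel.loc[channel, "positives"]),
                int(by_channel.loc[channel, "total"]),
            )
            for channel in ("target", "reference")
        }
        estimates.append(
            estimate_copy_number(
                lam["target"],
                lam["reference"],
                reference_copies=reference_copies,
                sample_id=str(sample_id),
                population=str(group["population"].iloc[0]),
            )
        )
    return estimates


def bin_copy_numbers(
    estimates: list[CopyNumberEstimate], bin_width: float = 0.5
) -> dict[float, int]:
    """Histogram of copy numbers in half-open bins [c - w/2, c + w/2)
    centered on multiples of the bin width."""
    if not estimates:
        raise ValueError("no estimates to bin")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    counts: dict[float, int] = {}
    for est in estimates:
        center = math.floor(est.cn / bin_width + 0.5) * bin_width
        center = round(center, 10)
        counts[center] = counts.get(center, 0) + 1
    return dict(sorted(counts.items()))


def population_summary(estimates: list[CopyNumberEstimate]) -> pd.DataFrame:
    """Per-population n, mean and sample (n-1) SD, plus a 'pooled' row.

    SD is NaN where a population has a single sample.
    """
    if not estimates:
        raise ValueError("no estimates to summarize")
    df = pd.DataFrame(
        {"population": [e.population for e in estimates], "cn": [e.cn for e in estimates]}
    )
    rows = []
    for population, group in df.groupby("population", sort=True):
        values = group["cn"].to_numpy()
        sd = float(np.std(values, ddof=1)) if values.size > 1 else float("nan")
        rows.append((population, values.size, float(values.mean()), sd))
    all_values = df["cn"].to_numpy()
    pooled_sd = float(np.std(all_values, ddof=1)) if all_values.size > 1 else float("nan")
    rows.append(("pooled", all_values.size, float(all_values.mean()), pooled_sd))
    return pd.DataFrame(rows, columns=["population", "n", "mean", "sd"])
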