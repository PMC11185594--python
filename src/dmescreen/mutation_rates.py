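"""Phenotypic mutation rates from plating assays and screen-saturation arithmetic.

A mutagenized pool is plated on selective medium (canavanine, copper, or
sulfite); the phenotypic mutation rate is the fraction of plated cells that
form colonies, with a Poisson error on the colony count.  Anchoring the
induced phenotypic rate to a published spontaneous baseline converts the
fold-increase into a per-base-pair mutation rate, and from there into the
expected number of mutations per genome and the expected number of
independent mutants per genomic site across the whole screen ("saturation").
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

# Published spontaneous baselines from a canavanine fluctuation-free plating
# assay: phenotypic rate of canavanine-resistant mutants per cell plated, and
# the per-base-pair per-division rate inferred from it.
BASELINE_PHENOTYPIC = 1.52e-7
BASELINE_PER_BP = 6.44e-10

# Haploid genome length (bp).  Not an assay measurement; a config constant.
GENOME_LENGTH = 1.2e7


@dataclass(frozen=True)
class PlatingCount:
    """Colonies recovered from plating a known number of cells on one plate."""

    strain: str
    colonies: int
    cells_plated: float
    ploidy: Literal["haploid", "diploid"] = "haploid"
    pool: Literal["mutagenized", "mock"] = "mutagenized"
    condition: str = "canavanine"
    concentration: float = 0.0

    def __post_init__(self) -> None:
        if self.colonies < 0:
            raise ValueError(f"colonies must be >= 0, got {self.colonies}")
        if self.cells_plated <= 0:
            raise ValueError(f"cells_plated must be > 0, got {self.cells_plated}")


@dataclass(frozen=True)
class RateEstimate:
    """Phenotypic mutation rate with its Poisson standard deviation.

    rate = colonies / cells_plated; sd = sqrt(colonies) / cells_plated,
    treating the colony count as Poisson distributed.
    """

    rate: float
    sd: float
    ci95: tuple[float, float] | None = None


@dataclass(frozen=True)
class SaturationEstimate:
    """Derived screen-saturation quantities.

    fold_increase
        Induced phenotypic rate over the spontaneous phenotypic baseline.
    per_bp_rate
        Induced mutations per base pair: fold_increase x per-bp baseline.
    per_genome
        Expected induced mutations per genome: per_bp_rate x genome length.
    per_site_coverage
        Expected number of independent mutants carrying a mutation at any
        given genomic site across the screen: per_bp_rate x cells screened.
    """

    fold_increase: float
    per_bp_rate: float
    per_genome: float
    per_site_coverage: float | None = None
    genome_length: float = GENOME_LENGTH
    baseline_phenotypic: float = BASELINE_PHENOTYPIC
    baseline_per_bp: float = BASELINE_PER_BP


def plating_rate(count: PlatingCount, ci: bool = False) -> RateEstimate:
    """Phenotypic mutation rate for one plating.

    Rate is colonies recovered divided by cells plated; the standard
    deviation assumes the colony count is Poisson.  With ``ci=True`` an
    exact (Garwood) 95% Poisson interval on the count is attached, divided
    through by cells plated; zero colonies then yield (0, 3.689/cells).
    """
    rate = count.colonies / count.cells_plated
    sd = math.sqrt(count.colonies) / count.cells_plated
    interval = None
    if ci:
        k = count.colonies
        lo = 0.0 if k == 0 else stats.chi2.ppf(0.025, 2 * k) / 2
        hi = stats.chi2.ppf(0.975, 2 * (k + 1)) / 2
        interval = (lo / count.cells_plated, hi / count.cells_plated)
    return RateEstimate(rate=rate, sd=sd, ci95=interval)


def fold_increase(induced: RateEstimate | float, baseline_phenotypic: float = BASELINE_PHENOTYPIC) -> float:
    """Fold increase of the induced phenotypic rate over the spontaneous baseline."""
    if baseline_phenotypic <= 0:
        raise ValueError("baseline phenotypic rate must be > 0")
    rate = induced.rate if isinstance(induced, RateEstimate) else float(induced)
    return rate / baseline_phenotypic


def per_bp_rate(fold: float, baseline_per_bp: float = BASELINE_PER_BP) -> float:
    """Induced per-base-pair mutation rate: fold increase x per-bp baseline."""
    return fold * baseline_per_bp


def mutations_per_genome(mu: float, genome_length: float = GENOME_LENGTH) -> float:
    """Expected induced mutations per genome at per-bp rate ``mu``."""
    return mu * genome_length


def per_site_screen_coverage(mu: float, cells_screened: float) -> float:
    """Expected mutants per genomic site across the whole screen.

    The product of the induced per-bp rate and the number of cells screened:
    how many independent mutants, on average, carry a mutation at any given
    site of the genome.  When per-strain cell counts are available, compute
    this per strain and average (see :func:`saturation_summary`).
    """
    return mu * cells_screened


def saturation_summary(
    fold: float,
    cells_screened: float | Sequence[float] | None = None,
    genome_length: float = GENOME_LENGTH,
    baseline_phenotypic: float = BASELINE_PHENOTYPIC,
    baseline_per_bp: float = BASELINE_PER_BP,
) -> SaturationEstimate:
    """Chain the saturation arithmetic from a fold increase.

    ``cells_screened`` may be a single pooled count or per-strain counts;
    per-strain counts are converted to per-strain coverages and averaged.
    """
    mu = per_bp_rate(fold, baseline_per_bp)
    lam = mutations_per_genome(mu, genome_length)
    coverage = None
    if cells_screened is not None:
        if np.ndim(cells_screened) == 0:
            coverage = per_site_screen_coverage(mu, float(cells_screened))
        else:
            coverage = float(np.mean([per_site_screen_coverage(mu, c) for c in np.asarray(cells_screened, dtype=float)]))
    return SaturationEstimate(
        fold_increase=fold,
        per_bp_rate=mu,
        per_genome=lam,
        per_site_coverage=coverage,
        genome_length=genome_length,
        baseline_phenotypic=baseline_phenotypic,
        baseline_per_bp=baseline_per_bp,
    )


def compare_rates(
    group_a: Sequence[PlatingCount],
    group_b: Sequence[PlatingCount],
    method: Literal["paired_t", "chi_square"] = "paired_t",
    yates: bool = False,
) -> tuple[float, float]:
    """Compare phenotypic rates between two strains or species.

    ``paired_t``: rates paired by concentration (lists must align);
    statistic is the paired t over the per-concentration rate differences.
    ``chi_square``: a single concentration each side; the 2x2 table is
    (colonies, non-colony cells) x (group A, group B).  Yates continuity
    correction is off by default.

    Returns (statistic, p-value).
    """
    if method == "paired_t":
        if len(group_a) != len(group_b):
            raise ValueError("paired_t requires equal-length, concentration-matched groups")
        for a, b in zip(group_a, group_b):
            if a.concentration != b.concentration:
                raise ValueError(
                    f"concentration mismatch in pairing: {a.concentration} vs {b.concentration}"
                )
        ra = [plating_rate(c).rate for c in group_a]
        rb = [plating_rate(c).rate for c in group_b]
        if np.allclose(ra, rb):
            # zero differences everywhere: no evidence of a difference
            return 0.0, 1.0
        res = stats.ttest_rel(ra, rb)
        return float(res.statistic), float(res.pvalue)
    if method == "chi_square":
        if len(group_a) != 1 or len(group_b) != 1:
            raise ValueError("chi_square compares one plating per group")
        a, b = group_a[0], group_b[0]
        table = np.array(
            [
                [a.colonies, a.cells_plated - a.colonies],
                [b.colonies, b.cells_plated - b.colonies],
            ]
        )
        chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
        return float(chi2), float(p)
    raise ValueError(f"unknown method: {method}")


# ---------------------------------------------------------------------------
# I/O


def read_plating_counts(path: str) -> list[PlatingCount]:
    """Read plating counts from a TSV with columns
    strain, ploidy, pool, condition, concentration, colonies, cells_plated."""
    df = pd.read_csv(path, sep="\t")
    return [
        PlatingCount(
            strain=str(r.strain),
            ploidy=r.ploidy,
            pool=r.pool,
            condition=str(r.condition),
            concentration=float(r.concentration),
            colonies=int(r.colonies),
            cells_plated=float(r.cells_plated),
        )
        for r in df.itertuples()
    ]


def rates_report(
    counts: Sequence[PlatingCount],
    baseline_phenotypic: float = BASELINE_PHENOTYPIC,
    baseline_per_bp: float = BASELINE_PER_BP,
    genome_length: float = GENOME_LENGTH,
    ci: bool = False,
) -> pd.DataFrame:
    """Per-plating rate table with fold increases and saturation chain."""
    rows = []
    for c in counts:
        est = plating_rate(c, ci=ci)
        fold = fold_increase(est, baseline_phenotypic)
        mu = per_bp_rate(fold, baseline_per_bp)
        rows.append(
            {
                "strain": c.strain,
                "ploidy": c.ploidy,
                "pool": c.pool,
                "condition": c.condition,
                "concentration": c.concentration,
                "colonies": c.colonies,
                "cells_plated": c.cells_plated,
                "rate": est.rate,
                "rate_sd": est.sd,
                "fold_increase": fold,
                "per_bp_rate": mu,
                "per_genome": mutations_per_genome(mu, genome_length),
            }
        )
    return pd.DataFrame(rows)


def write_rates_report(df: pd.DataFrame, tsv_path: str, json_path: str | None = None) -> None:
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=2)
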