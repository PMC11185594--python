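"""Colony-array phenotyping: resistance scores, escapee calls, edge
correction, and pleiotropic-cost statistics.

Colonies are arrayed on solid plates (typically 1536 = 32 x 48 format) and
imaged under a dilution series of a stressor.  Each strain's colony size at
each stressor concentration is normalized to its own no-stress size, giving
a dose-response profile; resistance is the trapezoid-rule area under that
profile (AUC, in mM), and effect size is the AUC shift relative to the
ancestral mean (dAUC).  Strains whose AUC does not exceed the ancestral mean
by more than three standard deviations are "physiological escapees" —
colonies recovered on selection without a heritable resistance mutation —
and are excluded from downstream analyses.  Growth in permissive media,
edge-corrected by layer normalization, measures pleiotropic cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Relative colony sizes are capped here after no-stress normalization, so a
#: fully resistant profile over a 0..c_max series has AUC exactly c_max.
DEFAULT_CAP = 1.0

#: Permissive media assayed for pleiotropic cost (base medium x carbon source).
PERMISSIVE_CONDITIONS = ("MMD", "MMG", "CMD", "CMG", "YPD", "YPG")


@dataclass(frozen=True)
class DoseResponseProfile:
    """Relative colony size of one strain along a stressor dilution series."""

    strain: str
    concentrations: tuple[float, ...]
    relative_sizes: tuple[float, ...]
    timepoint: float | None = None

    def __post_init__(self) -> None:
        c = self.concentrations
        if len(c) != len(self.relative_sizes):
            raise ValueError("concentrations and sizes differ in length")
        if len(c) >= 1 and c[0] != 0:
            raise ValueError("profile must start at concentration 0")
        if any(b <= a for a, b in zip(c, c[1:])):
            raise ValueError("concentrations must be strictly increasing")


@dataclass(frozen=True)
class ResistanceScore:
    strain: str
    auc: float
    delta_auc: float
    escapee: bool


def normalize_profile(
    measurements: pd.DataFrame,
    strain: str,
    timepoint: float | None = None,
    cap: float = DEFAULT_CAP,
) -> DoseResponseProfile:
    """Build a strain's dose-response profile from its colony-size table.

    ``measurements`` needs columns strain, concentration, size (and
    timepoint when ``timepoint`` is given).  Each size is divided by the
    strain's size on the no-stress (0 mM) plate and capped at ``cap``;
    concentrations with no measurement are simply absent from the profile
    (the AUC is taken over the observed grid, with no interpolation).

    A strain with no colony at 0 mM cannot be normalized and is flagged
    unscorable via ValueError.
    """
    sub = measurements[measurements["strain"] == strain]
    if timepoint is not None:
        sub = sub[sub["timepoint"] == timepoint]
    if sub.empty:
        raise ValueError(f"no measurements for strain {strain!r}")
    by_conc = sub.groupby("concentration")["size"].mean().sort_index()
    if 0.0 not in by_conc.index:
        raise ValueError(f"strain {strain!r} lacks a 0 mM measurement")
    base = by_conc.loc[0.0]
    if base == 0:
        raise ValueError(f"strain {strain!r} unscorable: zero size at 0 mM")
    rel = np.minimum(by_conc.values / base, cap)
    return DoseResponseProfile(
        strain=strain,
        concentrations=tuple(float(c) for c in by_conc.index),
        relative_sizes=tuple(float(s) for s in rel),
        timepoint=timepoint,
    )


def auc(profile: DoseResponseProfile) -> float:
    """Trapezoid-rule area of relative size over concentration (mM)."""
    if len(profile.concentrations) < 2:
        raise ValueError("AUC needs at least two concentrations")
    return float(np.trapezoid(profile.relative_sizes, profile.concentrations))


def delta_auc(mutant_auc: float, ancestor_aucs: Sequence[float]) -> float:
    """Mutant AUC minus the mean ancestral AUC."""
    return mutant_auc - float(np.mean(ancestor_aucs))


def classify_escapee(mutant_auc: float, ancestor_aucs: Sequence[float]) -> bool:
    """True when the mutant phenocopies its ancestor (no heritable resistance).

    A mutant is retained only when its AUC exceeds the ancestral mean by
    more than three sample standard deviations; the boundary itself counts
    as an escapee.  Needs >= 2 ancestor replicates for the sd.
    """
    if len(ancestor_aucs) < 2:
        raise ValueError("escapee threshold needs >= 2 ancestor AUC replicates")
    mean = float(np.mean(ancestor_aucs))
    sd = float(np.std(ancestor_aucs, ddof=1))
    return mutant_auc <= mean + 3 * sd


def layer_index(row: int, col: int, n_rows: int, n_cols: int) -> int:
    """1-based distance layer of a grid position from the plate edge.

    Layer 1 is the outermost ring; a 32 x 48 (1536-format) plate decomposes
    into 16 layers.
    """
    if not (1 <= row <= n_rows and 1 <= col <= n_cols):
        raise ValueError(f"position ({row},{col}) outside {n_rows}x{n_cols} grid")
    return 1 + min(row - 1, col - 1, n_rows - row, n_cols - col)


def n_layers(n_rows: int, n_cols: int) -> int:
    """Number of distinct edge-distance layers on a grid."""
    return math.ceil(min(n_rows, n_cols) / 2)


def layer_normalize(plate: pd.DataFrame, n_rows: int, n_cols: int) -> pd.DataFrame:
    """Remove plate edge effects by layer-based normalization.

    Colonies are grouped by their edge distance layer; each size is rescaled
    by median(all sizes on plate) / median(sizes in its layer), so every
    layer's median equals the plate median afterwards.  Medians are used for
    robustness to QC outliers.  A layer whose median is 0 cannot be rescaled
    and is left uncorrected.

    Returns a copy of ``plate`` with a ``size_corrected`` column (and a
    ``layer`` column).
    """
    out = plate.copy()
    out["layer"] = [
        layer_index(r, c, n_rows, n_cols) for r, c in zip(out["row"], out["col"])
    ]
    plate_median = out["size"].median()
    layer_medians = out.groupby("layer")["size"].median()
    factors = out["layer"].map(
        lambda l: plate_median / layer_medians[l] if layer_medians[l] > 0 else 1.0
    )
    out["size_corrected"] = out["size"] * factors
    return out


def relative_growth(mutant_size: float, ancestor_sizes: Sequence[float]) -> float:
    """Permissive growth relative to the ancestor (1 = equal colony size)."""
    mean = float(np.mean(ancestor_sizes))
    if mean <= 0:
        raise ValueError("ancestor mean size must be > 0")
    return mutant_size / mean


def average_technical_replicates(
    measurements: pd.DataFrame, by: Sequence[str] = ("strain", "condition", "concentration")
) -> pd.DataFrame:
    """Collapse technical replicates to one value per biological strain.

    QC-removed replicates (``qc_flag`` == 'removed') are dropped before the
    arithmetic mean; groups with every replicate removed vanish.
    """
    sub = measurements
    if "qc_flag" in sub.columns:
        sub = sub[sub["qc_flag"] != "removed"]
    return sub.groupby(list(by), as_index=False)["size"].mean()


def score_strains(
    measurements: pd.DataFrame,
    ancestor_strains: Sequence[str],
    timepoint: float | None = None,
    cap: float = DEFAULT_CAP,
) -> pd.DataFrame:
    """AUC, dAUC and escapee call for every non-ancestor strain in a table.

    Ancestor replicate AUCs (pooled across plates of the listed ancestor
    strains) define the mean and sd of the 3-SD escapee rule.
    """
    ancestor_aucs = []
    for a in ancestor_strains:
        for rep, grp in measurements[measurements["strain"] == a].groupby(
            "plate_id" if "plate_id" in measurements.columns else "strain"
        ):
            prof = normalize_profile(grp.assign(strain=a), a, timepoint=timepoint, cap=cap)
            ancestor_aucs.append(auc(prof))
    rows = []
    for strain in measurements["strain"].unique():
        if strain in set(ancestor_strains):
            continue
        prof = normalize_profile(measurements, strain, timepoint=timepoint, cap=cap)
        a = auc(prof)
        rows.append(
            {
                "strain": strain,
                "AUC": a,
                "dAUC": delta_auc(a, ancestor_aucs),
                "escapee": classify_escapee(a, ancestor_aucs),
            }
        )
    return pd.DataFrame(rows)


def cost_tests(
    costs: pd.DataFrame,
    n_tests: int = len(PERMISSIVE_CONDITIONS),
) -> pd.DataFrame:
    """Per-condition cost statistics with explicit Bonferroni correction.

    ``costs`` has columns condition, species, g (relative growth).  For each
    condition: a one-sample t of g against 1 (is there any cost at all?) and
    a Kruskal-Wallis between species (do species differ in cost?); both
    p-values are multiplied by ``n_tests`` (capped at 1).
    """
    rows = []
    for cond, grp in costs.groupby("condition"):
        g = grp["g"].to_numpy()
        if np.allclose(g, g[0]) and g[0] == 1.0:
            t_stat, t_p = 0.0, 1.0
        else:
            t_stat, t_p = stats.ttest_1samp(g, popmean=1.0)
        species_groups = [sg["g"].to_numpy() for _, sg in grp.groupby("species")]
        if len(species_groups) >= 2:
            if np.allclose(g, g[0]):  # every value tied: no rank signal
                kw_stat, kw_p = 0.0, 1.0
            else:
                kw_stat, kw_p = stats.kruskal(*species_groups)
        else:
            kw_stat, kw_p = float("nan"), float("nan")
        rows.append(
            {
                "condition": cond,
                "t_stat": float(t_stat),
                "t_p": float(t_p),
                "t_p_bonf": min(1.0, float(t_p) * n_tests),
                "kw_stat": float(kw_stat),
                "kw_p": float(kw_p),
                "kw_p_bonf": min(1.0, float(kw_p) * n_tests) if not math.isnan(kw_p) else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def effect_cost_relation(
    delta_aucs: Sequence[float],
    costs: Sequence[float],
    species: Sequence[str],
) -> dict:
    """Relate effect size to pleiotropic cost, per species and jointly.

    Per species: Spearman rank correlation of dAUC with relative growth
    (a negative rho means bigger-effect mutants grow worse in permissive
    media).  Jointly: a two-factor linear model
    ``cost ~ dAUC * species`` whose interaction p-value asks whether the
    cost-effect relationship differs between species.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame({"dauc": delta_aucs, "cost": costs, "species": species})
    per_species = {}
    for sp, grp in df.groupby("species"):
        rho, p = stats.spearmanr(grp["dauc"], grp["cost"])
        per_species[sp] = {"rho": float(rho), "p": float(p)}
    interaction_p = float("nan")
    if df["species"].nunique() >= 2:
        model = smf.ols("cost ~ dauc * C(species)", data=df).fit()
        table = anova_lm(model, typ=2)
        interaction_p = float(table.loc["dauc:C(species)", "PR(>F)"])
    return {"per_species": per_species, "interaction_p": interaction_p}


# ---------------------------------------------------------------------------
# I/O

COLONY_COLUMNS = ["plate_id", "row", "col", "condition", "conc_mM", "timepoint_h", "size_px"]


def read_colony_table(path: str) -> pd.DataFrame:
    """Read a colony-size TSV and map to the internal column names."""
    df = pd.read_csv(path, sep="\t")
    ren = {"conc_mM": "concentration", "timepoint_h": "timepoint", "size_px": "size"}
    return df.rename(columns=ren)
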