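"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the five kinds of data the analysis consumes —
colony-size tables from arrayed plates, dose-response series across a
stressor dilution, multi-strain genotype tables with filter-violating
sites, windowed coverage tracks with planted aneuploidies / diploidization
/ a step-shaped locus amplification, and per-gene mutation-hit tables with
planted enrichment — so the whole pipeline is testable without the original
sequencing or plate-image archives.  Every generated record maps to a
ground-truth entry, and all randomness flows from one seed through named
substreams, so a fixed seed gives bit-identical output.

Noise models: colony sizes are positive pixel counts, so noise is
multiplicative lognormal with a given coefficient of variation; window
depths are Poisson counts.  The ancestor's dose-response is a logistic
decline in concentration; a resistant mutant's curve is the ancestor's
shifted right by the mutant's true resistance shift, and an escapee's curve
is the ancestor's exactly (plus noise) — escapees phenocopy their ancestor.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_filters import (
    MISSING,
    GenotypeTable,
    SiteRecord,
)

# Named substreams: each generator derives its own child generator from
# (seed, stream id), so adding draws to one generator never perturbs another.
_STREAMS = {
    "plate": 1,
    "dose_response": 2,
    "genotype": 3,
    "coverage": 4,
    "hits": 5,
    "aneuploidy": 6,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


#: Scaled-down 16-chromosome genome for coverage simulations: 60-100 kb per
#: chromosome (60-100 windows) keeps per-chromosome means tight at Poisson
#: depth 30 while running in milliseconds.
DEFAULT_GENOME = tuple(
    (f"chr{i}", 60_000 + 2_500 * (i - 1)) for i in range(1, 17)
)

#: 18 copper concentrations spanning 0-0.8 mM, evenly spaced.
DEFAULT_CONCENTRATIONS = tuple(round(c, 6) for c in np.linspace(0.0, 0.8, 18))


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs shared by the generators."""

    seed: int = 0
    plate_rows: int = 32
    plate_cols: int = 48
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    n_mutants: int = 100
    n_escapees: int = 20
    n_ancestor_replicates: int = 6
    edge_effect_profile: tuple[float, ...] = ()  # per-layer factor; () = flat
    noise_cv: float = 0.05
    genome: tuple[tuple[str, int], ...] = DEFAULT_GENOME
    genes: tuple[tuple[str, int], ...] = ()
    depth_mean: float = 30.0
    base_size_px: float = 200.0
    # ancestor dose-response: logistic decline with this midpoint and width
    decline_midpoint: float = 0.25
    decline_width: float = 0.06

    def __post_init__(self) -> None:
        c = self.concentrations
        if not c or c[0] != 0 or any(b <= a for a, b in zip(c, c[1:])):
            raise ValueError("concentrations must be strictly increasing and start at 0")
        if any(l <= 0 for _, l in self.genome) or any(l <= 0 for _, l in self.genes):
            raise ValueError("all lengths must be > 0")

    def edge_factor(self, layer: int) -> float:
        if 1 <= layer <= len(self.edge_effect_profile):
            return self.edge_effect_profile[layer - 1]
        return 1.0


@dataclass
class GroundTruth:
    """Planted truth for whichever generator produced it."""

    true_shift: dict[str, float] = field(default_factory=dict)
    escapee: dict[str, bool] = field(default_factory=dict)
    expected_size: dict[str, float] = field(default_factory=dict)
    site_verdicts: dict[str, str] = field(default_factory=dict)
    karyotype: dict[str, int] = field(default_factory=dict)
    diploidized: bool = False
    cnv_interval: tuple[str, int, int] | None = None
    cnv_copies: int | None = None
    gene_multipliers: dict[str, float] = field(default_factory=dict)
    aneuploid_sets: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=str)


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size)
    sigma2 = np.log(1 + cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def _layer(row: int, col: int, n_rows: int, n_cols: int) -> int:
    return 1 + min(row - 1, col - 1, n_rows - row, n_cols - col)


# ---------------------------------------------------------------------------
# Plates and dose-response


def gen_plate(
    config: SimConfig,
    condition: str = "CMD",
    timepoints: Sequence[float] = (72.0,),
) -> tuple[pd.DataFrame, GroundTruth]:
    """One permissive-condition plate of arrayed strains.

    Mutants and ancestor replicates fill the grid row-major; each strain has
    a deterministic expected size (per-strain growth effect around the base
    size), multiplied by its layer's edge factor and lognormal noise.
    """
    n_strains = config.n_mutants + config.n_ancestor_replicates
    n_positions = config.plate_rows * config.plate_cols
    if n_strains > n_positions:
        raise ValueError(f"{n_strains} strains do not fit a {config.plate_rows}x{config.plate_cols} grid")
    rng = _rng(config.seed, "plate")
    strains = [f"mut{i:04d}" for i in range(config.n_mutants)] + [
        f"anc_rep{i}" for i in range(config.n_ancestor_replicates)
    ]
    roles = ["mutant"] * config.n_mutants + ["ancestor"] * config.n_ancestor_replicates
    # per-strain deterministic expectation: ancestors at the base size,
    # mutants with a mild strain effect
    strain_effect = rng.normal(1.0, 0.08, size=config.n_mutants)
    expected = {s: config.base_size_px * max(e, 0.1) for s, e in zip(strains, strain_effect)}
    expected.update({s: config.base_size_px for s in strains[config.n_mutants :]})

    rows = []
    truth = GroundTruth(expected_size=dict(expected))
    for tp in timepoints:
        noise = _lognormal_noise(rng, config.noise_cv, n_strains)
        for i, (s, role) in enumerate(zip(strains, roles)):
            r, c = divmod(i, config.plate_cols)
            r, c = r + 1, c + 1
            layer = _layer(r, c, config.plate_rows, config.plate_cols)
            size = expected[s] * config.edge_factor(layer) * noise[i]
            rows.append(
                {
                    "plate_id": "P1",
                    "row": r,
                    "col": c,
                    "strain": s,
                    "role": role,
                    "condition": condition,
                    "conc_mM": 0.0,
                    "timepoint_h": tp,
                    "size_px": max(size, 0.0),
                }
            )
    return pd.DataFrame(rows), truth


def ancestor_decline(config: SimConfig, conc: np.ndarray) -> np.ndarray:
    """Ancestor relative colony size along the dilution series.

    A logistic decline normalized to 1 at zero stressor; monotone
    nonincreasing in concentration.
    """
    f = 1.0 / (1.0 + np.exp((conc - config.decline_midpoint) / config.decline_width))
    return f / (1.0 / (1.0 + np.exp(-config.decline_midpoint / config.decline_width)))


def gen_dose_response(
    config: SimConfig,
    n_resistant: int | None = None,
    n_escapees: int | None = None,
    condition: str = "copper",
    timepoint: float = 72.0,
    shift_range: tuple[float, float] = (0.05, 0.55),
) -> tuple[pd.DataFrame, GroundTruth]:
    """Colony tables across the stressor dilution with planted resistance.

    Resistant mutants get the ancestor's decline curve shifted right by a
    true shift drawn uniformly from ``shift_range`` (relative size is 1 up
    to the shift, then declines); escapees reproduce the ancestor curve
    exactly apart from noise; ancestor replicates are included.
    """
    if n_resistant is None:
        n_resistant = config.n_mutants - config.n_escapees
    if n_escapees is None:
        n_escapees = config.n_escapees
    rng = _rng(config.seed, "dose_response")
    conc = np.asarray(config.concentrations)
    shifts = rng.uniform(*shift_range, size=n_resistant)

    truth = GroundTruth()
    rows = []

    def emit(strain: str, role: str, shift: float) -> None:
        eff_conc = np.maximum(conc - shift, 0.0)
        rel = ancestor_decline(config, eff_conc)
        noise = _lognormal_noise(rng, config.noise_cv, len(conc))
        sizes = config.base_size_px * rel * noise
        for c, s in zip(conc, sizes):
            rows.append(
                {
                    "plate_id": "DR1",
                    "row": 0,
                    "col": 0,
                    "strain": strain,
                    "role": role,
                    "condition": condition,
                    "conc_mM": float(c),
                    "timepoint_h": timepoint,
                    "size_px": float(max(s, 0.0)),
                }
            )

    for i in range(n_resistant):
        name = f"mut{i:04d}"
        truth.true_shift[name] = float(shifts[i])
        truth.escapee[name] = False
        emit(name, "mutant", float(shifts[i]))
    for i in range(n_escapees):
        name = f"esc{i:04d}"
        truth.true_shift[name] = 0.0
        truth.escapee[name] = True
        emit(name, "mutant", 0.0)
    for i in range(config.n_ancestor_replicates):
        emit(f"anc_rep{i}", "ancestor", 0.0)
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Genotype tables with planted filter violations


def _panel(config: SimConfig, n_derivatives: int = 10) -> tuple[dict[str, str], dict[str, str]]:
    lineage_of = {}
    ancestor_of = {}
    for lin in ("L1", "L2"):
        anc = f"{lin}_anc"
        lineage_of[anc] = lin
        ancestor_of[lin] = anc
        for i in range(n_derivatives):
            lineage_of[f"{lin}_d{i:02d}"] = lin
    return lineage_of, ancestor_of


def gen_genotype_table(
    config: SimConfig,
    planted_violations: Mapping[int, int] | None = None,
    n_clean: int = 4,
    n_derivatives: int = 10,
) -> tuple[GenotypeTable, GroundTruth]:
    """Genotype matrix with planted filter-violating sites plus clean sites.

    For each of the six hard filters, ``planted_violations[k]`` sites are
    constructed to violate exactly filter k (passing every earlier filter);
    clean sites carry a single derived homozygous call.  The expected
    verdict of every site is recorded in the ground truth, keyed
    "chrom:pos".  Strain panel: two lineages, each one ancestor plus
    ``n_derivatives`` derivatives.
    """
    planted_violations = dict(planted_violations or {})
    rng = _rng(config.seed, "genotype")
    lineage_of, ancestor_of = _panel(config, n_derivatives)
    strains = list(lineage_of)
    derivs1 = [s for s in strains if s.startswith("L1_d")]
    derivs2 = [s for s in strains if s.startswith("L2_d")]
    truth = GroundTruth()
    sites: list[SiteRecord] = []
    pos = iter(range(1000, 10_000_000, 997))

    def base_calls() -> tuple[dict[str, str], dict[str, int]]:
        calls = {s: "0/0" for s in strains}
        gq = {s: 60 for s in strains}
        return calls, gq

    def add(calls, gq, verdict, *, ref="A", alts=("T",), vclass="SNP", effect="nonsynonymous", gene=None):
        p = next(pos)
        site = SiteRecord(
            chrom="chrI", pos=p, ref=ref, alts=tuple(alts), variant_class=vclass,
            calls=calls, gq=gq, effect=effect, gene=gene,
        )
        sites.append(site)
        truth.site_verdicts[f"chrI:{p}"] = verdict

    gene_pool = [g for g, _ in config.genes] or ["GENE1", "GENE2", "GENE3"]

    for _ in range(n_clean):
        calls, gq = base_calls()
        carrier = rng.choice(derivs1 + derivs2)
        calls[carrier] = "1/1"
        add(calls, gq, "retained", gene=str(rng.choice(gene_pool)))

    for _ in range(planted_violations.get(1, 0)):
        calls, gq = base_calls()
        calls[derivs1[0]] = "1/1"
        calls[derivs1[1]] = "2/2"
        calls[derivs1[2]] = "0/1"
        add(calls, gq, "removed_by_filter_1", alts=("T", "G"))
    for _ in range(planted_violations.get(2, 0)):
        calls, gq = base_calls()
        calls[derivs1[0]] = "0/1"  # het only; no second homozygous genotype
        add(calls, gq, "removed_by_filter_2")
    for _ in range(planted_violations.get(3, 0)):
        calls, gq = base_calls()
        calls["L1_anc"] = "0/1"
        calls[derivs1[0]] = "1/1"
        add(calls, gq, "removed_by_filter_3")
    for _ in range(planted_violations.get(4, 0)):
        calls, gq = base_calls()
        calls["L1_anc"] = "1/1"  # disagrees with every other call
        add(calls, gq, "removed_by_filter_4")
    for _ in range(planted_violations.get(5, 0)):
        calls, gq = base_calls()
        n_missing = max(1, int(np.ceil(0.2 * len(derivs1))))
        for s in derivs1[:n_missing]:
            calls[s] = MISSING
        calls[derivs2[0]] = "1/1"
        add(calls, gq, "removed_for_lineages:L1")
    for i in range(planted_violations.get(6, 0)):
        calls, gq = base_calls()
        if i % 2 == 0:
            calls[derivs1[0]] = "1/1"
            gq[derivs1[1]] = 5  # low genotype quality
            add(calls, gq, "removed_by_filter_6")
        else:
            # two distinct indel alleles, each carried by two strains
            calls[derivs1[0]] = "1/1"
            calls[derivs1[1]] = "1/1"
            calls[derivs2[0]] = "2/2"
            calls[derivs2[1]] = "2/2"
            add(calls, gq, "removed_by_filter_6", ref="A", alts=("AT", "ATT"),
                vclass="indel", effect="frameshift")

    table = GenotypeTable(sites=sites, lineage_of=lineage_of, ancestor_of=ancestor_of)
    return table, truth


# ---------------------------------------------------------------------------
# Coverage tracks


def gen_coverage(
    config: SimConfig,
    karyotype: Mapping[str, int] | None = None,
    cnv_interval: tuple[str, int, int] | None = None,
    cnv_copies: int = 1,
    poisson_noise: bool = True,
    window: int = 1000,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Windowed depth track with a planted karyotype and locus amplification.

    Window depth is Poisson with mean depth_mean x the chromosome's planted
    copy number, further multiplied by ``cnv_copies`` inside the planted
    interval (a step-shaped amplification).  ``poisson_noise=False`` emits
    the exact means.
    """
    karyotype = dict(karyotype or {})
    rng = _rng(config.seed, "coverage")
    rows = []
    for chrom, length in config.genome:
        copies = karyotype.get(chrom, 1)
        starts = np.arange(0, length, window)
        ends = np.minimum(starts + window, length)
        lam = np.full(len(starts), config.depth_mean * copies, dtype=float)
        if cnv_interval is not None and cnv_interval[0] == chrom:
            _, istart, iend = cnv_interval
            inside = (starts < iend) & (ends > istart)
            lam[inside] *= cnv_copies
        depth = rng.poisson(lam).astype(float) if poisson_noise else lam
        for s, e, d in zip(starts, ends, depth):
            rows.append({"chrom": chrom, "start": int(s), "end": int(e), "depth": float(d)})
    full = {chrom: karyotype.get(chrom, 1) for chrom, _ in config.genome}
    truth = GroundTruth(
        karyotype=full,
        diploidized=False,
        cnv_interval=cnv_interval,
        cnv_copies=cnv_copies if cnv_interval is not None else None,
    )
    return pd.DataFrame(rows), truth


def gen_diploidized_coverage(
    config: SimConfig,
    trisomic: Sequence[str] = ("chr3", "chr8"),
    poisson_noise: bool = True,
    window: int = 1000,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Coverage for a diploidized strain: baseline 2 copies, listed
    chromosomes at 3 — ratios of 1.5 that only fit integers under base 2."""
    karyotype = {chrom: (3 if chrom in set(trisomic) else 2) for chrom, _ in config.genome}
    track, truth = gen_coverage(config, karyotype, poisson_noise=poisson_noise, window=window)
    truth.diploidized = len(set(trisomic)) > 1
    return track, truth


# ---------------------------------------------------------------------------
# Mutation hits and aneuploidy datasets


def gen_mutation_hits(
    config: SimConfig,
    n_mutations: int,
    enriched: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-gene hit counts with planted enrichment.

    Hits are multinomial over genes with probability proportional to CDS
    length x the gene's enrichment multiplier (1 = null).  Total hits equal
    ``n_mutations`` exactly.
    """
    if not config.genes:
        raise ValueError("config.genes is empty")
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    enriched = dict(enriched or {})
    rng = _rng(config.seed, "hits")
    genes = [g for g, _ in config.genes]
    weights = np.array(
        [l * enriched.get(g, 1.0) for g, l in config.genes], dtype=float
    )
    truth = GroundTruth(gene_multipliers={g: enriched.get(g, 1.0) for g in genes})
    if n_mutations == 0:
        return pd.DataFrame(columns=["gene", "count"]), truth
    counts = rng.multinomial(n_mutations, weights / weights.sum())
    df = pd.DataFrame({"gene": genes, "count": counts})
    return df[df["count"] > 0].reset_index(drop=True), truth


def gen_aneuploidy_dataset(
    config: SimConfig,
    strain_counts: Sequence[int],
    bias: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Aneuploid strains with per-strain distinct chromosome draws.

    Strain i carries ``strain_counts[i]`` distinct aneuploid chromosomes
    sampled by weight; a chromosome with infinite weight is carried by every
    strain (the remaining slots are drawn from the finite-weight rest).
    """
    rng = _rng(config.seed, "aneuploidy")
    chroms = [c for c, _ in config.genome]
    bias = dict(bias or {})
    w = np.array([bias.get(c, 1.0) for c in chroms], dtype=float)
    forced = [c for c, x in zip(chroms, w) if np.isinf(x)]
    finite_idx = [i for i, x in enumerate(w) if not np.isinf(x)]
    truth = GroundTruth()
    rows = []
    for i, a in enumerate(strain_counts):
        if a > len(chroms):
            raise ValueError(f"strain {i}: {a} > {len(chroms)} chromosomes")
        if a < len(forced):
            raise ValueError(f"strain {i}: count {a} below {len(forced)} forced chromosomes")
        chosen = list(forced)
        n_rest = a - len(forced)
        if n_rest > 0:
            probs = w[finite_idx] / w[finite_idx].sum()
            picks = rng.choice(finite_idx, size=n_rest, replace=False, p=probs)
            chosen += [chroms[j] for j in picks]
        name = f"aneu{i:03d}"
        truth.aneuploid_sets[name] = sorted(chosen)
        rows.append({"strain": name, "chrom_list": ",".join(sorted(chosen))})
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Writers (plain-text formats only)


def write_colony_table(df: pd.DataFrame, path: str) -> None:
    cols = ["plate_id", "row", "col", "strain", "role", "condition", "conc_mM", "timepoint_h", "size_px"]
    df[[c for c in cols if c in df.columns]].to_csv(path, sep="\t", index=False)


def write_bedgraph(windows: pd.DataFrame, path: str) -> None:
    windows[["chrom", "start", "end", "depth"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def write_gff3(genes: Sequence[tuple[str, int]], path: str, chrom: str = "chrI") -> None:
    """Gene models as GFF3, one single-exon CDS per gene, laid end to end."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        cursor = 1
        for gid, length in genes:
            start, end = cursor, cursor + length - 1
            fh.write(
                f"{chrom}\tsim\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}\n"
                f"{chrom}\tsim\tCDS\t{start}\t{end}\t.\t+\t0\tID={gid}_CDS;Parent={gid}\n"
            )
            cursor = end + 1000


def write_ground_truth(truth: GroundTruth, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(truth.to_json())


def write_lineage_map(table: GenotypeTable, path: str) -> None:
    rows = [
        {
            "strain": s,
            "lineage": lin,
            "is_ancestor": table.ancestor_of[lin] == s,
        }
        for s, lin in table.lineage_of.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
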