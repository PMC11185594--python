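"""Monte-Carlo significance tests for the mutant screen.

Gene-level test ("rain-down" null): the observed number of protein-altering
mutations is dropped uniformly per base pair of coding sequence — each
mutation hits gene g with probability L_g / L_tot — and the per-gene hit
counts are tallied.  Repeating this many times gives a null distribution of
hits per gene accounting for gene length; a gene's empirical p-value is the
fraction of iterations with at least as many hits as observed, Bonferroni
corrected by the number of genes.

Aneuploidy test (strain-structured null): the observed number of aneuploid
strains, each carrying its observed number of distinct aneuploid
chromosomes, has those chromosomes re-drawn uniformly from the 16 yeast
chromosomes each iteration; per-chromosome incidence across strains is
compared to the observed incidence.  A co-occurrence variant asks whether
two specific aneuploidies (e.g., chromosomes III and VIII) ride in the same
strains more often than their marginal frequencies predict.

Each Monte-Carlo test has an exact counterpart used as a cross-check:
binomial tail for the gene null, Poisson-binomial tail (dynamic-programming
convolution over strains) for aneuploidy incidence, hypergeometric tail for
co-occurrence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

N_CHROMOSOMES = 16
DEFAULT_ITERATIONS = 1_000_000

#: Iteration batch size; exceedance counters keep memory flat in iterations.
_BATCH = 10_000


@dataclass(frozen=True)
class GeneModel:
    """CDS lengths for one species' genes (the rain-down weights)."""

    genes: tuple[str, ...]
    lengths: tuple[float, ...]
    species: str | None = None

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.lengths):
            raise ValueError("genes and lengths differ in length")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("all CDS lengths must be > 0")

    @property
    def total_length(self) -> float:
        return float(sum(self.lengths))

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def probabilities(self) -> np.ndarray:
        arr = np.asarray(self.lengths, dtype=float)
        return arr / arr.sum()


@dataclass(frozen=True)
class EnrichmentResult:
    target: str  # gene or chromosome id
    observed: int
    p_empirical: float
    p_bonferroni: float
    iterations: int
    below_resolution: bool  # no iteration reached the observed count


@dataclass(frozen=True)
class AneuploidyDataset:
    """Aneuploid chromosome sets per strain (only aneuploid strains listed)."""

    strains: tuple[str, ...]
    chrom_sets: tuple[frozenset[str], ...]
    chromosomes: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, N_CHROMOSOMES + 1))

    def __post_init__(self) -> None:
        if len(self.strains) != len(self.chrom_sets):
            raise ValueError("strains and chromosome sets differ in length")
        valid = set(self.chromosomes)
        for s, cs in zip(self.strains, self.chrom_sets):
            if not cs <= valid:
                raise ValueError(f"strain {s}: unknown chromosomes {sorted(cs - valid)}")

    @property
    def aneuploid_counts(self) -> tuple[int, ...]:
        return tuple(len(cs) for cs in self.chrom_sets)

    def incidence(self, chrom: str) -> int:
        return sum(chrom in cs for cs in self.chrom_sets)


def _result(target: str, observed: int, exceed: int, iters: int, n_tests: int,
            conservative: bool = False) -> EnrichmentResult:
    if conservative:
        p = (exceed + 1) / (iters + 1)
    else:
        p = exceed / iters
    return EnrichmentResult(
        target=target,
        observed=int(observed),
        p_empirical=p,
        p_bonferroni=min(1.0, p * n_tests) if p > 0 else min(1.0, n_tests / iters),
        iterations=iters,
        below_resolution=exceed == 0,
    )


# ---------------------------------------------------------------------------
# Gene-level rain-down null


def simulate_gene_null(
    model: GeneModel,
    observed: Mapping[str, int],
    n_mutations: int | None = None,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int | np.random.Generator = 0,
) -> dict[str, int]:
    """Exceedance counts from the length-weighted multinomial null.

    Each iteration drops ``n_mutations`` hits onto the coding genome with
    per-gene probability L_g/L_tot and, for every gene with an observed
    count, tallies whether the simulated count reached it.  Only these
    exceedance counters are kept, so memory does not grow with iterations.
    ``n_mutations`` defaults to the total observed hits (coding-only).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_mutations is None:
        n_mutations = int(sum(observed.values()))
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    probs = model.probabilities
    gene_index = {g: i for i, g in enumerate(model.genes)}
    targets = [(g, gene_index[g], k) for g, k in observed.items() if g in gene_index]
    exceed = {g: 0 for g, _, _ in targets}
    done = 0
    while done < iterations:
        b = min(_BATCH, iterations - done)
        counts = rng.multinomial(n_mutations, probs, size=b)
        for g, idx, k in targets:
            exceed[g] += int(np.count_nonzero(counts[:, idx] >= k))
        done += b
    return exceed


def gene_empirical_p(
    exceedances: Mapping[str, int],
    observed: Mapping[str, int],
    iterations: int,
    n_genes: int,
    conservative: bool = False,
) -> list[EnrichmentResult]:
    """Empirical p per gene: exceedances/iterations, Bonferroni x n_genes.

    ``conservative=True`` switches to the (k+1)/(n+1) estimator.  A gene no
    iteration reached is flagged below resolution; its corrected value is
    the resolution bound n_genes/iterations.
    """
    return [
        _result(g, observed[g], exceedances[g], iterations, n_genes, conservative)
        for g in exceedances
    ]


def gene_enrichment(
    model: GeneModel,
    observed: Mapping[str, int],
    iterations: int = DEFAULT_ITERATIONS,
    seed: int | np.random.Generator = 0,
    n_mutations: int | None = None,
    conservative: bool = False,
) -> list[EnrichmentResult]:
    """Convenience wrapper: simulate the null and score every observed gene."""
    exceed = simulate_gene_null(model, observed, n_mutations, iterations, seed)
    return gene_empirical_p(exceed, observed, iterations, model.n_genes, conservative)


def binomial_oracle(length: float, total_length: float, n_mutations: int, k_obs: int) -> float:
    """Exact tail P(X >= k_obs), X ~ Binomial(n_mutations, length/total_length)."""
    if k_obs <= 0:
        return 1.0
    return float(stats.binom.sf(k_obs - 1, n_mutations, length / total_length))


def pooled_species_test(
    models: Sequence[GeneModel],
    observed: Sequence[Mapping[str, int]],
    gene: str,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int | np.random.Generator = 0,
) -> EnrichmentResult:
    """Cross-species pooled test for one gene (orthologs share an id).

    Gene lists, lengths and hits are concatenated across species; the shared
    gene's hits sum; the null rains the pooled mutation total onto the
    pooled coding genome, and Bonferroni runs over the pooled gene count.
    """
    genes, lengths = [], []
    for i, m in enumerate(models):
        genes.extend(f"{m.species or i}::{g}" if g != gene else gene for g in m.genes)
        lengths.extend(m.lengths)
    # the shared gene appears once per species; merge into one entry
    merged: dict[str, float] = {}
    for g, l in zip(genes, lengths):
        merged[g] = merged.get(g, 0.0) + l
    pooled = GeneModel(genes=tuple(merged), lengths=tuple(merged.values()))
    k_obs = sum(obs.get(gene, 0) for obs in observed)
    n_mut = sum(sum(obs.values()) for obs in observed)
    exceed = simulate_gene_null(pooled, {gene: k_obs}, n_mut, iterations, seed)
    return gene_empirical_p(exceed, {gene: k_obs}, iterations, pooled.n_genes)[0]


# ---------------------------------------------------------------------------
# Aneuploidy null


def simulate_aneuploidy_null(
    dataset: AneuploidyDataset,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int | np.random.Generator = 0,
    n_tests: int | None = None,
) -> list[EnrichmentResult]:
    """Per-chromosome aneuploidy enrichment against the strain-structured null.

    Each iteration re-draws, for every aneuploid strain, the same number of
    distinct aneuploid chromosomes uniformly at random; the per-chromosome
    strain incidence is compared to the observed incidence.  Bonferroni runs
    over the chromosome count by default.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = dataset.chromosomes
    n_chrom = len(chroms)
    a = dataset.aneuploid_counts
    if any(ai > n_chrom for ai in a):
        raise ValueError("a strain cannot carry more aneuploid chromosomes than exist")
    observed = np.array([dataset.incidence(c) for c in chroms])
    if n_tests is None:
        n_tests = n_chrom
    n_strains = len(a)
    exceed = np.zeros(n_chrom, dtype=np.int64)
    done = 0
    while done < iterations:
        b = min(_BATCH, iterations - done)
        # vectorised distinct-subset draws: rank of iid uniforms gives a
        # uniform random permutation per (iteration, strain); the first a_i
        # positions form a uniform a_i-subset
        u = rng.random((b, n_strains, n_chrom))
        order = np.argsort(u, axis=2)
        ranks = np.argsort(order, axis=2)
        carried = ranks < np.asarray(a)[None, :, None]
        incidence = carried.sum(axis=1)  # (b, n_chrom)
        exceed += (incidence >= observed[None, :]).sum(axis=0)
        done += b
    return [
        _result(c, int(observed[i]), int(exceed[i]), iterations, n_tests)
        for i, c in enumerate(chroms)
    ]


def poisson_binomial_oracle(
    aneuploid_counts: Sequence[int], k_obs: int, n_chromosomes: int = N_CHROMOSOMES
) -> float:
    """Exact tail P(K >= k_obs) for per-chromosome incidence.

    Under the null a fixed chromosome is aneuploid in strain i with
    probability a_i / n_chromosomes independently, so incidence K is a
    Poisson-binomial sum; its pmf is built by dynamic-programming
    convolution over strains.
    """
    if k_obs <= 0:
        return 1.0
    probs = [a / n_chromosomes for a in aneuploid_counts]
    pmf = np.zeros(len(probs) + 1)
    pmf[0] = 1.0
    for p in probs:
        pmf[1:] = pmf[1:] * (1 - p) + pmf[:-1] * p
        pmf[0] *= 1 - p
    if k_obs > len(probs):
        return 0.0
    return float(pmf[k_obs:].sum())


def cooccurrence_test(
    n_strains: int,
    n_a: int,
    n_b: int,
    observed_both: int,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Do two aneuploidies co-occur in the same strains more than chance?

    Each iteration assigns aneuploidy A to a uniform n_a-subset of strains
    and, independently, B to a uniform n_b-subset; the empirical p is the
    fraction of iterations with overlap >= observed_both.  Returns
    (empirical p, exact hypergeometric tail).
    """
    if not (0 <= n_a <= n_strains and 0 <= n_b <= n_strains):
        raise ValueError("marginal counts must lie in [0, n_strains]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = 0
    done = 0
    while done < iterations:
        b = min(_BATCH, iterations - done)
        # argsort of iid uniforms per row is a uniform permutation; taking
        # ranks < n gives a uniform n-subset
        ranks_a = np.argsort(np.argsort(rng.random((b, n_strains)), axis=1), axis=1)
        ranks_b = np.argsort(np.argsort(rng.random((b, n_strains)), axis=1), axis=1)
        overlap = ((ranks_a < n_a) & (ranks_b < n_b)).sum(axis=1)
        exceed += int(np.count_nonzero(overlap >= observed_both))
        done += b
    p_emp = exceed / iterations
    oracle = (
        1.0
        if observed_both <= 0
        else float(stats.hypergeom.sf(observed_both - 1, n_strains, n_a, n_b))
    )
    return p_emp, oracle


# ---------------------------------------------------------------------------
# I/O


def read_gene_model(path: str, species: str | None = None) -> GeneModel:
    """Gene model from a two-column TSV (gene, cds_length) or a GFF3.

    GFF3 input sums CDS feature lengths per gene (the ``Parent``/``ID``
    attribute, stripped of transcript suffixes).
    """
    if path.endswith((".gff", ".gff3")):
        lengths: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "CDS":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                gene = attrs.get("Parent") or attrs.get("ID") or "?"
                gene = gene.split(",")[0].removeprefix("gene:").split("_mRNA")[0]
                lengths[gene] = lengths.get(gene, 0.0) + (int(f[4]) - int(f[3]) + 1)
        return GeneModel(genes=tuple(lengths), lengths=tuple(lengths.values()), species=species)
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("gene model TSV needs columns gene, cds_length")
    return GeneModel(
        genes=tuple(df.iloc[:, 0].astype(str)),
        lengths=tuple(df.iloc[:, 1].astype(float)),
        species=species,
    )


def read_hits(path: str) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["gene"].astype(str), df["count"].astype(int)))


def read_aneuploidy_dataset(path: str) -> AneuploidyDataset:
    """Aneuploidy TSV: strain, comma-separated chrom_list."""
    df = pd.read_csv(path, sep="\t")
    strains = tuple(df["strain"].astype(str))
    sets = tuple(
        frozenset(x.strip() for x in str(v).split(",") if x.strip())
        for v in df["chrom_list"]
    )
    chroms = sorted(set().union(*sets)) if sets else []
    default = tuple(f"chr{i}" for i in range(1, N_CHROMOSOMES + 1))
    use_default = all(c in default for c in chroms)
    return AneuploidyDataset(
        strains=strains,
        chrom_sets=sets,
        chromosomes=default if use_default else tuple(chroms),
    )


def write_enrichment(results: Sequence[EnrichmentResult], path: str) -> None:
    pd.DataFrame([r.__dict__ for r in results]).to_csv(path, sep="\t", index=False)
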