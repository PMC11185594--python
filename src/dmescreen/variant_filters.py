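"""Hard filtering of multi-strain genotype matrices from a mutant screen.

The screen sequences panels of haploid mutants alongside the ancestor each
lineage was derived from.  Raw caller output contains many artifact sites;
six sequential hard filters remove them:

1. sites with four or more unique genotype calls across all strains
   (low-confidence multi-allelic noise);
2. sites lacking two different homozygous calls (all strains are haploid,
   so a real mutation must show two distinct homozygous genotypes);
3. sites where an ancestral strain is called heterozygous;
4. sites where an ancestral call disagrees with every other call;
5. per lineage, sites where more than 10% of an ancestor's derivatives
   lack a call — removed for that lineage only;
6. sites with more than one indel allele each called in multiple strains,
   or with any genotype quality below 10.

Structural-variant calls get an analogous treatment: low-quality and
imprecise calls are dropped, only singletons are kept, and heterozygous
singletons are kept only for duplications (a real duplication in a haploid
maps as a het).

Genotype calls are stored as allele-index strings ("0/0", "1/1", "0/1",
"2/2", ...; "./." for missing); haploid calls are encoded homozygous.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

MISSING = "./."

#: Functional-effect classes counted as disruptive (protein-altering).
DISRUPTIVE_EFFECTS = frozenset(
    {"nonsynonymous", "frameshift", "nonsense", "inframe_indel", "stop_lost"}
)

FILTER_NAMES = {
    1: "four_or_more_unique_calls",
    2: "no_two_homozygous_calls",
    3: "ancestor_heterozygous",
    4: "ancestor_disagrees_with_all",
    5: "lineage_missingness",
    6: "multi_indel_or_low_gq",
}


def is_missing(call: str) -> bool:
    return call == MISSING or "." in call


def is_het(call: str) -> bool:
    if is_missing(call):
        return False
    a, b = call.split("/")
    return a != b


def is_hom(call: str) -> bool:
    return not is_missing(call) and not is_het(call)


def call_alleles(call: str) -> set[int]:
    if is_missing(call):
        return set()
    return {int(a) for a in call.split("/")}


@dataclass
class SiteRecord:
    """One variant site: position, alleles and the per-strain genotype calls."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    variant_class: Literal["SNP", "indel"]
    calls: dict[str, str]  # strain -> "a/b" genotype string
    gq: dict[str, int]
    effect: str = "noncoding"
    gene: str | None = None

    def key(self) -> tuple:
        return (self.chrom, self.pos, self.alts)


@dataclass
class GenotypeTable:
    """Sites x strains call matrix with per-lineage ancestor designation."""

    sites: list[SiteRecord]
    lineage_of: dict[str, str]  # strain -> lineage
    ancestor_of: dict[str, str]  # lineage -> ancestor strain id

    def __post_init__(self) -> None:
        for lin, anc in self.ancestor_of.items():
            if self.lineage_of.get(anc) != lin:
                raise ValueError(f"ancestor {anc!r} not a member of lineage {lin!r}")
        seen = Counter(s.key() for s in self.sites)
        dup = [k for k, n in seen.items() if n > 1]
        if dup:
            raise ValueError(f"duplicate sites: {dup[:3]}")

    @property
    def strains(self) -> list[str]:
        return list(self.lineage_of)

    @property
    def lineages(self) -> list[str]:
        return list(self.ancestor_of)

    def derivatives(self, lineage: str) -> list[str]:
        anc = self.ancestor_of[lineage]
        return [s for s, l in self.lineage_of.items() if l == lineage and s != anc]


@dataclass
class FilterReport:
    """Per-site verdicts and per-filter removal tallies.

    ``verdicts`` maps a site key to either "retained", "removed_by_filter_k",
    or "removed_for_lineages:<comma list>" when only some lineages lost the
    site (filter 5).  Counts attribute each removal to the first filter that
    triggered, filters running in their listed order on the survivors of the
    previous one.
    """

    verdicts: dict[tuple, str]
    removed_by_filter: dict[int, int]
    lineage_removals: dict[tuple, set[str]]
    retained_per_lineage: dict[str, int]
    n_input: int
    n_retained: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_retained": self.n_retained,
                "removed_by_filter": {
                    FILTER_NAMES[k]: v for k, v in self.removed_by_filter.items()
                },
                "retained_per_lineage": self.retained_per_lineage,
                "verdicts": {
                    f"{k[0]}:{k[1]}": v for k, v in self.verdicts.items()
                },
            },
            indent=2,
        )


def _unique_called_genotypes(site: SiteRecord) -> set[str]:
    return {c for c in site.calls.values() if not is_missing(c)}


def _violates_filter1(site: SiteRecord, max_unique_calls: int) -> bool:
    return len(_unique_called_genotypes(site)) > max_unique_calls


def _violates_filter2(site: SiteRecord) -> bool:
    homs = {c for c in site.calls.values() if is_hom(c)}
    return len(homs) < 2


def _violates_filter3(site: SiteRecord, table: GenotypeTable) -> bool:
    return any(is_het(site.calls.get(anc, MISSING)) for anc in table.ancestor_of.values())


def _violates_filter4(site: SiteRecord, table: GenotypeTable) -> bool:
    # evaluated on called genotypes only
    ancestors = set(table.ancestor_of.values())
    for anc in ancestors:
        anc_call = site.calls.get(anc, MISSING)
        if is_missing(anc_call):
            continue
        others = [
            c
            for s, c in site.calls.items()
            if s != anc and not is_missing(c)
        ]
        if others and all(c != anc_call for c in others):
            return True
    return False


def _filter5_lineages(site: SiteRecord, table: GenotypeTable, max_missing_frac: float) -> set[str]:
    bad = set()
    for lin in table.lineages:
        derivs = table.derivatives(lin)
        if not derivs:
            continue
        n_missing = sum(is_missing(site.calls.get(s, MISSING)) for s in derivs)
        if n_missing / len(derivs) > max_missing_frac:
            bad.add(lin)
    return bad


def _violates_filter6(
    site: SiteRecord, gq_min: int, per_strain_gq: bool = False
) -> bool:
    if site.variant_class == "indel" and len(site.alts) > 1:
        # >1 distinct indel allele each carried by >= 2 strains
        multi = 0
        for idx, alt in enumerate(site.alts, start=1):
            if len(alt) == len(site.ref):
                continue
            carriers = sum(idx in call_alleles(c) for c in site.calls.values())
            if carriers >= 2:
                multi += 1
        if multi > 1:
            return True
    if not per_strain_gq:
        return any(q < gq_min for q in site.gq.values())
    return False


def apply_filters(
    table: GenotypeTable,
    gq_min: int = 10,
    max_unique_calls: int = 3,
    max_missing_frac: float = 0.10,
    per_strain_gq: bool = False,
) -> tuple[FilterReport, GenotypeTable]:
    """Run the six hard filters in order and return the report + survivors.

    With ``per_strain_gq`` the low-GQ clause of filter 6 masks individual
    calls instead of removing the site (off by default — the site-level
    reading).  A site removed only for some lineages (filter 5) stays in the
    filtered table with its lineage exclusions noted in the report.
    """
    verdicts: dict[tuple, str] = {}
    removed = {k: 0 for k in FILTER_NAMES}
    lineage_removals: dict[tuple, set[str]] = {}
    survivors: list[SiteRecord] = []

    for site in table.sites:
        key = site.key()
        if _violates_filter1(site, max_unique_calls):
            verdicts[key] = "removed_by_filter_1"
            removed[1] += 1
            continue
        if _violates_filter2(site):
            verdicts[key] = "removed_by_filter_2"
            removed[2] += 1
            continue
        if _violates_filter3(site, table):
            verdicts[key] = "removed_by_filter_3"
            removed[3] += 1
            continue
        if _violates_filter4(site, table):
            verdicts[key] = "removed_by_filter_4"
            removed[4] += 1
            continue
        bad_lineages = _filter5_lineages(site, table, max_missing_frac)
        if bad_lineages == set(table.lineages) and bad_lineages:
            verdicts[key] = "removed_by_filter_5"
            removed[5] += 1
            continue
        if _violates_filter6(site, gq_min, per_strain_gq):
            verdicts[key] = "removed_by_filter_6"
            removed[6] += 1
            continue
        if bad_lineages:
            verdicts[key] = "removed_for_lineages:" + ",".join(sorted(bad_lineages))
            lineage_removals[key] = bad_lineages
            removed[5] += 1  # counted as a (partial) filter-5 event
        else:
            verdicts[key] = "retained"
        survivors.append(site)

    retained_per_lineage = {
        lin: sum(
            1
            for s in survivors
            if lin not in lineage_removals.get(s.key(), set())
        )
        for lin in table.lineages
    }
    report = FilterReport(
        verdicts=verdicts,
        removed_by_filter=removed,
        lineage_removals=lineage_removals,
        retained_per_lineage=retained_per_lineage,
        n_input=len(table.sites),
        n_retained=sum(1 for v in verdicts.values() if v == "retained"),
    )
    filtered = GenotypeTable(
        sites=survivors,
        lineage_of=dict(table.lineage_of),
        ancestor_of=dict(table.ancestor_of),
    )
    return report, filtered


# ---------------------------------------------------------------------------
# Structural variants


@dataclass(frozen=True)
class SVCall:
    """One structural-variant call across the strain panel."""

    sv_id: str
    sv_type: Literal["DEL", "DUP", "INV", "TRA"]
    genotypes: Mapping[str, str]  # strain -> "hom" | "het" (carriers only)
    lowqual: bool = False
    imprecise: bool = False


def filter_structural_variants(
    calls: Sequence[SVCall], ancestors: Iterable[str] = ()
) -> list[SVCall]:
    """Quality + singleton filter for SV calls.

    Drops low-quality and imprecise calls; keeps only singletons (carried by
    exactly one non-ancestor strain); among singletons drops heterozygous
    calls unless the variant is a duplication, which is expected to map as
    het in a haploid.
    """
    anc = set(ancestors)
    kept = []
    for sv in calls:
        if sv.lowqual or sv.imprecise:
            continue
        carriers = [s for s in sv.genotypes if s not in anc]
        if len(carriers) != 1:
            continue
        gt = sv.genotypes[carriers[0]]
        if gt == "het" and sv.sv_type != "DUP":
            continue
        kept.append(sv)
    return kept


# ---------------------------------------------------------------------------
# Derived-call summaries


def _derived_strains(site: SiteRecord, table: GenotypeTable) -> list[str]:
    """Strains whose called genotype differs from their lineage ancestor's."""
    out = []
    for strain, lin in table.lineage_of.items():
        anc = table.ancestor_of[lin]
        if strain == anc:
            continue
        call = site.calls.get(strain, MISSING)
        anc_call = site.calls.get(anc, MISSING)
        if is_missing(call) or is_missing(anc_call):
            continue
        if call != anc_call:
            out.append(strain)
    return out


def count_disruptive_hits(
    table: GenotypeTable,
    disruptive: frozenset[str] = DISRUPTIVE_EFFECTS,
) -> pd.DataFrame:
    """Per-gene counts of derived disruptive calls (the enrichment input)."""
    counts: Counter[str] = Counter()
    for site in table.sites:
        if site.gene is None or site.effect not in disruptive:
            continue
        counts[site.gene] += len(_derived_strains(site, table))
    return pd.DataFrame(
        sorted(counts.items()), columns=["gene", "count"]
    )


def mean_mutations_per_strain(table: GenotypeTable) -> float:
    """Mean number of derived calls per mutant (non-ancestor) strain."""
    n_mutants = sum(
        1
        for s, lin in table.lineage_of.items()
        if s != table.ancestor_of[lin]
    )
    if n_mutants == 0:
        return 0.0
    total = sum(len(_derived_strains(site, table)) for site in table.sites)
    return total / n_mutants


# ---------------------------------------------------------------------------
# VCF I/O (pysam)


def read_lineage_map(path: str) -> tuple[dict[str, str], dict[str, str]]:
    """Read a strain/lineage/is_ancestor TSV into the two lookup dicts."""
    df = pd.read_csv(path, sep="\t")
    lineage_of = dict(zip(df["strain"].astype(str), df["lineage"].astype(str)))
    anc_rows = df[df["is_ancestor"].astype(bool)]
    ancestor_of = dict(zip(anc_rows["lineage"].astype(str), anc_rows["strain"].astype(str)))
    return lineage_of, ancestor_of


def read_genotype_vcf(
    vcf_path: str,
    lineage_of: Mapping[str, str],
    ancestor_of: Mapping[str, str],
) -> GenotypeTable:
    """Read a VCF 4.2 (GT + GQ, ANN-style effect tag) into a GenotypeTable."""
    import pysam

    sites = []
    with pysam.VariantFile(vcf_path) as vf:
        for rec in vf:
            calls = {}
            gq = {}
            for sample in rec.samples:
                gt = rec.samples[sample]["GT"]
                if gt is None or all(a is None for a in gt):
                    calls[sample] = MISSING
                else:
                    alleles = [0 if a is None else a for a in gt]
                    if len(alleles) == 1:  # haploid encoded homozygous
                        alleles = alleles * 2
                    calls[sample] = "/".join(str(a) for a in sorted(alleles))
                q = rec.samples[sample].get("GQ")
                gq[sample] = int(q) if q is not None else 99
            alts = tuple(rec.alts or ())
            vclass = (
                "indel"
                if any(len(a) != len(rec.ref) for a in alts)
                else "SNP"
            )
            ann = rec.info.get("ANN")
            effect, gene = "noncoding", None
            if ann:
                first = ann[0] if isinstance(ann, tuple) else ann
                parts = str(first).split("|")
                if len(parts) >= 2:
                    effect, gene = parts[0], (parts[1] or None)
                else:
                    effect = parts[0]
            sites.append(
                SiteRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=alts,
                    variant_class=vclass,
                    calls=calls,
                    gq=gq,
                    effect=effect,
                    gene=gene,
                )
            )
    return GenotypeTable(
        sites=sites,
        lineage_of=dict(lineage_of),
        ancestor_of=dict(ancestor_of),
    )


def write_genotype_vcf(table: GenotypeTable, path: str, contigs: Mapping[str, int] | None = None) -> None:
    """Write a GenotypeTable as an uncompressed VCF 4.2."""
    import pysam

    header = pysam.VariantHeader()
    if contigs is None:
        contigs = {}
        for s in table.sites:
            contigs[s.chrom] = max(contigs.get(s.chrom, 0), s.pos + 1000)
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.info.add("ANN", 1, "String", "Functional effect|gene")
    strains = table.strains
    for s in strains:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as out:
        for site in sorted(table.sites, key=lambda s: (s.chrom, s.pos)):
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                stop=site.pos - 1 + len(site.ref),
                alleles=(site.ref, *site.alts),
            )
            rec.info["ANN"] = f"{site.effect}|{site.gene or ''}"
            for s in strains:
                call = site.calls.get(s, MISSING)
                if is_missing(call):
                    rec.samples[s]["GT"] = (None, None)
                else:
                    a, b = (int(x) for x in call.split("/"))
                    rec.samples[s]["GT"] = (a, b)
                rec.samples[s]["GQ"] = site.gq.get(s, 99)
            out.write(rec)
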