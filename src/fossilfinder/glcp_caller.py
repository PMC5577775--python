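"""Calling genes with lost coding potential (GLCPs) from cross-species homology.

A GLCP is a protein-coding gene present in a non-mammalian reference species
(e.g. chicken) whose homologs are absent from essentially all mammals while
still supported by other vertebrates.  The caller scans a HomologyMap for
genes meeting configurable presence/absence criteria, and this module also
provides the family-multiplicity and family-matched-sampling statistics used
to compare GLCPs with other genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

CORE_MAMMALS = ("human", "rhesus", "marmoset", "mouse", "rabbit", "dog", "sheep", "ferret")
CORE_FISH = ("zebrafish", "stickleback", "tilapia", "medaka")
REFERENCE_SPECIES = ("opossum", "chicken", "lizard", "xenopus", "coelacanth", "dog")
PRIMATES_AND_GLIRES = ("human", "rhesus", "marmoset", "mouse", "rabbit")


@dataclass(frozen=True)
class SpeciesRoster:
    core_mammals: tuple[str, ...] = CORE_MAMMALS
    core_fish: tuple[str, ...] = CORE_FISH
    reference_species: tuple[str, ...] = REFERENCE_SPECIES
    outgroups: tuple[str, ...] = ()

    @property
    def non_mammals(self) -> tuple[str, ...]:
        out = [s for s in self.reference_species if s not in self.core_mammals]
        out += [s for s in self.core_fish if s not in out]
        out += [s for s in self.outgroups if s not in out]
        return tuple(out)


@dataclass
class HomologyMap:
    """Gene<->gene orthology plus gene->family assignments across species."""

    species_of: dict[str, str]
    family_of: dict[str, str]
    roster: SpeciesRoster | None = None
    orthologs: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.roster is None:
            self.roster = SpeciesRoster()
        self.families: dict[str, set[str]] = {}
        for g, fam in self.family_of.items():
            self.families.setdefault(fam, set()).add(g)

    def add_orthologs(self, a: str, b: str) -> None:
        self.orthologs.setdefault(a, set()).add(b)
        self.orthologs.setdefault(b, set()).add(a)

    def are_orthologs(self, a: str, b: str) -> bool:
        return b in self.orthologs.get(a, ())

    def orthologs_of(self, gene: str, species: str | None = None) -> set[str]:
        out = self.orthologs.get(gene, set())
        if species is None:
            return set(out)
        return {g for g in out if self.species_of.get(g) == species}

    def species_with_homolog(self, gene: str) -> set[str]:
        return {self.species_of[g] for g in self.orthologs.get(gene, ()) if g in self.species_of}

    def genes_of_species(self, species: str) -> list[str]:
        return sorted(g for g, s in self.species_of.items() if s == species)


@dataclass(frozen=True)
class GlcpCriteria:
    """Presence/absence scheme for GLCP calling.

    mammal_allowance: maximum number of 'lost-in' mammals that may still carry
    a homolog (1 by default; 0 for dog as reference, where the lost-in set is
    primates + glires).  min_vertebrate_support: minimum number of additional
    non-mammalian vertebrates (besides the reference) with a homolog.
    """

    mammal_allowance: int = 1
    lost_in: tuple[str, ...] | None = None
    min_vertebrate_support: int = 2


def default_criteria(reference_species: str, roster: SpeciesRoster) -> GlcpCriteria:
    if reference_species == "dog":
        return GlcpCriteria(mammal_allowance=0, lost_in=PRIMATES_AND_GLIRES)
    return GlcpCriteria(mammal_allowance=1, lost_in=roster.core_mammals)


@dataclass(frozen=True)
class GlcpCall:
    gene_id: str
    reference_species: str
    mammals_with_homolog: int
    vertebrate_support: tuple[str, ...]
    family_id: str
    family_size_in_reference: int


def call_glcps(
    homology: HomologyMap,
    reference_species: str,
    criteria: GlcpCriteria | None = None,
) -> list[GlcpCall]:
    """Scan the homology map for reference-species genes lost in mammals."""
    roster = homology.roster
    known = set(roster.core_mammals) | set(roster.core_fish) | set(roster.reference_species) | set(
        roster.outgroups
    )
    if reference_species not in known:
        raise ValueError(f"reference species {reference_species!r} not in roster")
    if criteria is None:
        criteria = default_criteria(reference_species, roster)
    lost_in = set(criteria.lost_in if criteria.lost_in is not None else roster.core_mammals)
    lost_in.discard(reference_species)
    mammal_set = set(roster.core_mammals)

    calls: list[GlcpCall] = []
    for gene in homology.genes_of_species(reference_species):
        present = homology.species_with_homolog(gene)
        n_lost_in_present = len(present & lost_in)
        if n_lost_in_present > criteria.mammal_allowance:
            continue
        support = {
            s for s in present if s not in mammal_set and s != reference_species
        }
        if len(support) < criteria.min_vertebrate_support:
            continue
        fam = homology.family_of.get(gene, f"singleton:{gene}")
        fam_size = sum(
            1
            for g in homology.families.get(fam, {gene})
            if homology.species_of.get(g) == reference_species
        )
        calls.append(
            GlcpCall(
                gene_id=gene,
                reference_species=reference_species,
                mammals_with_homolog=n_lost_in_present,
                vertebrate_support=tuple(sorted(support)),
                family_id=fam,
                family_size_in_reference=max(fam_size, 1),
            )
        )
    return calls


@dataclass
class FamilyMultiplicityResult:
    table: "np.ndarray"  # 2x2: rows GLCP/other, cols multi-family/singleton
    chi2: float
    p_value: float
    fraction_glcp_multi: float
    fraction_other_multi: float
    warning: str | None = None


def family_multiplicity(
    glcps: list[str], homology: HomologyMap, other_genes: list[str]
) -> FamilyMultiplicityResult:
    """2x2 association between GLCP status and multi-member family membership.

    Pearson chi-squared without continuity correction.
    """
    from scipy.stats import chi2_contingency

    glcp_set, other_set = set(glcps), set(other_genes)
    if not glcp_set or not other_set:
        raise ValueError("both gene sets must be non-empty")
    if glcp_set & other_set:
        raise ValueError("gene sets must be disjoint")

    def n_multi(genes: set[str]) -> int:
        count = 0
        for g in genes:
            fam = homology.family_of.get(g)
            species = homology.species_of.get(g)
            members = {
                m
                for m in homology.families.get(fam, {g})
                if homology.species_of.get(m) == species
            }
            if len(members) > 1:
                count += 1
        return count

    a = n_multi(glcp_set)
    b = len(glcp_set) - a
    c = n_multi(other_set)
    d = len(other_set) - c
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = chi2_contingency(table, correction=False)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    warning = "expected cell < 1" if (expected < 1).any() else None
    return FamilyMultiplicityResult(
        table=table,
        chi2=float(chi2),
        p_value=float(p),
        fraction_glcp_multi=a / len(glcp_set),
        fraction_other_multi=c / len(other_set),
        warning=warning,
    )


def sample_family_matched(
    glcps: list[str], homology: HomologyMap, seed: int | np.random.Generator
) -> list[str]:
    """Sample non-GLCP family members matched in number to the GLCPs per family.

    For each family containing k GLCPs, min(k, available) other members of the
    same family (same species) are drawn without replacement.  Families whose
    only members are GLCPs contribute nothing.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    glcp_set = set(glcps)
    per_family: dict[tuple[str, str], int] = {}
    for g in glcps:
        fam = homology.family_of.get(g)
        sp = homology.species_of.get(g)
        per_family[(fam, sp)] = per_family.get((fam, sp), 0) + 1
    sampled: list[str] = []
    for (fam, sp), k in sorted(per_family.items()):
        pool = sorted(
            m
            for m in homology.families.get(fam, set())
            if m not in glcp_set and homology.species_of.get(m) == sp
        )
        if not pool:
            continue
        take = min(k, len(pool))
        sampled.extend(rng.choice(pool, size=take, replace=False).tolist())
    return sampled


def write_glcp_table(calls: list[GlcpCall], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\treference_species\tmammals_with_homolog\tvertebrate_support\t"
            "family_id\tfamily_size_in_reference\n"
        )
        for c in sorted(calls, key=lambda c: c.gene_id):
            fh.write(
                f"{c.gene_id}\t{c.reference_species}\t{c.mammals_with_homolog}\t"
                f"{','.join(c.vertebrate_support)}\t{c.family_id}\t{c.family_size_in_reference}\n"
            )
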