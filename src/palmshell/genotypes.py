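"""Genotype containers and functional-copy arithmetic.

The SHELL model counts *functional copies*: a haplotype over the variant
panel is functional iff it is wildtype at every site, and a diploid palm
carries 0, 1 or 2 functional copies.  KASP-style assays return unphased
per-site calls, so a palm heterozygous at two or more sites has an unknown
phase: the mutations may sit on the same chromosome (cis, one functional
copy survives) or on different chromosomes (trans, none survives).  This
module computes the exact copy number for phased diplotypes and sharp
[min, max] bounds over all phasings consistent with an unphased genotype.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, Mapping, Tuple

from .panel import NUCLEOTIDES, ShellVariant, VariantPanel

MISSING_ALLELE = "."


class IncompleteGenotypeError(ValueError):
    """Raised when an operation requires calls at every panel site."""


class AlleleClass(str, Enum):
    WILDTYPE = "wildtype"
    KNOWN_MUTANT = "known_mutant"
    NOVEL_MUTANT = "novel_mutant"


def classify_allele(panel: VariantPanel, variant_id: str, allele: str) -> AlleleClass:
    """Classify a nucleotide observed at a panel site.

    Any non-wildtype allele counts as loss-of-function; alleles outside the
    catalogued mutant set are flagged ``novel_mutant`` (all five reported
    SHELL variants are loss-of-function, so this is the conservative
    reading for pisifera detection).

    Raises KeyError for an unknown variant id and ValueError for a
    non-nucleotide allele.
    """
    v = panel.get(variant_id)
    if allele not in NUCLEOTIDES:
        raise ValueError(f"allele {allele!r} at {variant_id} is not one of A/C/G/T")
    if allele == v.wildtype_allele:
        return AlleleClass.WILDTYPE
    if allele in v.known_mutant_alleles:
        return AlleleClass.KNOWN_MUTANT
    return AlleleClass.NOVEL_MUTANT


@dataclass(frozen=True)
class LocusCall:
    """A diploid call at one site.

    ``phased=True`` means the (allele_a, allele_b) order is meaningful:
    allele_a lies on haplotype 1 and allele_b on haplotype 2.  Missing data
    is represented by '.' in both alleles; a half-missing call is invalid.
    """

    variant_id: str
    allele_a: str
    allele_b: str
    phased: bool = False

    def __post_init__(self):
        if (self.allele_a == MISSING_ALLELE) != (self.allele_b == MISSING_ALLELE):
            raise ValueError(
                f"{self.variant_id}: half-missing call "
                f"{self.allele_a}/{self.allele_b} is not allowed"
            )

    @property
    def is_missing(self) -> bool:
        return self.allele_a == MISSING_ALLELE

    @property
    def alleles(self) -> Tuple[str, str]:
        return (self.allele_a, self.allele_b)

    @property
    def is_het(self) -> bool:
        return not self.is_missing and self.allele_a != self.allele_b

    @classmethod
    def missing(cls, variant_id: str) -> "LocusCall":
        return cls(variant_id, MISSING_ALLELE, MISSING_ALLELE)

    @classmethod
    def parse(cls, variant_id: str, text: str) -> "LocusCall":
        """Parse 'A/T' (unphased), 'A|T' (phased) or './.' (missing)."""
        sep = "|" if "|" in text else "/"
        parts = text.split(sep)
        if len(parts) != 2:
            raise ValueError(f"{variant_id}: cannot parse diploid call {text!r}")
        return cls(variant_id, parts[0], parts[1], phased=(sep == "|"))

    def __str__(self) -> str:
        return f"{self.allele_a}{'|' if self.phased else '/'}{self.allele_b}"


@dataclass
class MultiLocusGenotype:
    """Unphased (or partially phased) calls for one sample over a panel."""

    sample_id: str
    calls: Dict[str, LocusCall] = field(default_factory=dict)

    def call_for(self, variant_id: str) -> LocusCall:
        """The call at a site; sites without a call read as missing."""
        return self.calls.get(variant_id, LocusCall.missing(variant_id))

    def is_complete(self, panel: VariantPanel) -> bool:
        return all(not self.call_for(v.id).is_missing for v in panel)

    def require_complete(self, panel: VariantPanel) -> None:
        gaps = [v.id for v in panel if self.call_for(v.id).is_missing]
        if gaps:
            raise IncompleteGenotypeError(
                f"sample {self.sample_id}: missing calls at {gaps}"
            )


@dataclass(frozen=True, order=True)
class Haplotype:
    """One chromosome's alleles, in panel order.  No missing alleles."""

    alleles: Tuple[str, ...]

    def __post_init__(self):
        if MISSING_ALLELE in self.alleles:
            raise ValueError("haplotypes cannot carry missing alleles")

    def __len__(self) -> int:
        return len(self.alleles)

    def is_functional(self, panel: VariantPanel) -> bool:
        """Wildtype at every panel site?"""
        if len(self.alleles) != len(panel):
            raise ValueError(
                f"haplotype length {len(self.alleles)} != panel size {len(panel)}"
            )
        return all(a == v.wildtype_allele for a, v in zip(self.alleles, panel))


def wildtype_haplotype(panel: VariantPanel) -> Haplotype:
    return Haplotype(panel.wildtype_vector())


def mutant_haplotype(panel: VariantPanel, *variant_ids: str) -> Haplotype:
    """Haplotype carrying the first catalogued mutant allele at each named
    site and wildtype elsewhere.  Raises if a named site has no catalogued
    mutant (e.g. sh_MPOB3)."""
    alleles = list(panel.wildtype_vector())
    index = {v.id: i for i, v in enumerate(panel)}
    for vid in variant_ids:
        v = panel.get(vid)
        if not v.known_mutant_alleles:
            raise ValueError(f"{v.id} has no catalogued mutant allele")
        alleles[index[v.id]] = sorted(v.known_mutant_alleles)[0]
    return Haplotype(tuple(alleles))


@dataclass(frozen=True, eq=False)
class Diplotype:
    """A phased pair of haplotypes.

    Semantically an *unordered* pair: swapping the two haplotypes yields an
    equivalent diplotype, and equality/hashing reflect that.
    """

    hap1: Haplotype
    hap2: Haplotype

    def canonical(self) -> "Diplotype":
        """Equivalent diplotype with haplotypes in lexicographic order."""
        if self.hap2 < self.hap1:
            return Diplotype(self.hap2, self.hap1)
        return self

    @property
    def sorted_haplotypes(self) -> Tuple[Haplotype, Haplotype]:
        c = self.canonical()
        return (c.hap1, c.hap2)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Diplotype):
            return NotImplemented
        return self.sorted_haplotypes == other.sorted_haplotypes

    def __hash__(self) -> int:
        return hash(self.sorted_haplotypes)

    def __repr__(self) -> str:
        return f"Diplotype({'|'.join(''.join(h.alleles) for h in (self.hap1, self.hap2))})"

    def to_genotype(self, panel: VariantPanel, sample_id: str,
                    phased: bool = False) -> MultiLocusGenotype:
        """Collapse to per-site calls (losing phase unless ``phased``)."""
        calls = {
            v.id: LocusCall(v.id, a, b, phased=phased)
            for v, a, b in zip(panel, self.hap1.alleles, self.hap2.alleles)
        }
        return MultiLocusGenotype(sample_id, calls)


@dataclass(frozen=True)
class CopyBounds:
    """Sharp bounds on the functional-copy count over consistent phasings."""

    min_copies: int
    max_copies: int

    def __post_init__(self):
        if not (0 <= self.min_copies <= self.max_copies <= 2):
            raise ValueError(f"invalid bounds ({self.min_copies}, {self.max_copies})")

    @property
    def is_exact(self) -> bool:
        return self.min_copies == self.max_copies


def functional_copies_phased(d: Diplotype, panel: VariantPanel) -> int:
    """Number of functional copies (0-2) carried by a phased diplotype."""
    return int(d.hap1.is_functional(panel)) + int(d.hap2.is_functional(panel))


def mutant_burden(g: MultiLocusGenotype, panel: VariantPanel) -> Tuple[int, int]:
    """(het-mutant loci, hom-mutant loci) counts over the panel.

    A locus is het-mutant if exactly one of its two alleles is
    non-wildtype, hom-mutant if both are.  Requires a complete genotype.
    """
    g.require_complete(panel)
    n_het = n_hom = 0
    for v in panel:
        call = g.call_for(v.id)
        n_mut = sum(a != v.wildtype_allele for a in call.alleles)
        if n_mut == 1:
            n_het += 1
        elif n_mut == 2:
            n_hom += 1
    return n_het, n_hom


def _per_locus_phase_options(g, panel):
    # Ordered (hap1 allele, hap2 allele) assignments per locus. Phased het
    # calls contribute their stated order only; unphased hets contribute both.
    options = []
    for v in panel:
        call = g.call_for(v.id)
        if call.is_het and not call.phased:
            options.append([(call.allele_a, call.allele_b),
                            (call.allele_b, call.allele_a)])
        else:
            options.append([(call.allele_a, call.allele_b)])
    return options


def enumerate_phasings(g: MultiLocusGenotype, panel: VariantPanel) -> set:
    """All diplotypes whose unordered per-site allele pairs equal ``g``.

    Phase flags on the input are ignored: this is the brute-force space of
    phasings of the unphased genotype.  For h heterozygous loci the set has
    2^(h-1) unordered members (1 when h = 0).
    """
    g.require_complete(panel)
    per_locus = []
    for v in panel:
        call = g.call_for(v.id)
        if call.is_het:
            per_locus.append([(call.allele_a, call.allele_b),
                              (call.allele_b, call.allele_a)])
        else:
            per_locus.append([(call.allele_a, call.allele_b)])
    out = set()
    for combo in itertools.product(*per_locus):
        h1 = Haplotype(tuple(a for a, _ in combo))
        h2 = Haplotype(tuple(b for _, b in combo))
        out.add(Diplotype(h1, h2))
    return out


def functional_copy_bounds(g: MultiLocusGenotype, panel: VariantPanel) -> CopyBounds:
    """Min/max functional copies over phasings consistent with ``g``.

    Calls flagged phased are held fixed; unphased heterozygous calls range
    over both orientations.  For a fully unphased genotype this reduces to
    the closed form: any homozygous-mutant locus forces (0, 0); otherwise
    with h het-mutant loci the bounds are (2,2), (1,1) or (0,1) for h = 0,
    1, ≥2 — the ≥2 case being the cis/trans compound-heterozygote
    ambiguity.  Raises :class:`IncompleteGenotypeError` on missing calls.
    """
    g.require_complete(panel)
    lo, hi = 2, 0
    for combo in itertools.product(*_per_locus_phase_options(g, panel)):
        d = Diplotype(Haplotype(tuple(a for a, _ in combo)),
                      Haplotype(tuple(b for _, b in combo)))
        c = functional_copies_phased(d, panel)
        lo = min(lo, c)
        hi = max(hi, c)
    return CopyBounds(lo, hi)
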