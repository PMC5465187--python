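"""Mendelian transmission of the SHELL haplotype block.

The five panel sites span 55 bp (3,078,125–3,078,180), so recombination
within the block is negligible and each parent transmits one of its two
haplotypes intact with probability 1/2.  A cross between two parents
therefore yields at most four offspring diplotypes, collapsed over
unordered identity.  The canonical demonstration is the AVROS-SP tenera
(het at sh_AVROS) × Ekona tenera (het at sh_MPOB) hybrid cross, which
segregates 1/4 dura : 1/2 tenera : 1/4 pisifera — the pisifera quarter
being trans-compound heterozygotes that no single-site assay detects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .genotypes import (
    Diplotype,
    Haplotype,
    functional_copies_phased,
    mutant_haplotype,
    wildtype_haplotype,
)
from .panel import VariantPanel
from .predictor import FruitForm, copies_to_form


def gametes(parent: Diplotype) -> List[Tuple[Haplotype, float]]:
    """Transmitted haplotypes with probabilities (no recombination).

    Each parental haplotype is passed intact at probability 1/2; a
    homozygous parent yields a single gamete at probability 1.
    """
    if parent.hap1 == parent.hap2:
        return [(parent.hap1, 1.0)]
    return [(parent.hap1, 0.5), (parent.hap2, 0.5)]


@dataclass(frozen=True)
class OffspringDistribution:
    """Offspring diplotype distribution of one cross, plus its fruit-form
    marginal.  Genotypes are canonical (lexicographically sorted haplotype
    pairs) and listed in sorted order for deterministic reporting."""

    genotype_probs: Tuple[Tuple[Diplotype, float], ...]
    form_probs: Tuple[Tuple[FruitForm, float], ...]

    def genotype_dict(self) -> Dict[Diplotype, float]:
        return dict(self.genotype_probs)

    def form_dict(self) -> Dict[FruitForm, float]:
        return dict(self.form_probs)

    def __len__(self) -> int:
        return len(self.genotype_probs)


def cross_distribution(p1: Diplotype, p2: Diplotype,
                       panel: VariantPanel) -> OffspringDistribution:
    """Exact offspring distribution of p1 × p2 (selfing allowed).

    The product of the two gamete distributions, collapsed over unordered
    diplotype identity; the fruit-form marginal follows by classifying
    each offspring's functional-copy count.
    """
    probs: Dict[Diplotype, float] = {}
    for h1, q1 in gametes(p1):
        for h2, q2 in gametes(p2):
            d = Diplotype(h1, h2).canonical()
            probs[d] = probs.get(d, 0.0) + q1 * q2
    ordered = sorted(probs.items(), key=lambda kv: kv[0].sorted_haplotypes)
    forms: Dict[FruitForm, float] = {}
    for d, p in ordered:
        f = copies_to_form(functional_copies_phased(d, panel))
        forms[f] = forms.get(f, 0.0) + p
    form_order = [FruitForm.DURA, FruitForm.TENERA, FruitForm.PISIFERA]
    return OffspringDistribution(
        genotype_probs=tuple(ordered),
        form_probs=tuple((f, forms[f]) for f in form_order if f in forms),
    )


def sample_offspring(p1: Diplotype, p2: Diplotype, panel: VariantPanel,
                     n: int, seed: Optional[int] = None,
                     rng: Optional[np.random.Generator] = None) -> List[Diplotype]:
    """n i.i.d. offspring draws from ``cross_distribution``; reproducible
    given a seed (or an explicit numpy Generator)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    dist = cross_distribution(p1, p2, panel)
    genotypes = [d for d, _ in dist.genotype_probs]
    weights = np.array([p for _, p in dist.genotype_probs])
    idx = rng.choice(len(genotypes), size=n, p=weights / weights.sum())
    return [genotypes[i] for i in idx]


def parse_diplotype(text: str, panel: VariantPanel) -> Diplotype:
    """Parse a parent given as mutations carried per haplotype.

    Format: two '|'-separated haplotype specs, each either ``WT`` or a
    '+'-joined list of variant ids, e.g. ``"WT|sh_AVROS"`` or
    ``"sh_MPOB+sh_AVROS|WT"`` (a cis-compound carrier).  Each named
    variant contributes its catalogued mutant allele.
    """
    parts = text.split("|")
    if len(parts) != 2:
        raise ValueError(f"parent spec {text!r} must have exactly two '|'-separated haplotypes")
    haps = []
    for part in parts:
        part = part.strip()
        if part.upper() in ("WT", ""):
            haps.append(wildtype_haplotype(panel))
        else:
            ids = [p.strip() for p in part.split("+") if p.strip()]
            haps.append(mutant_haplotype(panel, *ids))
    return Diplotype(haps[0], haps[1])
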