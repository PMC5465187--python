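"""Fruit-form prediction rules.

Two predictors are provided:

* ``predict_single_marker`` — the classical one-site rule (wt/wt → dura,
  wt/mut → tenera, mut/mut → pisifera).  Exact within a population where a
  single causal variant segregates, but it miscalls introgressive hybrids
  in which two variants co-segregate.
* ``predict_copies`` — the haploinsufficiency rule: count functional SHELL
  copies over the whole panel and map 2/1/0 → dura/tenera/pisifera.  When
  two or more sites are heterozygous the copy count depends on phase; the
  default ``trans`` policy calls the trans-compound interpretation
  (pisifera) and flags the unconfirmed cis alternative (tenera).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Optional, Tuple

from .genotypes import (
    AlleleClass,
    IncompleteGenotypeError,
    MultiLocusGenotype,
    classify_allele,
    functional_copy_bounds,
)
from .panel import VariantPanel


class FruitForm(str, Enum):
    DURA = "dura"
    TENERA = "tenera"
    PISIFERA = "pisifera"

    @classmethod
    def parse(cls, text: str) -> "FruitForm":
        try:
            return cls(text.strip().lower())
        except ValueError:
            raise ValueError(f"unknown fruit form {text!r}") from None


def copies_to_form(copies: int) -> FruitForm:
    """Map a functional-copy count to its fruit form: 2 → dura (thick
    shell), 1 → tenera (thin shell, haploinsufficient), 0 → pisifera
    (shell-less)."""
    if copies == 2:
        return FruitForm.DURA
    if copies == 1:
        return FruitForm.TENERA
    if copies == 0:
        return FruitForm.PISIFERA
    raise ValueError(f"functional copies must be 0, 1 or 2, got {copies}")


@dataclass(frozen=True)
class Prediction:
    """A fruit-form call for one sample.

    ``form`` is None when the genotype cannot be scored (missing calls);
    such predictions propagate as "unknown" and are excluded from accuracy
    rather than defaulted to a form.  ``ambiguous`` marks phase ambiguity:
    the call assumes one phase (per policy) and ``alternative_form`` is the
    call under the opposite phase.  ``novel_allele`` marks a non-wildtype
    allele outside the catalogued mutant set.
    """

    form: Optional[FruitForm]
    copies_assumed: Optional[int]
    ambiguous: bool
    alternative_form: Optional[FruitForm]
    method: str
    variants_used: Tuple[str, ...]
    novel_allele: bool = False

    @property
    def is_unknown(self) -> bool:
        return self.form is None


def _unknown(method: str, variants_used: Tuple[str, ...]) -> Prediction:
    return Prediction(None, None, False, None, method, variants_used)


def predict_single_marker(g: MultiLocusGenotype, panel: VariantPanel,
                          variant_id: str) -> Prediction:
    """One-site co-dominant call at ``variant_id``.  Never ambiguous."""
    v = panel.get(variant_id)
    call = g.call_for(v.id)
    method = f"single:{v.id}"
    if call.is_missing:
        return _unknown(method, (v.id,))
    classes = [classify_allele(panel, v.id, a) for a in call.alleles]
    n_mut = sum(c is not AlleleClass.WILDTYPE for c in classes)
    novel = any(c is AlleleClass.NOVEL_MUTANT for c in classes)
    return Prediction(
        form=copies_to_form(2 - n_mut),
        copies_assumed=2 - n_mut,
        ambiguous=False,
        alternative_form=None,
        method=method,
        variants_used=(v.id,),
        novel_allele=novel,
    )


def predict_copies(g: MultiLocusGenotype, panel: VariantPanel,
                   phase_policy: str = "trans") -> Prediction:
    """Haploinsufficiency (functional-copy) call over the whole panel.

    phase_policy:
      ``trans`` (default) — assume compound heterozygous mutations lie on
      different chromosomes (minimum copies); ``cis`` — assume the same
      chromosome (maximum copies); ``both`` — the trans call with the cis
      alternative populated (identical to ``trans``; kept as an explicit
      reporting mode).
    """
    if phase_policy not in ("trans", "cis", "both"):
        raise ValueError(f"unknown phase policy {phase_policy!r}")
    method = "copies"
    try:
        bounds = functional_copy_bounds(g, panel)
    except IncompleteGenotypeError:
        return _unknown(method, panel.ids)
    novel = False
    for v in panel:
        for a in g.call_for(v.id).alleles:
            if classify_allele(panel, v.id, a) is AlleleClass.NOVEL_MUTANT:
                novel = True
    copies = bounds.max_copies if phase_policy == "cis" else bounds.min_copies
    other = bounds.min_copies if phase_policy == "cis" else bounds.max_copies
    ambiguous = not bounds.is_exact
    return Prediction(
        form=copies_to_form(copies),
        copies_assumed=copies,
        ambiguous=ambiguous,
        alternative_form=copies_to_form(other) if ambiguous else None,
        method=method,
        variants_used=panel.ids,
        novel_allele=novel,
    )


def segregating_variants(genotypes: Iterable[MultiLocusGenotype],
                         panel: VariantPanel) -> list:
    """Panel variants carrying at least one (non-missing) mutant allele in
    the cohort, in panel order.

    The choice of prediction method hinges on this: with one segregating
    site the single-marker rule suffices; with two or more (introgressive
    hybrids) functional-copy counting is required.
    """
    gts = list(genotypes)
    out = []
    for v in panel:
        seg = False
        for g in gts:
            call = g.call_for(v.id)
            if call.is_missing:
                continue
            if any(a != v.wildtype_allele for a in call.alleles):
                seg = True
                break
        if seg:
            out.append(v.id)
    return out
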