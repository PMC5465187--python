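"""Synthetic accession-structured cohorts with known truth.

Real SHELL validation cohorts are proprietary plantation materials, so
this module generates stand-ins that reproduce their structure: named
accessions in which one or two causal variants segregate (AVROS-side
material carries sh_AVROS, Ekona carries sh_MPOB, and their introgressive
hybrids segregate both), phenotypes produced deterministically from the
true phased functional-copy count, and discordance arising only from an
injected phenotyping-error rate or from a hidden (un-assayed) causal
mutation on the same linked block.

Three family specifications are supported: stratified accessions whose
fruit-form counts are reproduced exactly by construction, random draws of
founder haplotypes from an accession pool, and explicit Mendelian crosses
between named parent diplotypes.  Everything is reproducible from the
config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .concordance import PalmRecord
from .crosses import parse_diplotype, sample_offspring
from .genotypes import (
    Diplotype,
    Haplotype,
    LocusCall,
    MultiLocusGenotype,
    functional_copies_phased,
    mutant_haplotype,
    wildtype_haplotype,
)
from .io_formats import write_phenotypes, write_vcf
from .panel import ShellVariant, VariantPanel, builtin_panel
from .predictor import FruitForm, copies_to_form

_FORMS = (FruitForm.DURA, FruitForm.TENERA, FruitForm.PISIFERA)


@dataclass
class AccessionModel:
    """Founder haplotype pool of a named accession/origin."""

    name: str
    pool: List[Tuple[Haplotype, float]]
    description: str = ""

    def validate(self, panel: VariantPanel) -> None:
        total = sum(f for _, f in self.pool)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: pool frequencies sum to {total}, not 1")
        for h, f in self.pool:
            if f <= 0:
                raise ValueError(f"{self.name}: non-positive haplotype frequency {f}")
            if len(h) != len(panel):
                raise ValueError(f"{self.name}: haplotype length {len(h)} != panel size")


def builtin_accession_models(panel: VariantPanel) -> Dict[str, AccessionModel]:
    """Default founder pools for the classical origins.

    Each origin segregates its own causal variant; the mutant haplotype
    frequency defaults to 0.5, the expectation within tenera × tenera
    breeding material.  Cis-compound founder haplotypes are not included
    by default (their existence is unconfirmed) but can be supplied
    through explicit pools in a config file.
    """
    wt = wildtype_haplotype(panel)
    avros = mutant_haplotype(panel, "sh_AVROS")
    mpob = mutant_haplotype(panel, "sh_MPOB")
    return {
        "AVROS": AccessionModel("AVROS", [(wt, 0.5), (avros, 0.5)],
                                "Congo-derived AVROS; segregates sh_AVROS"),
        "AVROS x SP": AccessionModel("AVROS x SP", [(wt, 0.5), (avros, 0.5)],
                                     "AVROS × Serdang fertile pisifera; segregates sh_AVROS"),
        "Ekona": AccessionModel("Ekona", [(wt, 0.5), (mpob, 0.5)],
                                "Cameroon Ekona; segregates sh_MPOB"),
        "Nigerian": AccessionModel("Nigerian", [(wt, 0.5), (mpob, 0.5)],
                                   "Nigerian origin; segregates sh_MPOB"),
    }


# --------------------------------------------------------------------------
# Family specifications

@dataclass
class StratifiedFamilyGroup:
    """An accession block whose fruit-form counts are hit exactly.

    Genotypes are assigned by stratification, not rejection sampling:
    dura palms are wildtype homozygotes; tenera carry one heterozygous
    mutation (drawn among the accession's segregating variants); pisifera
    are mutant homozygotes when one variant segregates, or trans-compound
    heterozygotes when two do.  Palms are spread over ``n_families``
    round-robin.
    """

    accession: str
    variant_ids: Tuple[str, ...]
    n_dura: int
    n_tenera: int
    n_pisifera: int
    n_families: int = 1

    @property
    def size(self) -> int:
        return self.n_dura + self.n_tenera + self.n_pisifera

    def validate(self, panel: VariantPanel) -> None:
        if min(self.n_dura, self.n_tenera, self.n_pisifera) < 0 or self.size < 1:
            raise ValueError(f"{self.accession}: invalid form counts")
        if self.n_families < 1:
            raise ValueError(f"{self.accession}: n_families must be >= 1")
        if len(self.variant_ids) > 2:
            raise ValueError(f"{self.accession}: at most two segregating variants supported")
        if not self.variant_ids and (self.n_tenera or self.n_pisifera):
            raise ValueError(
                f"{self.accession}: tenera/pisifera palms need a segregating variant"
            )
        for vid in self.variant_ids:
            panel.get(vid)


@dataclass
class AccessionDrawFamily:
    """One family whose palms draw two founder haplotypes i.i.d. from an
    accession pool (named builtin model or explicit pool)."""

    accession: str
    size: int
    family_id: str
    pool: Optional[List[Tuple[Haplotype, float]]] = None

    def validate(self, panel: VariantPanel) -> None:
        if self.size < 1:
            raise ValueError(f"{self.family_id}: size must be >= 1")


@dataclass
class CrossFamily:
    """One full-sib family from an explicit parent cross (selfing allowed)."""

    parent1: str  # diplotype spec, e.g. "WT|sh_AVROS"
    parent2: str
    size: int
    family_id: str
    accession: str = "cross"

    def validate(self, panel: VariantPanel) -> None:
        if self.size < 1:
            raise ValueError(f"{self.family_id}: size must be >= 1")
        parse_diplotype(self.parent1, panel)
        parse_diplotype(self.parent2, panel)


FamilySpec = Union[StratifiedFamilyGroup, AccessionDrawFamily, CrossFamily]


@dataclass
class HiddenMutation:
    """An un-assayed sixth loss-of-function site on the linked block.

    Each founder haplotype carries it independently with ``frequency``;
    it contributes to the true functional-copy count but is invisible to
    the emitted panel genotypes, so carriers surface as rectification
    misses.
    """

    label: str = "sh_hidden"
    frequency: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"hidden mutation frequency {self.frequency} out of [0,1]")


@dataclass
class CohortConfig:
    """Simulation recipe: panel, families, error rates and seed."""

    panel: VariantPanel
    families: List[FamilySpec]
    phenotyping_error_rate: float = 0.0
    hidden_mutation: Optional[HiddenMutation] = None
    seed: int = 0

    def validate(self) -> None:
        if not self.families:
            raise ValueError("config has no families")
        if not 0.0 <= self.phenotyping_error_rate <= 1.0:
            raise ValueError(
                f"phenotyping_error_rate {self.phenotyping_error_rate} out of [0,1]"
            )
        for fam in self.families:
            fam.validate(self.panel)
        if self.hidden_mutation is not None:
            self.hidden_mutation.validate()


# --------------------------------------------------------------------------
# Simulation

def _extended_panel(panel: VariantPanel, hidden: Optional[HiddenMutation]) -> VariantPanel:
    # The hidden site rides at the end of the haplotype vector, a few bp
    # downstream of the last assayed site (still inside the linked block).
    label = hidden.label if hidden else "sh_hidden"
    max_pos = max(v.pos for v in panel)
    extra = ShellVariant(label, panel.variants[0].chrom, max_pos + 7, "G",
                         frozenset({"T"}), (), "", "synthetic un-assayed site")
    return VariantPanel([*panel.variants, extra], name=f"{panel.name}+hidden")


def _extend(h: Haplotype, ext: VariantPanel) -> Haplotype:
    return Haplotype((*h.alleles, ext.variants[-1].wildtype_allele))


def _with_hidden(h: Haplotype, ext: VariantPanel, rng, freq: float) -> Haplotype:
    if freq > 0.0 and rng.random() < freq:
        mut = sorted(ext.variants[-1].known_mutant_alleles)[0]
        return Haplotype((*h.alleles[:-1], mut))
    return h


def _describe(h: Haplotype, ext: VariantPanel) -> str:
    carried = [v.id for v, a in zip(ext, h.alleles) if a != v.wildtype_allele]
    return "+".join(carried) if carried else "WT"


def _stratified_diplotypes(group: StratifiedFamilyGroup, panel: VariantPanel,
                           ext: VariantPanel, rng) -> List[Diplotype]:
    wt = _extend(wildtype_haplotype(panel), ext)
    muts = [_extend(mutant_haplotype(panel, vid), ext) for vid in group.variant_ids]
    out: List[Diplotype] = []
    out += [Diplotype(wt, wt)] * group.n_dura
    for _ in range(group.n_tenera):
        m = muts[rng.integers(0, len(muts))] if len(muts) > 1 else muts[0]
        out.append(Diplotype(wt, m))
    for _ in range(group.n_pisifera):
        if len(muts) == 1:
            out.append(Diplotype(muts[0], muts[0]))
        else:  # trans-compound heterozygote
            out.append(Diplotype(muts[0], muts[1]))
    return out


def simulate_cohort(config: CohortConfig,
                    seed: Optional[int] = None) -> Tuple[List[PalmRecord], pd.DataFrame]:
    """Generate a cohort and its truth table.

    True fruit form is ``copies_to_form`` of the phased functional-copy
    count over panel ∪ hidden site; the observed form flips to a
    uniformly-chosen different form with probability
    ``phenotyping_error_rate``.  Emitted genotypes are unphased and
    exclude the hidden site.  Fertility labels are attached uniformly at
    random to observed pisifera only (metadata; no genotype linkage).
    Fully reproducible from the seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    panel = config.panel
    hid = config.hidden_mutation
    hid_freq = hid.frequency if hid else 0.0
    ext = _extended_panel(panel, hid)
    models = builtin_accession_models(panel)

    palms: List[Tuple[str, str, Diplotype]] = []  # (family, accession, diplotype)
    for fam in config.families:
        if isinstance(fam, StratifiedFamilyGroup):
            dips = _stratified_diplotypes(fam, panel, ext, rng)
            if hid_freq > 0.0:
                dips = [Diplotype(_with_hidden(d.hap1, ext, rng, hid_freq),
                                  _with_hidden(d.hap2, ext, rng, hid_freq))
                        for d in dips]
            fam_labels = [f"{fam.accession}-F{i + 1}" for i in range(fam.n_families)]
            for k, d in enumerate(dips):
                palms.append((fam_labels[k % fam.n_families], fam.accession, d))
        elif isinstance(fam, AccessionDrawFamily):
            pool = fam.pool
            if pool is None:
                if fam.accession not in models:
                    raise ValueError(f"unknown accession model {fam.accession!r}")
                pool = models[fam.accession].pool
            AccessionModel(fam.accession, list(pool)).validate(panel)
            haps = [_extend(h, ext) for h, _ in pool]
            freqs = np.array([f for _, f in pool])
            for _ in range(fam.size):
                i, j = rng.choice(len(haps), size=2, p=freqs / freqs.sum())
                d = Diplotype(_with_hidden(haps[i], ext, rng, hid_freq),
                              _with_hidden(haps[j], ext, rng, hid_freq))
                palms.append((fam.family_id, fam.accession, d))
        elif isinstance(fam, CrossFamily):
            p1 = parse_diplotype(fam.parent1, panel)
            p2 = parse_diplotype(fam.parent2, panel)
            # the hidden site enters through the parents' haplotypes, once
            # per family, and is then transmitted Mendelian-fashion
            p1 = Diplotype(_with_hidden(_extend(p1.hap1, ext), ext, rng, hid_freq),
                           _with_hidden(_extend(p1.hap2, ext), ext, rng, hid_freq))
            p2 = Diplotype(_with_hidden(_extend(p2.hap1, ext), ext, rng, hid_freq),
                           _with_hidden(_extend(p2.hap2, ext), ext, rng, hid_freq))
            for d in sample_offspring(p1, p2, ext, fam.size, rng=rng):
                palms.append((fam.family_id, fam.accession, d))
        else:  # pragma: no cover - guarded by validate()
            raise TypeError(f"unknown family spec {type(fam)}")

    records: List[PalmRecord] = []
    truth_rows = []
    for k, (family, accession, d) in enumerate(palms, start=1):
        sid = f"P{k:05d}"
        true_copies = functional_copies_phased(d, ext)
        true_form = copies_to_form(true_copies)
        observed = true_form
        err = False
        if config.phenotyping_error_rate > 0.0 and rng.random() < config.phenotyping_error_rate:
            others = [f for f in _FORMS if f is not true_form]
            observed = others[rng.integers(0, 2)]
            err = True
        fert = "missing"
        if observed is FruitForm.PISIFERA:
            fert = ("fertile", "sterile")[rng.integers(0, 2)]
        panel_calls = {
            v.id: LocusCall(v.id, a, b)
            for v, a, b in zip(panel, d.hap1.alleles, d.hap2.alleles)
        }
        g = MultiLocusGenotype(sid, panel_calls)
        records.append(PalmRecord(sid, accession, observed, genotype=g, fertility=fert))
        hidden_mut = ext.variants[-1]
        truth_rows.append({
            "sample_id": sid,
            "family": family,
            "accession": accession,
            "hap1": _describe(d.hap1, ext),
            "hap2": _describe(d.hap2, ext),
            "true_copies": true_copies,
            "true_form": true_form.value,
            "observed_form": observed.value,
            "phenotyping_error": err,
            "hidden_carrier": any(
                h.alleles[-1] != hidden_mut.wildtype_allele for h in (d.hap1, d.hap2)
            ),
        })
    return records, pd.DataFrame.from_records(truth_rows)


def write_cohort(records: Sequence[PalmRecord], truth: pd.DataFrame,
                 panel: VariantPanel, prefix: Union[str, Path]) -> Dict[str, Path]:
    """Write <prefix>.vcf, <prefix>.phenotypes.tsv and <prefix>.truth.tsv."""
    prefix = Path(prefix)
    paths = {
        "vcf": prefix.with_suffix(".vcf"),
        "phenotypes": Path(str(prefix) + ".phenotypes.tsv"),
        "truth": Path(str(prefix) + ".truth.tsv"),
    }
    write_vcf({r.sample_id: r.genotype for r in records}, panel, paths["vcf"])
    write_phenotypes(records, paths["phenotypes"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


# --------------------------------------------------------------------------
# Packaged study configurations and fixtures

def first_validation_config(seed: int = 2017) -> CohortConfig:
    """The 587-palm four-accession validation cohort.

    Accession blocks (families, dura/tenera/pisifera): AVROS 25 families
    73/197/84; AVROS × SP 15 families 12/70/58; AVROS-SP × Ekona 1 family
    23/24/10; Ekona 1 family 12/14/10.  AVROS-side material segregates
    sh_AVROS, Ekona segregates sh_MPOB, and the introgressive hybrid
    segregates both, so its shell-less palms are trans-compound
    heterozygotes.  Counts are reproduced exactly by construction.
    """
    return CohortConfig(
        panel=builtin_panel(),
        families=[
            StratifiedFamilyGroup("AVROS", ("sh_AVROS",), 73, 197, 84, n_families=25),
            StratifiedFamilyGroup("AVROS x SP", ("sh_AVROS",), 12, 70, 58, n_families=15),
            StratifiedFamilyGroup("AVROS-SP x Ekona", ("sh_AVROS", "sh_MPOB"),
                                  23, 24, 10, n_families=1),
            StratifiedFamilyGroup("Ekona", ("sh_MPOB",), 12, 14, 10, n_families=1),
        ],
        phenotyping_error_rate=0.0,
        hidden_mutation=None,
        seed=seed,
    )


def congo_cohort_config(seed: int = 2017) -> CohortConfig:
    """Pure Congo accession: 14 dura, 20 tenera, 6 pisifera, all explained
    by sh_AVROS alone."""
    return CohortConfig(
        panel=builtin_panel(),
        families=[StratifiedFamilyGroup("Congo", ("sh_AVROS",), 14, 20, 6)],
        seed=seed,
    )


def mpob_cohort_config(seed: int = 2017) -> CohortConfig:
    """Monomorphic MPOB accession: 136 wildtype dura palms."""
    return CohortConfig(
        panel=builtin_panel(),
        families=[StratifiedFamilyGroup("MPOB", (), 136, 0, 0)],
        seed=seed,
    )


def hybrid_cross_config(n: int, seed: int = 0,
                        phenotyping_error_rate: float = 0.0) -> CohortConfig:
    """An AVROS-SP tenera × Ekona tenera hybrid family of size n: both
    causal variants segregate, so single-marker prediction fails on the
    trans-heteroallelic pisifera quarter."""
    return CohortConfig(
        panel=builtin_panel(),
        families=[CrossFamily("WT|sh_AVROS", "sh_MPOB|WT", n, "HYB1",
                              accession="AVROS-SP x Ekona")],
        phenotyping_error_rate=phenotyping_error_rate,
        seed=seed,
    )


# Thirteen re-tested palms (five discrepancies, eight controls) with full
# five-site genotypes, transcribed in assay column order
# (sh_MPOB2, sh_MPOB4, sh_MPOB, sh_AVROS, sh_MPOB3).
_RETEST_ROWS = [
    # sample, accession, MPOB2, MPOB4, MPOB, AVROS, MPOB3, observed
    ("V907", "Cameroon x Congo", "A/A", "A/A", "T/T", "A/A", "C/C", "dura"),
    ("V670", "Congo",            "A/A", "A/A", "T/T", "A/A", "C/C", "dura"),
    ("V749", "MPOB",             "A/A", "A/A", "T/T", "A/A", "C/C", "dura"),
    ("V121", "Nigerian x AVROS", "A/A", "T/A", "C/T", "T/A", "C/C", "pisifera"),
    ("V152", "Tanzanian",        "A/A", "A/A", "T/T", "T/T", "C/C", "pisifera"),
    ("V685", "Congo",            "A/A", "A/A", "T/T", "T/T", "C/C", "pisifera"),
    ("V646", "Congo",            "A/A", "A/A", "T/T", "T/A", "C/C", "tenera"),
    ("V086", "Nigerian x AVROS", "A/A", "A/A", "C/T", "A/A", "C/C", "tenera"),
    ("C2",   "AVROS",            "C/A", "A/A", "T/T", "A/A", "C/C", "tenera"),
    ("C1",   "AVROS",            "C/A", "A/A", "T/T", "T/A", "C/C", "pisifera"),
    ("C3",   "AVROS",            "C/A", "A/A", "T/T", "T/A", "C/C", "pisifera"),
    ("V927", "Cameroon x Congo", "A/A", "A/A", "T/T", "A/A", "C/C", "tenera"),
    ("V599", "Cameroon x Congo", "A/A", "A/A", "C/T", "A/A", "C/C", "pisifera"),
]

_RETEST_COLUMNS = ("sh_MPOB2", "sh_MPOB4", "sh_MPOB", "sh_AVROS", "sh_MPOB3")


def retest_fixture() -> List[PalmRecord]:
    """The thirteen palms re-assayed at all five SHELL sites.

    Eight controls are concordant under the classical two-site test; the
    three AVROS discrepancies are explained by sh_MPOB2 (alone for the
    tenera C2, combined in trans with sh_AVROS for the pisifera C1 and
    C3); V927 and V599 stay discordant even on the full panel and point
    to a further, un-assayed mutation.
    """
    records = []
    for sid, acc, *cells, form in _RETEST_ROWS:
        calls = {
            vid: LocusCall.parse(vid, cell)
            for vid, cell in zip(_RETEST_COLUMNS, cells)
        }
        records.append(PalmRecord(
            sample_id=sid, accession=acc,
            observed_form=FruitForm.parse(form),
            genotype=MultiLocusGenotype(sid, calls),
        ))
    return records


# --------------------------------------------------------------------------
# YAML config round-trip

def load_config(path: Union[str, Path],
                panel: Optional[VariantPanel] = None) -> CohortConfig:
    """Parse a YAML cohort config.

    Top-level keys: ``panel`` ("builtin" or a panel TSV path), ``seed``,
    ``phenotyping_error_rate``, ``hidden_mutation`` ({label, frequency})
    and ``families`` — a list whose entries carry ``kind`` ∈ {stratified,
    draw, cross} plus the fields of the matching family spec.  ``draw``
    entries may name a builtin accession model or give an explicit
    ``pool`` of {mutations: [...], frequency} items.
    """
    data = yaml.safe_load(Path(path).read_text())
    if panel is None:
        spec = data.get("panel", "builtin")
        if spec == "builtin":
            panel = builtin_panel()
        else:
            from .panel import read_panel
            panel = read_panel(Path(path).parent / spec)
    families: List[FamilySpec] = []
    for i, fam in enumerate(data.get("families", [])):
        kind = fam.get("kind")
        if kind == "stratified":
            forms = fam.get("forms", {})
            families.append(StratifiedFamilyGroup(
                accession=fam["accession"],
                variant_ids=tuple(fam.get("variants", [])),
                n_dura=int(forms.get("dura", 0)),
                n_tenera=int(forms.get("tenera", 0)),
                n_pisifera=int(forms.get("pisifera", 0)),
                n_families=int(fam.get("n_families", 1)),
            ))
        elif kind == "draw":
            pool = None
            if "pool" in fam:
                pool = [
                    (mutant_haplotype(panel, *entry.get("mutations", [])),
                     float(entry["frequency"]))
                    for entry in fam["pool"]
                ]
            families.append(AccessionDrawFamily(
                accession=fam["accession"], size=int(fam["size"]),
                family_id=fam.get("family_id", f"{fam['accession']}-D{i + 1}"),
                pool=pool,
            ))
        elif kind == "cross":
            families.append(CrossFamily(
                parent1=fam["parent1"], parent2=fam["parent2"],
                size=int(fam["size"]),
                family_id=fam.get("family_id", f"X{i + 1}"),
                accession=fam.get("accession", "cross"),
            ))
        else:
            raise ValueError(f"family {i}: unknown kind {kind!r}")
    hidden = None
    if data.get("hidden_mutation"):
        hm = data["hidden_mutation"]
        hidden = HiddenMutation(label=hm.get("label", "sh_hidden"),
                                frequency=float(hm.get("frequency", 0.0)))
    cfg = CohortConfig(
        panel=panel,
        families=families,
        phenotyping_error_rate=float(data.get("phenotyping_error_rate", 0.0)),
        hidden_mutation=hidden,
        seed=int(data.get("seed", 0)),
    )
    cfg.validate()
    return cfg
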