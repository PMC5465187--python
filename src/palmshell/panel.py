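"""Registry of causal SHELL loss-of-function variants.

Shell thickness in oil palm (*Elaeis guineensis*) is a monogenic trait
controlled by the SHELL gene, a type II MADS-box transcription factor on
chromosome 2 (sequence CM002082.1 of the EG5 assembly).  Five independent
loss-of-function point mutations within the MADS-box domain are catalogued
here; a haplotype is "functional" only if it carries the wildtype
nucleotide at every one of these sites.

Coordinates are 1-based (VCF convention).  KASP assay strand is taken to be
the genome strand; allele letters are stored literally as reported.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

NUCLEOTIDES = frozenset("ACGT")

#: Sequence name of the SHELL-bearing pseudochromosome.
SHELL_CHROM = "CM002082.1"


@dataclass(frozen=True)
class ShellVariant:
    """A single causal site in the SHELL gene.

    Parameters
    ----------
    id
        Short variant name (``sh_MPOB``, ``sh_AVROS``, ...).
    chrom, pos
        1-based genomic coordinate of the site.
    wildtype_allele
        The functional (sh^DeliDura) nucleotide.
    known_mutant_alleles
        Catalogued loss-of-function nucleotides at this site.  May be
        empty: the site is a known causal position whose mutant
        nucleotide has not been reported, and *any* non-wildtype allele
        observed there is treated as a (novel) mutant.
    aliases
        Alternative labels, e.g. ``M1`` for sh_MPOB, ``M2`` for sh_AVROS.
    aa_change
        Free-text amino-acid consequence annotation.
    origin_note
        Free-text provenance note (accession of first report etc.).
    """

    id: str
    chrom: str
    pos: int
    wildtype_allele: str
    known_mutant_alleles: frozenset = frozenset()
    aliases: tuple = ()
    aa_change: str = ""
    origin_note: str = ""

    def is_wildtype(self, allele: str) -> bool:
        return allele == self.wildtype_allele

    def violations(self) -> list:
        """Invariant violations of this variant, as human-readable strings."""
        out = []
        if self.pos <= 0:
            out.append(f"{self.id}: position must be positive, got {self.pos}")
        if self.wildtype_allele not in NUCLEOTIDES:
            out.append(f"{self.id}: wildtype allele {self.wildtype_allele!r} is not a nucleotide")
        for a in self.known_mutant_alleles:
            if a not in NUCLEOTIDES:
                out.append(f"{self.id}: mutant allele {a!r} is not a nucleotide")
        if self.wildtype_allele in self.known_mutant_alleles:
            out.append(f"{self.id}: wildtype allele {self.wildtype_allele} listed among mutants")
        return out


class VariantPanel:
    """An ordered collection of :class:`ShellVariant` sites.

    The order of variants is fixed and defines the allele order of every
    haplotype vector built over the panel.
    """

    def __init__(self, variants: Sequence[ShellVariant], name: str = "panel"):
        self.variants = tuple(variants)
        self.name = name
        self._by_id = {v.id: v for v in self.variants}
        self._by_pos = {(v.chrom, v.pos): v for v in self.variants}

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[ShellVariant]:
        return iter(self.variants)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._by_id

    def __eq__(self, other) -> bool:
        if not isinstance(other, VariantPanel):
            return NotImplemented
        return self.name == other.name and self.variants == other.variants

    def __repr__(self) -> str:
        return f"VariantPanel({self.name!r}, {[v.id for v in self.variants]})"

    @property
    def ids(self) -> tuple:
        return tuple(v.id for v in self.variants)

    def get(self, variant_id: str) -> ShellVariant:
        """Look up a variant by id or alias.  Raises KeyError if absent."""
        if variant_id in self._by_id:
            return self._by_id[variant_id]
        for v in self.variants:
            if variant_id in v.aliases:
                return v
        raise KeyError(f"no variant {variant_id!r} in panel {self.name!r}")

    def at_position(self, chrom: str, pos: int):
        """Variant at a genomic coordinate, or None."""
        return self._by_pos.get((chrom, pos))

    def restrict(self, variant_ids: Iterable[str]) -> "VariantPanel":
        """Sub-panel containing only the named variants, in this panel's order.

        Ids may be given in any order; aliases are accepted.
        """
        wanted = {self.get(i).id for i in variant_ids}
        kept = [v for v in self.variants if v.id in wanted]
        missing = wanted - {v.id for v in kept}
        if missing:  # unreachable after get(), kept for defensive clarity
            raise KeyError(f"variants not in panel: {sorted(missing)}")
        return VariantPanel(kept, name=f"{self.name}[{len(kept)}]")

    def wildtype_vector(self, order: Sequence[str] | None = None) -> tuple:
        """Wildtype alleles, in panel order or an explicit id order."""
        if order is None:
            return tuple(v.wildtype_allele for v in self.variants)
        return tuple(self.get(i).wildtype_allele for i in order)


def builtin_panel() -> VariantPanel:
    """The five reported SHELL loss-of-function sites, in genomic order.

    sh_MPOB (alias M1, T>C, Leu->Pro, disrupts SHELL/SEP-like
    heterodimerization) and sh_AVROS (alias M2, A>T, Lys->Asn, disrupts DNA
    binding) are the two classical variants; sh_MPOB2/3/4 were found later
    in commercial tenera screening.  The mutant nucleotide of sh_MPOB3 is
    not catalogued here; any non-wildtype allele at that site is classified
    as a novel mutant.
    """
    return VariantPanel(
        [
            ShellVariant("sh_MPOB3", SHELL_CHROM, 3078125, "C",
                         frozenset(), (),
                         "", "MADS-box domain; mutant nucleotide not catalogued"),
            ShellVariant("sh_AVROS", SHELL_CHROM, 3078154, "A",
                         frozenset({"T"}), ("M2",),
                         "Lys→Asn", "Congo-derived AVROS pisifera"),
            ShellVariant("sh_MPOB", SHELL_CHROM, 3078161, "T",
                         frozenset({"C"}), ("M1",),
                         "Leu→Pro", "Nigerian tenera"),
            ShellVariant("sh_MPOB4", SHELL_CHROM, 3078178, "A",
                         frozenset({"T"}), (),
                         "", "MADS-box domain"),
            ShellVariant("sh_MPOB2", SHELL_CHROM, 3078180, "A",
                         frozenset({"C"}), (),
                         "", "MADS-box domain"),
        ],
        name="shell5",
    )


def validate_panel(panel: VariantPanel) -> list:
    """All invariant violations of a panel (empty list = well-formed).

    Checks per-variant invariants plus panel-level uniqueness of ids and
    genomic positions.  Violations are returned as data, not raised.
    """
    out = []
    if len(panel) == 0:
        out.append("panel has no variants")
    seen_ids: dict = {}
    seen_pos: dict = {}
    for v in panel:
        out.extend(v.violations())
        if v.id in seen_ids:
            out.append(f"duplicate variant id {v.id}")
        seen_ids[v.id] = v
        key = (v.chrom, v.pos)
        if key in seen_pos:
            out.append(
                f"duplicate position {v.chrom}:{v.pos} shared by "
                f"{seen_pos[key].id} and {v.id}"
            )
        else:
            seen_pos[key] = v
    return out


# ---------------------------------------------------------------------------
# Panel file format: TSV with '#'-prefixed header lines.
# Columns: id, alias, chrom, pos, wildtype, mutants, aa_change.

_COLUMNS = ("id", "alias", "chrom", "pos", "wildtype", "mutants", "aa_change")


def write_panel(panel: VariantPanel, path: Union[str, Path]) -> None:
    """Serialize a panel to its TSV file format."""
    lines = [
        f"# palmshell variant panel: {panel.name}",
        "# coordinates are 1-based (VCF convention)",
        "\t".join(_COLUMNS),
    ]
    for v in panel:
        lines.append("\t".join([
            v.id,
            ",".join(v.aliases),
            v.chrom,
            str(v.pos),
            v.wildtype_allele,
            ",".join(sorted(v.known_mutant_alleles)),
            v.aa_change,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_panel(path: Union[str, Path]) -> VariantPanel:
    """Parse a panel TSV written by :func:`write_panel`.

    The panel name is recovered from the ``# palmshell variant panel:``
    header line when present, so write→read round-trips exactly.
    """
    name = Path(path).stem
    rows = []
    header: list | None = None
    for raw in Path(path).read_text().splitlines():
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            tag = "panel:"
            if tag in line:
                name = line.split(tag, 1)[1].strip()
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            if tuple(header) != _COLUMNS:
                raise ValueError(
                    f"panel file {path}: expected columns {_COLUMNS}, got {tuple(header)}"
                )
            continue
        if len(fields) < len(_COLUMNS):
            fields = fields + [""] * (len(_COLUMNS) - len(fields))
        rec = dict(zip(_COLUMNS, fields))
        rows.append(ShellVariant(
            id=rec["id"],
            chrom=rec["chrom"],
            pos=int(rec["pos"]),
            wildtype_allele=rec["wildtype"],
            known_mutant_alleles=frozenset(a for a in rec["mutants"].split(",") if a),
            aliases=tuple(a for a in rec["alias"].split(",") if a),
            aa_change=rec["aa_change"],
        ))
    if header is None:
        raise ValueError(f"panel file {path}: no header row")
    return VariantPanel(rows, name=name)
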