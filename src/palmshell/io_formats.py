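"""File I/O: VCF, KASP-style call tables and phenotype TSVs.

VCF reading and writing go through pysam; sites are matched to the panel
by (chrom, pos), "|"-separated genotypes keep their phase, and sites
absent from a file surface as missing calls.  The call-table format is a
plain sample × variant TSV of diploid calls ("A/A", "T|C", "./.")
emulating a KASP genotyping export.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Union

import pandas as pd
import pysam

from .concordance import PalmRecord
from .genotypes import LocusCall, MultiLocusGenotype
from .panel import VariantPanel
from .predictor import FruitForm, Prediction

PathLike = Union[str, Path]


class VcfFormatError(ValueError):
    pass


def read_vcf(path: PathLike, panel: VariantPanel) -> Dict[str, MultiLocusGenotype]:
    """Panel genotypes for every sample in a VCF.

    Records are matched to panel sites by (chrom, pos); non-panel records
    are ignored and panel sites without a record yield missing calls.
    Alleles are resolved through the record's REF/ALT strings, so
    multi-allelic records are fine.  A REF differing from the panel
    wildtype triggers a warning and the file's allele is kept (it will be
    classified as mutant downstream).  Raises on non-diploid or
    half-missing GT fields.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    calls: Dict[str, Dict[str, LocusCall]] = {s: {} for s in samples}
    for rec in vf:
        v = panel.at_position(rec.chrom, rec.pos)
        if v is None:
            continue
        if rec.ref != v.wildtype_allele:
            warnings.warn(
                f"{path}: REF {rec.ref!r} at {rec.chrom}:{rec.pos} differs from "
                f"panel wildtype {v.wildtype_allele!r} for {v.id}; using file alleles"
            )
        for s in samples:
            sample = rec.samples[s]
            gt = sample.get("GT")
            if gt is None:
                raise VcfFormatError(f"{path}: no GT for sample {s} at {rec.chrom}:{rec.pos}")
            if len(gt) != 2:
                raise VcfFormatError(
                    f"{path}: sample {s} at {rec.chrom}:{rec.pos} has ploidy {len(gt)}, need 2"
                )
            if gt[0] is None and gt[1] is None:
                calls[s][v.id] = LocusCall.missing(v.id)
                continue
            if gt[0] is None or gt[1] is None:
                raise VcfFormatError(
                    f"{path}: half-missing genotype for sample {s} at {rec.chrom}:{rec.pos}"
                )
            alleles = (rec.alleles[gt[0]], rec.alleles[gt[1]])
            calls[s][v.id] = LocusCall(v.id, alleles[0], alleles[1], phased=sample.phased)
    out = {}
    for s in samples:
        for v in panel:
            calls[s].setdefault(v.id, LocusCall.missing(v.id))
        out[s] = MultiLocusGenotype(s, calls[s])
    return out


def write_vcf(genotypes: Mapping[str, MultiLocusGenotype], panel: VariantPanel,
              path: PathLike) -> None:
    """Write one VCF record per panel variant.

    REF is the panel wildtype; ALT lists observed non-wildtype alleles in
    first-seen order across samples (ALT '.' when none observed).  Phased
    calls are emitted with '|'.  An empty genotype mapping produces a
    header-only VCF.
    """
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(v.chrom for v in panel):
        header.contigs.add(chrom)
    header.formats.add("GT", 1, "String", "Genotype")
    samples = list(genotypes)
    for s in samples:
        header.add_sample(s)
    vf = pysam.VariantFile(str(path), "w", header=header)
    try:
        for v in panel if samples else ():
            alts: List[str] = []
            for s in samples:
                call = genotypes[s].call_for(v.id)
                if call.is_missing:
                    continue
                for a in call.alleles:
                    if a != v.wildtype_allele and a not in alts:
                        alts.append(a)
            # pysam needs >= 2 alleles; '.' yields a monomorphic ALT column
            alleles = (v.wildtype_allele, *alts) if alts else (v.wildtype_allele, ".")
            index = {a: i for i, a in enumerate((v.wildtype_allele, *alts))}
            rec = vf.new_record(contig=v.chrom, start=v.pos - 1,
                                alleles=alleles, id=v.id)
            for s in samples:
                call = genotypes[s].call_for(v.id)
                if call.is_missing:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    rec.samples[s]["GT"] = (index[call.allele_a], index[call.allele_b])
                    rec.samples[s].phased = call.phased
            vf.write(rec)
    finally:
        vf.close()


# ---------------------------------------------------------------------------
# Call tables (KASP export emulation)

def read_call_table(path: PathLike, panel: VariantPanel) -> Dict[str, MultiLocusGenotype]:
    """Read a sample × variant TSV of diploid calls.

    First column is ``sample_id``; remaining column names must be panel
    variant ids (aliases accepted).  Cells are "A/A", "T|C" or "./.".
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be sample_id")
    col_to_vid = {c: panel.get(c).id for c in df.columns[1:]}
    out = {}
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in out:
            raise ValueError(f"{path}: duplicate sample_id {sid!r}")
        calls = {}
        for col, vid in col_to_vid.items():
            calls[vid] = LocusCall.parse(vid, str(row[col]))
        out[sid] = MultiLocusGenotype(sid, calls)
    return out


def write_call_table(genotypes: Mapping[str, MultiLocusGenotype],
                     panel: VariantPanel, path: PathLike) -> None:
    rows = []
    for sid, g in genotypes.items():
        row = {"sample_id": sid}
        for v in panel:
            row[v.id] = str(g.call_for(v.id))
        rows.append(row)
    pd.DataFrame.from_records(rows, columns=["sample_id", *panel.ids]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Phenotype tables

_FERTILITY = {"fertile", "sterile", "missing"}


def read_phenotypes(path: PathLike) -> List[PalmRecord]:
    """Parse a phenotype TSV into genotype-less :class:`PalmRecord`s.

    Required columns: sample_id, accession, fruit_form; optional:
    fertility.  Forms parse case-insensitively from {dura, tenera,
    pisifera, NA}; NA means unphenotyped.  Duplicate sample ids are an
    error.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    required = {"sample_id", "accession", "fruit_form"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: phenotype table needs columns {sorted(required)}")
    records = []
    seen = set()
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in seen:
            raise ValueError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        raw_form = row["fruit_form"].strip()
        form = None if raw_form.upper() in ("NA", "") else FruitForm.parse(raw_form)
        fert = "missing"
        if "fertility" in df.columns:
            raw_f = row["fertility"].strip().lower()
            if raw_f not in ("na", ""):
                if raw_f not in _FERTILITY:
                    raise ValueError(f"{path}: unknown fertility label {row['fertility']!r}")
                fert = raw_f
        records.append(PalmRecord(
            sample_id=sid, accession=row["accession"],
            observed_form=form, fertility=fert,
        ))
    return records


def write_phenotypes(records: Iterable[PalmRecord], path: PathLike) -> None:
    rows = [{
        "sample_id": r.sample_id,
        "accession": r.accession,
        "fruit_form": r.observed_form.value if r.observed_form else "NA",
        "fertility": r.fertility if r.fertility != "missing" else "NA",
    } for r in records]
    pd.DataFrame.from_records(
        rows, columns=["sample_id", "accession", "fruit_form", "fertility"]
    ).to_csv(path, sep="\t", index=False)


def write_predictions(predictions: Mapping[str, Prediction], path: PathLike) -> None:
    """Per-sample prediction TSV (columns fixed for downstream parsing)."""
    rows = []
    for sid, p in predictions.items():
        rows.append({
            "sample_id": sid,
            "form": p.form.value if p.form else "unknown",
            "copies_assumed": p.copies_assumed if p.copies_assumed is not None else "NA",
            "ambiguous": p.ambiguous,
            "alternative_form": p.alternative_form.value if p.alternative_form else "NA",
            "novel_allele_flag": p.novel_allele,
            "variants_used": ",".join(p.variants_used),
        })
    pd.DataFrame.from_records(rows, columns=[
        "sample_id", "form", "copies_assumed", "ambiguous",
        "alternative_form", "novel_allele_flag", "variants_used",
    ]).to_csv(path, sep="\t", index=False)


def attach_genotypes(records: Iterable[PalmRecord],
                     genotypes: Mapping[str, MultiLocusGenotype],
                     require_overlap: bool = True) -> List[PalmRecord]:
    """Join phenotype records with genotypes by sample id."""
    out = []
    n_matched = 0
    for r in records:
        g = genotypes.get(r.sample_id)
        if g is not None:
            n_matched += 1
        out.append(PalmRecord(r.sample_id, r.accession, r.observed_form,
                              genotype=g, fertility=r.fertility))
    if require_overlap and n_matched == 0:
        raise ValueError("no overlapping sample ids between phenotypes and genotypes")
    return out
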