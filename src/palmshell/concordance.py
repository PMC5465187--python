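"""Genotype–phenotype concordance and the discrepancy-rectification workflow.

Accuracy is the percentage of evaluated palms whose predicted fruit form
matches the field phenotype, reported per accession and pooled.  Palms
with a missing observed form or an unscorable genotype are excluded, not
guessed.  Rectification re-tests discrepant palms on an extended variant
panel: a palm misscalled by the initial two-site panel but correctly
called with all five sites is "Corrected"; one still misscalled is a
"Miss" and points to an un-assayed mutation or a phenotyping error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import pandas as pd

from .genotypes import MultiLocusGenotype
from .panel import VariantPanel
from .predictor import (
    FruitForm,
    Prediction,
    predict_copies,
    predict_single_marker,
    segregating_variants,
)


@dataclass
class PalmRecord:
    """One palm: identity, field phenotype and panel genotype."""

    sample_id: str
    accession: str
    observed_form: Optional[FruitForm]
    genotype: Optional[MultiLocusGenotype] = None
    fertility: str = "missing"  # {fertile, sterile, missing}; metadata only


def round_accuracy(n_concordant: int, n_evaluated: int) -> float:
    """Percent concordant, round-half-up to 2 decimals (e.g. 747/752 → 99.34)."""
    if n_evaluated == 0:
        raise ZeroDivisionError("no evaluated records")
    pct = Decimal(100 * n_concordant) / Decimal(n_evaluated)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class AccessionAccuracy:
    accession: str
    method: str
    n_total: int = 0
    n_evaluated: int = 0
    n_excluded: int = 0
    n_concordant: int = 0
    n_ambiguous: int = 0

    @property
    def accuracy_percent(self) -> Optional[float]:
        if self.n_evaluated == 0:
            return None
        return round_accuracy(self.n_concordant, self.n_evaluated)


@dataclass
class AccuracyReport:
    """Per-accession rows (sorted by accession label) plus a pooled TOTAL.

    The pooled accuracy divides total concordant by total evaluated across
    accessions — it is not a mean of accession accuracies.
    """

    rows: List[AccessionAccuracy]
    total: AccessionAccuracy

    def row(self, accession: str) -> AccessionAccuracy:
        for r in self.rows:
            if r.accession == accession:
                return r
        raise KeyError(f"no accession {accession!r} in report")

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for r in self.rows + [self.total]:
            recs.append({
                "accession": r.accession,
                "n_total": r.n_total,
                "n_evaluated": r.n_evaluated,
                "n_excluded": r.n_excluded,
                "n_concordant": r.n_concordant,
                "accuracy_percent": (
                    f"{r.accuracy_percent:.2f}" if r.accuracy_percent is not None else "NA"
                ),
                "method": r.method,
                "n_ambiguous": r.n_ambiguous,
            })
        return pd.DataFrame.from_records(recs)

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def to_dict(self) -> dict:
        def as_dict(r: AccessionAccuracy) -> dict:
            return {
                "accession": r.accession, "method": r.method,
                "n_total": r.n_total, "n_evaluated": r.n_evaluated,
                "n_excluded": r.n_excluded, "n_concordant": r.n_concordant,
                "n_ambiguous": r.n_ambiguous,
                "accuracy_percent": r.accuracy_percent,
            }
        return {"accessions": [as_dict(r) for r in self.rows],
                "total": as_dict(self.total)}


def _predict(record: PalmRecord, panel: VariantPanel, method: str) -> Prediction:
    if record.genotype is None:
        g = MultiLocusGenotype(record.sample_id, {})
    else:
        g = record.genotype
    if method == "copies":
        return predict_copies(g, panel, phase_policy="trans")
    if method.startswith("single:"):
        return predict_single_marker(g, panel, method.split(":", 1)[1])
    raise ValueError(f"unknown prediction method {method!r}")


def _resolve_auto(records: Sequence[PalmRecord], panel: VariantPanel) -> str:
    seg = segregating_variants(
        [r.genotype for r in records if r.genotype is not None], panel
    )
    if len(seg) == 1:
        return f"single:{seg[0]}"
    return "copies"


def evaluate(cohort: Sequence[PalmRecord], panel: VariantPanel,
             method: str = "auto") -> AccuracyReport:
    """Accuracy of fruit-form prediction, per accession and pooled.

    ``method`` is ``"copies"``, ``"single:<variant_id>"`` or ``"auto"``.
    Auto picks the single-marker rule for an accession in which exactly
    one panel variant segregates and the functional-copy model otherwise
    (including monomorphic-wildtype accessions).  Records with a missing
    observed form or an unknown prediction count as excluded.  Ambiguous
    (cis-possible) predictions are scored on their trans-policy call and
    tallied in ``n_ambiguous``.

    Raises ValueError on an empty cohort or when no record is evaluable.
    """
    records = list(cohort)
    if not records:
        raise ValueError("empty cohort")
    by_acc: Dict[str, List[PalmRecord]] = {}
    for r in records:
        by_acc.setdefault(r.accession, []).append(r)

    rows: List[AccessionAccuracy] = []
    total = AccessionAccuracy(accession="TOTAL", method=method)
    for acc in sorted(by_acc):
        group = by_acc[acc]
        acc_method = _resolve_auto(group, panel) if method == "auto" else method
        row = AccessionAccuracy(accession=acc, method=acc_method, n_total=len(group))
        for r in group:
            pred = _predict(r, panel, acc_method)
            if r.observed_form is None or pred.is_unknown:
                row.n_excluded += 1
                continue
            row.n_evaluated += 1
            if pred.ambiguous:
                row.n_ambiguous += 1
            if pred.form == r.observed_form:
                row.n_concordant += 1
        rows.append(row)
        total.n_total += row.n_total
        total.n_evaluated += row.n_evaluated
        total.n_excluded += row.n_excluded
        total.n_concordant += row.n_concordant
        total.n_ambiguous += row.n_ambiguous
    if total.n_evaluated == 0:
        raise ValueError("no evaluable records (all observed forms or predictions missing)")
    return AccuracyReport(rows=rows, total=total)


def find_discrepancies(cohort: Sequence[PalmRecord], panel: VariantPanel,
                       method: str = "copies") -> List[str]:
    """Sample ids whose prediction is known and differs from the observed
    form, in cohort order.  ``method`` as in :func:`evaluate` except that
    ``auto`` resolves per accession."""
    records = list(cohort)
    resolved: Dict[str, str] = {}
    if method == "auto":
        by_acc: Dict[str, List[PalmRecord]] = {}
        for r in records:
            by_acc.setdefault(r.accession, []).append(r)
        resolved = {acc: _resolve_auto(grp, panel) for acc, grp in by_acc.items()}
    out = []
    for r in records:
        m = resolved.get(r.accession, method) if method == "auto" else method
        pred = _predict(r, panel, m)
        if r.observed_form is None or pred.is_unknown:
            continue
        if pred.form != r.observed_form:
            out.append(r.sample_id)
    return out


class RectificationStatus(str, Enum):
    CONCORDANT = "Concordant"
    CORRECTED = "Corrected"
    MISS = "Miss"


@dataclass
class RectifiedSample:
    sample_id: str
    accession: str
    observed_form: FruitForm
    initial: Prediction
    extended: Prediction
    status: RectificationStatus
    note: str = ""


@dataclass
class RectificationOutcome:
    samples: List[RectifiedSample]

    def status_of(self, sample_id: str) -> RectificationStatus:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s.status
        raise KeyError(sample_id)

    def counts(self) -> Dict[RectificationStatus, int]:
        out = {s: 0 for s in RectificationStatus}
        for s in self.samples:
            out[s.status] += 1
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame.from_records([
            {
                "sample_id": s.sample_id,
                "accession": s.accession,
                "observed_form": s.observed_form.value,
                "initial_form": s.initial.form.value if s.initial.form else "unknown",
                "extended_form": s.extended.form.value if s.extended.form else "unknown",
                "extended_ambiguous": s.extended.ambiguous,
                "status": s.status.value,
                "note": s.note,
            }
            for s in self.samples
        ])

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def rectify(cohort: Sequence[PalmRecord], initial_panel: VariantPanel,
            extended_panel: VariantPanel) -> RectificationOutcome:
    """Two-stage re-testing of palms on an extended variant panel.

    Each palm is scored with the functional-copy (trans) model on both
    panels and labelled: Concordant — the initial panel already matches
    the observed form; Corrected — initial mismatch resolved by the
    extended panel; Miss — still mismatched on the extended panel
    (suggesting another, un-assayed heterozygous mutation or a phenotype
    error).  Statuses partition the cohort.
    """
    out = []
    for r in cohort:
        if r.observed_form is None:
            raise ValueError(f"sample {r.sample_id}: observed form required for rectification")
        initial = _predict(r, initial_panel, "copies")
        extended = _predict(r, extended_panel, "copies")
        if initial.form == r.observed_form:
            status = RectificationStatus.CONCORDANT
            note = ""
        elif extended.form == r.observed_form:
            status = RectificationStatus.CORRECTED
            note = "resolved by extended panel"
        else:
            status = RectificationStatus.MISS
            note = "expect another heterozygous mutation"
        out.append(RectifiedSample(
            sample_id=r.sample_id, accession=r.accession,
            observed_form=r.observed_form, initial=initial,
            extended=extended, status=status, note=note,
        ))
    return RectificationOutcome(out)
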