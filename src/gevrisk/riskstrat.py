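"""Child-Pugh scoring and bleeding-risk stratification.

High bleeding risk for esophageal varices (EV) — the indication for
primary prophylaxis — is grade 2-3 varices, or grade 1 varices with red
color signs or Child-Pugh class C.  Two named rule presets are shipped:

``intro``
    high iff grade >= 2, or grade 1 with (RC >= 1 or Child-Pugh C) —
    the guideline formulation including RC; the default.
``methods``
    high iff grade >= 2, or grade 1 with Child-Pugh C — the narrower
    prophylaxis-indication wording without the RC trigger.

Gastric varices (GV) have no universally stated rule; the default mirrors
the EV rule with size big/small in place of grade, and is replaceable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

CHILD_BANDS = {"A": (5, 6), "B": (7, 9), "C": (10, 15)}


@dataclass(frozen=True)
class ChildPugh:
    """Five-component liver-disease severity score.

    Components (each 1-3 points): encephalopathy, ascites, bilirubin band,
    albumin band, coagulation band.  Total 5-15 banded into class A (5-6),
    B (7-9), C (10-15) — the standard clinical cut-offs.
    """

    components: tuple[int, int, int, int, int]
    total: int = field(init=False)
    cls: str = field(init=False)

    def __post_init__(self):
        if len(self.components) != 5 or any(c not in (1, 2, 3) for c in self.components):
            raise ValueError("Child-Pugh needs five component scores in {1, 2, 3}")
        total = int(sum(self.components))
        cls = next(c for c, (lo, hi) in CHILD_BANDS.items() if lo <= total <= hi)
        object.__setattr__(self, "total", total)
        object.__setattr__(self, "cls", cls)


def child_pugh(components: Iterable[int]) -> ChildPugh:
    return ChildPugh(tuple(int(c) for c in components))


@dataclass(frozen=True)
class RiskCall:
    target: str  # EV | GV
    risk: str  # high | low
    basis: tuple[str, ...] = ()  # fired triggers; non-empty iff high


def _check_child(child: str) -> None:
    if child not in ("A", "B", "C"):
        raise ValueError("Child-Pugh class must be A, B or C")


def stratify_ev(grade: int, rc: int, child: str, rule: str = "intro") -> RiskCall:
    """Patient-level EV bleeding-risk call (grade 0 = no varix -> low)."""
    if grade not in (0, 1, 2, 3):
        raise ValueError("grade must be 0 (absent), 1, 2 or 3")
    if rc not in (0, 1, 2, 3):
        raise ValueError("rc must be in 0..3")
    _check_child(child)
    if rule not in ("intro", "methods"):
        raise ValueError("rule must be 'intro' or 'methods'")
    basis = []
    if grade >= 2:
        basis.append("grade>=2")
    if grade == 1 and rule == "intro" and rc >= 1:
        basis.append("grade1+RC")
    if grade == 1 and child == "C":
        basis.append("grade1+childC")
    return RiskCall("EV", "high" if basis else "low", tuple(basis))


def stratify_gv(size: str, rc: int, child: str) -> RiskCall:
    """Patient-level GV risk call, mirroring the EV rule on size big/small."""
    if size not in ("absent", "small", "big"):
        raise ValueError("size must be absent, small or big")
    if rc not in (0, 1):
        raise ValueError("GV rc must be 0 or 1")
    _check_child(child)
    basis = []
    if size == "big":
        basis.append("size_big")
    if size == "small" and rc == 1:
        basis.append("small+RC")
    if size == "small" and child == "C":
        basis.append("small+childC")
    return RiskCall("GV", "high" if basis else "low", tuple(basis))


@dataclass
class CohortStratification:
    calls: pd.DataFrame  # per patient: target, true risk, called risk
    confusion: dict  # target -> 2x2 counts array [[hh, hl], [lh, ll]]
    excluded: list[str] = field(default_factory=list)

    def confusion_table(self, target: str) -> pd.DataFrame:
        """Counts with percentages of the total, gold rows x called cols."""
        m = np.asarray(self.confusion[target])
        total = m.sum()
        rows = []
        for i, gold in enumerate(("High risk", "Low risk")):
            row = {"gold": gold}
            for j, called in enumerate(("High risk", "Low risk")):
                pct = 100.0 * m[i, j] / total if total else 0.0
                row[called] = f"{m[i, j]} ({pct:.2f})"
            rows.append(row)
        return pd.DataFrame(rows).set_index("gold")


def stratify_cohort(
    reports_and_patients: Iterable[tuple],
    rule: str = "intro",
) -> CohortStratification:
    """Risk-call every patient from their exam report and tabulate vs truth.

    Takes (ExamReport, PatientRecord) pairs; patients without varices of a
    family (true risk 'none') are excluded from that family's confusion
    table.  Patients with missing Child-Pugh data are skipped entirely and
    logged in ``excluded``.
    """
    records = []
    excluded = []
    confusion = {"EV": np.zeros((2, 2), int), "GV": np.zeros((2, 2), int)}
    for report, patient in reports_and_patients:
        if not getattr(patient, "child_class", None):
            excluded.append(patient.patient_id)
            continue
        labels = report.final_labels
        ev_call = stratify_ev(labels["ev_grade"], labels["rc_ev"], patient.child_class, rule)
        gv_call = stratify_gv(labels["gv_size"], labels["rc_gv"], patient.child_class)
        for target, call, truth in (
            ("EV", ev_call, patient.true_ev_risk),
            ("GV", gv_call, patient.true_gv_risk),
        ):
            records.append(
                {"patient_id": patient.patient_id, "target": target,
                 "true_risk": truth, "called_risk": call.risk,
                 "basis": ";".join(call.basis)}
            )
            if truth in ("high", "low"):
                i = 0 if truth == "high" else 1
                j = 0 if call.risk == "high" else 1
                confusion[target][i, j] += 1
    return CohortStratification(
        calls=pd.DataFrame(records), confusion=confusion, excluded=excluded
    )
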