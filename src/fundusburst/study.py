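"""Paired two-camera study evaluation: image selection for grading, 3-grader
majority vote, proportions of clinically interpretable images, the QC-versus-
gradability 2x2 contingency table, and the phi coefficient.

Two distinct binary grader judgments are kept apart throughout: "sufficient
quality for clinical interpretation" (the comparative-performance endpoint)
and "gradable" (the QC-concordance endpoint).  They are separate columns in
the CSV schema and never conflated.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic import SessionTable

__all__ = [
    "Camera",
    "QCDecision",
    "EyeRecord",
    "Contingency2x2",
    "select_image_for_grading",
    "majority_vote",
    "proportion_sufficient",
    "build_contingency",
    "phi_coefficient",
    "records_from_session",
    "select_from_session",
    "eligible_paired_records",
    "records_to_frame",
]


class Camera(str, enum.Enum):
    INVESTIGATIONAL = "investigational"
    REFERENCE = "reference"


class QCDecision(str, enum.Enum):
    PASS = "PASS"
    RECAPTURE_NEEDED = "RECAPTURE_NEEDED"
    NA = "NA"


@dataclass(frozen=True)
class EyeRecord:
    """One graded eye image: the unit of analysis.

    ``participant_id`` is the cluster unit for the bootstrap.  Exactly three
    grader labels per judgment; the analysis label is their majority.
    ``grader_gradable`` may be None when only the sufficiency endpoint was
    annotated.
    """

    participant_id: str
    eye: str
    camera: Camera
    selected_image_id: str
    qc_decision: QCDecision
    grader_sufficient: tuple[bool, bool, bool] | None = None
    grader_gradable: tuple[bool, bool, bool] | None = None

    def __post_init__(self) -> None:
        for name, labels in (("grader_sufficient", self.grader_sufficient),
                             ("grader_gradable", self.grader_gradable)):
            if labels is not None and len(labels) != 3:
                raise ValueError(f"{name} must hold exactly 3 labels, got {len(labels)}")

    @property
    def majority_sufficient(self) -> bool:
        return majority_vote(self.grader_sufficient)

    @property
    def majority_gradable(self) -> bool:
        return majority_vote(self.grader_gradable)


def majority_vote(labels: Sequence[bool]) -> bool:
    """Mode of exactly 3 binary grader labels."""
    if labels is None or len(labels) != 3:
        raise ValueError("majority vote requires exactly 3 labels")
    return sum(bool(x) for x in labels) >= 2


def select_image_for_grading(acquisitions: Sequence[tuple[str, bool]], camera: Camera | str) -> str:
    """Pick the image sent to graders for one (participant, eye, camera).

    ``acquisitions`` is the time-ordered list of (image_id, qc_passed) for up
    to 3 attempts.  Reference camera: graders receive the last image
    acquired.  Investigational camera: the first image that passed QC, or the
    last acquired if none passed.
    """
    if not acquisitions:
        raise ValueError("no acquisitions for this eye; it is excluded")
    if len(acquisitions) > 3:
        raise ValueError("at most 3 acquisitions per eye and camera")
    camera = Camera(camera)
    if camera is Camera.REFERENCE:
        return acquisitions[-1][0]
    for image_id, passed in acquisitions:
        if passed:
            return image_id
    return acquisitions[-1][0]


def proportion_sufficient(records: Iterable[EyeRecord], camera: Camera | str) -> dict:
    """k, n and k/n of majority-sufficient images for one camera."""
    camera = Camera(camera)
    sub = [r for r in records if r.camera == camera and r.grader_sufficient is not None]
    if not sub:
        raise ValueError(f"no graded records for camera {camera.value}")
    k = sum(r.majority_sufficient for r in sub)
    n = len(sub)
    return {"k": k, "n": n, "proportion": k / n}


@dataclass(frozen=True)
class Contingency2x2:
    """QC decision (rows) versus majority gradability (columns).

    a = recapture-needed & nongradable, b = recapture-needed & gradable,
    c = pass & nongradable, d = pass & gradable.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total == 0:
            raise ValueError("contingency table must hold at least one record")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    def row_fractions(self) -> dict[str, float]:
        out = {}
        if self.a + self.b:
            out["recapture_gradable"] = self.b / (self.a + self.b)
        if self.c + self.d:
            out["pass_gradable"] = self.d / (self.c + self.d)
        return out

    def column_fractions(self) -> dict[str, float]:
        out = {}
        if self.a + self.c:
            out["nongradable_recapture"] = self.a / (self.a + self.c)
        if self.b + self.d:
            out["gradable_recapture"] = self.b / (self.b + self.d)
        return out


def build_contingency(records: Iterable[EyeRecord]) -> Contingency2x2:
    """Cross-tabulate QC decision against majority gradability.

    Every record must carry a non-NA QC decision and gradability labels;
    offenders are listed in the error.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to tabulate")
    bad = [r.selected_image_id or f"{r.participant_id}/{r.eye}/{r.camera.value}"
           for r in records
           if r.qc_decision is QCDecision.NA or r.grader_gradable is None]
    if bad:
        raise ValueError(f"records lacking QC decision or gradability labels: {bad}")
    a = b = c = d = 0
    for r in records:
        gradable = r.majority_gradable
        if r.qc_decision is QCDecision.RECAPTURE_NEEDED:
            b += gradable
            a += not gradable
        else:
            d += gradable
            c += not gradable
    return Contingency2x2(a=a, b=b, c=c, d=d)


def phi_coefficient(table: Contingency2x2) -> float:
    """phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)).

    Equals the Pearson correlation of the two 0/1 codings; positive when QC
    pass aligns with gradable.  Undefined (error) when any marginal is zero.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError(f"phi undefined: zero marginal in {margins}")
    return (a * d - b * c) / math.sqrt(math.prod(margins))


# ---------------------------------------------------------------------------
# session-table plumbing


def select_from_session(session: SessionTable | pd.DataFrame) -> pd.DataFrame:
    """Apply the grading-selection rule to an acquisition-level session table.

    Returns one row per captured (participant, eye, camera) with the selected
    acquisition's QC decision and that eye-camera's grader labels.
    """
    df = session.df if isinstance(session, SessionTable) else session
    df = df[df["capture_success"].astype(bool)]
    if df.empty:
        return df.copy()
    keys = ["participant_id", "eye", "camera"]
    df = df.sort_values(keys + ["acquisition_index"], kind="stable")

    ref = df[df["camera"] == Camera.REFERENCE.value].groupby(keys).tail(1)
    inv = df[df["camera"] == Camera.INVESTIGATIONAL.value]
    first_pass = inv[inv["qc_pass"] == 1.0].groupby(keys).head(1)
    passed_keys = set(map(tuple, first_pass[keys].to_numpy()))
    has_pass = inv[keys].apply(tuple, axis=1).isin(passed_keys) if len(inv) else []
    fallback = inv[~np.asarray(has_pass, dtype=bool)].groupby(keys).tail(1) if len(inv) else inv
    out = pd.concat([ref, first_pass, fallback], ignore_index=True)
    return out.sort_values(keys, kind="stable").reset_index(drop=True)


def records_from_session(session: SessionTable | pd.DataFrame) -> list[EyeRecord]:
    """Selected :class:`EyeRecord` list for a simulated session."""
    sel = select_from_session(session)
    records = []
    for _, row in sel.iterrows():
        suff = tuple(bool(row[f"grader{g}_sufficient"]) for g in (1, 2, 3))
        grad = tuple(bool(row[f"grader{g}_gradable"]) for g in (1, 2, 3))
        qc = QCDecision.PASS if row["qc_pass"] == 1.0 else QCDecision.RECAPTURE_NEEDED
        records.append(EyeRecord(
            participant_id=row["participant_id"], eye=row["eye"],
            camera=Camera(row["camera"]),
            selected_image_id=(f"{row['participant_id']}-{row['eye']}-"
                               f"{row['camera']}-{int(row['acquisition_index'])}"),
            qc_decision=qc, grader_sufficient=suff, grader_gradable=grad))
    return records


def eligible_paired_records(records: Iterable[EyeRecord]) -> list[EyeRecord]:
    """Restrict to eyes graded on both cameras (comparative-analysis
    eligibility): eyes captured or annotated on only one camera are dropped."""
    records = list(records)
    graded: dict[tuple[str, str], set[str]] = {}
    for r in records:
        if r.grader_sufficient is not None:
            graded.setdefault((r.participant_id, r.eye), set()).add(r.camera.value)
    keep = {k for k, cams in graded.items() if len(cams) == 2}
    return [r for r in records
            if (r.participant_id, r.eye) in keep and r.grader_sufficient is not None]


def records_to_frame(records: Iterable[EyeRecord]) -> pd.DataFrame:
    """Tidy frame of records (one row per graded eye image)."""
    rows = []
    for r in records:
        row = {
            "participant_id": r.participant_id, "eye": r.eye,
            "camera": r.camera.value, "selected_image_id": r.selected_image_id,
            "qc_decision": r.qc_decision.value,
        }
        for g in range(3):
            row[f"grader{g + 1}_sufficient"] = (
                None if r.grader_sufficient is None else bool(r.grader_sufficient[g]))
            row[f"grader{g + 1}_gradable"] = (
                None if r.grader_gradable is None else bool(r.grader_gradable[g]))
        rows.append(row)
    return pd.DataFrame(rows)
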