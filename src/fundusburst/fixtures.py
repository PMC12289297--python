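"""Packaged study tables as record-level fixtures.

The published comparative study reports only aggregate counts; these
functions expand them into deterministic record-level datasets with the
declared cluster structure so that every summary (proportions, contingency
cells, phi) can be recomputed from records rather than asserted.

Which particular eyes carry the minority outcomes is not published; the
assignment here is an arbitrary fixed choice (first records in participant
order) and is irrelevant to every aggregate statistic computed from these
fixtures.  The participant-to-eye allocation (how many contribute two eyes)
is likewise reconstructed from the totals, not published.
"""

from __future__ import annotations

from .study import Camera, EyeRecord, QCDecision

__all__ = [
    "comparative_records",
    "concordance_records",
    "COMPARATIVE_N_PARTICIPANTS",
    "COMPARATIVE_N_EYES",
    "CONCORDANCE_N_PARTICIPANTS",
    "CONCORDANCE_N_EYES",
]

# comparative performance: 108 participants, 206 eyes per camera,
# 203/206 majority-sufficient (investigational) vs 200/206 (reference)
COMPARATIVE_N_PARTICIPANTS = 108
COMPARATIVE_N_EYES = 206
_COMPARATIVE_YES = {"investigational": 203, "reference": 200}

# QC concordance: 172 participants, 343 images;
# cells (recapture & nongradable, recapture & gradable, pass & nongradable,
# pass & gradable) = (20, 30, 1, 292)
CONCORDANCE_N_PARTICIPANTS = 172
CONCORDANCE_N_EYES = 343
_CONCORDANCE_CELLS = (20, 30, 1, 292)

_YES = (True, True, True)
_NO = (False, False, False)


def _eye_slots(n_participants: int, n_eyes: int) -> list[tuple[str, str]]:
    """(participant, eye) slots: the first participants contribute both eyes."""
    n_both = n_eyes - n_participants
    if not (0 <= n_both <= n_participants):
        raise ValueError("inconsistent participant/eye totals")
    slots = []
    for j in range(n_participants):
        pid = f"P{j + 1:04d}"
        slots.append((pid, "R"))
        if j < n_both:
            slots.append((pid, "L"))
    return slots


def comparative_records() -> list[EyeRecord]:
    """Paired records reproducing the comparative-performance totals."""
    slots = _eye_slots(COMPARATIVE_N_PARTICIPANTS, COMPARATIVE_N_EYES)
    records = []
    for camera in (Camera.INVESTIGATIONAL, Camera.REFERENCE):
        n_no = COMPARATIVE_N_EYES - _COMPARATIVE_YES[camera.value]
        # minority outcomes on disjoint leading slots per camera
        no_idx = set(range(n_no)) if camera is Camera.INVESTIGATIONAL \
            else set(range(3, 3 + n_no))
        for i, (pid, eye) in enumerate(slots):
            records.append(EyeRecord(
                participant_id=pid, eye=eye, camera=camera,
                selected_image_id=f"{pid}-{eye}-{camera.value}",
                qc_decision=QCDecision.NA,
                grader_sufficient=_NO if i in no_idx else _YES))
    return records


def concordance_records() -> list[EyeRecord]:
    """Records reproducing the QC-versus-gradability contingency cells."""
    a, b, c, d = _CONCORDANCE_CELLS
    slots = _eye_slots(CONCORDANCE_N_PARTICIPANTS, CONCORDANCE_N_EYES)
    records = []
    for i, (pid, eye) in enumerate(slots):
        if i < a:
            qc, grad = QCDecision.RECAPTURE_NEEDED, _NO
        elif i < a + b:
            qc, grad = QCDecision.RECAPTURE_NEEDED, _YES
        elif i < a + b + c:
            qc, grad = QCDecision.PASS, _NO
        else:
            qc, grad = QCDecision.PASS, _YES
        records.append(EyeRecord(
            participant_id=pid, eye=eye, camera=Camera.INVESTIGATIONAL,
            selected_image_id=f"{pid}-{eye}-investigational",
            qc_decision=qc, grader_gradable=grad))
    return records
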