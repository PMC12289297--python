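"""Selection rule, majority vote, proportions, contingency table and phi."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fundusburst import (
    Camera,
    Contingency2x2,
    EyeRecord,
    QCDecision,
    build_contingency,
    majority_vote,
    phi_coefficient,
    proportion_sufficient,
    select_image_for_grading,
)
from fundusburst.fixtures import comparative_records, concordance_records
from fundusburst.study import eligible_paired_records, records_from_session
from fundusburst.synthetic import simulate_session


def _rec(pid="P1", eye="R", camera=Camera.INVESTIGATIONAL, qc=QCDecision.PASS,
         suff=None, grad=None, image="img"):
    return EyeRecord(participant_id=pid, eye=eye, camera=camera,
                     selected_image_id=image, qc_decision=qc,
                     grader_sufficient=suff, grader_gradable=grad)


class TestSelection:
    def test_investigational_takes_first_qc_pass(self):
        acq = [("a1", False), ("a2", True), ("a3", True)]
        assert select_image_for_grading(acq, Camera.INVESTIGATIONAL) == "a2"

    def test_investigational_falls_back_to_last(self):
        acq = [("a1", False), ("a2", False), ("a3", False)]
        assert select_image_for_grading(acq, Camera.INVESTIGATIONAL) == "a3"

    def test_reference_takes_last_acquired(self):
        acq = [("a1", True), ("a2", False)]
        assert select_image_for_grading(acq, Camera.REFERENCE) == "a2"

    def test_empty_acquisitions_error(self):
        with pytest.raises(ValueError, match="excluded"):
            select_image_for_grading([], Camera.REFERENCE)

    def test_more_than_three_error(self):
        with pytest.raises(ValueError, match="3"):
            select_image_for_grading([("a", True)] * 4, Camera.REFERENCE)


class TestMajorityVote:
    @pytest.mark.parametrize("labels,expected", [
        ((True, True, False), True),
        ((False, False, False), False),
        ((True, False, False), False),
        ((True, True, True), True),
    ])
    def test_mode_of_three(self, labels, expected):
        assert majority_vote(labels) is expected

    def test_wrong_arity_errors(self):
        with pytest.raises(ValueError):
            majority_vote((True, False))


class TestProportions:
    def test_comparative_fixture_proportions(self):
        records = comparative_records()
        inv = proportion_sufficient(records, "investigational")
        ref = proportion_sufficient(records, "reference")
        assert (inv["k"], inv["n"]) == (203, 206)
        assert (ref["k"], ref["n"]) == (200, 206)
        assert round(inv["proportion"], 3) == 0.985
        assert round(ref["proportion"], 3) == 0.971

    def test_all_no_gives_zero(self):
        records = [_rec(pid=f"P{i}", suff=(False, False, False)) for i in range(5)]
        assert proportion_sufficient(records, "investigational")["proportion"] == 0.0

    def test_brute_force_count_matches(self):
        records = comparative_records()
        for cam in ("investigational", "reference"):
            got = proportion_sufficient(records, cam)
            brute = [sum(r.grader_sufficient) >= 2 for r in records
                     if r.camera.value == cam]
            assert got["k"] == sum(brute) and got["n"] == len(brute)

    def test_no_records_errors(self):
        with pytest.raises(ValueError):
            proportion_sufficient([], "reference")


class TestContingency:
    def test_concordance_fixture_cells(self):
        table = build_contingency(concordance_records())
        assert (table.a, table.b, table.c, table.d) == (20, 30, 1, 292)
        assert table.total == 343

    def test_one_record_per_cell(self):
        records = [
            _rec(pid="P1", qc=QCDecision.RECAPTURE_NEEDED, grad=(False,) * 3),
            _rec(pid="P2", qc=QCDecision.RECAPTURE_NEEDED, grad=(True,) * 3),
            _rec(pid="P3", qc=QCDecision.PASS, grad=(False,) * 3),
            _rec(pid="P4", qc=QCDecision.PASS, grad=(True,) * 3),
        ]
        table = build_contingency(records)
        assert (table.a, table.b, table.c, table.d) == (1, 1, 1, 1)

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            build_contingency([])

    def test_na_decision_lists_offenders(self):
        records = [_rec(qc=QCDecision.NA, grad=(True,) * 3, image="bad-image")]
        with pytest.raises(ValueError, match="bad-image"):
            build_contingency(records)

    def test_cells_sum_to_record_count(self):
        sess = simulate_session(40, seed=5)
        records = [r for r in records_from_session(sess)
                   if r.grader_gradable is not None]
        table = build_contingency(records)
        assert table.total == len(records)


class TestPhi:
    def test_published_cells_round_to_058(self):
        phi = phi_coefficient(Contingency2x2(20, 30, 1, 292))
        assert round(phi, 2) == 0.58

    def test_perfect_association(self):
        assert phi_coefficient(Contingency2x2(5, 0, 0, 5)) == pytest.approx(1.0)

    def test_independence(self):
        assert phi_coefficient(Contingency2x2(10, 10, 10, 10)) == pytest.approx(0.0)

    def test_zero_marginal_errors(self):
        with pytest.raises(ValueError, match="marginal"):
            phi_coefficient(Contingency2x2(0, 0, 5, 5))

    @given(a=st.integers(0, 50), b=st.integers(0, 50),
           c=st.integers(0, 50), d=st.integers(0, 50))
    @settings(max_examples=200, derandomize=True)
    def test_phi_equals_pearson_of_binary_codings(self, a, b, c, d):
        margins = [(a + b), (c + d), (a + c), (b + d)]
        if any(m == 0 for m in margins):
            return
        table = Contingency2x2(a, b, c, d)
        phi = phi_coefficient(table)
        assert -1.0 <= phi <= 1.0
        # brute-force oracle: Pearson correlation over the expanded records
        x = np.repeat([1, 1, 0, 0], [a, b, c, d])  # recapture-needed coding
        y = np.repeat([0, 1, 0, 1], [a, b, c, d])  # gradable coding
        pearson = np.corrcoef(x, y)[0, 1]
        # phi is positive when pass aligns with gradable: x codes recapture
        assert phi == pytest.approx(-pearson, abs=1e-12)

    @given(a=st.integers(1, 50), b=st.integers(1, 50),
           c=st.integers(1, 50), d=st.integers(1, 50))
    @settings(max_examples=100, derandomize=True)
    def test_phi_symmetries(self, a, b, c, d):
        phi = phi_coefficient(Contingency2x2(a, b, c, d))
        both_swapped = phi_coefficient(Contingency2x2(d, c, b, a))
        rows_swapped = phi_coefficient(Contingency2x2(c, d, a, b))
        assert phi == pytest.approx(both_swapped, abs=1e-12)
        assert phi == pytest.approx(-rows_swapped, abs=1e-12)


class TestSessionRecords:
    def test_eligible_records_are_fully_paired(self):
        sess = simulate_session(60, seed=9)
        records = eligible_paired_records(records_from_session(sess))
        cams = {}
        for r in records:
            cams.setdefault((r.participant_id, r.eye), set()).add(r.camera)
        assert all(len(v) == 2 for v in cams.values())

    def test_at_most_one_record_per_eye_camera(self):
        sess = simulate_session(60, seed=9)
        records = records_from_session(sess)
        keys = [(r.participant_id, r.eye, r.camera) for r in records]
        assert len(keys) == len(set(keys))
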