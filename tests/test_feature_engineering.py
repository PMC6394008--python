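"""Code abstraction, cut-offs, monthly binning, normalization, windows."""

import datetime
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lifehorizon.emr_data import (
    CodedEvent,
    Cohort,
    Consultation,
    EventCategory,
    LabFlag,
    LabResult,
    PatientRecord,
    Sex,
)
from lifehorizon.feature_engineering import (
    AbstractionLevel,
    CutoffMethod,
    DEFAULT_CATEGORY_CONFIG,
    FeatureVocabulary,
    abstract_code,
    apply_cutoff,
    bin_monthly,
    build_vocabulary,
    clean_medication,
    extract_windows,
    filter_lab,
    load_element_table,
    normalize_monthly,
)


class TestAbstractCode:
    @pytest.mark.parametrize(
        "level,expected",
        [
            (AbstractionLevel.FULL, "D84.02"),
            (AbstractionLevel.LETTER_NUMBER, "D84"),
            (AbstractionLevel.LETTER, "D"),
        ],
    )
    def test_levels(self, level, expected):
        assert abstract_code("D84.02", level) == expected

    def test_letter_element(self):
        table = {84: "standard procedure"}
        assert (
            abstract_code("D84.02", AbstractionLevel.LETTER_ELEMENT, table)
            == "D+standard procedure"
        )

    def test_element_missing_is_error(self):
        with pytest.raises(KeyError, match="D84.02"):
            abstract_code("D84.02", AbstractionLevel.ELEMENT, {1: "x"})

    def test_shipped_element_table_covers_icpc_components(self):
        table = load_element_table()
        assert table[84] and set(table) == set(range(1, 100))


class TestCleanMedication:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("paracetamol 500mg 3dd", "paracetamol"),
            ("metoprolol", "metoprolol"),
            ("  insuline  ", "insuline"),
            ("furosemide 40mg zo nodig", "furosemide"),
            ("morfine 10mg 2dd", "morfine"),
        ],
    )
    def test_examples(self, raw, expected):
        assert clean_medication(raw) == expected


class TestFilterLab:
    @pytest.mark.parametrize(
        "flag,kept",
        [(LabFlag.NORMAL, False), (LabFlag.IRREGULAR, True), (LabFlag.ABNORMAL, True)],
    )
    def test_flags(self, flag, kept):
        assert filter_lab(LabResult("HB", "1", flag)) is kept


def _coverage_oracle(counts: dict[str, float]) -> set[str]:
    """Enumerate drop sets over all count-ascending orders; keep the set
    dropping the most mass within 25%, resolving ties by dropping the
    lexicographically larger features."""
    total = sum(counts.values())
    feasible = []
    for perm in itertools.permutations(counts):
        if any(counts[perm[i]] > counts[perm[i + 1]] for i in range(len(perm) - 1)):
            continue  # not count-ascending
        mass = 0.0
        drop = []
        for f in perm:
            if mass + counts[f] > 0.25 * total:
                break
            mass += counts[f]
            drop.append(f)
        feasible.append(frozenset(drop))
    best_size = max(len(s) for s in feasible)
    candidates = [s for s in feasible if len(s) == best_size]
    # prefer dropping lexicographically larger features
    drop = max(candidates, key=lambda s: sorted(s, reverse=True))
    return set(counts) - drop


class TestApplyCutoff:
    def test_absolute_100(self):
        assert apply_cutoff({"a": 150, "b": 99}, CutoffMethod.ABSOLUTE_100) == {"a"}

    def test_relative_1pct_boundary_kept(self):
        assert apply_cutoff({"a": 99, "b": 1}, CutoffMethod.RELATIVE_1PCT) == {"a", "b"}

    def test_bottom_coverage_example(self):
        counts = {"a": 70, "b": 20, "c": 6, "d": 4}
        assert apply_cutoff(counts, CutoffMethod.BOTTOM_25PCT_COVERAGE) == {"a", "b"}

    def test_none_keeps_all(self):
        assert apply_cutoff({"a": 1}, CutoffMethod.NONE) == {"a"}

    def test_empty_counts(self):
        assert apply_cutoff({}, CutoffMethod.ABSOLUTE_100) == set()

    @given(
        st.dictionaries(
            st.sampled_from("abcdefg"),
            st.integers(min_value=1, max_value=40),
            min_size=1,
            max_size=6,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_coverage_matches_enumeration_oracle(self, counts):
        counts = {k: float(v) for k, v in counts.items()}
        assert apply_cutoff(counts, CutoffMethod.BOTTOM_25PCT_COVERAGE) == _coverage_oracle(counts)

    @given(
        st.dictionaries(
            st.sampled_from("abcde"),
            st.integers(min_value=0, max_value=500),
            min_size=1,
            max_size=5,
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_relative_matches_direct_rule(self, counts):
        total = sum(counts.values()) or 1
        expected = {f for f, c in counts.items() if c / total >= 0.01 and total > 0}
        if sum(counts.values()) == 0:
            expected = set()
        assert apply_cutoff(dict(counts), CutoffMethod.RELATIVE_1PCT) == expected


def _toy_cohort(n_events: int) -> Cohort:
    death = datetime.date(2018, 1, 1)
    patients = []
    for i in range(n_events):
        patients.append(
            PatientRecord(
                patient_id=f"T{i:04d}",
                sex=Sex.FEMALE,
                birth_date=datetime.date(1940, 1, 1),
                death_date=death,
                consultations=[
                    Consultation(
                        date=death - datetime.timedelta(days=10),
                        consultation_type="visit",
                        events=[CodedEvent(EventCategory.DIAGNOSIS_ICPC, "D84.02")],
                    )
                ],
            )
        )
    return Cohort(patients)


class TestBuildVocabulary:
    def test_abstracted_code_kept_above_cutoff(self):
        vocab = build_vocabulary(_toy_cohort(150))
        assert ("diagnosis_icpc", "D84") in vocab.index

    def test_below_cutoff_excluded(self):
        vocab = build_vocabulary(_toy_cohort(99))
        assert ("diagnosis_icpc", "D84") not in vocab.index

    def test_empty_cohort(self):
        assert len(build_vocabulary(Cohort())) == 0

    def test_missing_category_config_is_error(self):
        cfg = {k: v for k, v in DEFAULT_CATEGORY_CONFIG.items() if k != "lab"}
        with pytest.raises(ValueError, match="lab"):
            build_vocabulary(Cohort(), cfg)

    def test_tsv_round_trip(self, tmp_path, small_generated_cohort):
        vocab = build_vocabulary(small_generated_cohort, _no_cutoff())
        vocab.to_tsv(tmp_path / "v.tsv")
        again = FeatureVocabulary.from_tsv(tmp_path / "v.tsv")
        assert again.entries == vocab.entries


def _no_cutoff():
    return {k: (v[0], CutoffMethod.NONE) for k, v in DEFAULT_CATEGORY_CONFIG.items()}


class TestBinMonthly:
    def test_single_event_lands_in_bin_60(self, one_patient):
        vocab = FeatureVocabulary([("diagnosis_icpc", "D84")])
        vectors = bin_monthly(one_patient, vocab)
        assert len(vectors) == 61
        counts = {v.month: v.values[0] for v in vectors if v.values[0]}
        assert counts == {60: 1.0}

    def test_no_events_all_zero(self, one_patient):
        one_patient.consultations.clear()
        vocab = FeatureVocabulary([("diagnosis_icpc", "D84")])
        vectors = bin_monthly(one_patient, vocab)
        assert all(v.values.sum() == 0 for v in vectors)

    def test_count_conservation(self, small_generated_cohort):
        cfg = _no_cutoff()
        vocab = build_vocabulary(small_generated_cohort, cfg)
        for patient in small_generated_cohort.patients[:5]:
            vectors = bin_monthly(patient, vocab, cfg)
            total = sum(v.values.sum() for v in vectors)
            expected = sum(
                1  # consultation type
                + len(c.events)
                + sum(filter_lab(lb) for lb in c.labs)
                + len(c.medications)
                for c in patient.consultations
            )
            assert total == expected


class TestNormalize:
    def test_max_division_within_category(self):
        vocab = FeatureVocabulary([("diagnosis_icpc", c) for c in ("A", "B", "C")])
        from lifehorizon.feature_engineering import MonthlyVector

        vectors = [MonthlyVector(m, np.zeros(3)) for m in range(1, 62)]
        vectors[0].values[:] = (2, 4, 0)
        out = normalize_monthly(vectors, vocab)
        assert out[0].values.tolist() == [0.5, 1.0, 0.0]

    def test_all_zero_month_stays_zero(self, one_patient):
        vocab = FeatureVocabulary([("diagnosis_icpc", "D84")])
        out = normalize_monthly(bin_monthly(one_patient, vocab), vocab)
        assert out[0].values.sum() == 0

    def test_bounds_and_block_maxima(self, small_generated_cohort):
        cfg = _no_cutoff()
        vocab = build_vocabulary(small_generated_cohort, cfg)
        patient = small_generated_cohort.patients[0]
        out = normalize_monthly(bin_monthly(patient, vocab, cfg), vocab)
        matrix = np.stack([v.values for v in out])
        assert matrix.min() >= 0 and matrix.max() <= 1
        for sl in vocab.category_slices.values():
            block = matrix[:, sl]
            if block.shape[1] == 0:
                continue
            row_max = block.max(axis=1)
            assert np.all((row_max == 0) | (row_max == 1))

    def test_per_history_switch(self, one_patient):
        vocab = FeatureVocabulary([("diagnosis_icpc", "D84")])
        raw = bin_monthly(one_patient, vocab)
        out = normalize_monthly(raw, vocab, per_history=True)
        assert max(v.values.max() for v in out) == 1.0


class TestExtractWindows:
    def test_labels_bijective_onto_1_50(self, one_patient):
        vocab = FeatureVocabulary([("diagnosis_icpc", "D84")])
        vectors = bin_monthly(one_patient, vocab)
        windows = extract_windows(vectors, one_patient.patient_id)
        assert sorted(w.label for w in windows) == list(range(1, 51))

    def test_windows_are_contiguous_months(self, one_patient):
        vocab = FeatureVocabulary([("diagnosis_icpc", "D84")])
        vectors = bin_monthly(one_patient, vocab)
        for w in extract_windows(vectors, one_patient.patient_id):
            assert w.vectors.shape == (10, 1)

    def test_short_history_is_error(self):
        from lifehorizon.feature_engineering import MonthlyVector

        vectors = [MonthlyVector(m, np.zeros(1)) for m in range(1, 6)]
        with pytest.raises(ValueError, match="shorter"):
            extract_windows(vectors, "X")
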