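import numpy as np
import pytest

from tadfminer.document import read_document
from tadfminer.ontology import Quantity
from tadfminer.parsers import CandidateRecord, Provenance
from tadfminer.postprocess import (PHYSICAL_RANGES, build_classifier_context,
                                   classify_is_experimental, clean_records,
                                   filter_physical_range, keyword_classifier,
                                   standardize_temperature)


def _rec(pid, std, unit="", extra=None, cell=None):
    return CandidateRecord(
        property_id=pid, quantity=Quantity(list(std), unit),
        standard_value=list(std), extra=dict(extra or {}),
        provenance=Provenance("d", 1, 0 if cell is None else None, cell,
                              "sentence_parser"))


class TestRangeFilter:
    @pytest.mark.parametrize("pid,value,keep", [
        ("lambda_em", 250.0, False),   # below exclusive lower bound
        ("lambda_em", 300.0, False),   # boundary excluded
        ("lambda_em", 470.0, True),
        ("lambda_em", 1600.0, False),
        ("plqy", 0.0, True),           # inclusive boundary
        ("plqy", 100.0, True),         # inclusive boundary
        ("plqy", 100.1, False),
        ("delta_e_st", -0.2, True),
        ("delta_e_st", -1.5, False),
        ("delta_e_st", 1.5, False),
        ("tau_d", 0.05, False),        # 50 ns, below 100 ns
        ("tau_d", 3.2, True),
        ("tau_d", 1.0e7, False),       # 10 s, boundary excluded
    ])
    def test_bounds(self, pid, value, keep):
        assert filter_physical_range(_rec(pid, [value]))[0] is keep

    def test_idempotent(self):
        rec = _rec("plqy", [68.0])
        first = filter_physical_range(rec)
        assert filter_physical_range(rec) == first

    def test_randomized_survivors_satisfy_bounds(self, models):
        rng = np.random.default_rng(3)
        span = {"lambda_em": (0, 2000), "plqy": (-50, 150),
                "delta_e_st": (-3, 3), "tau_d": (1e-3, 1e8)}
        for pid, (lo, hi) in span.items():
            low, high, inclusive = PHYSICAL_RANGES[pid]
            for v in rng.uniform(lo, hi, size=200):
                keep, _ = filter_physical_range(_rec(pid, [float(v)]))
                expected = low <= v <= high if inclusive else low < v < high
                assert keep == expected


class TestTemperature:
    def test_rt_flag_becomes_293(self):
        rec = standardize_temperature(_rec("tau_d", [3.2], extra={"rt_flag": True}))
        assert rec.extra["temperature"] == 293.0

    def test_explicit_wins_over_flag(self):
        rec = standardize_temperature(
            _rec("tau_d", [3.2], extra={"rt_flag": True, "temperature_K": 77.0}))
        assert rec.extra["temperature"] == 77.0

    def test_absent_info_leaves_field_absent(self):
        rec = standardize_temperature(_rec("tau_d", [3.2]))
        assert "temperature" not in rec.extra

    def test_nonphysical_temperature_drops(self):
        assert standardize_temperature(
            _rec("tau_d", [3.2], extra={"temperature_K": -5.0})) is None

    def test_other_properties_never_gain_temperature(self, models):
        recs = [_rec("plqy", [68.0], "%", extra={"rt_flag": True}),
                _rec("lambda_em", [470.0], "nm", extra={"rt_flag": True})]
        cleaned = clean_records(recs, models)
        assert all("temperature" not in r.extra for r in cleaned)


class TestClassifier:
    def _doc(self, tmp_path):
        markup = (
            "<article><section><h>Photophysical properties</h>"
            "<p>All emitters were measured in toluene. "
            "The ΔEST of 2CzPN is 0.09 eV.</p></section></article>")
        path = tmp_path / "c.xml"
        path.write_text(markup, encoding="utf-8")
        return read_document(path, "xml-like")

    def test_three_part_context(self, tmp_path):
        doc = self._doc(tmp_path)
        rec = _rec("delta_e_st", [0.09],
                   extra={"source_text": "The ΔEST of 2CzPN is 0.09 eV."})
        rec.provenance.element_index = 1  # the paragraph
        ctx = build_classifier_context(rec, doc)
        assert ctx == ("Photophysical properties "
                       "All emitters were measured in toluene. "
                       "The ΔEST of 2CzPN is 0.09 eV.")

    def test_first_sentence_record_included_once(self, tmp_path):
        doc = self._doc(tmp_path)
        rec = _rec("delta_e_st", [0.09],
                   extra={"source_text": "All emitters were measured in toluene."})
        rec.provenance.element_index = 1
        ctx = build_classifier_context(rec, doc)
        assert ctx.count("All emitters were measured in toluene.") == 1

    def test_standalone_table_record_has_no_context(self, tmp_path):
        doc = self._doc(tmp_path)
        rec = _rec("delta_e_st", [0.09], cell=(0, 1))
        assert build_classifier_context(rec, doc) is None

    @pytest.mark.parametrize("context,expected", [
        ("TD-DFT calculations gave the gap", "false"),
        ("onsets of fluorescence and phosphorescence spectra", "true"),
        ("the gap was reported previously", "unknown"),
        ("measured and calculated values agree", "unknown"),  # both cue sets
    ])
    def test_keyword_classifier(self, context, expected):
        assert keyword_classifier(context) == expected

    def test_no_context_is_unknown(self):
        assert classify_is_experimental(None) == "unknown"

    def test_table_only_records_stay_unknown(self, models, tmp_path):
        doc = self._doc(tmp_path)
        rec = _rec("delta_e_st", [0.09], "eV", cell=(0, 1))
        cleaned = clean_records([rec], models, doc)
        assert cleaned[0].extra["is_experimental"] == "unknown"
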