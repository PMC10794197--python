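import pytest

from tadfminer.document import Table
from tadfminer.nlp import LexiconTagger, segment_sentences, tag_cems
from tadfminer.parsers import (CELL_SEPARATOR, Compound, parse_cell,
                               parse_combined_est_cell,
                               parse_fractional_plqy_cell, parse_sentence,
                               parse_shared_lifetime_cell, parse_table,
                               parse_table_cell, serialize_cell,
                               REGISTERED_PARSERS)

SEP = CELL_SEPARATOR


def _sentence(text, lexicon=("2CzPN", "4CzIPN")):
    s = segment_sentences(text)[0]
    return tag_cems(s, LexiconTagger(list(lexicon)))


class TestSentenceParser:
    def test_specifier_of_compound_template(self, models):
        recs = parse_sentence(_sentence("The delayed lifetime of 2CzPN is 3.2 μs."),
                              models["tau_d"])
        assert len(recs) == 1
        r = recs[0]
        assert r.quantity.values == [3.2] and r.quantity.unit == "μs"
        assert r.compound.names == ["2CzPN"]
        assert r.provenance.parser == "sentence_parser"

    def test_no_specifier_no_record(self, models):
        recs = parse_sentence(_sentence("The device efficiency was 20%."),
                              models["plqy"])
        assert recs == []

    def test_temperature_capture(self, models):
        recs = parse_sentence(
            _sentence("ΔEST of 4CzIPN was measured to be 0.05 eV at 300 K."),
            models["delta_e_st"])
        assert len(recs) == 1
        assert recs[0].quantity.values == [0.05]
        assert recs[0].compound.names == ["4CzIPN"]
        assert recs[0].extra["temperature_K"] == 300.0

    def test_room_temperature_flag(self, models):
        recs = parse_sentence(
            _sentence("The delayed lifetime of 2CzPN is 3.2 μs at room temperature."),
            models["tau_d"])
        assert recs[0].extra.get("rt_flag") is True

    def test_compound_verb_specifier_template(self, models):
        recs = parse_sentence(_sentence("2CzPN shows a PLQY of 68%."),
                              models["plqy"])
        assert recs[0].compound.names == ["2CzPN"]
        assert recs[0].quantity.values == [68.0]


class TestSerializeCell:
    def test_single_header(self):
        t = Table(header_rows=[["τd (μs)"]], body=[["3.2"]])
        assert serialize_cell(t, 0, 0) == f"τd (μs){SEP}3.2"

    def test_nested_headers_outer_first(self):
        t = Table(header_rows=[["Photophysics"], ["ΦPL (%)"]], body=[["68"]])
        assert serialize_cell(t, 0, 0) == f"Photophysics{SEP}ΦPL (%){SEP}68"

    def test_empty_cell_ends_with_separator(self):
        t = Table(header_rows=[["τd (μs)"]], body=[[""]])
        assert serialize_cell(t, 0, 0).endswith(SEP)

    def test_out_of_range(self):
        t = Table(header_rows=[["h"]], body=[["1"]])
        with pytest.raises(IndexError):
            serialize_cell(t, 2, 0)

    def test_separator_is_four_upside_down_faces(self):
        assert CELL_SEPARATOR == "\U0001F643" * 4


class TestGenericCellParser:
    def test_unit_from_header(self, models):
        recs = parse_cell(f"λem (nm){SEP}470", models["lambda_em"],
                          Compound(names=["2CzPN"]))
        assert len(recs) == 1
        assert recs[0].quantity.values == [470.0]
        assert recs[0].quantity.unit == "nm"
        assert recs[0].compound.names == ["2CzPN"]

    def test_first_come_first_served(self, models):
        recs = parse_cell(f"λem (nm){SEP}470, 3.2", models["lambda_em"])
        assert recs[0].quantity.values == [470.0]

    def test_no_specifier_in_headers_no_record(self, models):
        assert parse_cell(f"Year{SEP}2019", models["lambda_em"]) == []

    def test_unit_from_cell_when_header_lacks_it(self, models):
        recs = parse_cell(f"τd{SEP}3.2 μs", models["tau_d"])
        assert recs[0].quantity.unit == "μs"


class TestCombinedEstParser:
    def test_positional_alignment(self):
        recs = parse_combined_est_cell(f"ES/ET/ΔEST (eV){SEP}3.0/2.9/0.1")
        assert len(recs) == 1
        assert recs[0].property_id == "delta_e_st"
        assert recs[0].quantity.values == [0.1]
        assert recs[0].quantity.unit == "eV"
        assert "consistency_warning" not in recs[0].extra

    def test_field_count_mismatch(self):
        assert parse_combined_est_cell(f"ES/ET/ΔEST (eV){SEP}3.0/2.9") == []

    def test_consistency_warning(self):
        recs = parse_combined_est_cell(f"ES/ET/ΔEST (eV){SEP}3.0/2.9/0.5")
        assert recs[0].quantity.values == [0.5]
        assert recs[0].extra["consistency_warning"] is True

    def test_not_applicable_returns_none(self):
        assert parse_combined_est_cell(f"λem (nm){SEP}470") is None


class TestFractionalPlqyParser:
    def test_fraction_times_hundred(self, models):
        recs = parse_fractional_plqy_cell(f"ΦPL{SEP}0.68", models["plqy"])
        assert recs[0].standard_value == [68.0]

    def test_percent_header_defers(self, models):
        assert parse_fractional_plqy_cell(f"ΦPL (%){SEP}68", models["plqy"]) is None
        recs = parse_table_cell(f"ΦPL (%){SEP}68", models)
        assert recs[0].quantity.values == [68.0]
        assert recs[0].provenance.parser == "table_cell_parser"

    def test_boundary_value_one(self, models):
        recs = parse_fractional_plqy_cell(f"ΦPL{SEP}1.0", models["plqy"])
        assert recs[0].standard_value == [100.0]


class TestSharedLifetimeParser:
    def test_per_slot_units(self):
        recs = parse_shared_lifetime_cell(f"τp/τd (ns/μs){SEP}25/3.2")
        assert len(recs) == 1
        assert recs[0].property_id == "tau_d"
        assert recs[0].quantity.values == [3.2]
        assert recs[0].quantity.unit == "μs"

    def test_lambda_partner(self):
        recs = parse_shared_lifetime_cell(f"λem/τd (nm/μs){SEP}470/3.2")
        assert recs[0].quantity.values == [3.2] and recs[0].quantity.unit == "μs"

    def test_prompt_only_header_not_applicable(self):
        assert parse_shared_lifetime_cell(f"τp (ns){SEP}25") is None

    def test_single_unit_applies_to_all_slots(self):
        recs = parse_shared_lifetime_cell(f"τp/τd (μs){SEP}0.5/3.2")
        assert recs[0].quantity.unit == "μs"

    def test_alignment_failure(self):
        assert parse_shared_lifetime_cell(f"τp/τd (ns/μs){SEP}25") == []


class TestDispatch:
    def test_special_parsers_claim_headers_exclusively(self, models):
        # a combined column never reaches the generic ΔE_ST parser
        recs = parse_table_cell(f"ES/ET/ΔEST (eV){SEP}3.0/2.9/0.1", models)
        assert [r.provenance.parser for r in recs] == ["combined_est_table_parser"]
        assert recs[0].quantity.values == [0.1]  # not 3.0

    def test_shared_cell_emits_only_tau_d(self, models):
        recs = parse_table_cell(f"λem/τd (nm/μs){SEP}470/3.2", models)
        assert [r.property_id for r in recs] == ["tau_d"]

    def test_parser_names_registered(self, models):
        t = Table(header_rows=[["Compounds", "λem (nm)", "ΦPL", "τp/τd (ns/μs)"]],
                  body=[["2CzPN", "470", "0.68", "25/3.2"]])
        recs = parse_table(t, models, "doc", 0)
        assert {r.provenance.parser for r in recs} <= set(REGISTERED_PARSERS)
        assert all(r.provenance.cell is not None for r in recs)
        assert all(r.compound.names == ["2CzPN"] for r in recs)
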