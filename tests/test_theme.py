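import random

import pytest

from tadfminer.document import Document
from tadfminer.parsers import CELL_SEPARATOR, CandidateRecord, Provenance
from tadfminer.ontology import Quantity
from tadfminer.theme import (ThemeRegistry, apply_label_rules, apply_name_rules,
                             blocklist_cutoff, build_blocklist,
                             build_frequency_table, resolve_compound)


class TestFrequencyTable:
    def test_within_document_deduplication(self):
        stream = [("d1", "toluene")] * 5
        assert build_frequency_table(stream).counts["toluene"] == 1

    def test_cross_document_counting(self):
        stream = [(f"d{i}", "toluene") for i in range(3)]
        assert build_frequency_table(stream).counts["toluene"] == 3

    def test_empty_stream(self):
        table = build_frequency_table([])
        assert table.counts == {} and table.n_documents == 0

    def test_counts_match_brute_force_oracle(self):
        rng = random.Random(42)
        names = ["toluene", "nitrogen", "2CzPN", "DPEPO", "chloroform"]
        stream = [(f"d{rng.randrange(30)}", rng.choice(names))
                  for _ in range(500)]
        table = build_frequency_table(stream)
        for name in names:
            expected = len({d for d, n in stream if n == name})
            assert table.counts.get(name, 0) == expected
        assert all(1 <= c <= table.n_documents for c in table.counts.values())


class TestBlocklist:
    def _freq(self, count, n):
        from tadfminer.theme import FrequencyTable
        return FrequencyTable(counts={"x": count}, n_documents=n)

    def test_seven_of_1200_blocklisted(self):
        bl = build_blocklist(self._freq(7, 1200), 7 / 1200)
        assert bl.blocks("x")

    def test_six_of_1200_not_blocklisted(self):
        bl = build_blocklist(self._freq(6, 1200), 7 / 1200)
        assert not bl.blocks("x")

    def test_ceiling_scales_to_small_corpora(self):
        # n=600 at fraction 7/1200: cut-off ceil(3.5) = 4
        assert blocklist_cutoff(self._freq(0, 600), 7 / 1200) == 4
        assert build_blocklist(self._freq(4, 600), 7 / 1200).blocks("x")
        assert not build_blocklist(self._freq(3, 600), 7 / 1200).blocks("x")

    def test_monotone_in_threshold(self):
        from tadfminer.theme import FrequencyTable
        freq = FrequencyTable(counts={f"c{i}": i for i in range(1, 21)},
                              n_documents=20)
        previous = set()
        for fraction in (0.9, 0.5, 0.25, 0.1, 0.05):
            entries = build_blocklist(freq, fraction).entries
            assert previous <= entries
            previous = entries

    def test_allowlist_overrides(self):
        bl = build_blocklist(self._freq(7, 1200), 7 / 1200,
                             allowlist={"x"})
        assert not bl.blocks("x")

    def test_name_variants_enrich(self):
        from tadfminer.theme import FrequencyTable
        freq = FrequencyTable(counts={"DMAC-TRZ": 10}, n_documents=10)
        bl = build_blocklist(freq, 0.5)
        assert bl.blocks("dmac-trz") and bl.blocks("DMAC TRZ")

    def test_roundtrip_json(self, tmp_path):
        from tadfminer.theme import Blocklist
        bl = build_blocklist(self._freq(7, 1200), 7 / 1200, allowlist={"keepme"})
        path = tmp_path / "bl.json"
        bl.to_json(path)
        loaded = Blocklist.from_json(path)
        assert loaded.entries == bl.entries
        assert loaded.allowlist == bl.allowlist


class TestNameRules:
    @pytest.mark.parametrize("name,expected", [
        ("amino", "block"),
        ("phenyl", "block"),
        ("pyridine-based", "block"),
        ("methoxy", "block"),
        ("2CzPN", "allow"),
        ("anthracene", "allow"),
    ])
    def test_examples(self, name, expected):
        assert apply_name_rules(name)[0] == expected

    def test_separator_blocked(self):
        assert apply_name_rules(f"a{CELL_SEPARATOR}b")[0] == "block"

    def test_doi_string_blocked(self):
        doc = Document(doc_id="d", metadata={"doi": "10.1039/x123"})
        assert apply_name_rules("10.1039/x123-suffix", doc)[0] == "block"

    def test_followed_by_based_blocked(self):
        assert apply_name_rules("pyridine", following_text="-based materials")[0] == "block"

    def test_allowlist_beats_every_rule(self):
        assert apply_name_rules("phenyl", allowlist={"phenyl"})[0] == "allow"


class TestLabelRules:
    @pytest.mark.parametrize("label,expected", [
        ("15%", "block"),
        ("3 wt %", "block"),
        ("ABCDE", "block"),
        ("T1", "block"),
        ("S0", "block"),
        ("nm", "block"),
        ("2023-01-17", "block"),
        ("3a", "allow"),
        ("1b", "allow"),
    ])
    def test_examples(self, label, expected):
        assert apply_label_rules(label)[0] == expected


def _record(pid="plqy", element=0, offset=0):
    return CandidateRecord(property_id=pid, quantity=Quantity([68.0], "%"),
                           provenance=Provenance("d", element, 0, None,
                                                 "sentence_parser"),
                           extra={"offset": offset})


class TestResolution:
    def test_nearest_registered_compound_attached(self):
        reg = ThemeRegistry("d")
        reg.register("2CzPN", 0, 5)
        reg.register("4CzIPN", 3, 0)  # different element: not a candidate
        rec = resolve_compound(_record(offset=40), reg, record_offset=40)
        assert rec.compound.names == ["2CzPN"]

    def test_tie_breaks_toward_preceding(self):
        reg = ThemeRegistry("d")
        reg.register("2CzPN", 0, 10)
        reg.register("4CzIPN", 0, 30)
        rec = resolve_compound(_record(offset=20), reg, record_offset=20)
        assert rec.compound.names == ["2CzPN"]

    def test_unresolvable_record_dropped(self):
        reg = ThemeRegistry("d")
        assert resolve_compound(_record(), reg, record_offset=0) is None

    def test_existing_compound_untouched(self):
        from tadfminer.parsers import Compound
        reg = ThemeRegistry("d")
        reg.register("4CzIPN", 0, 0)
        rec = _record()
        rec.compound = Compound(names=["2CzPN"])
        assert resolve_compound(rec, reg).compound.names == ["2CzPN"]

    def test_reset_clears_everything(self):
        reg = ThemeRegistry("d")
        reg.register("2CzPN", 0, 0)
        reg.reset()
        assert reg.known() == [] and reg.positions == {}
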