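import pytest

from tadfminer.nlp import LexiconTagger
from tadfminer.ontology import load_default_models
from tadfminer.synth import CorpusSpec, generate_corpus


@pytest.fixture(scope="session")
def models():
    return load_default_models()


@pytest.fixture()
def lexicon_tagger():
    return LexiconTagger(["2CzPN", "4CzIPN", "toluene", "nitrogen",
                          "4,5-Bis(carbazol-9-yl)-1,2-dicyanobenzene",
                          "DMAC-TRZ", "3a"])


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """Noiseless 6-document synthetic corpus shared across tests."""
    out = tmp_path_factory.mktemp("corpus")
    spec = CorpusSpec(n_documents=6, facts_per_property=3, seed=11)
    return generate_corpus(spec, out)


XML_FIXTURE = """\
<article>
 <meta>
  <doi>10.0000/fixture-0001</doi>
  <authors>A. Author</authors>
  <journal>J. Fixtures</journal>
  <year>2023</year>
 </meta>
 <title>A fixture article</title>
 <section>
  <h>Photophysical properties</h>
  <p>The PLQY of 2CzPN is 68%.</p>
  <p>The delayed lifetime of 2CzPN is 3.2 μs at room temperature.</p>
  <table>
   <caption>Data.</caption>
   <tr><th>Compounds</th><th>λem (nm)</th></tr>
   <tr><td>2CzPN</td><td>470</td></tr>
  </table>
 </section>
</article>
"""


@pytest.fixture()
def xml_fixture_path(tmp_path):
    path = tmp_path / "fixture.xml"
    path.write_text(XML_FIXTURE, encoding="utf-8")
    return path
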