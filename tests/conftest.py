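import pytest

from frannot.dictionary import BuildOptions, build_dictionary
from frannot.terminology import Concept, Terminology, load_semantic_table


@pytest.fixture(scope="session")
def semantic_table():
    return load_semantic_table()


@pytest.fixture()
def mesh_breast():
    """The breast-neoplasm concept with its preferred label + 3 synonyms."""
    t = Terminology("MSHFRE")
    t.add(Concept(
        concept_id="D001943", pref_label="Tumeurs du sein",
        synonyms=("carcinome mammaire humain", "cancer du sein",
                  "tumeurs mammaires humaines"),
        cuis=frozenset({"C0006142"}), tuis=frozenset({"T191"}),
        uri="http://purl.bioontology.org/ontology/MSHFRE/D001943"))
    t.validate()
    return t


@pytest.fixture()
def small_terminology():
    """Three concepts incl. nested labels and a 2-level hierarchy."""
    t = Terminology("DEMO")
    t.add(Concept(concept_id="ROOT", pref_label="tumeur",
                  tuis=frozenset({"T191"})))
    t.add(Concept(concept_id="CDS", pref_label="cancer du sein",
                  parent_ids=("ROOT",),
                  cuis=frozenset({"C0006142"}), tuis=frozenset({"T191"})))
    t.add(Concept(concept_id="SEIN", pref_label="sein",
                  cuis=frozenset({"C0006141"}), tuis=frozenset({"T023"})))
    t.validate()
    return t


@pytest.fixture()
def small_dictionary(small_terminology):
    return build_dictionary([small_terminology], BuildOptions())
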