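import numpy as np
import pytest

from assayscope.corpus import AssayCorpus, AssayRecord


@pytest.fixture
def small_corpus() -> AssayCorpus:
    """Three fully annotated assay records."""
    return AssayCorpus([
        AssayRecord("A1", "Displacement of [3H]DPCPX from membranes",
                    "B", "Ki", "BAO_0000357", tax_id="9606", confidence_score="9",
                    relationship_type="D", src_id="1", curated_by="Expert",
                    pref_name="Adenosine A1"),
        AssayRecord("A2", "Inhibition of forskolin-stimulated cAMP accumulation",
                    "F", "IC50", "BAO_0000219", tax_id="9606", confidence_score="8",
                    relationship_type="D", src_id="1", curated_by="Expert",
                    pref_name="Adenosine A2a"),
        AssayRecord("A3", "Displacement of [125I]AB-MECA from CHO cells",
                    "B", "Ki", "BAO_0000219", tax_id="10090", confidence_score="9",
                    relationship_type="H", src_id="1", curated_by="Autocuration",
                    pref_name="Adenosine A3"),
    ])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
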