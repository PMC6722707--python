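import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import HealthCheck, settings

from littopics.preprocess import DocumentTermMatrix

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tiny_dtm():
    """Enumerable instance: 2 docs, 3 tokens each, V=3 (doc0: aab, doc1: bcc)."""
    counts = sp.csr_matrix(np.array([[2, 1, 0], [0, 1, 2]]))
    return DocumentTermMatrix(counts, np.array(["a", "b", "c"], dtype=object))


WOS_FIXTURE = """\
FN Clarivate Analytics Web of Science
VR 1.0
PT J
AU Smith, J.
TI Diatom community response to eutrophication in boreal lakes
SO JOURNAL OF PALEOLIMNOLOGY
AB Diatom assemblages respond rapidly to nutrient enrichment. We analysed
   sediment cores from twelve boreal lakes.
C1 [Smith, J.] Univ Toronto, Dept Ecol & Evolutionary Biol, Toronto, ON, Canada.
PY 2005
TC 12
WC Limnology; Environmental Sciences
DT Article
ER

PT J
AU Li, W.
   Chen, H.
TI Growth rates of marine diatoms under iron limitation
SO LIMNOLOGY AND OCEANOGRAPHY
C1 [Li, W.] Xiamen Univ, State Key Lab Marine Environm Sci, Xiamen, Peoples R China.
PY 1998
TC 47
WC Oceanography; Limnology
DT Article
ER

PT J
AU Brown, A.
TI A review of diatom-based transfer functions
SO DIATOM RESEARCH
AB Transfer functions calibrate diatom assemblages against environmental
   gradients for quantitative reconstruction.
C1 [Brown, A.] Univ Coll London, Dept Geog, London, England.
PY 2014
TC 3
WC Marine & Freshwater Biology
DT Review
ER
EF
"""


@pytest.fixture
def wos_file(tmp_path):
    path = tmp_path / "export.txt"
    path.write_text(WOS_FIXTURE)
    return path
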