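import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make reference.py importable

from tangoplan import canonicalize

DATA_DIR = Path(__file__).parent / "data"

# 50 small drug-like / reagent-like molecules used as a fixture corpus
CORPUS_SMILES = [
    "CCO", "CCN", "CCC", "CC(=O)O", "CC(=O)OCC", "c1ccccc1", "Cc1ccccc1",
    "Oc1ccccc1", "Nc1ccccc1", "OC(=O)c1ccccc1", "c1ccncc1", "C1CCCCC1",
    "OC1CCCCC1", "C1CCOC1", "C1CCNC1", "CC(C)O", "CC(C)N", "CCCl", "CCBr",
    "CC#N", "CCS", "CCOC", "CCOCC", "CC=O", "C=CC", "CC(C)(C)O",
    "OCC(O)CO", "NCCO", "OCCO", "CNC", "CN(C)C", "CC(=O)N", "CC(=O)NC",
    "CSC", "CS(=O)C", "OCc1ccccc1", "NCc1ccccc1", "O=Cc1ccccc1",
    "CC(=O)c1ccccc1", "CC(O)c1ccccc1", "COc1ccccc1", "CCc1ccccc1",
    "Clc1ccccc1", "Brc1ccccc1", "O=C(O)CC(=O)O", "OCCCO", "CCCN", "CCCO",
    "CC(N)C(=O)O", "OC(=O)c1ccncc1",
]


@pytest.fixture(scope="session")
def corpus():
    return [canonicalize(s) for s in CORPUS_SMILES]


@pytest.fixture(scope="session")
def template_path():
    return DATA_DIR / "templates.tsv"
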