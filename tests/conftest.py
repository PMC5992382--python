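"""Shared fixtures: small hand-built tables and the study-design sample sheet."""

import numpy as np
import pandas as pd
import pytest

from cryoclean import OtuTable, SampleSheet, TaxonomyTable


@pytest.fixture
def small_table() -> OtuTable:
    counts = np.array([[5, 0, 3],
                       [0, 7, 2],
                       [10, 20, 70],
                       [1, 1, 1]])
    return OtuTable(counts, ["s1", "s2", "s3", "s4"], ["otuA", "otuB", "otuC"])


@pytest.fixture
def ice_core_sheet() -> SampleSheet:
    """The four-ice / four-control design with the study's qPCR copy numbers."""
    rows = []
    for sid, q in [("D41_100_A", 4600.0), ("D41_20_A", 970.0),
                   ("D41_50_F", 950.0), ("D49_50_F", 1250.0)]:
        rows.append({"sample_id": sid, "role": "specimen",
                     "group": "D49" if sid.startswith("D49") else "D41",
                     "qpcr_copies_per_ul": q})
    for sid, q in [("Air_ColdRoom", 49.0), ("Air_CleanRoom", 49.0),
                   ("Artificial_ice", 51.0), ("Blank", 27.0)]:
        rows.append({"sample_id": sid, "role": "control", "group": "control",
                     "qpcr_copies_per_ul": q})
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture
def simple_taxonomy() -> TaxonomyTable:
    def rec(otu, genus, family="FamX", organelle=False):
        return {"otu_id": otu, "lineage": "", "confidence": 1.0,
                "is_organelle": organelle, "domain": "Bacteria",
                "phylum": "Proteobacteria", "class": "Alpha", "order": "Ord",
                "family": family, "genus": genus}
    return TaxonomyTable(pd.DataFrame([
        rec("otuA", "Sphingomonas"),
        rec("otuB", "Sphingomonas"),
        rec("otuC", "Methylobacterium", family="Methylobacteriaceae"),
    ]))
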