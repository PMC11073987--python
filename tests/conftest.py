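import numpy as np
import pandas as pd
import pytest

from ereflow.io import EreLocus, GeneModel, GenomicInterval
from ereflow.synthetic import SimConfig


@pytest.fixture
def small_config():
    """Desk-scale-but-small simulation config used across module tests."""
    return SimConfig(
        seed=1, n_genes=300, n_ere=400, n_cta=20, n_gene_up=30, n_gene_down=10,
        n_proteins=100, n_peptides=400, cohort_n=60, cohort_n_genes=200,
        cohort_n_ere=120, n_induced_ere=60, n_autophagy=20,
    )


@pytest.fixture
def tiny_annotation():
    genes = [
        GeneModel("GENE_A", "protein_coding", intervals=(GenomicInterval("chr1", 0, 100, "+"),)),
        GeneModel("GENE_B", "protein_coding", is_cta=True,
                  intervals=(GenomicInterval("chr1", 200, 300, "-"),)),
        GeneModel("GENE_C", "lncRNA", intervals=(GenomicInterval("chr1", 400, 500, "+"),)),
    ]
    loci = [
        EreLocus("ERE_1", GenomicInterval("chr2", 0, 300, "+"), "LINE", "L1"),
        EreLocus("ERE_2", GenomicInterval("chr2", 500, 800, "-"), "SINE", "Alu"),
        EreLocus("ERE_3", GenomicInterval("chr2", 900, 1200, "+"), "LTR", "ERVL"),
    ]
    return genes, loci


@pytest.fixture
def peptide_table():
    """Six peptides with hand-set detection patterns over 3 + 3 replicates."""
    cols = ["AZA_1", "AZA_2", "AZA_3", "CT_1", "CT_2", "CT_3"]
    data = {
        "ALLTREATED": [100.0, 110.0, 90.0, np.nan, np.nan, np.nan],
        "PARTLYSEEN": [100.0, 120.0, np.nan, np.nan, np.nan, np.nan],
        "INCONTROLS": [100.0, 100.0, 100.0, 80.0, np.nan, np.nan],
        "EVERYWHERE": [200.0, 210.0, 190.0, 100.0, 95.0, 105.0],
        "CTONLYPEPK": [np.nan, np.nan, np.nan, 50.0, 55.0, 55.0],
        "WEAKSIGNAL": [np.nan, np.nan, 10.0, np.nan, np.nan, 9.0],
    }
    df = pd.DataFrame(data, index=cols).T
    df.attrs["condition_columns"] = {"AZA": cols[:3], "CT": cols[3:]}
    return df
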