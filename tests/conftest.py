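import numpy as np
import pytest

from gblreg.cluster_io import CdsFeature, ClusterRecord, revcomp
from gblreg.synthetic_data import random_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_record():
    """120-bp record with one + strand and one − strand gene."""
    rng = np.random.default_rng(7)
    bg = random_sequence(rng, 120, 0.5)
    # plusA: CDS at 41..61 (ATG + 5 codons + TGA), minusB: CDS at 80..100 on −
    seq = list(bg)
    seq[40:61] = list("ATG" + "TTA" + "CTG" + "AAA" + "CCC" + "GGG" + "TGA")
    seq[79:100] = list(revcomp("ATG" + "GAA" + "TTC" + "CAT" + "GCA" + "TAA" + "TGA"))
    record = ClusterRecord(
        "toy",
        "".join(seq),
        [
            CdsFeature("plusA", 41, 61, "+", "ATG"),
            CdsFeature("minusB", 80, 100, "-", "ATG"),
        ],
    )
    return record


def mirror_record(record: ClusterRecord) -> ClusterRecord:
    """Reverse-complemented copy with strand-flipped features (oracle helper)."""
    n = len(record.sequence)
    feats = [
        CdsFeature(f.gene, n - f.end + 1, n - f.start + 1,
                   "-" if f.strand == "+" else "+", f.start_codon)
        for f in record.features
    ]
    return ClusterRecord(record.id + "_rc", revcomp(record.sequence), feats)
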