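import numpy as np
import pytest

from cooccurnet import AbundanceStudy


@pytest.fixture
def tiny_study() -> AbundanceStudy:
    """3 taxa x 4 samples, one ecosystem with two replicates."""
    counts = np.array(
        [
            [5, 3, 8, 2],
            [1, 0, 4, 9],
            [0, 7, 2, 6],
        ]
    )
    samples = ["S1", "S2", "S3", "S4"]
    meta = {
        "S1": ("E1", "R1"),
        "S2": ("E1", "R1"),
        "S3": ("E1", "R2"),
        "S4": ("E1", "R2"),
    }
    return AbundanceStudy(counts, ["TaxA", "TaxB", "TaxC"], samples, meta)


def balanced_study(profiles_by_replicate, taxa=None):
    """Build a study from {(eco, rep): taxa-x-samples array} blocks."""
    blocks = list(profiles_by_replicate.items())
    n_taxa = blocks[0][1].shape[0]
    taxa = taxa or [f"T{i + 1}" for i in range(n_taxa)]
    counts = np.hstack([b for _, b in blocks])
    sample_ids, meta = [], {}
    for (eco, rep), block in blocks:
        for k in range(block.shape[1]):
            sid = f"{eco}_{rep}_S{k + 1}"
            sample_ids.append(sid)
            meta[sid] = (eco, rep)
    return AbundanceStudy(counts.astype(np.int64), taxa, sample_ids, meta)
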