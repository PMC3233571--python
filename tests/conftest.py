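import numpy as np
import pytest

from hapnet.alignment_io import (
    AlignedSeqMatrix,
    HaplotypeTable,
    SampleRecord,
    collapse_haplotypes,
)


def raw_table(seqs, region="Tibet", status="domestic", n_each=1):
    """HaplotypeTable with Hap1..HapK in the given sequence order, each
    carried by ``n_each`` individuals of one (region, status)."""
    assert len(set(seqs)) == len(seqs)
    haps = [(f"Hap{i + 1}", s) for i, s in enumerate(seqs)]
    membership = {h: {f"{h}_s{k}" for k in range(n_each)} for h, _ in haps}
    counts = {(h, region, status): n_each for h, _ in haps}
    return HaplotypeTable(haplotypes=haps, membership=membership, counts=counts)


def table_from_samples(samples):
    """Collapse explicit samples: iterable of (sample_id, seq, region, status).

    Returns (table, hap_of_seq)."""
    samples = list(samples)
    L = len(samples[0][1])
    matrix = AlignedSeqMatrix(
        sample_ids=tuple(s[0] for s in samples),
        residues=tuple(s[1] for s in samples),
        source_columns=tuple(range(L)),
    )
    ann = [
        SampleRecord(sample_id=sid, region=region, status=status)
        for sid, _seq, region, status in samples
    ]
    table = collapse_haplotypes(matrix, ann)
    hap_of_seq = {s: h for h, s in table.haplotypes}
    return table, hap_of_seq


def random_star_seqs(rng, n_leaves, length=20):
    """A centre sequence plus ``n_leaves`` one-step derivatives at distinct
    columns."""
    center = "".join(rng.choice(list("ACGT"), size=length))
    cols = rng.choice(length, size=n_leaves, replace=False)
    leaves = []
    for c in cols:
        alt = [b for b in "ACGT" if b != center[c]][rng.integers(3)]
        leaves.append(center[:c] + alt + center[c + 1 :])
    return center, leaves


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
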