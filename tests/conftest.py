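import itertools

import pytest

from mtprov.alignment_io import AlignedSample, AlignmentDataset, ReferenceFrame


def make_dataset(
    seqs,
    localities=None,
    countries=None,
    species=None,
    ids=None,
    frame=None,
):
    """Build a small AlignmentDataset from bare sequences."""
    n = len(seqs)
    localities = localities or ["AA"] * n
    countries = countries or ["C01"] * n
    species = species or ["savanna"] * n
    ids = ids or [f"{localities[i]}{i + 1:04d}" for i in range(n)]
    samples = tuple(
        AlignedSample(
            sample_id=ids[i],
            sequence=seqs[i],
            locality=localities[i],
            country=countries[i],
            species=species[i],
        )
        for i in range(n)
    )
    return AlignmentDataset(samples=samples, frame=frame)


@pytest.fixture
def toy_frame():
    return ReferenceFrame.ungapped("ref", 101, 10)


@pytest.fixture
def dataset_factory():
    return make_dataset
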