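import numpy as np
import pytest

from vtdisorder.records import ProteinRecord, ScoreTrack, Species, TrackKind


def make_protein(length, accession="P1", tm=(), species=Species.HUMAN, **kwargs):
    return ProteinRecord(
        accession=accession,
        name=kwargs.pop("name", accession),
        species=species,
        sequence="A" * length,
        tm_segments=tuple(tm),
        **kwargs,
    )


def track_from_flags(flags, kind=TrackKind.DISORDER, hi=0.9, lo=0.1):
    scores = np.where(np.asarray(flags, dtype=bool), hi, lo)
    return ScoreTrack(kind, scores)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
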