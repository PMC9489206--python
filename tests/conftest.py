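import numpy as np
import pytest

from scoutlite.simulate import SimSpec, simulate_faces
from scoutlite.stimio import FaceObservation, TranscriptWord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def words():
    """Short force-aligned transcript."""
    return [
        TranscriptWord("The", 0.5, 0.3),
        TranscriptWord("dog", 1.0, 0.5),
        TranscriptWord("barked.", 2.0, 0.8),
    ]


@pytest.fixture
def face_blobs():
    """Three tight, well-separated identity blobs with true labels."""
    obs, labels = simulate_faces(3, appearances=8, seed=7, duration=30.0)
    return obs, labels


@pytest.fixture
def tiny_sim_spec():
    """Smallest multistudy configuration that exercises all three levels."""
    return SimSpec(
        n_studies=2,
        n_subjects=2,
        n_runs=2,
        n_volumes=60,
        tr=2.0,
        grid=(4, 4, 4),
        seed=99,
    )


def make_obs(embedding, time=0.0, probability=1.0):
    emb = np.zeros(512)
    emb[: len(np.atleast_1d(embedding))] = embedding
    return FaceObservation(time=time, embedding=emb, probability=probability)
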