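import pytest

from ptmppi import worked_example
from ptmppi.backbone import Hyperparams, build_ensemble
from ptmppi.kb_dataset import build_dataset
from ptmppi.synthetic import CorpusSpec, generate_corpus
from ptmppi.transform import prepare_classifier_samples
from ptmppi.types import PTM_TYPES

BALANCED_MIX = tuple((p, 1 / 6) for p in PTM_TYPES)


@pytest.fixture()
def example_bundle():
    """The fully traced one-document data-preparation example."""
    return worked_example.bundle()


@pytest.fixture(scope="session")
def balanced_corpus():
    """Noise-free corpus with a balanced PTM mix (separable by design)."""
    return generate_corpus(CorpusSpec(n_documents=240, ptm_mix=BALANCED_MIX, seed=11))


@pytest.fixture(scope="session")
def balanced_split(balanced_corpus):
    bundle, _ = balanced_corpus
    split, report = build_dataset(bundle, seed=11)
    return split, report


@pytest.fixture(scope="session")
def masked_splits(balanced_split):
    split, _ = balanced_split
    return tuple(
        prepare_classifier_samples(getattr(split, part))
        for part in ("train", "val", "test")
    )


@pytest.fixture(scope="session")
def small_ensemble(masked_splits):
    """10-model reference ensemble on the balanced separable corpus."""
    train, val, _ = masked_splits
    return build_ensemble(
        train, val, M=10, base_seed=7, hyperparams=Hyperparams(epochs=20)
    )
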