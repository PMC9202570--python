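import numpy as np
import pytest

from icccml import CNNConfig, build_corpus, default_config
from icccml.corpus import CorpusConfig, default_age_profiles
from icccml.recode import fixture_table
from icccml.textcnn import train


@pytest.fixture(scope="session")
def table():
    return fixture_table()


@pytest.fixture(scope="session")
def small_corpus():
    """Imbalanced 47-class corpus, 600 reports."""
    return build_corpus(default_config(n_reports=600, seed=11))


def make_balanced_config(
    codes, n_reports, seed, signal_strength=0.9, **kwargs
) -> CorpusConfig:
    return CorpusConfig(
        n_reports=n_reports,
        class_proportions={c: 1.0 / len(codes) for c in codes},
        age_profiles=default_age_profiles(),
        seed=seed,
        signal_strength=signal_strength,
        **kwargs,
    )


TINY_CNN = CNNConfig(
    embedding_dim=16,
    filters_per_width=8,
    dropout=0.2,
    max_len=50,
    epochs=5,
    learning_rate=2e-3,
    batch_size=32,
    seed=0,
)


@pytest.fixture(scope="session")
def tiny_separable():
    """(train_df, test_df, clf): 5 balanced classes, strong signal."""
    codes = ["011", "021", "031", "041", "050"]
    df = build_corpus(make_balanced_config(codes, 500, seed=5))
    train_df, test_df = df.iloc[:400], df.iloc[400:]
    clf = train(train_df, "iccc_subgroup", TINY_CNN)
    return train_df, test_df, clf
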