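"""Canonical desk-scale study settings.

One place defines the synthetic-study conditions used by the packaged
reproduction: the corpus size, the cross-validation depth and the CNN
hyperparameters sized so a full four-scenario comparison runs on one CPU
core in minutes. The corpus keeps the published class-imbalance profile
and a signal strength of 0.9 (strongly, not perfectly, separable text).
"""

from __future__ import annotations

import numpy as np

from .corpus import CorpusConfig, build_corpus, default_config
from .evaluate import UQConfig, run_scenario
from .reference import SUBGROUP_CODES
from .textcnn import CNNConfig, train

STUDY_N_REPORTS = 1500
STUDY_K_FOLDS = 4
STUDY_SIGNAL = 0.9


def study_corpus_config(seed: int) -> CorpusConfig:
    """Corpus settings of the packaged synthetic study."""
    return default_config(
        n_reports=STUDY_N_REPORTS, seed=seed, signal_strength=STUDY_SIGNAL
    )


def study_cnn_config(seed: int) -> CNNConfig:
    """Desk-scale CNN: trains one fold in a few seconds on one core."""
    return CNNConfig(
        embedding_dim=32,
        filters_per_width=32,
        filter_widths=(3, 4, 5),
        dropout=0.3,
        max_len=50,
        epochs=8,
        learning_rate=2e-3,
        batch_size=64,
        seed=seed,
    )


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """n reproducible 31-bit seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


def run_comparison_study(seeds: list[int], uq_threshold: float = 0.9) -> list[dict]:
    """One replicate per seed: scenarios 1a and 2a, plus 2a with abstention.

    Each replicate generates a fresh study corpus, cross-validates the
    recode-based scenario 1a and the direct-ICCC scenario 2a, and runs 2a
    again with the confidence model at the given threshold. Returns one
    dict of summary metrics per seed.
    """
    records = []
    for seed in seeds:
        corpus = build_corpus(study_corpus_config(seed))
        cnn = study_cnn_config(seed)
        r1a = run_scenario("1a", corpus, cnn, k=STUDY_K_FOLDS, seed=seed)
        r2a = run_scenario("2a", corpus, cnn, k=STUDY_K_FOLDS, seed=seed)
        ruq = run_scenario(
            "2a", corpus, cnn, UQConfig(threshold=uq_threshold),
            k=STUDY_K_FOLDS, seed=seed,
        )
        records.append({
            "seed": seed,
            "macro_f1_1a": r1a.macro_f1,
            "micro_f1_1a": r1a.micro_f1,
            "macro_f1_2a": r2a.macro_f1,
            "micro_f1_2a": r2a.micro_f1,
            "uq_micro_f1_retained": ruq.micro_f1,
            "uq_macro_f1_retained": ruq.macro_f1,
            "uq_micro_f1_all": ruq.micro_f1_all,
            "uq_abstention": ruq.abstention_rate_overall,
        })
    return records


def holdout_accuracy(
    seed: int,
    signal_strength: float,
    n_reports: int = 2000,
    n_classes: int = 10,
) -> tuple[float, float]:
    """(held-out accuracy, majority-class rate) on a balanced corpus.

    Trains the desk-scale CNN on 80% of a balanced ``n_classes``-subgroup
    corpus at the given signal strength and scores the remaining 20%.
    """
    codes = list(SUBGROUP_CODES[:n_classes])
    config = CorpusConfig(
        n_reports=n_reports,
        class_proportions={c: 1.0 / len(codes) for c in codes},
        age_profiles=default_config().age_profiles,
        seed=seed,
        signal_strength=signal_strength,
    )
    corpus = build_corpus(config)
    split = int(0.8 * len(corpus))
    train_df, test_df = corpus.iloc[:split], corpus.iloc[split:]
    clf = train(train_df, "iccc_subgroup", study_cnn_config(seed))
    pred = np.array(clf.predict_label_batch(test_df["text"].tolist())[0])
    accuracy = float(np.mean(pred == test_df["iccc_subgroup"].values))
    majority = train_df["iccc_subgroup"].value_counts(normalize=True).iloc[0]
    return accuracy, float(majority)
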