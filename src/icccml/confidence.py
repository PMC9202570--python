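"""Post-training confidence scoring and threshold abstention.

A classifier that assists registry annotators must know when not to
answer. The confidence model here is fitted on a held-out validation
split, never on training predictions. Each validation case contributes a
scalar summary of its softmax output (the maximum predicted probability)
and a correctness flag. From these the model estimates

* priors ``p(correct)`` and ``p(incorrect)`` as relative frequencies, and
* conditional likelihoods of the score given correctness, realized as
  empirical tail probabilities: ``p(y | correct)`` is the survival
  function of the correct-stratum scores at the new score, and
  ``p(y | incorrect)`` the survival function of the incorrect stratum,
  each floored at 1e-6 so the Bayes ratio is always defined. Because
  incorrect predictions concentrate at low scores, their survival decays
  faster, making the posterior monotone non-decreasing in the score.

Bayes' theorem then gives the posterior probability that the prediction
is correct::

    p(correct | y) = p(y|correct) p(correct) /
                     (p(y|correct) p(correct) + p(y|incorrect) p(incorrect))

A case is abstained when this confidence falls strictly below the
threshold (default 0.9; equality assigns). The percentile knob ``tau``
optionally trims each stratum to its [tau, 1-tau] quantile range before
the distributions are built (default 0, no trimming). The raw
max-softmax score can be thresholded instead via ``score_mode="raw"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "CalibrationSample",
    "CalibrationError",
    "EmpiricalDistribution",
    "ConfidenceModel",
    "AbstainDecision",
    "summarize_softmax",
    "fit_priors",
    "fit_conditionals",
    "confidence_score",
    "decide",
]

_EPS = 1e-6
_SUM_TOL = 1e-6


class CalibrationError(ValueError):
    """Raised when a correctness stratum is empty.

    Widen the validation split (or use more folds) so that both correct
    and incorrect predictions are observed.
    """


class CalibrationSample(NamedTuple):
    score: float
    correct: bool


def summarize_softmax(y: Sequence[float] | np.ndarray) -> float:
    """Scalar summary of a softmax vector: its maximum probability."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("expected a 1-D probability vector")
    if (y < -_SUM_TOL).any() or abs(y.sum() - 1.0) > _SUM_TOL:
        raise ValueError("probability vector is not normalized")
    return float(y.max())


def fit_priors(
    samples: Sequence[CalibrationSample],
) -> tuple[float, float]:
    """Relative frequencies of correct and incorrect decisions."""
    if len(samples) == 0:
        raise ValueError("no calibration samples")
    n_correct = sum(1 for s in samples if s.correct)
    n = len(samples)
    return n_correct / n, (n - n_correct) / n


class EmpiricalDistribution:
    """ECDF of a score sample, with survival and cumulative evaluation."""

    def __init__(self, scores: Sequence[float] | np.ndarray):
        arr = np.sort(np.asarray(scores, dtype=float))
        if arr.size == 0:
            raise CalibrationError("empty score stratum")
        self._scores = arr

    def __len__(self) -> int:
        return len(self._scores)

    def cdf(self, s: float) -> float:
        """P(X <= s)."""
        return float(np.searchsorted(self._scores, s, side="right")) / len(self)

    def survival(self, s: float) -> float:
        """P(X >= s), i.e. 1 - ECDF(s^-)."""
        n = len(self)
        return float(n - np.searchsorted(self._scores, s, side="left")) / n

    @property
    def scores(self) -> np.ndarray:
        return self._scores.copy()


def _trim(scores: np.ndarray, tau: float) -> np.ndarray:
    """Drop scores outside the [tau, 1-tau] quantile range."""
    if tau <= 0.0:
        return scores
    lo, hi = np.quantile(scores, [tau, 1.0 - tau])
    kept = scores[(scores >= lo) & (scores <= hi)]
    return kept if kept.size else scores


def fit_conditionals(
    samples: Sequence[CalibrationSample], tau: float = 0.0
) -> tuple[EmpiricalDistribution, EmpiricalDistribution]:
    """Empirical score distributions within each correctness stratum."""
    if not 0.0 <= tau < 0.5:
        raise ValueError("tau must lie in [0, 0.5)")
    correct = np.array([s.score for s in samples if s.correct])
    incorrect = np.array([s.score for s in samples if not s.correct])
    if correct.size == 0 or incorrect.size == 0:
        raise CalibrationError(
            "a correctness stratum is empty; widen the validation split"
        )
    return (
        EmpiricalDistribution(_trim(correct, tau)),
        EmpiricalDistribution(_trim(incorrect, tau)),
    )


@dataclass
class ConfidenceModel:
    """Fitted priors plus conditional score distributions and a threshold."""

    p_correct: float
    p_incorrect: float
    cond_correct: EmpiricalDistribution | None
    cond_incorrect: EmpiricalDistribution | None
    tau: float = 0.0
    threshold: float = 0.9
    score_mode: str = "bayes"  # "bayes" thresholds the posterior, "raw" max(y)

    def __post_init__(self) -> None:
        if abs(self.p_correct + self.p_incorrect - 1.0) > 1e-12:
            raise ValueError("priors must sum to 1")
        if min(self.p_correct, self.p_incorrect) < 0:
            raise ValueError("priors must be non-negative")
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must lie in (0, 1]")
        if self.score_mode not in ("bayes", "raw"):
            raise ValueError("score_mode must be 'bayes' or 'raw'")

    @classmethod
    def fit(
        cls,
        samples: Sequence[CalibrationSample],
        tau: float = 0.0,
        threshold: float = 0.9,
        score_mode: str = "bayes",
    ) -> "ConfidenceModel":
        """Fit priors and conditionals from validation samples.

        Degenerate strata are allowed here: with no incorrect (or no
        correct) validation decision the posterior is constant 1 (or 0)
        and the conditionals are not needed.
        """
        p_correct, p_incorrect = fit_priors(samples)
        if p_incorrect == 0.0 or p_correct == 0.0:
            return cls(p_correct, p_incorrect, None, None, tau, threshold,
                       score_mode)
        cond_correct, cond_incorrect = fit_conditionals(samples, tau)
        return cls(p_correct, p_incorrect, cond_correct, cond_incorrect,
                   tau, threshold, score_mode)

    def likelihoods(self, score: float) -> tuple[float, float]:
        """(p(y|correct), p(y|incorrect)) at a new score, floored at 1e-6."""
        if self.cond_correct is None or self.cond_incorrect is None:
            raise CalibrationError("conditionals not fitted (degenerate prior)")
        return (
            max(self.cond_correct.survival(score), _EPS),
            max(self.cond_incorrect.survival(score), _EPS),
        )

    def to_dict(self) -> dict:
        return {
            "p_correct": self.p_correct,
            "p_incorrect": self.p_incorrect,
            "correct_scores": (
                self.cond_correct.scores.tolist()
                if self.cond_correct is not None else []
            ),
            "incorrect_scores": (
                self.cond_incorrect.scores.tolist()
                if self.cond_incorrect is not None else []
            ),
            "tau": self.tau,
            "threshold": self.threshold,
            "score_mode": self.score_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConfidenceModel":
        return cls(
            p_correct=float(d["p_correct"]),
            p_incorrect=float(d["p_incorrect"]),
            cond_correct=(
                EmpiricalDistribution(d["correct_scores"])
                if d["correct_scores"] else None
            ),
            cond_incorrect=(
                EmpiricalDistribution(d["incorrect_scores"])
                if d["incorrect_scores"] else None
            ),
            tau=float(d.get("tau", 0.0)),
            threshold=float(d.get("threshold", 0.9)),
            score_mode=str(d.get("score_mode", "bayes")),
        )


def confidence_score(score: float, model: ConfidenceModel) -> float:
    """Posterior probability that a prediction with this score is correct."""
    if model.p_incorrect == 0.0:
        return 1.0
    if model.p_correct == 0.0:
        return 0.0
    l_correct, l_incorrect = model.likelihoods(score)
    num = l_correct * model.p_correct
    den = num + l_incorrect * model.p_incorrect
    return num / den


class AbstainDecision(NamedTuple):
    predicted_label: object
    confidence: float
    abstained: bool


def decide(
    y: Sequence[float] | np.ndarray,
    model: ConfidenceModel,
    label_space: Sequence[str] | None = None,
) -> AbstainDecision:
    """Predict-or-abstain for one softmax vector.

    The predicted label is the argmax (ties to the lowest index); the
    case abstains when the confidence is strictly below the threshold.
    """
    y = np.asarray(y, dtype=float)
    score = summarize_softmax(y)
    idx = int(y.argmax())
    label = label_space[idx] if label_space is not None else idx
    if model.score_mode == "raw":
        conf = score
    else:
        conf = confidence_score(score, model)
    return AbstainDecision(label, conf, conf < model.threshold)
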