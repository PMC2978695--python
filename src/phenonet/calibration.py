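"""Probability calibration of raw classifier scores.

SVM decision values are distances to the separating hyperplane and have no
probabilistic meaning of their own. To make them interpretable, the score
distributions of positive and negative examples are each fitted with a
normal distribution; Bayes' rule on the two class-conditional densities
then converts a raw score X into the probability of phenotype association:

    p(y | X) = p(X | y) p(y) / (p(X | y) p(y) + p(X | n) p(n))

Scores below the negative-class mean are assigned probability zero (the
score carries no evidence of association there). Calibration is monotone in
X when the class variances are equal and mu_y > mu_n, so it does not change
rank-based evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .ontology import GoldStandard
from .predict import ScoreVector

logger = logging.getLogger(__name__)

_SIGMA_FLOOR = 1e-6


@dataclass(frozen=True)
class CalibrationModel:
    """Two-Gaussian score model: N(mu_y, sigma_y) vs N(mu_n, sigma_n)."""

    mu_y: float
    sigma_y: float
    mu_n: float
    sigma_n: float
    p_y: float

    def __post_init__(self) -> None:
        if self.sigma_y <= 0 or self.sigma_n <= 0:
            raise ValueError("class standard deviations must be positive")
        if not 0.0 < self.p_y < 1.0:
            raise ValueError("class prior must be in (0, 1)")

    @property
    def p_n(self) -> float:
        return 1.0 - self.p_y


def fit_calibration(
    scores: ScoreVector,
    gold: GoldStandard,
    prior: str = "prevalence",
) -> CalibrationModel:
    """Fit class-conditional normals to raw scores.

    mu and sigma are the sample mean and standard deviation (ddof=1) of the
    scores within each class. ``prior="prevalence"`` sets
    p(y) = n_p / (n_p + n_n); ``prior="half"`` uses 0.5. A zero within-class
    variance is floored at a tiny positive value with a warning.
    """
    pos = [scores[g] for g in sorted(gold.positives) if g in scores.scores]
    neg = [scores[g] for g in sorted(gold.negatives) if g in scores.scores]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 scored genes in each class")
    if prior == "prevalence":
        p_y = gold.n_p / (gold.n_p + gold.n_n)
    elif prior == "half":
        p_y = 0.5
    else:
        raise ValueError("prior must be 'prevalence' or 'half'")
    sds = []
    for vals in (pos, neg):
        sd = float(np.std(vals, ddof=1))
        if sd < _SIGMA_FLOOR:
            logger.warning("zero within-class score variance; flooring sigma")
            sd = _SIGMA_FLOOR
        sds.append(sd)
    return CalibrationModel(
        mu_y=float(np.mean(pos)),
        sigma_y=sds[0],
        mu_n=float(np.mean(neg)),
        sigma_n=sds[1],
        p_y=p_y,
    )


def calibrate(X, model: CalibrationModel):
    """Convert raw score(s) X to association probability p(y | X).

    Scores strictly below mu_n map to exactly 0; a score equal to mu_n is
    calibrated normally. Accepts a scalar or array and returns the same
    shape; results lie in [0, 1].
    """
    x = np.asarray(X, dtype=float)
    like_y = norm.pdf(x, model.mu_y, model.sigma_y) * model.p_y
    like_n = norm.pdf(x, model.mu_n, model.sigma_n) * model.p_n
    denom = like_y + like_n
    with np.errstate(invalid="ignore"):
        p = np.where(denom > 0, like_y / np.where(denom > 0, denom, 1.0), _tail_limit(x, model))
    p = np.where(x < model.mu_n, 0.0, p)
    return float(p) if np.isscalar(X) or np.ndim(X) == 0 else p


def _tail_limit(x, model: CalibrationModel):
    """Limit of p(y|X) when both densities underflow to zero.

    Decided by the log-density difference, which stays finite where the
    pdfs do not.
    """
    log_y = norm.logpdf(x, model.mu_y, model.sigma_y) + np.log(model.p_y)
    log_n = norm.logpdf(x, model.mu_n, model.sigma_n) + np.log(model.p_n)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(np.minimum(log_n - log_y, 700.0)))


def calibrate_scores(scores: ScoreVector, model: CalibrationModel) -> dict[str, float]:
    """Calibrate every gene in a ScoreVector; returns gene -> probability."""
    genes = scores.genes()
    p = calibrate(scores.array(genes), model)
    return {g: float(v) for g, v in zip(genes, np.atleast_1d(p))}
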