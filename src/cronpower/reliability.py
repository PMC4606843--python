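"""Population algebra of the parallel-items measurement model.

A questionnaire instrument with ``k`` parallel items measures a single
latent construct: subject ``i`` has true score ``mu_i`` with population
variance ``sigma_mu2``, and each item score is ``Y_ij = mu_i + e_ij`` with
independent measurement errors of variance ``sigma_e2``.  The item-score
covariance matrix is then compound-symmetric (essential tau-equivalence),

    Sigma = sigma_e2 * I + sigma_mu2 * 11'

with inter-item correlation ``rho = sigma_mu2 / (sigma_mu2 + sigma_e2)``.
Under this structure Cronbach alpha, the reliability of the scale score
``S = sum_j Y_ij``, and the test-retest correlation of ``S`` all coincide:

    C_alpha = k*rho / (1 + rho*(k - 1))

Throughout the package the *true-score variance is held fixed*: making
items more consistent (raising ``rho``) shrinks the error variance
``sigma_e2 = (1/rho - 1) * sigma_mu2`` and hence the total variance
``sigma2 = sigma_mu2 / rho``, which is why every downstream power function
increases with ``C_alpha``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DomainError",
    "InstrumentModel",
    "alpha_from_rho",
    "rho_from_alpha",
    "variance_decomposition",
    "scale_score_variance",
    "cronbach_alpha_sample",
    "testretest_correlation",
    "read_score_matrix",
    "write_score_matrix",
]


class DomainError(ValueError):
    """A design parameter lies outside the domain of the requested quantity."""


def alpha_from_rho(rho: float, k: int) -> float:
    """Cronbach alpha of ``k`` parallel items with inter-item correlation ``rho``.

    ``C_alpha = k*rho / (1 + rho*(k-1))``.  Nondecreasing in both arguments;
    equals ``rho`` when ``k = 1`` (a single item's alpha is its test-retest
    correlation).

    Parameters
    ----------
    rho : float
        Inter-item correlation, in ``[0, 1]``.
    k : int
        Number of items, at least 1.
    """
    _check_k(k)
    if not 0.0 <= rho <= 1.0:
        raise DomainError(f"rho must lie in [0, 1], got {rho}")
    return k * rho / (1.0 + rho * (k - 1))


def rho_from_alpha(c_alpha: float, k: int) -> float:
    """Inter-item correlation implied by Cronbach alpha for ``k`` parallel items.

    Exact inverse of :func:`alpha_from_rho`:
    ``rho = C_alpha / (k - C_alpha*(k-1))``.
    """
    _check_k(k)
    if not 0.0 <= c_alpha <= 1.0:
        raise DomainError(f"c_alpha must lie in [0, 1], got {c_alpha}")
    return c_alpha / (k - c_alpha * (k - 1))


@dataclass(frozen=True)
class InstrumentModel:
    """Population description of a parallel-item instrument.

    Stored as ``(k, rho, sigma_mu2)``; Cronbach alpha and the variance
    components are always derived, never stored, so the state cannot become
    inconsistent.  Construct from a known alpha with :meth:`from_alpha`.

    Parameters
    ----------
    k : int
        Number of items (>= 1).
    rho : float
        Inter-item correlation, in ``(0, 1]``.  Zero is rejected here because
        the fixed-true-score-variance model then implies infinite total
        variance.
    sigma_mu2 : float, default 1.0
        True-score variance (> 0).  The simulation default of 1 loses no
        generality because effect sizes are standardized by ``sigma_mu``.
    """

    k: int
    rho: float
    sigma_mu2: float = 1.0

    def __post_init__(self) -> None:
        _check_k(self.k)
        if not 0.0 < self.rho <= 1.0:
            raise DomainError(f"rho must lie in (0, 1], got {self.rho}")
        if not self.sigma_mu2 > 0.0:
            raise DomainError(f"sigma_mu2 must be positive, got {self.sigma_mu2}")

    @classmethod
    def from_alpha(cls, k: int, c_alpha: float, sigma_mu2: float = 1.0) -> "InstrumentModel":
        """Build a model from Cronbach alpha instead of ``rho``."""
        return cls(k=k, rho=rho_from_alpha(c_alpha, k), sigma_mu2=sigma_mu2)

    @property
    def sigma_e2(self) -> float:
        """Measurement-error variance ``(1/rho - 1) * sigma_mu2``."""
        return (1.0 / self.rho - 1.0) * self.sigma_mu2

    @property
    def sigma2(self) -> float:
        """Total item-score variance ``sigma_mu2 / rho = sigma_mu2 + sigma_e2``."""
        return self.sigma_mu2 / self.rho

    @property
    def c_alpha(self) -> float:
        """Cronbach alpha ``k*rho / (1 + rho*(k-1))``; equals reliability R."""
        return alpha_from_rho(self.rho, self.k)

    @property
    def sigma_mu(self) -> float:
        return math.sqrt(self.sigma_mu2)


def variance_decomposition(model: InstrumentModel) -> tuple[float, float]:
    """Return ``(sigma_e2, sigma2)`` for a model, with ``sigma2 = sigma_mu2 + sigma_e2``."""
    return model.sigma_e2, model.sigma2


def scale_score_variance(model: InstrumentModel) -> float:
    """Variance of the scale score ``S = sum_j Y_ij``.

    Equals ``k * sigma2 * (1 + rho*(k-1))`` and, equivalently,
    ``k**2 * sigma_mu2 / C_alpha``.  Under fixed true-score variance this is
    a *decreasing* function of ``rho``: more consistent items shrink the
    total variance faster than the positive covariances inflate the sum.
    """
    return model.k ** 2 * model.sigma_mu2 / model.c_alpha


def testretest_correlation(model: InstrumentModel) -> float:
    """Correlation of scale scores across two administrations sharing true scores.

    Equals Cronbach alpha (and the reliability R) exactly, which is what
    lets a test-retest correlation stand in for the alpha of a single-item
    instrument.
    """
    return alpha_from_rho(model.rho, model.k)


def cronbach_alpha_sample(scores: np.ndarray | pd.DataFrame) -> float:
    """Sample Cronbach alpha of an ``N x k`` score matrix (rows = subjects).

    Plug-in value of ``k/(k-1) * (1 - trace(Sigma) / 1' Sigma 1)`` with the
    unbiased (``N-1``) sample covariance ``Sigma`` of the columns.  The
    value is passed through unclamped and may be negative for adversarial
    covariance patterns.

    Raises
    ------
    DomainError
        If fewer than 2 items or fewer than 2 subjects are supplied —
        alpha is undefined for one item and covariance needs two subjects.
    """
    values = np.asarray(scores, dtype=float)
    if values.ndim != 2:
        raise DomainError("score matrix must be 2-dimensional (subjects x items)")
    n, k = values.shape
    if k < 2:
        raise DomainError("sample Cronbach alpha requires at least 2 items")
    if n < 2:
        raise DomainError("sample covariance requires at least 2 subjects")
    cov = np.cov(values, rowvar=False, ddof=1)
    total = float(cov.sum())
    if total == 0.0:
        raise DomainError("degenerate score matrix: total covariance is zero")
    return k / (k - 1) * (1.0 - float(np.trace(cov)) / total)


def read_score_matrix(path, *, long: bool | None = None) -> pd.DataFrame:
    """Read an item-score matrix from delimited text (CSV/TSV).

    Wide format: a header row of item labels, one row per subject.  Long
    format: columns ``subject, item, score``, which is pivoted to wide.
    When ``long`` is None the format is inferred from the header.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    frame = pd.read_csv(path, sep=sep)
    cols = [c.lower() for c in frame.columns]
    if long is None:
        long = cols[:3] == ["subject", "item", "score"] or set(cols) == {
            "subject",
            "item",
            "score",
        }
    if long:
        frame.columns = cols
        frame = frame.pivot(index="subject", columns="item", values="score")
        frame = frame.sort_index()
        frame.columns.name = None
        frame.index.name = "subject"
    return frame


def write_score_matrix(frame: pd.DataFrame, path) -> None:
    """Write a wide score matrix as delimited text (TSV if the suffix says so)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    frame.to_csv(path, sep=sep, index=False)


def _check_k(k: int) -> None:
    if not float(k).is_integer() or k < 1:
        raise DomainError(f"k must be a positive integer, got {k}")
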