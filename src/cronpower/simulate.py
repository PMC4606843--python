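"""Monte Carlo generator of parallel-item score data.

Item scores follow the random-intercept model ``Y_ij = mu_i + e_ij`` with
``mu_i ~ Normal(mu, sigma_mu2)`` and ``e_ij ~ Normal(0, sigma_e2)``, giving
the compound-symmetry column covariance ``sigma_e2*I + sigma_mu2*11'``.
Within a subject, repeated administrations (test/retest, pre/post) share the
same true score ``mu_i`` while measurement errors are drawn independently
per administration and per item — the only reading under which the
test-retest correlation of scale scores equals Cronbach alpha.  Treatment
effects enter as a fixed location shift ``delta`` added to every item score
of the shifted administration or group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .power import Design, DesignSpec
from .reliability import DomainError, InstrumentModel

__all__ = [
    "Arm",
    "ItemScoreDataset",
    "SimulationConfig",
    "simulate_scores",
    "simulate_design",
    "scale_scores",
    "dataset_to_frame",
]

# administration labels per design, in generation order
_LAYOUTS: dict[Design, dict[str, tuple[str, ...]]] = {
    Design.ALPHA_TEST: {"cohort": ("test", "retest")},
    Design.PRE_POST: {"cohort": ("pre", "post")},
    Design.BETWEEN_WITHIN: {"control": ("pre", "post"), "treatment": ("pre", "post")},
    Design.TWO_SAMPLE: {"control": ("obs",), "treatment": ("obs",)},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one Monte Carlo experiment.

    The replicate stream is derived from ``seed`` via ``SeedSequence.spawn``,
    so replicate ``r`` can be regenerated in isolation and the full run is
    bit-reproducible.
    """

    model: InstrumentModel
    design: DesignSpec
    mu: float = 0.0
    seed: int = 0
    n_reps: int = 1000

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise DomainError(f"n_reps must be >= 1, got {self.n_reps}")
        if abs(self.model.c_alpha - self.design.c_alpha) > 1e-8:
            raise DomainError(
                f"inconsistent configuration: model implies c_alpha="
                f"{self.model.c_alpha:.6f} but design specifies {self.design.c_alpha:.6f}"
            )

    @classmethod
    def from_parameters(
        cls,
        design: Design | str,
        *,
        k: int,
        c_alpha: float,
        n: int,
        delta_std: float = 0.0,
        alpha_level: float = 0.05,
        sigma_mu2: float = 1.0,
        mu: float = 0.0,
        seed: int = 0,
        n_reps: int = 1000,
    ) -> "SimulationConfig":
        """Build a consistent model/design pair from scalar parameters."""
        model = InstrumentModel.from_alpha(k=k, c_alpha=c_alpha, sigma_mu2=sigma_mu2)
        spec = DesignSpec(
            design=Design(design),
            delta_std=delta_std,
            n=n,
            c_alpha=model.c_alpha,
            alpha_level=alpha_level,
        )
        return cls(model=model, design=spec, mu=mu, seed=seed, n_reps=n_reps)

    def replicate_rngs(self) -> list[np.random.Generator]:
        """One independent generator per replicate, spawned from the root seed."""
        root = np.random.SeedSequence(self.seed)
        return [np.random.Generator(np.random.PCG64(child)) for child in root.spawn(self.n_reps)]


@dataclass
class Arm:
    """One group of subjects: latent true scores plus one matrix per administration."""

    true_scores: np.ndarray
    administrations: dict[str, np.ndarray]


@dataclass
class ItemScoreDataset:
    """Simulated item scores for one replicate of a design.

    ``shift`` is the applied mean shift in score units and ``shifted_at``
    names the (group, administration) that received it.
    """

    design: Design
    arms: dict[str, Arm]
    model: InstrumentModel
    shift: float = 0.0
    shifted_at: tuple[str, str] | None = None

    @property
    def n_per_arm(self) -> int:
        return len(next(iter(self.arms.values())).true_scores)


def simulate_scores(
    n: int,
    model: InstrumentModel,
    mu: float = 0.0,
    shift: float = 0.0,
    rng: np.random.Generator | None = None,
    true_scores: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one ``n x k`` item-score matrix; returns ``(scores, true_scores)``.

    Supplying ``true_scores`` reuses latent values from a previous
    administration (errors are still drawn fresh); otherwise
    ``mu_i ~ Normal(mu, sigma_mu2)`` are drawn.  ``shift`` offsets every
    item score, i.e. shifts the construct mean of this administration.
    """
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    if rng is None:
        rng = np.random.default_rng()
    if true_scores is None:
        true_scores = mu + model.sigma_mu * rng.standard_normal(n)
    errors = np.sqrt(model.sigma_e2) * rng.standard_normal((n, model.k))
    scores = true_scores[:, None] + shift + errors
    return scores, true_scores


def simulate_design(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> ItemScoreDataset:
    """Generate one replicate dataset with the arm/administration layout of the design.

    Layouts: pre-post — one cohort, two administrations, shift on post only;
    between-within — two groups with independent true-score draws, shift on
    the treatment post; two-sample — two independent single-administration
    groups, shift on treatment; alpha-test — one cohort, test and retest,
    no shift.
    """
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed)))
    model, spec = config.model, config.design
    delta = spec.delta_std * model.sigma_mu
    layout = _LAYOUTS[spec.design]
    shifted_at = {
        Design.ALPHA_TEST: None,
        Design.PRE_POST: ("cohort", "post"),
        Design.BETWEEN_WITHIN: ("treatment", "post"),
        Design.TWO_SAMPLE: ("treatment", "obs"),
    }[spec.design]
    arms: dict[str, Arm] = {}
    for group, admins in layout.items():
        true_scores = None
        mats: dict[str, np.ndarray] = {}
        for admin in admins:
            shift = delta if shifted_at == (group, admin) else 0.0
            mats[admin], true_scores = simulate_scores(
                spec.n, model, mu=config.mu, shift=shift, rng=rng, true_scores=true_scores
            )
        arms[group] = Arm(true_scores=true_scores, administrations=mats)
    return ItemScoreDataset(
        design=spec.design,
        arms=arms,
        model=model,
        shift=0.0 if shifted_at is None else delta,
        shifted_at=shifted_at,
    )


def scale_scores(matrix: np.ndarray) -> np.ndarray:
    """Per-subject scale scores: row sums of an ``N x k`` item-score matrix."""
    values = np.asarray(matrix, dtype=float)
    if values.ndim != 2:
        raise DomainError("score matrix must be 2-dimensional (subjects x items)")
    return values.sum(axis=1)


def dataset_to_frame(dataset: ItemScoreDataset) -> pd.DataFrame:
    """Flatten a replicate to a tidy wide table.

    Columns: ``subject, group, time, item1..itemk, true_score``; one row per
    subject per administration.
    """
    k = dataset.model.k
    rows = []
    for group, arm in dataset.arms.items():
        for admin, matrix in arm.administrations.items():
            frame = pd.DataFrame(matrix, columns=[f"item{j + 1}" for j in range(k)])
            frame.insert(0, "subject", np.arange(1, len(matrix) + 1))
            frame.insert(1, "group", group)
            frame.insert(2, "time", admin)
            frame["true_score"] = arm.true_scores
            rows.append(frame)
    return pd.concat(rows, ignore_index=True)
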