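"""Monte Carlo validation engine.

Runs the design-appropriate t-test on each simulated replicate, counts
two-sided rejections, and reports the empirical power with its binomial
standard error alongside the closed-form value.  Also implements the
moment estimators of the treatment effect and their known-variance z
statistics, and the table driver used to regenerate the validation grids.

The tests assume variances are unknown (as a practitioner would):

* pre-post — paired t-test on per-subject scale-score differences;
* between-within — two-sample t-test on per-subject pre-post differences
  between groups (the unique t-test whose known-variance analogue is the
  interaction z statistic);
* two-sample — two-sample t-test on scale scores.

Pooled variance is the default since the model guarantees equal variances
across arms; ``equal_var=False`` switches to Welch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .power import Design, DesignSpec, PowerResult, theoretical_power
from .reliability import DomainError, rho_from_alpha
from .simulate import ItemScoreDataset, SimulationConfig, scale_scores, simulate_design

__all__ = [
    "DeltaEstimate",
    "EmpiricalPowerResult",
    "estimate_delta",
    "run_test",
    "empirical_power",
    "empirical_testretest",
    "reproduce_table",
    "TABLE_GRIDS",
]


class DeltaEstimate(NamedTuple):
    """Moment estimate of the mean shift and its known-variance z statistic."""

    delta_hat: float
    z_stat: float


@dataclass(frozen=True)
class EmpiricalPowerResult:
    """Monte Carlo rejection proportion with its binomial standard error."""

    p_hat: float
    n_reps: int
    seed: int
    theoretical: PowerResult

    @property
    def mc_se(self) -> float:
        return math.sqrt(self.p_hat * (1.0 - self.p_hat) / self.n_reps)


def estimate_delta(design: Design | str, dataset: ItemScoreDataset) -> DeltaEstimate:
    """Moment estimator of the shift and its z statistic with *known* variances.

    The estimator divides the relevant scale-score mean contrast by ``k``;
    its variance uses the true ``(rho, sigma_mu2)`` of the generating model:
    ``2*(1/rho - 1)*sigma_mu2/(k*N)`` (pre-post), four times that
    (between-within), and ``2*(1/rho + k - 1)*sigma_mu2/(k*N)``
    (two-sample).  Under the null the z statistic is standard normal.
    """
    design = Design(design)
    _check_layout(design, dataset)
    model = dataset.model
    k, n = model.k, dataset.n_per_arm
    if design is Design.PRE_POST:
        cohort = dataset.arms["cohort"]
        contrast = np.mean(
            scale_scores(cohort.administrations["post"])
            - scale_scores(cohort.administrations["pre"])
        )
        var = 2.0 * (1.0 / model.rho - 1.0) * model.sigma_mu2 / (k * n)
    elif design is Design.BETWEEN_WITHIN:
        diffs = {
            g: scale_scores(arm.administrations["post"]) - scale_scores(arm.administrations["pre"])
            for g, arm in dataset.arms.items()
        }
        contrast = np.mean(diffs["treatment"]) - np.mean(diffs["control"])
        var = 4.0 * (1.0 / model.rho - 1.0) * model.sigma_mu2 / (k * n)
    elif design is Design.TWO_SAMPLE:
        contrast = np.mean(scale_scores(dataset.arms["treatment"].administrations["obs"])) - np.mean(
            scale_scores(dataset.arms["control"].administrations["obs"])
        )
        var = 2.0 * (1.0 / model.rho + k - 1.0) * model.sigma_mu2 / (k * n)
    else:
        raise DomainError("estimate_delta is undefined for the alpha-test layout")
    delta_hat = float(contrast) / k
    return DeltaEstimate(delta_hat, delta_hat / math.sqrt(var))


def run_test(design: Design | str, dataset: ItemScoreDataset, equal_var: bool = True) -> float:
    """Two-sided p-value of the design-appropriate t-test on scale scores.

    A degenerate all-zero difference vector (possible only with error-free
    items and no shift) is reported as ``p = 1`` — no evidence — rather than
    an exception, keeping Monte Carlo loops total.
    """
    design = Design(design)
    _check_layout(design, dataset)
    if dataset.n_per_arm < 2:
        raise DomainError("t-tests need at least 2 subjects per arm")
    if design is Design.PRE_POST:
        cohort = dataset.arms["cohort"]
        d = scale_scores(cohort.administrations["post"]) - scale_scores(
            cohort.administrations["pre"]
        )
        p = stats.ttest_1samp(d, 0.0).pvalue
    elif design is Design.BETWEEN_WITHIN:
        diffs = {
            g: scale_scores(arm.administrations["post"]) - scale_scores(arm.administrations["pre"])
            for g, arm in dataset.arms.items()
        }
        p = stats.ttest_ind(diffs["treatment"], diffs["control"], equal_var=equal_var).pvalue
    elif design is Design.TWO_SAMPLE:
        p = stats.ttest_ind(
            scale_scores(dataset.arms["treatment"].administrations["obs"]),
            scale_scores(dataset.arms["control"].administrations["obs"]),
            equal_var=equal_var,
        ).pvalue
    else:
        raise DomainError("run_test is undefined for the alpha-test layout")
    p = float(p)
    return p if math.isfinite(p) else 1.0


def empirical_power(config: SimulationConfig, equal_var: bool = True) -> EmpiricalPowerResult:
    """Rejection proportion ``sum 1(p_s < alpha) / n_reps`` over simulated replicates.

    Deterministic given ``config.seed``; each replicate uses its own spawned
    RNG substream.  Strict inequality ``p < alpha`` is used for rejection.
    """
    spec = config.design
    if spec.design is Design.ALPHA_TEST:
        raise DomainError("empirical_power needs a comparison design; see empirical_testretest")
    rejections = 0
    for rng in config.replicate_rngs():
        dataset = simulate_design(config, rng=rng)
        if run_test(spec.design, dataset, equal_var=equal_var) < spec.alpha_level:
            rejections += 1
    return EmpiricalPowerResult(
        p_hat=rejections / config.n_reps,
        n_reps=config.n_reps,
        seed=config.seed,
        theoretical=theoretical_power(spec),
    )


def empirical_testretest(config: SimulationConfig) -> float:
    """Mean Pearson correlation of test vs retest scale scores over replicates.

    The estimand equals Cronbach alpha for parallel items; averaging the
    per-replicate sample correlations mirrors how the equality is validated
    empirically.
    """
    if config.design.design is not Design.ALPHA_TEST:
        raise DomainError("empirical_testretest needs the alpha-test (test/retest) layout")
    corrs = np.empty(config.n_reps)
    for r, rng in enumerate(config.replicate_rngs()):
        dataset = simulate_design(config, rng=rng)
        cohort = dataset.arms["cohort"]
        s_test = scale_scores(cohort.administrations["test"])
        s_retest = scale_scores(cohort.administrations["retest"])
        if np.ptp(s_test) == 0.0 or np.ptp(s_retest) == 0.0:
            corrs[r] = 1.0  # error-free items: both sums are k*mu_i exactly
        else:
            corrs[r] = np.corrcoef(s_test, s_retest)[0, 1]
    return float(corrs.mean())


# validation grids: (design, [(n, delta_std), ...], c_alpha list, k list)
TABLE_GRIDS: dict[int, tuple[Design, list[tuple[int, float]], list[float], list[int]]] = {
    1: (Design.ALPHA_TEST, [(30, 0.0), (50, 0.0)], [round(0.1 * i, 1) for i in range(1, 10)], [5, 10]),
    2: (Design.PRE_POST, [(30, 0.4), (50, 0.3)], [0.5, 0.6, 0.7, 0.8, 0.9], [5, 10]),
    3: (Design.BETWEEN_WITHIN, [(30, 0.4), (50, 0.3)], [0.5, 0.6, 0.7, 0.8, 0.9], [5, 10]),
    4: (Design.TWO_SAMPLE, [(50, 0.7), (100, 0.5)], [0.5, 0.6, 0.7, 0.8, 0.9], [5, 10]),
}


def reproduce_table(table_id: int, n_reps: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Regenerate one of the four validation grids as a tidy table.

    Grid 1 tabulates the mean test-retest correlation against its target
    (Cronbach alpha); grids 2-4 tabulate empirical vs theoretical power of
    the pre-post, between-within and two-sample tests.  Columns:
    ``design, n, k, delta, c_alpha, rho, power_theory, power_empirical,
    mc_se, n_reps, seed``.  For grid 1 ``power_theory`` holds the target
    correlation and ``mc_se`` the standard error of the mean correlation.
    Deterministic given ``seed`` (one spawned substream per cell).
    """
    if table_id not in TABLE_GRIDS:
        raise DomainError(f"unknown table id {table_id}; choose from 1-4")
    design, blocks, alphas, ks = TABLE_GRIDS[table_id]
    cells = [
        (n, delta, c_alpha, k) for (n, delta) in blocks for c_alpha in alphas for k in ks
    ]
    children = np.random.SeedSequence(seed).spawn(len(cells))
    rows = []
    for (n, delta, c_alpha, k), child in zip(cells, children):
        cell_seed = int(child.generate_state(1, dtype=np.uint32)[0] % 2**31)
        config = SimulationConfig.from_parameters(
            design,
            k=k,
            c_alpha=c_alpha,
            n=n,
            delta_std=delta,
            seed=cell_seed,
            n_reps=n_reps,
        )
        if design is Design.ALPHA_TEST:
            corr = empirical_testretest(config)
            theory, emp = c_alpha, corr
            mc_se = math.sqrt(max(0.0, 1.0 - corr**2)) / math.sqrt(n_reps)
        else:
            result = empirical_power(config)
            theory, emp, mc_se = result.theoretical.power, result.p_hat, result.mc_se
        rows.append(
            {
                "design": design.value,
                "n": n,
                "k": k,
                "delta": delta,
                "c_alpha": c_alpha,
                "rho": rho_from_alpha(c_alpha, k),
                "power_theory": theory,
                "power_empirical": emp,
                "mc_se": mc_se,
                "n_reps": n_reps,
                "seed": cell_seed,
            }
        )
    return pd.DataFrame(rows)


def _check_layout(design: Design, dataset: ItemScoreDataset) -> None:
    if dataset.design is not design:
        raise DomainError(
            f"dataset layout is {dataset.design.value!r} but {design.value!r} was requested"
        )
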