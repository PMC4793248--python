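"""Monte-Carlo evaluation of matching x analysis x estimation combinations.

:func:`run_simulation` repeats, over seeded replicates: generate a dataset,
fit the shared nuisance models, apply every matching method in the grid, run
every analysis on the weighted samples, and record the ATT estimates.  The
replicate estimates are then summarised per combination as percent bias,
variance (divisor ``n``, so the identity ``MSE = bias^2 + variance`` is
exact) and MSE, with deterministic ranks on all three.

:func:`bootstrap_applied` provides the analogous exercise for an applied
dataset: nonparametric bootstrap resamples drawn within treatment arm, every
combination re-run per resample, and the replicate estimates summarised
against a reference value (for instance an experimental benchmark).

Nuisance fits are shared across combinations within a replicate: the
parametric and ensemble propensity fits serve both matching and TMLE, and the
outcome fits for TMLE are computed once; only g-computation refits its
(parametric, cheap) outcome model per matched sample, because its definition
requires training on the weighted sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import balance as bal
from .estimators import TMLEConfig, estimate_gcomp, estimate_naive, estimate_tmle_att
from .matching import (
    GAConfig,
    MATCH_METHODS,
    match_full,
    match_genetic,
    match_greedy_nn,
    match_none,
    match_optimal,
    match_subclassification,
    weights_iptw_att,
)
from .nuisance import (
    EnsembleSpec,
    fit_ensemble,
    fit_outcome_parametric,
    fit_propensity_parametric,
)
from .synthetic import ScenarioSpec, StudyData, generate_dataset, true_att

__all__ = [
    "Triple",
    "default_grid",
    "performance",
    "rank_table",
    "run_simulation",
    "bootstrap_applied",
    "SimulationResult",
    "BootstrapResult",
    "evaluate_grid",
]

logger = logging.getLogger(__name__)

ANALYSES = ("naive", "gcomp", "tmle")


@dataclass(frozen=True)
class Triple:
    """One (matching, analysis, estimation) combination."""

    match: str
    analysis: str
    estimation: str

    def __post_init__(self):
        if self.match not in MATCH_METHODS:
            raise ValueError(f"unknown match method {self.match!r}")
        if self.analysis not in ANALYSES:
            raise ValueError(f"unknown analysis {self.analysis!r}")

    @property
    def label(self) -> str:
        return f"{self.match}|{self.analysis}|{self.estimation}"


def default_grid() -> list[Triple]:
    """The 28-combination grid: 7 matching options x 4 analyses.

    Analyses: naive contrast; parametric g-computation; TMLE with parametric
    nuisances; TMLE with ensemble nuisances.  (G-computation is parametric
    only.)
    """
    grid = []
    for m in MATCH_METHODS:
        grid.append(Triple(m, "naive", "none"))
        grid.append(Triple(m, "gcomp", "parametric"))
        grid.append(Triple(m, "tmle", "parametric"))
        grid.append(Triple(m, "tmle", "ensemble"))
    return grid


def performance(estimates, psi_true: float) -> dict:
    """Percent bias, variance (divisor n) and MSE of replicate estimates."""
    est = np.asarray(estimates, dtype=float)
    est = est[np.isfinite(est)]
    if est.size < 2:
        raise ValueError("need at least two finite estimates")
    bias = float(est.mean() - psi_true)
    var = float(est.var())  # divisor n: makes mse = bias^2 + var exact
    out = {"abs_bias": bias, "variance": var, "mse": bias**2 + var}
    if psi_true == 0:
        raise ValueError("percent bias undefined for psi_true = 0 (absolute bias available)")
    out["pct_bias"] = 100.0 * bias / psi_true
    return out


def _dense_rank(values: pd.Series) -> pd.Series:
    """Deterministic ranks 1..n: ties broken by the row label (lexicographic)."""
    order = sorted(values.index, key=lambda k: (round(float(values[k]), 12), str(k)))
    return pd.Series({k: i + 1 for i, k in enumerate(order)})


def rank_table(perf: pd.DataFrame) -> pd.DataFrame:
    """Append bias/variance/MSE ranks to a performance table."""
    out = perf.copy()
    out["bias_rank"] = _dense_rank(out["pct_bias"].abs())
    out["var_rank"] = _dense_rank(out["variance"])
    out["mse_rank"] = _dense_rank(out["mse"])
    return out


# ---------------------------------------------------------------------------
# Single-dataset grid evaluation
# ---------------------------------------------------------------------------


def _build_matches(data, grid, ps_param, ga_config, n_subclasses):
    matches = {}
    for m in {t.match for t in grid}:
        if m == "none":
            matches[m] = match_none(data)
        elif m == "nn":
            matches[m] = match_greedy_nn(data, ps_param)
        elif m == "optimal":
            matches[m] = match_optimal(data, ps_param)
        elif m == "subclass":
            matches[m] = match_subclassification(data, ps_param, n_subclasses)
        elif m == "full":
            matches[m] = match_full(data, ps_param)
        elif m == "iptw":
            matches[m] = weights_iptw_att(ps_param, data.treatment)
        elif m == "genetic":
            matches[m] = match_genetic(data, ga_config)
    return matches


def evaluate_grid(
    data: StudyData,
    grid: list[Triple],
    ensemble_spec: EnsembleSpec | None = None,
    ga_config: GAConfig | None = None,
    n_subclasses: int = 10,
    tmle_config: TMLEConfig | None = None,
    return_matches: bool = False,
):
    """Run every combination of the grid on one dataset.

    Returns a dict mapping each triple's label to its ATT estimate (NaN for a
    combination that failed, with the reason logged).
    """
    estimates: dict[str, float] = {}
    ps_param = fit_propensity_parametric(data)
    need_ens = any(t.estimation == "ensemble" for t in grid)
    ps_ens = q_ens = None
    if need_ens:
        ps_ens = fit_ensemble(data, "treatment", spec=ensemble_spec)
        q_ens = fit_ensemble(data, "outcome", spec=ensemble_spec)
    q_param_shared = fit_outcome_parametric(data)
    matches = _build_matches(data, grid, ps_param, ga_config, n_subclasses)
    for t in grid:
        try:
            match = matches[t.match]
            if t.analysis == "naive":
                est = estimate_naive(data, match)
            elif t.analysis == "gcomp":
                qfit = fit_outcome_parametric(data, weights=match.weights)
                est = estimate_gcomp(data, match, qfit)
            else:
                q = q_param_shared if t.estimation == "parametric" else q_ens
                g = ps_param if t.estimation == "parametric" else ps_ens
                est = estimate_tmle_att(data, match, q, g, tmle_config)
            estimates[t.label] = est.estimate
        except Exception as exc:
            logger.warning("combination %s failed: %s", t.label, exc)
            estimates[t.label] = np.nan
    if return_matches:
        return estimates, matches
    return estimates


def _balance_dedicated_ps(data: StudyData):
    """Balance-dedicated propensity fit, distinct from the matching fit.

    On the packaged simulations the known treatment-model form (W1, W2, W1^2,
    W1*W2 logistic) is used; otherwise a main-terms logistic fit.
    """
    import statsmodels.api as sm

    if list(data.covariates.columns) == ["W1", "W2"]:
        w1 = data.covariates["W1"].to_numpy()
        w2 = data.covariates["W2"].to_numpy()
        X = np.column_stack([np.ones(data.n), w1, w2, w1**2, w1 * w2])
        res = sm.GLM(data.treatment, X, family=sm.families.Binomial()).fit()
        return np.asarray(res.fittedvalues)
    return fit_propensity_parametric(data).fitted_ps


def _balance_dedicated_prognostic(data: StudyData):
    """Prognostic score from the known outcome form on simulations."""
    if list(data.covariates.columns) == ["W1", "W2"]:
        w1 = data.covariates["W1"].to_numpy()
        w2 = data.covariates["W2"].to_numpy()
        design = np.column_stack([w1, w2, w2**2, w1 * w2])
        return bal.prognostic_scores(data, design=design)
    return bal.prognostic_scores(data)


# ---------------------------------------------------------------------------
# Monte-Carlo study
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Replicate estimates and their performance summary."""

    estimates: pd.DataFrame  # reps x combination labels
    performance: pd.DataFrame
    psi_true: float
    spec_name: str
    balance: pd.DataFrame | None = None  # match method x mean balance metrics

    def to_csv(self, path) -> None:
        self.performance.to_csv(path)


def run_simulation(
    spec: ScenarioSpec,
    grid: list[Triple] | None = None,
    reps: int = 1000,
    n: int = 1000,
    seed: int = 0,
    ensemble_spec: EnsembleSpec | None = None,
    ga_config: GAConfig | None = None,
    n_subclasses: int = 10,
    tmle_config: TMLEConfig | None = None,
    collect_balance: bool = False,
    max_failure_rate: float = 0.01,
    progress: bool = False,
) -> SimulationResult:
    """Monte-Carlo comparison of all grid combinations under one scenario.

    Fully reproducible from ``(spec, seed)``: replicate data seeds and all
    stochastic learners derive from a single seed sequence.  A combination
    failing on more than ``max_failure_rate`` of replicates aborts the run.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    grid = grid if grid is not None else default_grid()
    psi_true = spec.oracle_att if spec.oracle_att is not None else true_att(spec)
    root = np.random.SeedSequence(seed)
    children = root.spawn(reps)
    rows = []
    balance_acc: list[pd.DataFrame] = []
    for r, child in enumerate(children):
        sub = child.generate_state(2)
        data = generate_dataset(spec, n, int(sub[0]) % 2**31)
        rep_seed = int(sub[1]) % 2**31
        es = ensemble_spec or EnsembleSpec()
        es = EnsembleSpec(learners=es.learners, folds=es.folds, seed=rep_seed, loss=es.loss)
        ga = ga_config or GAConfig()
        ga = GAConfig(
            pop_size=ga.pop_size,
            generations=ga.generations,
            seed=rep_seed,
            fitness=ga.fitness,
            mutation_rate=ga.mutation_rate,
            mutation_scale=ga.mutation_scale,
            max_log_weight=ga.max_log_weight,
        )
        out = evaluate_grid(
            data,
            grid,
            ensemble_spec=es,
            ga_config=ga,
            n_subclasses=n_subclasses,
            tmle_config=tmle_config,
            return_matches=collect_balance,
        )
        if collect_balance:
            out, matches = out
            ps_bal = _balance_dedicated_ps(data)
            prog = _balance_dedicated_prognostic(data)
            recs = {}
            for m, match in matches.items():
                rep = bal.balance_report(data, match, ps_bal, prognostic=prog)
                recs[m] = rep.to_series()
            balance_acc.append(pd.DataFrame(recs).T)
        rows.append(out)
        if progress and (r + 1) % 25 == 0:
            logger.info("replicate %d/%d done", r + 1, reps)
    est = pd.DataFrame(rows)
    fail = est.isna().mean()
    bad = fail[fail > max_failure_rate]
    if len(bad):
        raise RuntimeError(f"combinations failing on >{max_failure_rate:.0%} of replicates: {dict(bad)}")
    perf = pd.DataFrame({lbl: performance(est[lbl], psi_true) for lbl in est.columns}).T
    perf.index.name = "combination"
    perf = rank_table(perf)
    balance_df = None
    if collect_balance:
        balance_df = (
            pd.concat(balance_acc).groupby(level=0).mean().loc[
                [m for m in MATCH_METHODS if m in {t.match for t in grid}]
            ]
        )
    return SimulationResult(
        estimates=est,
        performance=perf,
        psi_true=psi_true,
        spec_name=spec.name,
        balance=balance_df,
    )


# ---------------------------------------------------------------------------
# Applied-data bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Replicate estimates over bootstrap resamples of an applied dataset."""

    estimates: pd.DataFrame
    reference_value: float
    performance: pd.DataFrame
    intervals: pd.DataFrame  # percentile 95% CI per combination


def bootstrap_applied(
    data: StudyData,
    grid: list[Triple] | None = None,
    B: int = 500,
    seed: int = 0,
    reference: float = 0.0,
    ensemble_spec: EnsembleSpec | None = None,
    ga_config: GAConfig | None = None,
    n_subclasses: int = 5,
    tmle_config: TMLEConfig | None = None,
) -> BootstrapResult:
    """Seeded nonparametric bootstrap of every grid combination.

    Units are resampled with replacement *within treatment arm* (so both
    arms always survive), every combination is run per resample, and the
    replicate estimates are summarised against ``reference``.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    grid = grid if grid is not None else default_grid()
    a = data.treatment
    t_idx = np.flatnonzero(a == 1)
    c_idx = np.flatnonzero(a == 0)
    root = np.random.SeedSequence(seed)
    rows = []
    for child in root.spawn(B):
        rng = np.random.default_rng(child)
        take = np.concatenate(
            [rng.choice(t_idx, size=t_idx.size), rng.choice(c_idx, size=c_idx.size)]
        )
        boot = StudyData(
            covariates=data.covariates.iloc[take].reset_index(drop=True),
            treatment=a[take],
            outcome=data.outcome[take],
        )
        rep_seed = int(child.generate_state(1)[0]) % 2**31
        es = ensemble_spec or EnsembleSpec()
        es = EnsembleSpec(learners=es.learners, folds=es.folds, seed=rep_seed, loss=es.loss)
        ga = ga_config or GAConfig()
        ga = GAConfig(
            pop_size=ga.pop_size,
            generations=ga.generations,
            seed=rep_seed,
            fitness=ga.fitness,
        )
        rows.append(
            evaluate_grid(
                boot,
                grid,
                ensemble_spec=es,
                ga_config=ga,
                n_subclasses=n_subclasses,
                tmle_config=tmle_config,
            )
        )
    est = pd.DataFrame(rows)
    perf = pd.DataFrame(
        {lbl: performance(est[lbl], reference) for lbl in est.columns if reference != 0}
        if reference != 0
        else {
            lbl: {
                "abs_bias": est[lbl].mean() - reference,
                "variance": est[lbl].var(ddof=0),
                "mse": (est[lbl].mean() - reference) ** 2 + est[lbl].var(ddof=0),
            }
            for lbl in est.columns
        }
    ).T
    if "mse" in perf.columns and "pct_bias" in perf.columns:
        perf = rank_table(perf)
    intervals = pd.DataFrame(
        {
            lbl: {
                "lo": float(np.nanpercentile(est[lbl], 2.5)),
                "hi": float(np.nanpercentile(est[lbl], 97.5)),
            }
            for lbl in est.columns
        }
    ).T
    return BootstrapResult(
        estimates=est, reference_value=reference, performance=perf, intervals=intervals
    )
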