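"""Covariate-balance diagnostics for weighted matched samples.

The report collects ten metrics: the mean, median and maximum absolute
standardized mean difference (ASMD) across the balance covariates; the
percent of covariates with ASMD below 20%, 10%, 5% and 1%; the ASMD of the
propensity score; the ASMD of the prognostic score (the predicted outcome
from a model fit among controls only); and the mean absolute Welch
t-statistic across covariates, computed from weighted moments with Kish
effective sample sizes.

Conventions: every ASMD denominator is the standard deviation of that
covariate among *treated units in the original, unmatched sample*, so the
same yardstick applies before and after any matching method.  For the
packaged two-covariate simulations the balance table is computed on an
eight-term basis (W1, W2, their squares, the interaction, and three hinge
terms of W2) so that balance on nonlinear features is visible; for applied
data the covariate columns are used as they are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matching import MatchResult, effective_sample_size
from .synthetic import StudyData

__all__ = [
    "BalanceReport",
    "asmd",
    "prognostic_scores",
    "balance_report",
    "balance_terms",
]

#: Hinge knots for the W2 spline terms of the simulation balance basis
#: (quartiles of the standard normal).
W2_KNOTS = (-0.6745, 0.0, 0.6745)


def asmd(x, treatment, weights=None, denom_sd: float | None = None) -> float:
    """Absolute standardized mean difference of ``x`` between arms.

    ``|weighted mean(x | A=1) - weighted mean(x | A=0)| / denom_sd``.  If no
    denominator is supplied, the treated-group standard deviation of ``x`` is
    used.  Invariant to rescaling the weights and to affine rescaling of
    ``x`` (when the denominator is computed from the same ``x``).
    """
    x = np.asarray(x, dtype=float)
    a = np.asarray(treatment)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if denom_sd is None:
        denom_sd = float(x[a == 1].std(ddof=1))
    if not denom_sd > 0:
        raise ValueError("zero ASMD denominator; drop constant covariates first")
    mt = np.average(x[a == 1], weights=w[a == 1])
    mc = np.average(x[a == 0], weights=w[a == 0])
    return float(abs(mt - mc) / denom_sd)


def prognostic_scores(data: StudyData, fit_weights=None, design: np.ndarray | None = None) -> np.ndarray:
    """Predicted outcomes from a main-terms linear model fit among controls.

    The model is trained on control units only (optionally weighted) and its
    predictions are emitted for every unit; balance on this score proxies
    balance on outcome-relevant covariate combinations.
    """
    a = data.treatment
    X = data.X if design is None else np.asarray(design, dtype=float)
    ctrl = a == 0
    if ctrl.sum() < 2:
        raise ValueError("need at least two control units to fit the prognostic model")
    w = np.ones(data.n) if fit_weights is None else np.asarray(fit_weights, dtype=float)
    Xc = np.column_stack([np.ones(int(ctrl.sum())), X[ctrl]])
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("prognostic design is rank deficient")
    sw = np.sqrt(w[ctrl])
    beta, *_ = np.linalg.lstsq(Xc * sw[:, None], data.outcome[ctrl] * sw, rcond=None)
    return beta[0] + X @ beta[1:]


def balance_terms(data: StudyData) -> pd.DataFrame:
    """The balance covariate basis for a study.

    Two-covariate simulated studies (columns ``W1``, ``W2``) expand to the
    eight-term basis described in the module docstring; any other study uses
    its covariate columns unchanged.
    """
    cols = list(data.covariates.columns)
    if cols == ["W1", "W2"]:
        w1 = data.covariates["W1"].to_numpy()
        w2 = data.covariates["W2"].to_numpy()
        terms = {
            "W1": w1,
            "W2": w2,
            "W1^2": w1**2,
            "W2^2": w2**2,
            "W1*W2": w1 * w2,
        }
        for k in W2_KNOTS:
            terms[f"(W2-{k:g})+"] = np.maximum(w2 - k, 0.0)
        return pd.DataFrame(terms)
    return data.covariates.copy()


@dataclass
class BalanceReport:
    """The ten balance metrics of one weighted matched sample."""

    per_covariate_asmd: pd.Series
    mean_asmd: float
    median_asmd: float
    max_asmd: float
    pct_under_20: float
    pct_under_10: float
    pct_under_5: float
    pct_under_1: float
    asmd_prognostic: float
    asmd_propensity: float
    mean_abs_t: float

    def __post_init__(self):
        pcts = (self.pct_under_1, self.pct_under_5, self.pct_under_10, self.pct_under_20)
        if not all(x <= y + 1e-12 for x, y in zip(pcts, pcts[1:])):
            raise AssertionError("ASMD threshold percentages must be monotone")

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "mean_asmd": self.mean_asmd,
                "median_asmd": self.median_asmd,
                "max_asmd": self.max_asmd,
                "pct_under_20": self.pct_under_20,
                "pct_under_10": self.pct_under_10,
                "pct_under_5": self.pct_under_5,
                "pct_under_1": self.pct_under_1,
                "asmd_prognostic": self.asmd_prognostic,
                "asmd_propensity": self.asmd_propensity,
                "mean_abs_t": self.mean_abs_t,
            }
        )


def _score_asmd(score, a, w) -> float:
    """ASMD of a derived score; a degenerate (constant) score is balanced."""
    score = np.asarray(score, dtype=float)
    if score[a == 1].std(ddof=1) == 0:
        mt = np.average(score[a == 1], weights=w[a == 1])
        mc = np.average(score[a == 0], weights=w[a == 0])
        if abs(mt - mc) < 1e-12:
            return 0.0
    return asmd(score, a, w)


def _welch_t(x, a, w) -> float:
    wt, wc = w[a == 1], w[a == 0]
    xt, xc = x[a == 1], x[a == 0]
    mt = np.average(xt, weights=wt)
    mc = np.average(xc, weights=wc)
    vt = np.average((xt - mt) ** 2, weights=wt)
    vc = np.average((xc - mc) ** 2, weights=wc)
    nt = effective_sample_size(wt)
    nc = effective_sample_size(wc)
    se = np.sqrt(vt / nt + vc / nc)
    return 0.0 if se == 0 else float((mt - mc) / se)


def balance_report(
    data: StudyData,
    match: MatchResult,
    ps_for_balance,
    prognostic: np.ndarray | None = None,
) -> BalanceReport:
    """Compute the ten balance metrics for one matched sample.

    ``ps_for_balance`` should come from a balance-dedicated propensity fit,
    distinct from the one used to construct the matching.  ASMD denominators
    are treated-group SDs from the unmatched sample.
    """
    terms = balance_terms(data)
    a = data.treatment
    w = match.weights
    ps = ps_for_balance.fitted_ps if hasattr(ps_for_balance, "fitted_ps") else np.asarray(
        ps_for_balance, dtype=float
    )
    denoms = terms.to_numpy()[a == 1].std(axis=0, ddof=1)
    per = pd.Series(
        {
            c: asmd(terms[c].to_numpy(), a, w, denom_sd=float(d))
            for c, d in zip(terms.columns, denoms)
        }
    )
    vals = per.to_numpy()
    if prognostic is None:
        prognostic = prognostic_scores(data, design=terms.to_numpy())
    report = BalanceReport(
        per_covariate_asmd=per,
        mean_asmd=float(vals.mean()),
        median_asmd=float(np.median(vals)),
        max_asmd=float(vals.max()),
        pct_under_20=float(100.0 * np.mean(vals < 0.20)),
        pct_under_10=float(100.0 * np.mean(vals < 0.10)),
        pct_under_5=float(100.0 * np.mean(vals < 0.05)),
        pct_under_1=float(100.0 * np.mean(vals < 0.01)),
        asmd_prognostic=_score_asmd(prognostic, a, w),
        asmd_propensity=_score_asmd(ps, a, w),
        mean_abs_t=float(
            np.mean([abs(_welch_t(terms[c].to_numpy(), a, w)) for c in terms.columns])
        ),
    )
    return report
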