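"""Matching methods as pre-processing: every method emits per-unit weights.

Matching is treated as a pre-processing step that reweights (or discards)
control units so the weighted control group resembles the treated group on
observed covariates; any outcome analysis can then be run on the weighted
sample.  The universal output is a :class:`MatchResult` holding one
nonnegative weight per unit.

Conventions shared by the propensity-based methods:

- treated units always keep weight 1 (the ATT estimand averages over the
  treated as they are);
- control weights are rescaled so their total equals the number of treated
  units, which makes naive weighted contrasts location-correct and comparable
  across methods (IPTW is the exception: raw odds weights ``g/(1-g)`` are
  kept, as is conventional);
- ties in nearest-neighbour choices break to the lowest row index, so results
  are deterministic and permutation-equivariant up to exact ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .synthetic import StudyData

__all__ = [
    "MatchResult",
    "GAConfig",
    "match_none",
    "match_greedy_nn",
    "match_optimal",
    "match_subclassification",
    "match_full",
    "weights_iptw_att",
    "match_genetic",
    "gen_mahalanobis",
    "effective_sample_size",
    "MATCH_METHODS",
]

logger = logging.getLogger(__name__)

MATCH_METHODS = ("none", "nn", "optimal", "subclass", "full", "iptw", "genetic")


def effective_sample_size(weights) -> float:
    """Kish effective sample size ``(sum w)^2 / sum w^2`` of one arm."""
    w = np.asarray(weights, dtype=float)
    w = w[w > 0]
    if w.size == 0:
        raise ValueError("no positive weights in arm")
    return float(w.sum() ** 2 / np.sum(w**2))


@dataclass
class MatchResult:
    """Per-unit weights produced by a matching method."""

    weights: np.ndarray
    method: str
    subclass: np.ndarray | None = None
    sets: list[tuple[list[int], list[int]]] | None = None
    ess_treated: float = 0.0
    ess_control: float = 0.0
    distance_used: str = "propensity"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0) or not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite and nonnegative")
        if self.method not in MATCH_METHODS:
            raise ValueError(f"unknown method {self.method!r}")


def _finalize(data: StudyData, weights: np.ndarray, method: str, **kw) -> MatchResult:
    a = data.treatment
    return MatchResult(
        weights=weights,
        method=method,
        ess_treated=effective_sample_size(weights[a == 1]),
        ess_control=effective_sample_size(weights[a == 0]),
        **kw,
    )


def _rescale_controls(weights: np.ndarray, treatment: np.ndarray) -> np.ndarray:
    """Scale control weights so they sum to the treated weight total."""
    w = weights.copy()
    ctrl = treatment == 0
    tot = w[ctrl].sum()
    if tot <= 0:
        raise ValueError("no control unit received positive weight")
    w[ctrl] *= w[treatment == 1].sum() / tot
    return w


def _ps_vector(ps, data: StudyData) -> np.ndarray:
    p = ps.fitted_ps if hasattr(ps, "fitted_ps") else np.asarray(ps, dtype=float)
    if p.shape != (data.n,):
        raise ValueError("propensity vector length mismatch")
    return p


def match_none(data: StudyData) -> MatchResult:
    """The unmatched sample: every unit keeps weight 1."""
    return _finalize(data, np.ones(data.n), "none")


def match_greedy_nn(data: StudyData, ps) -> MatchResult:
    """1:1 greedy nearest-neighbour matching with replacement on the propensity.

    Each treated unit is matched to the control with the smallest absolute
    propensity difference; controls may be reused.  Treated units are
    processed in descending propensity order (irrelevant to the result under
    replacement, but it fixes the log order).
    """
    p = _ps_vector(ps, data)
    a = data.treatment
    t_idx = np.flatnonzero(a == 1)
    c_idx = np.flatnonzero(a == 0)
    if c_idx.size == 0:
        raise ValueError("no control units")
    order = t_idx[np.argsort(-p[t_idx], kind="stable")]
    w = np.zeros(data.n)
    w[t_idx] = 1.0
    pc = p[c_idx]
    for i in order:
        d = np.abs(pc - p[i])
        j = c_idx[int(np.argmin(d))]  # argmin returns lowest index on ties
        w[j] += 1.0
    w = _rescale_controls(w, a)
    return _finalize(data, w, "nn")


def match_optimal(data: StudyData, ps) -> MatchResult:
    """1:1 optimal matching without replacement, solved as an assignment problem.

    Minimises the total absolute propensity difference over all one-to-one
    pairings of treated to distinct controls; unmatched controls get weight 0.
    """
    p = _ps_vector(ps, data)
    a = data.treatment
    t_idx = np.flatnonzero(a == 1)
    c_idx = np.flatnonzero(a == 0)
    if c_idx.size < t_idx.size:
        raise ValueError(
            f"optimal 1:1 matching infeasible: {t_idx.size} treated but only "
            f"{c_idx.size} controls"
        )
    D = np.abs(p[t_idx][:, None] - p[c_idx][None, :])
    rows, cols = linear_sum_assignment(D)
    w = np.zeros(data.n)
    w[t_idx] = 1.0
    w[c_idx[cols]] = 1.0
    pairs = [([int(t_idx[r])], [int(c_idx[c])]) for r, c in zip(rows, cols)]
    return _finalize(
        data, w, "optimal", sets=pairs, extra={"total_distance": float(D[rows, cols].sum())}
    )


def match_subclassification(data: StudyData, ps, n_subclasses: int = 10) -> MatchResult:
    """Stratification on quantiles of the propensity among treated units.

    Subclass boundaries are the treated-propensity quantiles (ATT-appropriate);
    every unit is assigned by its propensity with half-open intervals
    ``[low, high)`` and the last interval closed.  Controls in subclass ``s``
    receive weight ``n_treated_s / n_control_s``; subclasses that contain no
    control are merged with the nearest nonempty neighbour.
    """
    if n_subclasses < 2:
        raise ValueError("n_subclasses must be >= 2")
    p = _ps_vector(ps, data)
    a = data.treatment
    qs = np.quantile(p[a == 1], np.linspace(0, 1, n_subclasses + 1)[1:-1])
    # assign: number of boundaries strictly below the value
    sub = np.searchsorted(qs, p, side="right")
    # merge subclasses with no treated or no control into the nearest
    # neighbouring subclass (toward the centre) until all are valid
    labels = sorted(set(sub.tolist()))
    merged = True
    while merged and len(labels) > 1:
        merged = False
        for s in list(labels):
            mask = sub == s
            nt = int((a[mask] == 1).sum())
            nc = int((a[mask] == 0).sum())
            if nt == 0 or nc == 0:
                pos = labels.index(s)
                neighbour = labels[pos - 1] if pos > 0 else labels[pos + 1]
                logger.info("merging empty subclass %d into %d", s, neighbour)
                sub[mask] = neighbour
                labels.remove(s)
                merged = True
                break
    w = np.zeros(data.n)
    w[a == 1] = 1.0
    any_control = False
    for s in labels:
        mask = sub == s
        nt = int((a[mask] == 1).sum())
        nc = int((a[mask] == 0).sum())
        if nc > 0 and nt > 0:
            w[mask & (a == 0)] = nt / nc
            any_control = True
    if not any_control:
        raise ValueError("no subclass contains both treated and control units")
    w = _rescale_controls(w, a)
    return _finalize(data, w, "subclass", subclass=sub)


def match_full(data: StudyData, ps) -> MatchResult:
    """Optimal full matching: partition all units into treated+control sets.

    Every unit is placed in exactly one matched set containing at least one
    treated and one control; the total within-set treated-control propensity
    distance is minimised.  The minimal partition is always a union of
    "stars" (one treated with several controls, or one control with several
    treated), which makes the problem a minimum-weight edge cover of the
    bipartite distance graph; that in turn reduces exactly to an assignment
    problem on pair "savings".

    ATT weights: treated 1; controls in set ``s`` get ``n_treated_s /
    n_control_s``, rescaled so total control weight equals the treated count.
    """
    p = _ps_vector(ps, data)
    a = data.treatment
    t_idx = np.flatnonzero(a == 1)
    c_idx = np.flatnonzero(a == 0)
    nt, nc = t_idx.size, c_idx.size
    D = np.abs(p[t_idx][:, None] - p[c_idx][None, :])
    cheapest_t = D.min(axis=1)
    cheapest_c = D.min(axis=0)
    # savings of covering a (t, c) pair by one shared edge instead of each
    # unit's cheapest edge
    S = np.maximum(cheapest_t[:, None] + cheapest_c[None, :] - D, 0.0)
    # max-weight partial matching: pad with zero columns so any row may stay
    # unmatched; minimise the negated savings
    pad = np.zeros((nt, nt))
    rows, cols = linear_sum_assignment(np.hstack([-S, pad]))
    partner_of_t = {}
    for r, c in zip(rows, cols):
        if c < nc and S[r, c] > 0:
            partner_of_t[r] = c
    matched_c = set(partner_of_t.values())
    # build edge cover: matched pairs plus each unmatched unit's cheapest edge
    edges = [(r, c) for r, c in partner_of_t.items()]
    for r in range(nt):
        if r not in partner_of_t:
            edges.append((r, int(np.argmin(D[r]))))
    for c in range(nc):
        if c not in matched_c:
            edges.append((int(np.argmin(D[:, c])), c))
    # connected components of the cover are the matched sets
    parent = list(range(nt + nc))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for r, c in edges:
        ra, rb = find(r), find(nt + c)
        if ra != rb:
            parent[ra] = rb
    comp: dict[int, tuple[list[int], list[int]]] = {}
    for r in range(nt):
        comp.setdefault(find(r), ([], []))[0].append(int(t_idx[r]))
    for c in range(nc):
        comp.setdefault(find(nt + c), ([], []))[1].append(int(c_idx[c]))
    sets = sorted(comp.values(), key=lambda tc: tc[0][0])
    w = np.zeros(data.n)
    sub = np.full(data.n, -1)
    for s, (ts, cs) in enumerate(sets):
        if not ts or not cs:  # pragma: no cover - cover guarantees both sides
            raise RuntimeError("invalid matched set without both arms")
        for i in ts:
            w[i] = 1.0
            sub[i] = s
        for j in cs:
            w[j] = len(ts) / len(cs)
            sub[j] = s
    w = _rescale_controls(w, a)
    total = float(sum(np.abs(p[t] - p[c]) for ts, cs in sets for t in ts for c in cs))
    return _finalize(
        data, w, "full", subclass=sub, sets=sets, extra={"total_distance": total}
    )


def weights_iptw_att(ps, treatment, data: StudyData | None = None) -> MatchResult:
    """ATT inverse-probability weights: treated 1, control ``g/(1-g)`` (odds).

    No stabilisation or trimming is applied; the propensities must already be
    truncated away from 0 and 1.
    """
    a = np.asarray(treatment)
    p = ps.fitted_ps if hasattr(ps, "fitted_ps") else np.asarray(ps, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("propensities must lie strictly in (0,1); truncate upstream")
    w = np.where(a == 1, 1.0, p / (1.0 - p))
    res = MatchResult(
        weights=w,
        method="iptw",
        ess_treated=effective_sample_size(w[a == 1]),
        ess_control=effective_sample_size(w[a == 0]),
    )
    return res


def gen_mahalanobis(x_i, x_j, scale: np.ndarray, W: np.ndarray) -> float:
    """Generalized Mahalanobis distance with diagonal balance weights ``W``.

    ``sqrt((x_i - x_j)' S^{-1/2}' W S^{-1/2} (x_i - x_j))`` where ``S^{-1/2}``
    is the symmetric inverse square root of the covariance ``scale``.  With
    ``W = I`` this is the classical Mahalanobis distance.
    """
    S = np.atleast_2d(np.asarray(scale, dtype=float))
    Si = _inv_sqrt(S)
    d = Si @ (np.asarray(x_i, dtype=float) - np.asarray(x_j, dtype=float))
    Wd = np.diag(np.atleast_2d(np.asarray(W, dtype=float)))
    return float(np.sqrt(np.sum(Wd * d**2)))


def _inv_sqrt(S: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(S)
    if np.any(vals <= 1e-12 * vals.max()):
        raise np.linalg.LinAlgError(
            "covariate covariance is singular; drop collinear covariates before "
            "generalized Mahalanobis matching"
        )
    return (vecs / np.sqrt(vals)) @ vecs.T


@dataclass
class GAConfig:
    """Genetic-algorithm settings for :func:`match_genetic`."""

    pop_size: int = 50
    generations: int = 30
    seed: int = 0
    fitness: str = "asmd"  # "asmd" (deterministic default) or "pvalue"
    mutation_rate: float = 0.3
    mutation_scale: float = 0.5
    max_log_weight: float = np.log(1000.0)


def _nn_with_replacement_weights(Z_t: np.ndarray, Z_c: np.ndarray, diag_w: np.ndarray):
    """Inner matcher of genetic matching: NN with replacement in a whitened,

    diagonally reweighted covariate space.  Returns per-control usage counts.
    """
    A = Z_t * np.sqrt(diag_w)
    B = Z_c * np.sqrt(diag_w)
    d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2)
    picks = np.argmin(d2, axis=1)  # lowest index on ties
    counts = np.bincount(picks, minlength=Z_c.shape[0]).astype(float)
    return counts, picks


def _asmd_vector(X: np.ndarray, a: np.ndarray, w: np.ndarray, denom: np.ndarray) -> np.ndarray:
    wt = w[a == 1]
    wc = w[a == 0]
    mt = np.average(X[a == 1], axis=0, weights=wt)
    mc = np.average(X[a == 0], axis=0, weights=wc)
    return np.abs(mt - mc) / denom


def match_genetic(data: StudyData, ga_config: GAConfig | None = None) -> MatchResult:
    """Genetic matching: tune generalized-Mahalanobis weights for balance.

    A seeded real-coded genetic algorithm searches the diagonal weight matrix
    ``W`` (entries >= 1, first entry fixed at 1 for identifiability) of the
    generalized Mahalanobis distance; the inner matcher is 1:1 nearest
    neighbour with replacement.  Fitness is by default the lexicographic
    minimisation of the descending-sorted per-covariate ASMD vector (the
    deterministic, weight-free criterion); ``fitness="pvalue"`` switches to
    lexicographic maximisation of the ascending-sorted paired t-test and KS
    p-values.
    """
    cfg = ga_config or GAConfig()
    if cfg.generations < 1:
        raise ValueError("generations must be >= 1")
    X = data.X
    a = data.treatment
    p = X.shape[1]
    S = np.cov(X, rowvar=False)
    Z = X @ _inv_sqrt(np.atleast_2d(S)).T
    Z_t, Z_c = Z[a == 1], Z[a == 0]
    denom = X[a == 1].std(axis=0, ddof=1)
    if np.any(denom == 0):
        denom = np.where(denom == 0, 1.0, denom)
    rng = np.random.default_rng(cfg.seed)

    def weights_from_counts(counts: np.ndarray) -> np.ndarray:
        w = np.zeros(data.n)
        w[a == 1] = 1.0
        w[np.flatnonzero(a == 0)] = counts
        return _rescale_controls(w, a)

    def fitness_key(log_w: np.ndarray):
        diag_w = np.ones(p)
        if p > 1:
            diag_w[1:] = np.exp(log_w)
        counts, _ = _nn_with_replacement_weights(Z_t, Z_c, diag_w)
        w = weights_from_counts(counts)
        if cfg.fitness == "asmd":
            vec = np.sort(_asmd_vector(X, a, w, denom))[::-1]
            return tuple(vec), w
        if cfg.fitness == "pvalue":
            key = tuple(-pv for pv in sorted(_balance_pvalues(X, a, w)))
            return key, w
        raise ValueError(f"unknown fitness {cfg.fitness!r}")

    n_genes = max(p - 1, 0)
    if n_genes == 0:
        # one covariate: the distance ordering is weight-invariant
        key, w = fitness_key(np.zeros(0))
        return _finalize(
            data, w, "genetic", distance_used="gen_mahalanobis", extra={"W": np.ones(1)}
        )

    pop = rng.uniform(0.0, cfg.max_log_weight, size=(cfg.pop_size, n_genes))
    pop[0] = 0.0  # start from the classical Mahalanobis distance
    scored = [fitness_key(ind) for ind in pop]
    keys = [s[0] for s in scored]

    def tournament():
        idx = rng.integers(0, cfg.pop_size, size=3)
        return pop[min(idx, key=lambda i: keys[i])]

    best_i = min(range(cfg.pop_size), key=lambda i: keys[i])
    best = (keys[best_i], pop[best_i].copy(), scored[best_i][1])
    for _ in range(cfg.generations):
        new = [best[1].copy()]  # elitism
        while len(new) < cfg.pop_size:
            p1, p2 = tournament(), tournament()
            alpha = rng.uniform(-0.5, 1.5, size=n_genes)  # blend crossover
            child = np.clip(p1 + alpha * (p2 - p1), 0.0, cfg.max_log_weight)
            mut = rng.uniform(size=n_genes) < cfg.mutation_rate
            child = np.where(
                mut,
                np.clip(child + rng.normal(0, cfg.mutation_scale, n_genes), 0.0, cfg.max_log_weight),
                child,
            )
            new.append(child)
        pop = np.array(new)
        scored = [fitness_key(ind) for ind in pop]
        keys = [s[0] for s in scored]
        best_i = min(range(cfg.pop_size), key=lambda i: keys[i])
        if keys[best_i] < best[0]:
            best = (keys[best_i], pop[best_i].copy(), scored[best_i][1])
    diag_w = np.ones(p)
    diag_w[1:] = np.exp(best[1])
    return _finalize(
        data,
        best[2],
        "genetic",
        distance_used="gen_mahalanobis",
        extra={"W": diag_w, "fitness": best[0]},
    )


def _balance_pvalues(X: np.ndarray, a: np.ndarray, w: np.ndarray) -> list[float]:
    """Weighted two-sample t and KS p-values per covariate (p-value fitness)."""
    from scipy import stats

    out = []
    wt, wc = w[a == 1], w[a == 0]
    for j in range(X.shape[1]):
        xt, xc = X[a == 1, j], X[a == 0, j]
        mt = np.average(xt, weights=wt)
        mc = np.average(xc, weights=wc)
        vt = np.average((xt - mt) ** 2, weights=wt)
        vc = np.average((xc - mc) ** 2, weights=wc)
        nt_e = effective_sample_size(wt)
        nc_e = effective_sample_size(wc)
        se = np.sqrt(vt / nt_e + vc / nc_e)
        t = 0.0 if se == 0 else (mt - mc) / se
        df = max(nt_e + nc_e - 2, 1)
        out.append(2 * stats.t.sf(abs(t), df))
        # unweighted KS on the matched support (controls with positive weight)
        xc_used = xc[wc > 0]
        if xc_used.size:
            out.append(stats.ks_2samp(xt, xc_used).pvalue)
        else:
            out.append(0.0)
    return out
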