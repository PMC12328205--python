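"""Likelihood engine for DEC-family range-evolution models.

Anagenesis is a continuous-time Markov chain over range states: a range R
gains area a at rate d * sum_{b in R} m(b,a) (m are epoch-specific dispersal
multipliers in [0, 1]) and loses each of its areas at rate e; the null range
is absorbing. Cladogenesis divides the parent range between daughters
according to the model family (DEC, DIVALIKE, BAYAREALIKE), optionally with
founder-event ("+j") jumps into areas outside the parent range. The tree
likelihood is computed by pruning with per-epoch matrix exponentials; the
root is conditioned on an unweighted average over non-null states.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .areas import AreaScheme, FIVE_REGIONS
from .statespace import RangeStateSpace, build_state_space
from .trees import TimeCalibratedTree

__all__ = [
    "MODELS",
    "BiogeoParams",
    "EpochSchedule",
    "CladoTable",
    "FitResult",
    "anagenetic_rate_matrix",
    "cladogenesis_table",
    "tree_loglik",
    "ancestral_ranges",
    "fit_ml",
    "DECModel",
]

MODELS = ("DEC", "DIVALIKE", "BAYAREALIKE")

_MIN_SEGMENT = 1e-9  # Myr; shorter branch segments are treated as identity


@dataclass(frozen=True)
class BiogeoParams:
    """Anagenetic rates (per Myr) and founder-event weight."""

    d: float
    e: float
    j: float = 0.0
    model: str = "DEC"

    def __post_init__(self):
        if self.d < 0 or self.e < 0:
            raise ValueError("d and e must be non-negative")
        if not 0.0 <= self.j <= 3.0:
            raise ValueError("j must be in [0, 3]")
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")


@dataclass(frozen=True)
class EpochSchedule:
    """Piecewise-constant dispersal multipliers over time.

    ``breaks`` are strictly decreasing ages (Ma); ``multipliers`` holds one
    K x K matrix per epoch, oldest first (len(breaks) + 1 matrices). An age
    a falls in epoch ``#{b in breaks : b >= a}``, so a bin [225, 224] built
    from breaks (225, 224) covers ages in (224, 225].
    """

    k: int
    breaks: tuple[float, ...] = ()
    multipliers: tuple = None  # tuple of (K, K) arrays

    def __post_init__(self):
        if any(b2 >= b1 for b1, b2 in zip(self.breaks, self.breaks[1:])):
            raise ValueError("breakpoints must be strictly decreasing")
        mults = self.multipliers
        if mults is None:
            mults = tuple(np.ones((self.k, self.k)) for _ in range(len(self.breaks) + 1))
        mults = tuple(np.asarray(m, dtype=float) for m in mults)
        if len(mults) != len(self.breaks) + 1:
            raise ValueError("need len(breaks) + 1 multiplier matrices")
        for m in mults:
            if m.shape != (self.k, self.k):
                raise ValueError(f"multiplier matrix must be {self.k} x {self.k}")
            if np.any(m < 0) or np.any(m > 1):
                raise ValueError("multipliers must lie in [0, 1]")
        object.__setattr__(self, "multipliers", mults)

    @classmethod
    def free(cls, k: int) -> "EpochSchedule":
        return cls(k=k)

    @property
    def n_epochs(self) -> int:
        return len(self.breaks) + 1

    def epoch_of(self, age: float) -> int:
        return sum(1 for b in self.breaks if b >= age)

    def is_free(self) -> bool:
        return all(np.all(m == 1.0) for m in self.multipliers)

    def segments(self, child_age: float, parent_age: float) -> list[tuple[int, float]]:
        """(epoch index, duration) pieces of a branch, oldest first."""
        cuts = [parent_age] + [b for b in self.breaks if child_age < b < parent_age]
        cuts.append(child_age)
        out = []
        for hi, lo in zip(cuts, cuts[1:]):
            if hi - lo > _MIN_SEGMENT:
                out.append((self.epoch_of(hi), hi - lo))
        return out


def anagenetic_rate_matrix(
    space: RangeStateSpace, params: BiogeoParams, multipliers: np.ndarray | None = None
) -> np.ndarray:
    """Instantaneous rate matrix over range states for one epoch.

    rate(R -> R + {a}) = sum_{b in R} d * m(b, a); rate(R -> R - {a}) = e.
    Rows sum to zero; the null-range row is zero (absorbing).
    """
    k = space.k
    if multipliers is None:
        multipliers = np.ones((k, k))
    m = np.asarray(multipliers, dtype=float)
    if m.shape != (k, k):
        raise ValueError(f"multiplier matrix must be {k} x {k}")
    idx = {s: i for i, s in enumerate(space.states)}
    n = space.n_states
    Q = np.zeros((n, n))
    for i, R in enumerate(space.states):
        if not R:
            continue
        if len(R) < space.max_range_size:
            for a in range(k):
                if a in R:
                    continue
                rate = params.d * sum(m[b, a] for b in R)
                if rate > 0:
                    Q[i, idx[R | {a}]] += rate
        for a in R:
            Q[i, idx[R - {a}]] += params.e
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


@dataclass(frozen=True)
class CladoTable:
    """Normalized cladogenetic event table as flat arrays.

    For each event i, parent state ``parents[i]`` splits into daughter
    states (``lefts[i]``, ``rights[i]``) with probability ``probs[i]``.
    Daughter order is symmetrized: both orders of every asymmetric event
    are present with equal probability.
    """

    n_states: int
    parents: np.ndarray
    lefts: np.ndarray
    rights: np.ndarray
    probs: np.ndarray

    def as_dict(self) -> dict[int, list[tuple[int, int, float]]]:
        out: dict[int, list] = {}
        for p, l, r, w in zip(self.parents, self.lefts, self.rights, self.probs):
            out.setdefault(int(p), []).append((int(l), int(r), float(w)))
        return out


def cladogenesis_table(
    space: RangeStateSpace, params: BiogeoParams
) -> CladoTable:
    """Enumerate allowed cladogenetic events per parent range and normalize.

    DEC: single-area parents copy themselves; widespread parents undergo
    subset sympatry (one daughter a single area inside R, the other R) or
    vicariance with one singleton daughter. DIVALIKE: vicariance into any
    two disjoint non-empty subsets; sympatric copying only for singletons.
    BAYAREALIKE: both daughters copy the parent. "+j" adds founder events
    (one daughter a single area outside R) with relative weight j against
    base weight 1 per non-jump event.
    """
    idx = {s: i for i, s in enumerate(space.states)}
    parents, lefts, rights, probs = [], [], [], []
    for pi, R in enumerate(space.states):
        if not R:
            continue
        base: set[tuple[int, int]] = set()
        model = params.model
        if model == "BAYAREALIKE" or len(R) == 1:
            base.add((pi, pi))
        elif model == "DEC":
            for a in R:
                sa = idx[frozenset([a])]
                base.add((sa, pi))           # subset sympatry, both orders
                base.add((pi, sa))
                rem = R - {a}
                if rem in idx:
                    base.add((sa, idx[rem]))  # vicariance with a singleton
                    base.add((idx[rem], sa))
        elif model == "DIVALIKE":
            for sub in _proper_subsets(R):
                rem = R - sub
                if sub in idx and rem in idx:
                    base.add((idx[sub], idx[rem]))
        jumps: set[tuple[int, int]] = set()
        if params.j > 0:
            for a in range(space.k):
                if a in R:
                    continue
                sa = idx[frozenset([a])]
                jumps.add((sa, pi))
                jumps.add((pi, sa))
        total = len(base) * 1.0 + len(jumps) * params.j
        for l, r in sorted(base):
            parents.append(pi); lefts.append(l); rights.append(r)
            probs.append(1.0 / total)
        for l, r in sorted(jumps):
            parents.append(pi); lefts.append(l); rights.append(r)
            probs.append(params.j / total)
    return CladoTable(
        space.n_states,
        np.array(parents, dtype=int),
        np.array(lefts, dtype=int),
        np.array(rights, dtype=int),
        np.array(probs, dtype=float),
    )


def _proper_subsets(R: frozenset):
    items = sorted(R)
    n = len(items)
    for mask in range(1, 2 ** n - 1):
        yield frozenset(items[i] for i in range(n) if mask >> i & 1)


class _EpochPropagator:
    """exp(Q t) evaluator; eigendecomposition fast path with verified
    reconstruction, scipy scaling-and-squaring fallback."""

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        self._eig = None
        try:
            w, V = np.linalg.eig(Q)
            Vinv = np.linalg.inv(V)
            recon = (V * w) @ Vinv
            if np.max(np.abs(recon - Q)) < 1e-10 * max(1.0, np.max(np.abs(Q))):
                self._eig = (w, V, Vinv)
        except np.linalg.LinAlgError:
            pass

    def transition(self, dt: float) -> np.ndarray:
        if self._eig is not None:
            w, V, Vinv = self._eig
            P = (V * np.exp(w * dt)) @ Vinv
            P = np.real(P)
        else:
            P = expm(self.Q * dt)
        np.clip(P, 0.0, None, out=P)
        return P


@dataclass
class FitResult:
    params: BiogeoParams
    loglik: float
    n_params: int
    converged: bool
    diagnostics: list = field(default_factory=list)
    node_marginals: np.ndarray | None = None
    state_labels: list[str] | None = None

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik

    def to_json(self, tree: TimeCalibratedTree | None = None) -> str:
        payload = {
            "model": self.params.model,
            "d": self.params.d,
            "e": self.params.e,
            "j": self.params.j,
            "loglik": self.loglik,
            "aic": self.aic,
            "n_params": self.n_params,
            "converged": self.converged,
        }
        if self.node_marginals is not None:
            payload["node_marginals"] = {
                str(i): {
                    lab: float(p)
                    for lab, p in zip(self.state_labels, row)
                    if p > 1e-12
                }
                for i, row in enumerate(self.node_marginals)
            }
        return json.dumps(payload, indent=2)


class _DECLikelihood:
    """Pruning machinery bound to one (tree, tip ranges, space, schedule)."""

    def __init__(self, tree, tip_ranges, space, schedule=None):
        self.tree = tree
        self.space = space
        self.schedule = schedule or EpochSchedule.free(space.k)
        if self.schedule.k != space.k:
            raise ValueError("schedule area count does not match scheme")
        self.tip_states = np.zeros(tree.n_tips, dtype=int)
        for label in tip_ranges:
            if label not in tree.tip_labels:
                raise KeyError(f"tip taxon {label!r} absent from tree")
        for i, label in enumerate(tree.tip_labels):
            if label not in tip_ranges:
                raise KeyError(f"tree tip {label!r} has no observed range")
            self.tip_states[i] = space.index(tip_ranges[label])
        self.postorder = tree.postorder()
        # per-node branch segments (to its parent)
        self.segments = {}
        for v in self.postorder:
            p = tree.parent[v]
            if p >= 0:
                self.segments[v] = self.schedule.segments(
                    float(tree.ages[v]), float(tree.ages[p])
                )
        nn = space.n_states - 1
        self.root_prior = np.zeros(space.n_states)
        self.root_prior[1:] = 1.0 / nn

    def _propagators(self, params: BiogeoParams) -> list[_EpochPropagator]:
        return [
            _EpochPropagator(anagenetic_rate_matrix(self.space, params, m))
            for m in self.schedule.multipliers
        ]

    def _branch_matrix(self, v: int, props) -> np.ndarray:
        P = None
        for epoch, dt in self.segments[v]:
            Pe = props[epoch].transition(dt)
            P = Pe if P is None else P @ Pe
        if P is None:
            P = np.eye(self.space.n_states)
        return P

    def _passes(self, params: BiogeoParams, want_marginals: bool = False):
        space, tree = self.space, self.tree
        S = space.n_states
        clado = cladogenesis_table(space, params)
        props = self._propagators(params)
        branch_P = {v: self._branch_matrix(v, props) for v in self.segments}

        inside = np.zeros((tree.n_nodes, S))
        logscale = 0.0
        messages = {}  # v -> branch-propagated inside of v, seen from parent
        for v in self.postorder:
            if v < tree.n_tips:
                inside[v, self.tip_states[v]] = 1.0
            else:
                kids = tree.children[v]
                msgs = []
                for c in kids:
                    msgs.append(branch_P[c] @ inside[c])
                    messages[c] = msgs[-1]
                if len(kids) == 1:
                    inside[v] = msgs[0]
                else:
                    m1, m2 = msgs
                    vals = clado.probs * m1[clado.lefts] * m2[clado.rights]
                    inside[v] = np.bincount(clado.parents, weights=vals, minlength=S)
            tot = inside[v].sum()
            if tot <= 0 or not np.isfinite(tot):
                return -np.inf, None
            inside[v] /= tot
            logscale += np.log(tot)
        root = tree.root
        if root < tree.n_tips:  # degenerate single-node tree
            pass
        lik = float(self.root_prior @ inside[root])
        if lik <= 0:
            return -np.inf, None
        lnL = np.log(lik) + logscale
        if not want_marginals:
            return lnL, None

        outside = np.zeros((tree.n_nodes, S))
        outside[root] = self.root_prior
        marginals = np.zeros((tree.n_nodes, S))
        for v in self.postorder[::-1]:  # preorder
            pvec = outside[v] * inside[v]
            tot = pvec.sum()
            marginals[v] = pvec / tot if tot > 0 else pvec
            if v < tree.n_tips:
                continue
            kids = tree.children[v]
            if len(kids) == 1:
                c = kids[0]
                outside[c] = outside[v] @ branch_P[c]
                continue
            c1, c2 = kids
            for c, sib in ((c1, c2), (c2, c1)):
                # symmetrized table: put c in the left slot throughout
                w = outside[v][clado.parents] * clado.probs * messages[sib][clado.rights]
                o_top = np.bincount(clado.lefts, weights=w, minlength=S)
                outside[c] = o_top @ branch_P[c]
                tot = outside[c].sum()
                if tot > 0:  # rescale; marginals are normalized anyway
                    outside[c] /= tot
        return lnL, marginals

    def loglik(self, params: BiogeoParams) -> float:
        lnL, _ = self._passes(params)
        return lnL

    def marginals(self, params: BiogeoParams) -> np.ndarray:
        lnL, marg = self._passes(params, want_marginals=True)
        if marg is None:
            raise ValueError("likelihood underflowed to zero; no marginals")
        return marg


def tree_loglik(
    tree: TimeCalibratedTree,
    tip_ranges: dict,
    space: RangeStateSpace,
    params: BiogeoParams,
    schedule: EpochSchedule | None = None,
) -> float:
    """Log-likelihood of tip ranges under a DEC-family model.

    Returns -inf when the likelihood underflows to zero.
    """
    return _DECLikelihood(tree, tip_ranges, space, schedule).loglik(params)


def ancestral_ranges(
    tree: TimeCalibratedTree,
    tip_ranges: dict,
    space: RangeStateSpace,
    params: BiogeoParams,
    schedule: EpochSchedule | None = None,
) -> np.ndarray:
    """Marginal range probabilities per node (rows sum to 1)."""
    return _DECLikelihood(tree, tip_ranges, space, schedule).marginals(params)


DEFAULT_STARTS = ((1e-3, 1e-3), (0.1, 0.1), (1.0, 0.1))


def fit_ml(
    tree: TimeCalibratedTree,
    tip_ranges: dict,
    space: RangeStateSpace,
    model: str = "DEC",
    schedule: EpochSchedule | None = None,
    founder: bool = False,
    starts=DEFAULT_STARTS,
    bounds: tuple[float, float] = (1e-12, 5.0),
    j_bounds: tuple[float, float] = (0.0, 3.0),
    compute_marginals: bool = True,
) -> FitResult:
    """Maximum-likelihood fit of (d, e[, j]) by bounded quasi-Newton
    optimization on log-rates from deterministic multi-starts."""
    if tree.n_tips < 2:
        raise ValueError("ML fitting needs at least 2 tips")
    engine = _DECLikelihood(tree, tip_ranges, space, schedule)
    lo, hi = np.log(bounds[0]), np.log(bounds[1])

    def unpack(x):
        d, e = np.exp(x[0]), np.exp(x[1])
        j = float(x[2]) if founder else 0.0
        return BiogeoParams(d=d, e=e, j=j, model=model)

    def nll(x):
        lnL = engine.loglik(unpack(x))
        return -lnL if np.isfinite(lnL) else 1e12

    opt_bounds = [(lo, hi), (lo, hi)] + ([j_bounds] if founder else [])
    results = []
    for d0, e0 in starts:
        x0 = [np.log(d0), np.log(e0)] + ([0.1] if founder else [])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(nll, x0, method="L-BFGS-B", bounds=opt_bounds)
        results.append(res)
    best = min(results, key=lambda r: r.fun)
    params = unpack(best.x)
    n_params = 3 if founder else 2
    marg = engine.marginals(params) if compute_marginals else None
    return FitResult(
        params=params,
        loglik=-float(best.fun),
        n_params=n_params,
        converged=any(r.success for r in results),
        diagnostics=[
            {"x": list(map(float, r.x)), "fun": float(r.fun), "success": bool(r.success)}
            for r in results
        ],
        node_marginals=marg,
        state_labels=[engine.space.label_string(i) for i in range(space.n_states)],
    )


class DECModel(BaseEstimator):
    """Scikit-learn-style estimator for DEC-family biogeographic models.

    Parameters
    ----------
    scheme : AreaScheme
        Discrete areas used to code tip ranges.
    model : {"DEC", "DIVALIKE", "BAYAREALIKE"}
    founder : bool
        Add the "+j" founder-event parameter.
    max_range_size : int or None
        Cap on range size (None = number of areas).
    schedule : EpochSchedule or None
        Time-stratified dispersal multipliers (None = unconstrained).

    After :meth:`fit`: ``d_``, ``e_``, ``j_``, ``loglik_``, ``aic_``,
    ``node_marginals_`` (n_nodes x n_states), ``state_space_``,
    ``fit_result_``.
    """

    def __init__(self, scheme: AreaScheme = FIVE_REGIONS, model: str = "DEC",
                 founder: bool = False, max_range_size: int | None = None,
                 schedule: EpochSchedule | None = None, starts=DEFAULT_STARTS):
        self.scheme = scheme
        self.model = model
        self.founder = founder
        self.max_range_size = max_range_size
        self.schedule = schedule
        self.starts = starts

    def fit(self, tree: TimeCalibratedTree, tip_ranges: dict) -> "DECModel":
        self.state_space_ = build_state_space(self.scheme, self.max_range_size)
        res = fit_ml(
            tree, tip_ranges, self.state_space_, model=self.model,
            schedule=self.schedule, founder=self.founder, starts=self.starts,
        )
        self.fit_result_ = res
        self.d_, self.e_, self.j_ = res.params.d, res.params.e, res.params.j
        self.loglik_, self.aic_ = res.loglik, res.aic
        self.node_marginals_ = res.node_marginals
        self.tree_ = tree
        return self

    def loglik(self, tree, tip_ranges, params: BiogeoParams) -> float:
        space = getattr(self, "state_space_", None) or build_state_space(
            self.scheme, self.max_range_size
        )
        return tree_loglik(tree, tip_ranges, space, params, self.schedule)
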