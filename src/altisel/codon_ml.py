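"""GY94 codon-model likelihood machinery and positive-selection tests.

Implements the Goldman–Yang (1994) codon substitution model over the 61
sense codons, with likelihood computed by Felsenstein pruning, and the
three fits used by the selection scan:

* ``fit_m0`` — a single dN/dS ratio (omega) shared by all branches;
* ``fit_branch`` — one omega per user-defined branch class, used for
  per-branch evolutionary-rate estimation;
* ``fit_branch_site`` — branch-site model A on a designated foreground
  branch, with the likelihood-ratio test of positive selection (the
  alternative allows omega2 > 1 on the foreground; the null fixes
  omega2 = 1).

Equilibrium codon frequencies default to F3x4 (empirical nucleotide
frequencies per codon position), and each rate matrix is scaled to one
expected substitution per codon per unit branch length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from ._codons import (
    GAP_STATE,
    IS_SYNONYMOUS,
    IS_TRANSITION,
    N_SENSE,
    ONE_DIFF,
    SENSE_CODONS,
)
from .alignment import CodonAlignment
from .trees import Phylogeny

__all__ = [
    "CodonModelParams",
    "SiteClassMix",
    "LRTResult",
    "FitResult",
    "BranchSiteResult",
    "f3x4_frequencies",
    "build_rate_matrix",
    "log_likelihood",
    "fit_m0",
    "fit_branch",
    "fit_branch_site",
    "lrt",
]

# optimisation bounds (on the natural scale)
OMEGA_BOUNDS = (1e-4, 999.0)
KAPPA_BOUNDS = (0.1, 99.0)
BRANCH_BOUNDS = (0.0, 50.0)
LNL_TOL = 1e-4
MAX_SWEEPS = 50


# ---------------------------------------------------------------------------
# parameters and results
# ---------------------------------------------------------------------------


@dataclass
class CodonModelParams:
    """GY94 parameters: kappa, per-branch omega, equilibrium frequencies."""

    kappa: float
    omega_map: dict[str, float]
    codon_freqs: np.ndarray

    def __post_init__(self):
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.codon_freqs.shape != (N_SENSE,):
            raise ValueError(f"codon_freqs must have length {N_SENSE}")
        if abs(self.codon_freqs.sum() - 1.0) > 1e-9:
            raise ValueError("codon_freqs must sum to 1")
        if any(w < 0 for w in self.omega_map.values()):
            raise ValueError("omega values must be non-negative")


@dataclass
class SiteClassMix:
    """Model A site classes: {0: omega0, 1: neutral, 2a/2b: omega2 on fg}.

    Class proportions follow the standard constraint: p2a and p2b split
    the remainder 1 - p0 - p1 in the ratio p0 : p1.
    """

    p0: float
    p1: float
    omega0: float
    omega2: float

    def __post_init__(self):
        if self.p0 < 0 or self.p1 < 0 or self.p0 + self.p1 > 1 + 1e-12:
            raise ValueError("need p0, p1 >= 0 and p0 + p1 <= 1")
        if not (0 <= self.omega0 < 1):
            raise ValueError("omega0 must lie in [0, 1)")
        if self.omega2 < 1:
            raise ValueError("omega2 must be >= 1")

    def proportions(self) -> np.ndarray:
        tot = self.p0 + self.p1
        rest = max(0.0, 1.0 - tot)
        if tot <= 0:
            # degenerate: split the selected classes evenly
            return np.array([0.0, 0.0, rest / 2, rest / 2])
        return np.array(
            [
                self.p0,
                self.p1,
                rest * self.p0 / tot,
                rest * self.p1 / tot,
            ]
        )

    def class_omegas(self, foreground: bool) -> tuple[float, float, float, float]:
        """Omega of each site class on a foreground/background branch."""
        if foreground:
            return (self.omega0, 1.0, self.omega2, self.omega2)
        return (self.omega0, 1.0, self.omega0, 1.0)


@dataclass
class LRTResult:
    """Outcome of the branch-site likelihood-ratio test for one gene."""

    gene_id: str
    lnl_null: float
    lnl_alt: float
    statistic: float
    df: int
    p_value: float
    is_psg: bool


@dataclass
class FitResult:
    """A fitted codon model: parameters, branch lengths, and lnL."""

    kappa: float
    omega_map: dict[str, float]
    branch_lengths: dict[str, float]
    codon_freqs: np.ndarray
    lnl: float
    mix: SiteClassMix | None = None
    converged: bool = True
    n_sweeps: int = 0

    @property
    def omega(self) -> float:
        """The single omega of an M0 fit (errors if branch-specific)."""
        values = set(self.omega_map.values())
        if len(values) != 1:
            raise ValueError("fit has branch-specific omegas")
        return values.pop()

    def params(self) -> CodonModelParams:
        return CodonModelParams(self.kappa, dict(self.omega_map), self.codon_freqs)


@dataclass
class BranchSiteResult:
    gene_id: str
    null: FitResult
    alt: FitResult
    lrt: LRTResult
    low_information: bool = False


# ---------------------------------------------------------------------------
# frequencies and rate matrix
# ---------------------------------------------------------------------------


def f3x4_frequencies(aln: CodonAlignment, pseudocount: float = 0.1) -> np.ndarray:
    """F3x4 codon frequencies from position-specific nucleotide counts.

    A small pseudocount keeps every sense codon at positive frequency so
    the rate matrix stays irreducible on sparse alignments.
    """
    counts = np.full((3, 4), pseudocount, dtype=float)
    base_index = {"T": 0, "C": 1, "A": 2, "G": 3}
    for seq in aln.sequences:
        for i, ch in enumerate(seq):
            idx = base_index.get(ch)
            if idx is not None:
                counts[i % 3, idx] += 1
    pos_freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freqs[0, base_index[c[0]]]
            * pos_freqs[1, base_index[c[1]]]
            * pos_freqs[2, base_index[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def build_rate_matrix(
    params: CodonModelParams | np.ndarray,
    omega: float,
    kappa: float | None = None,
    scale_factor: float | None = None,
) -> np.ndarray:
    """GY94 generator: off-diagonal rates for single-nucleotide changes.

    Rate x->y is pi_y, multiplied by kappa for transitions and omega for
    nonsynonymous changes; multi-step changes have rate 0. By default
    the matrix is scaled so the expected substitution rate at
    equilibrium is one per codon, making branch lengths expected
    substitutions per codon. Site-class mixtures must instead share one
    common `scale_factor` across classes, so that classes with higher
    omega genuinely evolve faster (see ``gy94_mean_rate``).
    """
    if isinstance(params, CodonModelParams):
        pi = params.codon_freqs
        kappa = params.kappa
    else:
        pi = np.asarray(params, dtype=float)
        if kappa is None:
            raise ValueError("kappa required when passing raw frequencies")
    if np.any(pi <= 0):
        warnings.warn(
            "zero codon frequencies; applying pseudo-frequency", stacklevel=2
        )
        pi = pi + 1e-6
        pi = pi / pi.sum()
    rate = np.where(ONE_DIFF, np.tile(pi, (N_SENSE, 1)), 0.0)
    rate = rate * np.where(IS_TRANSITION, kappa, 1.0)
    rate = rate * np.where(IS_SYNONYMOUS, 1.0, omega)
    np.fill_diagonal(rate, 0.0)
    np.fill_diagonal(rate, -rate.sum(axis=1))
    scale = scale_factor if scale_factor is not None else -np.dot(pi, np.diag(rate))
    if scale > 0:
        rate = rate / scale
    return rate


def gy94_mean_rate(pi: np.ndarray, kappa: float, omega: float = 1.0) -> float:
    """Equilibrium substitution rate of the unscaled GY94 generator.

    Used as the shared normalisation of site-class mixtures: every
    class matrix is divided by the neutral-class (omega = 1) rate, so a
    branch length is the expected number of substitutions per codon at
    a neutrally evolving site and relative class rates follow omega.
    """
    pi = np.asarray(pi, dtype=float)
    rate = np.where(ONE_DIFF, np.tile(pi, (N_SENSE, 1)), 0.0)
    rate = rate * np.where(IS_TRANSITION, kappa, 1.0)
    rate = rate * np.where(IS_SYNONYMOUS, 1.0, omega)
    return float(pi @ rate.sum(axis=1))


def _eigen_gy94(
    pi: np.ndarray, kappa: float, omega: float, scale_factor: float | None = None
):
    """Spectral decomposition of the (reversible) GY94 generator.

    Returns (lam, U, V) with P(t) = (U * exp(lam t)) @ V; computed via
    the pi^{1/2} similarity transform, which is symmetric by detailed
    balance.
    """
    q = build_rate_matrix(pi, omega, kappa, scale_factor=scale_factor)
    sqrt_pi = np.sqrt(pi)
    b = q * (sqrt_pi[:, None] / sqrt_pi[None, :])
    b = 0.5 * (b + b.T)  # symmetrize away round-off
    lam, vec = np.linalg.eigh(b)
    u = vec / sqrt_pi[:, None]
    v = vec.T * sqrt_pi[None, :]
    return lam, u, v


def transition_probabilities(eig, t: float) -> np.ndarray:
    lam, u, v = eig
    p = (u * np.exp(lam * t)) @ v
    np.maximum(p, 0.0, out=p)
    return p


# ---------------------------------------------------------------------------
# likelihood engine
# ---------------------------------------------------------------------------


class _LikelihoodEngine:
    """Pruning likelihood on compressed site patterns with eigen caching.

    One engine is built per (alignment, tree, pi) triple and reused
    across all likelihood evaluations of a fit; subtree partials are
    shared between site classes whose branch-omega assignments agree on
    that subtree.
    """

    def __init__(
        self,
        aln: CodonAlignment,
        tree: Phylogeny,
        pi: np.ndarray,
        mixture_scaling: bool = False,
    ):
        encoded = aln.encode()
        order = [aln.taxon_ids.index(t) for t in tree.taxa]
        cols = encoded[order, :]
        patterns, weights = np.unique(cols, axis=1, return_counts=True)
        self.patterns = patterns  # (n_taxa, n_patterns), rows follow tree.taxa
        self.weights = weights.astype(float)
        self.n_patterns = patterns.shape[1]
        self.tree = tree
        self.pi = np.asarray(pi, dtype=float)
        # single-omega models use the standard per-matrix normalisation
        # (branch length = expected substitutions per codon on that
        # branch); site-class mixtures share the neutral-rate scale so
        # relative class rates follow omega
        self.mixture_scaling = mixture_scaling
        self.taxon_row = {t: i for i, t in enumerate(tree.taxa)}
        self._eigcache: dict[tuple[float, float], tuple] = {}
        self._pcache: dict[tuple, np.ndarray] = {}
        self._clcache: dict[tuple, np.ndarray] = {}
        # descendant branch names per node, in a fixed order, for memo keys
        self._desc: dict[str, tuple[str, ...]] = {}
        for node in tree.postorder:
            names = []
            for child in node.children:
                names.append(child.name)
                names.extend(self._desc[child.name])
            self._desc[node.name] = tuple(names)

    # -- primitives --

    def eig(self, kappa: float, omega: float):
        key = (round(kappa, 12), round(omega, 12))
        out = self._eigcache.get(key)
        if out is None:
            if len(self._eigcache) > 256:
                self._eigcache.clear()
            scale = (
                gy94_mean_rate(self.pi, kappa) if self.mixture_scaling else None
            )
            out = _eigen_gy94(self.pi, kappa, omega, scale_factor=scale)
            self._eigcache[key] = out
        return out

    def pmat(self, kappa: float, omega: float, t: float) -> np.ndarray:
        key = (round(kappa, 12), round(omega, 12), round(t, 12))
        p = self._pcache.get(key)
        if p is None:
            if len(self._pcache) > 4096:
                self._pcache.clear()
            p = transition_probabilities(self.eig(kappa, omega), t)
            self._pcache[key] = p
        return p

    def _tip_message(self, node, p: np.ndarray) -> np.ndarray:
        states = self.patterns[self.taxon_row[node.name]]
        msg = np.empty((self.n_patterns, N_SENSE))
        observed = states >= 0
        msg[observed] = p[:, states[observed]].T
        msg[~observed] = 1.0
        return msg

    def _partials(self, kappa: float, omega_of: dict[str, float], lengths, memo):
        """Down (subtree) partials for one site class, with log-scaling.

        Returns {node_name: (partial (npat, 61), logscale (npat,))} for
        internal nodes. `memo` is shared across classes of one
        evaluation, keyed by the omegas on the node's subtree.
        """
        out = {}
        for node in self.tree.postorder:
            if node.is_leaf:
                continue
            key = (
                node.name,
                tuple(omega_of[b] for b in self._desc[node.name]),
            )
            cached = memo.get(key)
            if cached is None:
                partial = np.ones((self.n_patterns, N_SENSE))
                logscale = np.zeros(self.n_patterns)
                for child in node.children:
                    p = self.pmat(kappa, omega_of[child.name], lengths[child.name])
                    if child.is_leaf:
                        partial *= self._tip_message(child, p)
                    else:
                        cp, cs = out[child.name]
                        partial *= cp @ p.T
                        logscale += cs
                    scale = partial.max(axis=1)
                    scale[scale == 0] = 1.0
                    partial /= scale[:, None]
                    logscale += np.log(scale)
                cached = (partial, logscale)
                memo[key] = cached
            out[node.name] = cached
        return out

    def _class_site_loglik(self, kappa, omega_of, lengths, memo) -> np.ndarray:
        branches = self.tree.branches
        key = (
            round(kappa, 12),
            tuple(round(omega_of[b], 12) for b in branches),
            tuple(round(lengths[b], 12) for b in branches),
        )
        cached = self._clcache.get(key)
        if cached is not None:
            return cached
        partials = self._partials(kappa, omega_of, lengths, memo)
        root_partial, root_scale = partials[self.tree.root.name]
        site = root_partial @ self.pi
        out = np.log(np.maximum(site, 1e-300)) + root_scale
        if len(self._clcache) > 2048:
            self._clcache.clear()
        self._clcache[key] = out
        return out

    # -- public evaluations --

    def lnl(self, kappa, class_omega_maps, class_weights, lengths):
        """Total log-likelihood of a (possibly one-class) mixture."""
        memo: dict = {}
        logliks = np.stack(
            [
                self._class_site_loglik(kappa, om, lengths, memo)
                for om in class_omega_maps
            ]
        )
        return float(self.weights @ _weighted_logsumexp(logliks, class_weights))

    def class_site_logliks(self, kappa, class_omega_maps, lengths) -> np.ndarray:
        memo: dict = {}
        return np.stack(
            [
                self._class_site_loglik(kappa, om, lengths, memo)
                for om in class_omega_maps
            ]
        )

    def branch_profiles(self, kappa, class_omega_maps, lengths):
        """Per-branch 1-D likelihood profiles from one set of partials.

        For every class, computes inside (subtree) and outside
        (rest-of-tree) partials in a single postorder + preorder pass;
        a candidate length on branch v then costs one 61x61 propagation
        per class instead of a full pruning. The profiles share the
        partials computed at the current lengths, so updating several
        branches from one call is a coordinate pass with slightly stale
        partials — callers guard the true likelihood across passes.

        Returns {branch: f} with f(t) -> (n_classes, n_patterns) site
        log-likelihoods.
        """
        per_branch: dict[str, list] = {b: [] for b in self.tree.branches}
        for omega_of in class_omega_maps:
            memo: dict = {}
            down = self._partials(kappa, omega_of, lengths, memo)
            # messages up through each branch, and outside partials
            msgs, mscale = {}, {}
            for node in self.tree.postorder:
                if node.parent is None:
                    continue
                p = self.pmat(kappa, omega_of[node.name], lengths[node.name])
                if node.is_leaf:
                    msgs[node.name] = self._tip_message(node, p)
                    mscale[node.name] = np.zeros(self.n_patterns)
                else:
                    dn, ds = down[node.name]
                    msgs[node.name] = dn @ p.T
                    mscale[node.name] = ds
            outside = {
                self.tree.root.name: (
                    np.tile(self.pi, (self.n_patterns, 1)),
                    np.zeros(self.n_patterns),
                )
            }
            for node in reversed(self.tree.postorder):  # preorder
                if node.is_leaf:
                    continue
                a_u, s_u = outside[node.name]
                for child in node.children:
                    aex = a_u.copy()
                    sex = s_u.copy()
                    for sib in node.children:
                        if sib is child:
                            continue
                        aex = aex * msgs[sib.name]
                        sex = sex + mscale[sib.name]
                    norm = aex.max(axis=1)
                    norm[norm == 0] = 1.0
                    aex /= norm[:, None]
                    sex = sex + np.log(norm)
                    # profile pieces for the branch to `child`
                    eig = self.eig(kappa, omega_of[child.name])
                    if child.is_leaf:
                        states = self.patterns[self.taxon_row[child.name]]
                        per_branch[child.name].append(
                            (eig, aex, sex, None, states)
                        )
                    else:
                        dn, ds = down[child.name]
                        per_branch[child.name].append(
                            (eig, aex, sex + ds, dn, None)
                        )
                        # outside partial at the child itself
                        p = self.pmat(
                            kappa, omega_of[child.name], lengths[child.name]
                        )
                        a_c = aex @ p
                        norm = a_c.max(axis=1)
                        norm[norm == 0] = 1.0
                        a_c /= norm[:, None]
                        outside[child.name] = (a_c, sex + np.log(norm))

        def make_profile(pieces):
            def site_logliks(t: float) -> np.ndarray:
                rows = []
                for eig, aex, scale, dn, states in pieces:
                    p = transition_probabilities(eig, t)
                    if dn is None:
                        observed = states >= 0
                        msg = np.empty((self.n_patterns, N_SENSE))
                        msg[observed] = p[:, states[observed]].T
                        msg[~observed] = 1.0
                    else:
                        msg = dn @ p.T
                    site = np.einsum("ps,ps->p", aex, msg)
                    rows.append(np.log(np.maximum(site, 1e-300)) + scale)
                return np.stack(rows)

            return site_logliks

        return {b: make_profile(pieces) for b, pieces in per_branch.items()}


def _weighted_logsumexp(logliks: np.ndarray, weights) -> np.ndarray:
    """log(sum_k w_k exp(L_k)) per column, safe against -inf classes."""
    weights = np.asarray(weights, dtype=float)
    keep = weights > 0
    logliks = logliks[keep] + np.log(weights[keep])[:, None]
    m = logliks.max(axis=0)
    return m + np.log(np.exp(logliks - m).sum(axis=0))


# ---------------------------------------------------------------------------
# public likelihood
# ---------------------------------------------------------------------------


def _check_taxa(aln: CodonAlignment, tree: Phylogeny) -> None:
    if set(aln.taxon_ids) != set(tree.taxa):
        raise ValueError(
            f"alignment taxa {sorted(aln.taxon_ids)} do not match "
            f"tree taxa {sorted(tree.taxa)}"
        )


def _mix_class_maps(tree: Phylogeny, mix: SiteClassMix) -> list[dict[str, float]]:
    maps = []
    for k in range(4):
        maps.append(
            {
                b: mix.class_omegas(b in tree.foreground)[k]
                for b in tree.branches
            }
        )
    return maps


def log_likelihood(
    aln: CodonAlignment,
    tree: Phylogeny,
    params: CodonModelParams,
    mix: SiteClassMix | None = None,
) -> float:
    """GY94 log-likelihood by pruning; columns with gaps are partial data.

    Without `mix`, each branch uses its omega from ``params.omega_map``.
    With `mix`, branch-site model A class structure applies, using the
    tree's foreground flags; ``params.omega_map`` is ignored.
    """
    _check_taxa(aln, tree)
    engine = _LikelihoodEngine(
        aln, tree, params.codon_freqs, mixture_scaling=mix is not None
    )
    lengths = tree.branch_lengths
    if mix is None:
        missing = [b for b in tree.branches if b not in params.omega_map]
        if missing:
            raise ValueError(f"omega_map missing branches: {missing}")
        return engine.lnl(params.kappa, [params.omega_map], [1.0], lengths)
    return engine.lnl(
        params.kappa, _mix_class_maps(tree, mix), mix.proportions(), lengths
    )


def lrt(lnl_null: float, lnl_alt: float, df: int = 1) -> float:
    """Upper-tail chi-square p-value of 2*(lnL_alt - lnL_null), clipped at 0."""
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = max(0.0, 2.0 * (lnl_alt - lnl_null))
    return float(chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _brent(f, lo, hi, x0=None, coarse=False, window=None):
    """Bounded 1-D maximisation; returns (argmax, max).

    With `window` (and x0), the search is restricted to
    [x0 - window, x0 + window] and widened once if the optimum presses
    against an interior edge — cheap refinement for late sweeps where
    parameters barely move.
    """
    xatol = 2e-3 if coarse else 1e-5

    def solve(a, b):
        res = minimize_scalar(
            lambda x: -f(x), bounds=(a, b), method="bounded",
            options={"xatol": xatol, "maxiter": 25},
        )
        return float(res.x), -float(res.fun)

    if window is not None and x0 is not None:
        a = max(lo, x0 - window)
        b = min(hi, x0 + window)
        x, fx = solve(a, b)
        edge = 0.05 * (b - a)
        if (x - a < edge and a > lo) or (b - x < edge and b < hi):
            x, fx = solve(lo, hi)
    else:
        x, fx = solve(lo, hi)
    if x0 is not None:
        f0 = f(x0)
        if f0 >= fx:  # guard: never move downhill
            return x0, f0
    return x, fx


class _FitState:
    """Mutable optimisation state shared by the three model fits."""

    def __init__(self, engine, tree, kappa, lengths):
        self.engine = engine
        self.tree = tree
        self.kappa = kappa
        self.lengths = dict(lengths)
        self.sweep_no = 0

    def _window(self):
        """Log-scale search window: full bounds early, local later."""
        return None if self.sweep_no <= 2 else 0.7

    def class_maps_weights(self):  # overridden per model
        raise NotImplementedError

    # transformed parameter vector (for sweep extrapolation)
    def _extra_vector(self):
        return np.empty(0)

    def _set_extra_vector(self, v):
        pass

    def get_vector(self) -> np.ndarray:
        lengths = [self.lengths[b] for b in self.tree.branches]
        return np.concatenate(
            [[np.log(self.kappa)], lengths, self._extra_vector()]
        )

    def set_vector(self, v: np.ndarray) -> None:
        self.kappa = float(np.exp(np.clip(v[0], *np.log(KAPPA_BOUNDS))))
        n_b = len(self.tree.branches)
        for b, t in zip(self.tree.branches, v[1 : 1 + n_b]):
            self.lengths[b] = float(np.clip(t, *BRANCH_BOUNDS))
        self._set_extra_vector(v[1 + n_b :])

    def lnl(self) -> float:
        maps, weights = self.class_maps_weights()
        return self.engine.lnl(self.kappa, maps, weights, self.lengths)

    def optimize_lengths(self):
        maps, weights = self.class_maps_weights()
        weights = np.asarray(weights, dtype=float)
        w = self.engine.weights
        before = self.lnl()
        old = dict(self.lengths)
        profiles = self.engine.branch_profiles(self.kappa, maps, self.lengths)
        for branch in self.tree.branches:
            profile = profiles[branch]

            def f(t):
                return float(w @ _weighted_logsumexp(profile(t), weights))

            t_new, _ = _brent(
                f, *BRANCH_BOUNDS, x0=self.lengths[branch], coarse=True
            )
            self.lengths[branch] = t_new
        # profiles share partials computed at the old lengths; updating
        # several branches at once can (rarely) overshoot — guard on the
        # true likelihood and revert if so
        if self.lnl() < before:
            self.lengths = old

    def optimize_kappa(self):
        def f(log_k):
            self.kappa = float(np.exp(log_k))
            return self.lnl()

        lo, hi = np.log(KAPPA_BOUNDS)
        best, _ = _brent(
            f, lo, hi, x0=np.log(self.kappa), coarse=True, window=self._window()
        )
        self.kappa = float(np.exp(best))


class _OmegaMapState(_FitState):
    """M0 / branch-model state: one omega per branch class."""

    def __init__(self, engine, tree, kappa, lengths, partition, omegas):
        super().__init__(engine, tree, kappa, lengths)
        self.partition = partition  # branch -> class label
        self.omegas = dict(omegas)  # class label -> omega

    def omega_map(self):
        return {b: self.omegas[c] for b, c in self.partition.items()}

    def _extra_vector(self):
        return np.log([self.omegas[c] for c in sorted(self.omegas)])

    def _set_extra_vector(self, v):
        for c, x in zip(sorted(self.omegas), v):
            self.omegas[c] = float(np.exp(np.clip(x, *np.log(OMEGA_BOUNDS))))

    def class_maps_weights(self):
        return [self.omega_map()], [1.0]

    def optimize_omegas(self):
        lo, hi = np.log(OMEGA_BOUNDS)
        for label in self.omegas:

            def f(log_w):
                self.omegas[label] = float(np.exp(log_w))
                return self.lnl()

            best, _ = _brent(
                f, lo, hi, x0=np.log(self.omegas[label]), coarse=True,
                window=self._window(),
            )
            self.omegas[label] = float(np.exp(best))

    def sweep(self, number: int = 1):
        self.optimize_lengths()
        if number <= 2 or number % 3 == 0:
            self.optimize_kappa()
        self.optimize_omegas()


class _BranchSiteState(_FitState):
    """Model A state: kappa, lengths, (p0, p1, omega0, omega2)."""

    def __init__(self, engine, tree, kappa, lengths, mix, fix_omega2):
        super().__init__(engine, tree, kappa, lengths)
        self.mix = mix
        self.fix_omega2 = fix_omega2

    def class_maps_weights(self):
        return _mix_class_maps(self.tree, self.mix), self.mix.proportions()

    def _extra_vector(self):
        m = self.mix
        return np.array(
            [m.p0, m.p1, np.log(max(m.omega0, OMEGA_BOUNDS[0])), np.log(m.omega2)]
        )

    def _set_extra_vector(self, v):
        p0 = float(np.clip(v[0], 1e-9, 1 - 2e-9))
        p1 = float(np.clip(v[1], 1e-9, 1 - 1e-9 - p0))
        omega0 = float(np.exp(np.clip(v[2], np.log(OMEGA_BOUNDS[0]), np.log(1 - 1e-9))))
        if self.fix_omega2:
            omega2 = self.mix.omega2
        else:
            omega2 = float(np.exp(np.clip(v[3], 0.0, np.log(OMEGA_BOUNDS[1]))))
        self.mix = SiteClassMix(p0, p1, omega0, omega2)

    def _set(self, **kw):
        d = dict(
            p0=self.mix.p0, p1=self.mix.p1,
            omega0=self.mix.omega0, omega2=self.mix.omega2,
        )
        d.update(kw)
        self.mix = SiteClassMix(**d)

    def optimize_proportions(self):
        # class likelihoods do not depend on the proportions: compute the
        # per-class site log-likelihoods once, then optimise the weights.
        maps, _ = self.class_maps_weights()
        logliks = self.engine.class_site_logliks(self.kappa, maps, self.lengths)
        w = self.engine.weights

        def value(tot, r):
            mix = SiteClassMix(tot * r, tot * (1 - r), self.mix.omega0, self.mix.omega2)
            return float(w @ _weighted_logsumexp(logliks, mix.proportions()))

        tot = min(max(self.mix.p0 + self.mix.p1, 1e-6), 1 - 1e-6)
        r = self.mix.p0 / tot if tot > 0 else 0.5
        r = min(max(r, 1e-6), 1 - 1e-6)
        for _ in range(3):  # alternate the two cheap 1-D problems
            tot, _v = _brent(lambda x: value(x, r), 1e-6, 1 - 1e-6, x0=tot)
            r, _v = _brent(lambda x: value(tot, x), 1e-6, 1 - 1e-6, x0=r)
        self._set(p0=tot * r, p1=tot * (1 - r))

    def optimize_omega0(self):
        lo, hi = np.log(OMEGA_BOUNDS[0]), np.log(1 - 1e-6)

        def f(log_w):
            self._set(omega0=float(np.exp(log_w)))
            return self.lnl()

        best, _ = _brent(
            f, lo, hi, x0=np.log(max(self.mix.omega0, OMEGA_BOUNDS[0])),
            coarse=True, window=self._window(),
        )
        self._set(omega0=float(np.exp(best)))

    def optimize_omega2(self):
        if self.fix_omega2:
            return
        lo, hi = 0.0, np.log(OMEGA_BOUNDS[1])

        def f(log_w):
            self._set(omega2=float(np.exp(log_w)))
            return self.lnl()

        best, _ = _brent(
            f, lo, hi, x0=np.log(self.mix.omega2), coarse=True,
            window=self._window(),
        )
        self._set(omega2=float(np.exp(best)))

    def sweep(self, number: int = 1):
        self.optimize_lengths()
        if number <= 2 or number % 3 == 0:
            self.optimize_kappa()
        self.optimize_omega0()
        self.optimize_omega2()
        self.optimize_proportions()


def _run_sweeps(state, tol=LNL_TOL, max_sweeps=MAX_SWEEPS):
    last = state.lnl()
    converged = False
    n = 0
    prev_vec = None
    for n in range(1, max_sweeps + 1):
        state.sweep_no = n
        state.sweep(n)
        current = state.lnl()
        # coordinate sweeps converge geometrically along a nearly fixed
        # direction; extrapolating the parameter vector along the last
        # step skips most of that tail
        vec = state.get_vector()
        if prev_vec is not None and current - last >= tol and n >= 2:
            step = vec - prev_vec
            best_vec = vec
            for gamma in (2.0, 6.0):
                state.set_vector(vec + gamma * step)
                trial = state.lnl()
                if trial > current:
                    current = trial
                    best_vec = state.get_vector()
            state.set_vector(best_vec)
            vec = best_vec
        prev_vec = vec
        if current - last < tol:
            converged = True
            last = max(last, current)
            break
        last = current
    return last, converged, n


def _initial_lengths(tree: Phylogeny) -> dict[str, float]:
    return {
        b: max(t, 0.02) for b, t in tree.branch_lengths.items()
    }


def fit_m0(
    aln: CodonAlignment,
    tree: Phylogeny,
    *,
    starts: tuple[float, ...] = (0.5, 2.0),
    kappa0: float = 2.0,
    tol: float = LNL_TOL,
    max_sweeps: int = MAX_SWEEPS,
) -> FitResult:
    """Fit the one-ratio (M0) model: a single omega shared by all branches."""
    partition = {b: "all" for b in tree.branches}
    return fit_branch(
        aln, tree, partition, starts=starts, kappa0=kappa0,
        tol=tol, max_sweeps=max_sweeps,
    )


def fit_branch(
    aln: CodonAlignment,
    tree: Phylogeny,
    branch_partition: dict[str, str],
    *,
    starts: tuple[float, ...] = (0.5, 2.0),
    kappa0: float = 2.0,
    tol: float = LNL_TOL,
    max_sweeps: int = MAX_SWEEPS,
    initial: FitResult | None = None,
) -> FitResult:
    """Fit a branch model: one free omega per class of ``branch_partition``.

    With every branch in one class this is exactly M0. `initial` warm-starts
    from a previous fit (used by the bootstrap).
    """
    _check_taxa(aln, tree)
    missing = [b for b in tree.branches if b not in branch_partition]
    if missing:
        raise ValueError(f"branch_partition missing branches: {missing}")
    pi = f3x4_frequencies(aln)
    engine = _LikelihoodEngine(aln, tree, pi)
    labels = sorted(set(branch_partition.values()))
    best = None
    if initial is not None:
        omegas = {
            lab: np.median(
                [initial.omega_map[b] for b, c in branch_partition.items() if c == lab]
            )
            for lab in labels
        }
        start_sets = [(initial.kappa, initial.branch_lengths, omegas)]
    else:
        start_sets = [
            (kappa0, _initial_lengths(tree), {lab: w0 for lab in labels})
            for w0 in starts
        ]
    for kappa, lengths, omegas in start_sets:
        state = _OmegaMapState(engine, tree, kappa, lengths, branch_partition, omegas)
        lnl, converged, n = _run_sweeps(state, tol=tol, max_sweeps=max_sweeps)
        result = FitResult(
            kappa=state.kappa,
            omega_map=state.omega_map(),
            branch_lengths=dict(state.lengths),
            codon_freqs=pi,
            lnl=lnl,
            converged=converged,
            n_sweeps=n,
        )
        if best is None or result.lnl > best.lnl:
            best = result
    return best


def _count_variable_sites(aln: CodonAlignment) -> int:
    enc = aln.encode()
    variable = 0
    for j in range(enc.shape[1]):
        col = enc[:, j]
        col = col[col >= 0]
        if col.size and np.unique(col).size > 1:
            variable += 1
    return variable


def fit_branch_site(
    aln: CodonAlignment,
    tree: Phylogeny,
    foreground=None,
    *,
    p_threshold: float = 0.05,
    alt_omega2_starts: tuple[float, ...] = (1.5, 5.0),
    tol: float = LNL_TOL,
    max_sweeps: int = MAX_SWEEPS,
) -> BranchSiteResult:
    """Branch-site model A test of positive selection on the foreground.

    Fits the null (omega2 fixed at 1) and the alternative (omega2 free,
    >= 1, warm-started from the null so lnL_alt >= lnL_null by
    construction) and performs the LRT with one degree of freedom. A
    gene is called a putative positively selected gene (PSG) when the
    p-value falls below `p_threshold`.
    """
    _check_taxa(aln, tree)
    if foreground is not None:
        tree = tree.copy()
        tree.set_foreground(
            [foreground] if isinstance(foreground, str) else foreground
        )
    if not tree.foreground:
        raise ValueError("no foreground branch designated")
    low_information = _count_variable_sites(aln) < 2
    pi = f3x4_frequencies(aln)
    engine = _LikelihoodEngine(aln, tree, pi, mixture_scaling=True)

    # null: omega2 = 1 fixed
    null_state = _BranchSiteState(
        engine, tree, 2.0, _initial_lengths(tree),
        SiteClassMix(0.7, 0.2, 0.2, 1.0), fix_omega2=True,
    )
    null_lnl, null_conv, n0 = _run_sweeps(null_state, tol=tol, max_sweeps=max_sweeps)
    null_fit = FitResult(
        kappa=null_state.kappa,
        omega_map={},
        branch_lengths=dict(null_state.lengths),
        codon_freqs=pi,
        lnl=null_lnl,
        mix=null_state.mix,
        converged=null_conv,
        n_sweeps=n0,
    )

    # alternative: omega2 free, multi-started from the null solution.
    # Under the null the selected-class weight is unidentifiable and may
    # collapse to ~0, which would leave omega2 without a gradient; restart
    # the proportions at an interior point so omega2 and the weights can
    # co-adapt.
    tot0 = null_state.mix.p0 + null_state.mix.p1
    r0 = null_state.mix.p0 / tot0 if tot0 > 0 else 0.5
    best_alt = None
    for w2 in alt_omega2_starts:
        if best_alt is not None and best_alt.mix.omega2 > 1.05:
            break  # first start found an interior omega2; skip the re-start
        alt_state = _BranchSiteState(
            engine, tree, null_state.kappa, dict(null_state.lengths),
            SiteClassMix(0.8 * r0, 0.8 * (1 - r0), null_state.mix.omega0, w2),
            fix_omega2=False,
        )
        alt_lnl, alt_conv, n1 = _run_sweeps(alt_state, tol=tol, max_sweeps=max_sweeps)
        fit = FitResult(
            kappa=alt_state.kappa,
            omega_map={},
            branch_lengths=dict(alt_state.lengths),
            codon_freqs=pi,
            lnl=alt_lnl,
            mix=alt_state.mix,
            converged=alt_conv,
            n_sweeps=n1,
        )
        if best_alt is None or fit.lnl > best_alt.lnl:
            best_alt = fit
    # the alternative nests the null; never report a worse alternative
    if best_alt.lnl < null_fit.lnl:
        best_alt = FitResult(
            kappa=null_fit.kappa, omega_map={},
            branch_lengths=dict(null_fit.branch_lengths),
            codon_freqs=pi, lnl=null_fit.lnl,
            mix=SiteClassMix(null_fit.mix.p0, null_fit.mix.p1,
                             null_fit.mix.omega0, 1.0),
            converged=best_alt.converged, n_sweeps=best_alt.n_sweeps,
        )
    stat = max(0.0, 2.0 * (best_alt.lnl - null_fit.lnl))
    p = lrt(null_fit.lnl, best_alt.lnl, df=1)
    result = LRTResult(
        gene_id=aln.gene_id,
        lnl_null=null_fit.lnl,
        lnl_alt=best_alt.lnl,
        statistic=stat,
        df=1,
        p_value=p,
        is_psg=p < p_threshold,
    )
    return BranchSiteResult(
        gene_id=aln.gene_id, null=null_fit, alt=best_alt, lrt=result,
        low_information=low_information,
    )
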