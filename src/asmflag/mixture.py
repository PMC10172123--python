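"""Constrained four-component coverage mixture fitted by EM.

The model explains a read-depth histogram of a phased diploid assembly as
a mixture of four region classes:

* **Err** — bases with little or no read support, modelled as Poisson with
  mean ``err_lambda`` constrained to ``[0, 10]``; its M-step uses only
  depths below 10 to keep it from absorbing real coverage modes.
* **Dup** — falsely duplicated sequence: reads split between the extra
  copies, so depth concentrates near half the haploid mean.  Gaussian with
  mean tied to ``hap_mean / 2``.
* **Hap** — correctly assembled haploid sequence.  Gaussian with free mean
  ``hap_mean`` and s.d. ``hap_sd``.
* **Col** — collapsed repeats: k true copies assembled as one, giving depth
  near ``k * hap_mean``.  A family of Gaussians with means tied to
  ``k * hap_mean`` for ``k = 2 .. n_collapsed + 1``.

Only ``hap_mean`` is a free location parameter; the Dup and Col means are
derived from it and can never drift.  Densities are evaluated at integer
depths without continuity correction (a mixture-over-counts approximation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm, poisson

from .coverage import CoverageHistogram
from .errors import DegenerateFitError

ERR_LAMBDA_MAX = 10.0  # upper bound on the erroneous component's Poisson mean
ERR_MSTEP_MAX_DEPTH = 10  # the lambda M-step only uses depths below this

# tie multipliers: Dup at mu/2, Hap at mu, Col_k at k*mu
_DUP_RATIO = 0.5


@dataclass
class FitOptions:
    """Knobs of the EM fit.

    init_coverage is the starting haploid mean in reads — the only
    initialization the pipeline exposes, because the likelihood is
    multi-modal and the haploid mode must be seeded near the truth.
    """

    init_coverage: float
    max_iter: int = 300
    tol: float = 1e-6  # relative log-likelihood change
    n_collapsed: int = 4
    seed: int = 0  # reserved; the EM itself is deterministic
    min_bases: int = 10_000  # histograms thinner than this are degenerate
    sd_floor: float = 0.5  # reads; avoids zero-variance spikes

    def __post_init__(self) -> None:
        if self.init_coverage <= 0:
            raise ValueError("init_coverage must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.n_collapsed < 1:
            raise ValueError("n_collapsed must be >= 1")


@dataclass
class MixtureModel:
    """Fitted parameters of the constrained coverage mixture.

    Component order everywhere is ``[err, dup, hap, col_2, ..,
    col_(n_collapsed+1)]``.  ``dup`` and the collapsed means are derived
    from ``hap_mean`` and stored implicitly.
    """

    err_lambda: float
    hap_mean: float
    hap_sd: float
    dup_sd: float
    collapsed_sds: np.ndarray
    weights: np.ndarray
    loglik: float = float("nan")
    n_iter: int = 0
    converged: bool = False
    ll_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.collapsed_sds = np.asarray(self.collapsed_sds, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != 3 + self.n_collapsed:
            raise ValueError("weights length must be 3 + n_collapsed")
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-9):
            raise ValueError("weights must sum to 1")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if not (0.0 <= self.err_lambda <= ERR_LAMBDA_MAX):
            raise ValueError(f"err_lambda must lie in [0, {ERR_LAMBDA_MAX}]")
        if self.hap_mean <= 0 or self.hap_sd <= 0 or self.dup_sd <= 0:
            raise ValueError("hap_mean and s.d. parameters must be positive")

    @property
    def n_collapsed(self) -> int:
        return len(self.collapsed_sds)

    @property
    def n_components(self) -> int:
        return 3 + self.n_collapsed

    @property
    def dup_mean(self) -> float:
        return _DUP_RATIO * self.hap_mean

    @property
    def collapsed_means(self) -> np.ndarray:
        return self.hap_mean * np.arange(2, self.n_collapsed + 2, dtype=float)

    @property
    def component_names(self) -> list[str]:
        return ["err", "dup", "hap"] + [f"col{k}" for k in range(2, self.n_collapsed + 2)]

    def log_density_matrix(self, depths: np.ndarray) -> np.ndarray:
        """(len(depths), n_components) matrix of per-component log densities."""
        depths = np.asarray(depths, dtype=float)
        cols = [poisson.logpmf(depths, self.err_lambda)]
        means = np.concatenate(([self.dup_mean, self.hap_mean], self.collapsed_means))
        sds = np.concatenate(([self.dup_sd, self.hap_sd], self.collapsed_sds))
        for m, s in zip(means, sds):
            cols.append(norm.logpdf(depths, loc=m, scale=s))
        return np.column_stack(cols)

    def log_weighted_density(self, depths: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            logw = np.log(self.weights)
        return self.log_density_matrix(depths) + logw

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "err_lambda": self.err_lambda,
                "hap_mean": self.hap_mean,
                "hap_sd": self.hap_sd,
                "dup_mean": self.dup_mean,
                "dup_sd": self.dup_sd,
                "collapsed_means": self.collapsed_means.tolist(),
                "collapsed_sds": self.collapsed_sds.tolist(),
                "weights": self.weights.tolist(),
                "component_names": self.component_names,
                "loglik": self.loglik,
                "n_iter": self.n_iter,
                "converged": self.converged,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MixtureModel":
        d = json.loads(text)
        return cls(
            err_lambda=d["err_lambda"],
            hap_mean=d["hap_mean"],
            hap_sd=d["hap_sd"],
            dup_sd=d["dup_sd"],
            collapsed_sds=np.array(d["collapsed_sds"]),
            weights=np.array(d["weights"]),
            loglik=d.get("loglik", float("nan")),
            n_iter=d.get("n_iter", 0),
            converged=d.get("converged", False),
        )


@dataclass
class AssignmentTable:
    """Depth -> label lookup derived from a fitted model.

    ``labels[k]`` is the integer label code for depth ``k`` (see
    :mod:`asmflag.flagging` for the code/name mapping); collapsed
    sub-components are pooled into the single Col label.
    """

    labels: np.ndarray  # int8, index = depth, 0..max_depth

    @property
    def max_depth(self) -> int:
        return len(self.labels) - 1

    def label(self, depth: int) -> int:
        if not 0 <= depth <= self.max_depth:
            raise KeyError(f"depth {depth} outside table 0..{self.max_depth}")
        return int(self.labels[depth])


# label codes shared with the flagging module (kept here to avoid a cycle)
LABEL_ERR, LABEL_DUP, LABEL_HAP, LABEL_COL, LABEL_UNK = range(5)
LABEL_NAMES = ("Err", "Dup", "Hap", "Col", "Unk")


def _initial_model(hist: CoverageHistogram, opts: FitOptions) -> MixtureModel:
    mu = float(opts.init_coverage)
    sd = max(mu / 8.0, opts.sd_floor)
    k = opts.n_collapsed
    weights = np.concatenate(([0.05, 0.05, 0.80], np.full(k, 0.10 / k)))
    return MixtureModel(
        err_lambda=1.0,
        hap_mean=mu,
        hap_sd=sd,
        dup_sd=sd,
        collapsed_sds=np.full(k, sd),
        weights=weights,
    )


def fit_mixture(hist: CoverageHistogram, opts: FitOptions) -> MixtureModel:
    """Fit the constrained mixture to a depth histogram by EM.

    The E-step evaluates all components at all observed depths; the M-step
    re-estimates the tied haploid mean jointly across the Gaussian family,
    per-component s.d.s (floored at ``opts.sd_floor``), the mixing weights,
    and the Poisson mean from responsibilities at depths below 10 only,
    clamped to ``[0, 10]``.

    Raises :class:`DegenerateFitError` when the histogram has fewer than
    two distinct depths or fewer than ``opts.min_bases`` bases — callers
    fitting windows should fall back to the whole-genome model.
    """
    if hist.total_bases < opts.min_bases:
        raise DegenerateFitError(
            f"histogram has {hist.total_bases} bases (< {opts.min_bases}); "
            f"fall back to the whole-genome model"
        )
    if hist.n_distinct() < 2:
        raise DegenerateFitError(
            "histogram has a single distinct depth; fall back to the "
            "whole-genome model"
        )

    support = np.flatnonzero(hist.counts)
    counts = hist.counts[support].astype(float)
    depths = support.astype(float)
    total = counts.sum()
    err_mask = depths < ERR_MSTEP_MAX_DEPTH
    tie = np.concatenate(
        ([_DUP_RATIO, 1.0], np.arange(2, opts.n_collapsed + 2, dtype=float))
    )

    model = _initial_model(hist, opts)
    ll_trace: list[float] = []
    converged = False
    for it in range(opts.max_iter):
        # E-step (log space; finite everywhere except zero-weight components)
        logwd = model.log_weighted_density(depths)
        row_ll = logsumexp(logwd, axis=1)
        ll = float(np.dot(counts, row_ll))
        ll_trace.append(ll)
        resp = np.exp(logwd - row_ll[:, None])  # (D, C)

        # M-step
        wc = counts[:, None] * resp
        nc = wc.sum(axis=0)  # effective bases per component
        weights = nc / total
        weights = weights / weights.sum()

        # Poisson mean from low depths only, clamped
        err_w = wc[err_mask, 0]
        err_mass = err_w.sum()
        if err_mass > 0:
            lam = float(np.dot(err_w, depths[err_mask]) / err_mass)
            lam = min(max(lam, 0.0), ERR_LAMBDA_MAX)
        else:
            lam = model.err_lambda

        # tied haploid mean across the Gaussian family (current s.d.s)
        sds = np.concatenate(([model.dup_sd, model.hap_sd], model.collapsed_sds))
        inv_var = 1.0 / sds**2
        num = float(np.einsum("dc,d,c->", wc[:, 1:], depths, tie * inv_var))
        den = float(wc[:, 1:].sum(axis=0) @ (tie**2 * inv_var))
        mu = num / den if den > 0 else model.hap_mean
        if mu <= 0:
            mu = model.hap_mean

        # per-component s.d.s around the tied means, floored
        new_sds = sds.copy()
        gmeans = tie * mu
        for j in range(len(tie)):
            mass = nc[j + 1]
            if mass > 1e-12:
                var = float(np.dot(wc[:, j + 1], (depths - gmeans[j]) ** 2) / mass)
                new_sds[j] = max(np.sqrt(var), opts.sd_floor)

        model = MixtureModel(
            err_lambda=lam,
            hap_mean=mu,
            hap_sd=new_sds[1],
            dup_sd=new_sds[0],
            collapsed_sds=new_sds[2:],
            weights=weights,
        )

        if it > 0:
            prev = ll_trace[-2]
            if abs(ll - prev) / (abs(prev) + 1e-12) < opts.tol:
                converged = True
                break

    # final log-likelihood under the returned parameters
    final_ll = float(
        np.dot(counts, logsumexp(model.log_weighted_density(depths), axis=1))
    )
    ll_trace.append(final_ll)
    model.loglik = final_ll
    model.n_iter = len(ll_trace) - 1
    model.converged = converged
    model.ll_trace = ll_trace
    return model


def component_posteriors(model: MixtureModel, depth: int) -> np.ndarray:
    """Posterior probability of each component at an integer depth."""
    if depth < 0:
        raise ValueError("depth must be non-negative")
    logwd = model.log_weighted_density(np.array([depth]))[0]
    return np.exp(logwd - logsumexp(logwd))


# per-label tie preference: safer labels win exact density ties
_LABEL_PREFERENCE = (LABEL_HAP, LABEL_DUP, LABEL_COL, LABEL_ERR)


def assign_components(model: MixtureModel, max_depth: int) -> AssignmentTable:
    """Map every depth in ``0..max_depth`` to its most probable label.

    The argmax is over weighted component densities; the collapsed
    sub-components pool into the single Col label.  Exact ties break
    toward Hap, then Dup, then Col, then Err.
    """
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    depths = np.arange(max_depth + 1)
    logwd = model.log_weighted_density(depths)  # (D, C)
    per_label = np.full((len(depths), 4), -np.inf)
    per_label[:, LABEL_ERR] = logwd[:, 0]
    per_label[:, LABEL_DUP] = logwd[:, 1]
    per_label[:, LABEL_HAP] = logwd[:, 2]
    if model.n_collapsed:
        per_label[:, LABEL_COL] = logwd[:, 3:].max(axis=1)
    # argmax with explicit preference order on exact ties
    ordered = per_label[:, list(_LABEL_PREFERENCE)]
    pick = np.argmax(ordered, axis=1)  # first max wins -> preference order
    labels = np.array(_LABEL_PREFERENCE, dtype=np.int8)[pick]
    # a depth where every label has -inf density cannot occur unless all
    # weights of finite-density components vanish; guard with Err
    dead = ~np.isfinite(ordered.max(axis=1))
    labels[dead] = LABEL_ERR
    return AssignmentTable(labels=labels)


def refit_with_init(
    hist: CoverageHistogram,
    opts: FitOptions,
    init_multiplier: float,
    reference_mean: float | None = None,
) -> MixtureModel:
    """Refit with the EM start point scaled by ``init_multiplier``.

    Used for coverage-biased satellite classes: the haploid-mean start
    point becomes ``init_multiplier`` times ``reference_mean`` (the
    genome-wide average sequencing coverage) or, if no reference is given,
    times the mean of the histogram itself.
    """
    if init_multiplier <= 0:
        raise ValueError("init_multiplier must be positive")
    base = reference_mean if reference_mean is not None else hist.mean()
    if base <= 0:
        raise DegenerateFitError("cannot derive a positive starting coverage")
    new_opts = FitOptions(
        init_coverage=init_multiplier * base,
        max_iter=opts.max_iter,
        tol=opts.tol,
        n_collapsed=opts.n_collapsed,
        seed=opts.seed,
        min_bases=opts.min_bases,
        sd_floor=opts.sd_floor,
    )
    return fit_mixture(hist, new_opts)
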