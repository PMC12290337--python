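"""Maximum-likelihood conjoint measurement for paired-comparison data.

An observer compares two stimuli that vary along two physical dimensions
(here: specularity level i and transparent-layer level j) and reports
which appears glossier.  The decision variable is the difference of
perceptual scale values plus one Gaussian judgment error, so the
probability of choosing the left stimulus is a probit of the scale
difference.  Three nested observer models are fitted by maximum
likelihood:

- **independent**: only the attended dimension contributes,
  ``delta = psi_g[i] - psi_g[k]``;
- **additive**: the unattended dimension shifts perceived gloss
  additively, ``delta = (psi_g[i] + psi_r[j]) - (psi_g[k] + psi_r[l])``;
- **full**: an interaction term ``psi_gr[i, j]`` is added, saturating the
  per-stimulus utilities.

Identifiability follows the standard conjoint-measurement convention: the
decision noise is fixed at sigma = 1 (scales are in d'-like units) and the
first level of each dimension is anchored at 0 (first row and column of
the interaction matrix for the full model).  Model comparison uses the
chi-square likelihood-ratio test for nested models.

The surface mirrors statsmodels: build a :class:`ConjointModel` from
trials or a tidy DataFrame, call :meth:`~ConjointModel.fit`, and work with
the returned :class:`ConjointResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2, norm

from .synth import ConjointTrial, ObserverModel, conjoint_trials_from_frame

__all__ = [
    "ConjointModel",
    "ConjointResults",
    "LRTestResult",
    "ProportionMatrix",
    "proportion_matrix",
    "lr_test",
    "bonferroni_level",
    "normalize_and_aggregate",
]

logger = logging.getLogger(__name__)

MODELS = ("independent", "additive", "full")
_MODEL_ORDER = {m: k for k, m in enumerate(MODELS)}

#: Box bound on anchored scale parameters; estimates pinned here indicate
#: complete separation (an empirical choice proportion of 0 or 1).
PARAM_CAP = 10.0
RIDGE = 1e-6


@dataclass(frozen=True)
class LRTestResult:
    """Nested likelihood-ratio test: 2*(LL_full - LL_reduced) ~ chi2(df)."""

    statistic: float
    df: int
    p_value: float
    reduced_model: str
    full_model: str


@dataclass(frozen=True)
class ProportionMatrix:
    """Pairwise choice proportions over the stimulus set.

    ``entries[a, b]`` is the fraction of trials pairing stimuli a and b
    (in either presentation order) in which a was judged glossier; NaN for
    unobserved pairs.  Stimulus index ``s = i * n_filter + j``.
    """

    entries: np.ndarray
    counts: np.ndarray
    n_gloss: int
    n_filter: int

    def stimulus_label(self, s: int) -> tuple[int, int]:
        return divmod(s, self.n_filter)


def bonferroni_level(family_alpha: float, m: int) -> float:
    """Per-test level controlling the family-wise error at `family_alpha`
    over `m` comparisons (e.g. 0.05 / 8 = 0.00625)."""
    if m < 1:
        raise ValueError("number of comparisons m must be >= 1")
    if not (0.0 < family_alpha <= 1.0):
        raise ValueError("family_alpha must be in (0, 1]")
    return family_alpha / m


class ConjointModel:
    """Conjoint-measurement model for binary paired-comparison data.

    Parameters
    ----------
    trials : list of ConjointTrial
        Responded trials; ``response == 1`` means the left stimulus was
        judged glossier.
    n_gloss, n_filter : int, optional
        Grid dimensions; inferred from the trials when omitted.
    """

    def __init__(self, trials, n_gloss: int | None = None, n_filter: int | None = None):
        trials = list(trials)
        if not trials:
            raise ValueError("no trials provided")
        if any(t.response is None for t in trials):
            raise ValueError("all trials must carry responses")
        self.trials = trials
        self.gi = np.array([t.left[0] for t in trials])
        self.fj = np.array([t.left[1] for t in trials])
        self.gk = np.array([t.right[0] for t in trials])
        self.fl = np.array([t.right[1] for t in trials])
        self.y = np.array([t.response for t in trials], dtype=float)
        self.n_gloss = int(n_gloss if n_gloss is not None else max(self.gi.max(), self.gk.max()) + 1)
        self.n_filter = int(n_filter if n_filter is not None else max(self.fj.max(), self.fl.max()) + 1)
        if len(set(self.gi) | set(self.gk)) < 2:
            raise ValueError("trials must span at least two gloss levels")
        self._data_key = hash(tuple((t.left, t.right, t.response) for t in trials))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ConjointModel":
        """Build from the conjoint CSV schema (gloss_left, filter_left,
        gloss_right, filter_right, response)."""
        return cls(conjoint_trials_from_frame(df), **kwargs)

    # -- design matrices -----------------------------------------------------

    def _check_coverage(self, model: str) -> None:
        ng, nf = self.n_gloss, self.n_filter
        gloss_seen = set(self.gi) | set(self.gk)
        filt_seen = set(self.fj) | set(self.fl)
        if gloss_seen != set(range(ng)):
            raise ValueError("under-identified: some gloss level never appears in the trials")
        if model in ("additive", "full") and filt_seen != set(range(nf)):
            raise ValueError("under-identified: some filter level never appears in the trials")
        if model == "full":
            seen = set(zip(self.gi, self.fj)) | set(zip(self.gk, self.fl))
            if len(seen) < ng * nf:
                raise ValueError("under-identified: some stimulus cell never appears in the trials")

    def _design(self, model: str) -> np.ndarray:
        """Signed indicator matrix X with delta = X @ theta.

        Anchored parameterizations: independent -> theta = psi_g[1:];
        additive -> (psi_g[1:], psi_r[1:]); full -> per-stimulus utilities
        u[1:] with u for stimulus (0, 0) anchored at 0.
        """
        ng, nf = self.n_gloss, self.n_filter
        n = len(self.y)
        if model == "independent":
            X = np.zeros((n, ng - 1))
            for m in range(1, ng):
                X[:, m - 1] = (self.gi == m).astype(float) - (self.gk == m).astype(float)
        elif model == "additive":
            X = np.zeros((n, (ng - 1) + (nf - 1)))
            for m in range(1, ng):
                X[:, m - 1] = (self.gi == m).astype(float) - (self.gk == m).astype(float)
            for m in range(1, nf):
                X[:, ng - 1 + m - 1] = (self.fj == m).astype(float) - (self.fl == m).astype(float)
        elif model == "full":
            s_left = self.gi * nf + self.fj
            s_right = self.gk * nf + self.fl
            X = np.zeros((n, ng * nf - 1))
            for s in range(1, ng * nf):
                X[:, s - 1] = (s_left == s).astype(float) - (s_right == s).astype(float)
        else:
            raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
        return X

    # -- likelihood ----------------------------------------------------------

    @staticmethod
    def _nll_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray, ridge: float):
        """Penalized negative Bernoulli-probit log-likelihood and gradient."""
        delta = X @ theta
        # log P(y) with numerically stable tails via norm.logcdf
        ll = y @ norm.logcdf(delta) + (1.0 - y) @ norm.logcdf(-delta)
        logpdf = norm.logpdf(delta)
        w = y * np.exp(logpdf - norm.logcdf(delta)) - (1.0 - y) * np.exp(
            logpdf - norm.logcdf(-delta)
        )
        grad = -(X.T @ w) + 2.0 * ridge * theta
        return -ll + ridge * (theta @ theta), grad

    def loglike(self, theta: np.ndarray, model: str = "additive") -> float:
        """Unpenalized log-likelihood at an anchored parameter vector."""
        nll, _ = self._nll_grad(np.asarray(theta, float), self._design(model), self.y, 0.0)
        return -nll

    def fit(self, model: str = "additive", maxiter: int = 500) -> "ConjointResults":
        """Fit by (lightly ridge-penalized) maximum likelihood.

        A tiny ridge (1e-6 * ||theta||^2) regularizes complete separation,
        which low-repetition designs can produce; parameters are bounded
        at +/-10 and a fit pinned at the bound is flagged as separated,
        not raised.  Multistart (zeros + one random start) guards against
        flat regions; the reported log-likelihood is unpenalized, after a
        final unpenalized polish, so nested fits are directly comparable.
        """
        self._check_coverage(model)
        X = self._design(model)
        p = X.shape[1]
        bounds = [(-PARAM_CAP, PARAM_CAP)] * p
        rng = np.random.default_rng(12345)  # fixed: fits are deterministic
        starts = [np.zeros(p), rng.normal(0.0, 0.5, size=p)]
        best = None
        for x0 in starts:
            res = optimize.minimize(
                self._nll_grad, x0, args=(X, self.y, RIDGE), jac=True,
                method="L-BFGS-B", bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9},
            )
            if best is None or res.fun < best.fun:
                best = res
        # Unpenalized polish from the penalized optimum (convex problem,
        # so the box-constrained optimum is global).
        res = optimize.minimize(
            self._nll_grad, best.x, args=(X, self.y, 0.0), jac=True,
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9},
        )
        theta = res.x
        separated = bool(np.any(np.abs(theta) >= PARAM_CAP - 1e-6))
        if separated:
            logger.warning("fit(%s): parameters at the +/-%g cap (complete separation)", model, PARAM_CAP)
        llf = -self._nll_grad(theta, X, self.y, 0.0)[0]
        return ConjointResults(
            model_name=model,
            params=theta.copy(),
            estimates=self._unpack(theta, model),
            llf=float(llf),
            n_free_params=p,
            converged=bool(res.success or best.success),
            separated=separated,
            n_trials=len(self.y),
            n_gloss=self.n_gloss,
            n_filter=self.n_filter,
            data_key=self._data_key,
        )

    def _unpack(self, theta: np.ndarray, model: str) -> ObserverModel:
        ng, nf = self.n_gloss, self.n_filter
        if model == "independent":
            psi_g = np.concatenate([[0.0], theta])
            return ObserverModel(psi_g=tuple(psi_g), psi_r=(0.0,) * nf, sigma=1.0)
        if model == "additive":
            psi_g = np.concatenate([[0.0], theta[: ng - 1]])
            psi_r = np.concatenate([[0.0], theta[ng - 1 :]])
            return ObserverModel(psi_g=tuple(psi_g), psi_r=tuple(psi_r), sigma=1.0)
        # full: utilities u[i, j] with u[0, 0] = 0, decomposed so that the
        # interaction matrix has zero first row and column.
        u = np.concatenate([[0.0], theta]).reshape(ng, nf)
        psi_g = u[:, 0].copy()
        psi_r = u[0, :].copy()
        psi_gr = u - psi_g[:, None] - psi_r[None, :]
        return ObserverModel(
            psi_g=tuple(psi_g), psi_r=tuple(psi_r), psi_gr=tuple(map(tuple, psi_gr)), sigma=1.0
        )


@dataclass(frozen=True)
class ConjointResults:
    """Fitted conjoint-measurement observer model.

    ``estimates`` holds the anchored perceptual scales as an
    :class:`~glosstrans.synth.ObserverModel` with sigma = 1; ``llf`` is the
    (unpenalized) maximized log-likelihood.
    """

    model_name: str
    params: np.ndarray
    estimates: ObserverModel
    llf: float
    n_free_params: int
    converged: bool
    separated: bool
    n_trials: int
    n_gloss: int
    n_filter: int
    data_key: int = 0

    def predict(self, trials) -> np.ndarray:
        """P(left judged glossier) for each trial under the fitted scales."""
        gl = np.array([t.left[0] for t in trials])
        fl = np.array([t.left[1] for t in trials])
        gr = np.array([t.right[0] for t in trials])
        fr = np.array([t.right[1] for t in trials])
        delta = self.estimates.utility(gl, fl) - self.estimates.utility(gr, fr)
        return norm.cdf(delta)

    def summary(self) -> str:
        est = self.estimates
        lines = [
            "Conjoint measurement fit",
            "=" * 46,
            f"Model:            {self.model_name}",
            f"Trials:           {self.n_trials}",
            f"Free parameters:  {self.n_free_params}",
            f"Log-likelihood:   {self.llf:.4f}",
            f"Converged:        {self.converged}" + ("  [separation flagged]" if self.separated else ""),
            "-" * 46,
            "Gloss scale psi_g:  " + "  ".join(f"{v: .3f}" for v in est.psi_g),
            "Filter scale psi_r: " + "  ".join(f"{v: .3f}" for v in est.psi_r),
        ]
        if est.psi_gr is not None:
            lines.append("Interaction psi_gr:")
            for row in est.psi_gr:
                lines.append("  " + "  ".join(f"{v: .3f}" for v in row))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "model": self.model_name,
            "log_likelihood": self.llf,
            "n_free_params": self.n_free_params,
            "converged": self.converged,
            "separated": self.separated,
            "n_trials": self.n_trials,
            "psi_g": list(self.estimates.psi_g),
            "psi_r": list(self.estimates.psi_r),
        }
        if self.estimates.psi_gr is not None:
            d["psi_gr"] = [list(r) for r in self.estimates.psi_gr]
        return d


def lr_test(reduced: ConjointResults, full: ConjointResults) -> LRTestResult:
    """Likelihood-ratio test of nested conjoint observer models."""
    if _MODEL_ORDER.get(reduced.model_name, 99) >= _MODEL_ORDER.get(full.model_name, -1):
        raise ValueError(
            f"{reduced.model_name!r} is not nested within {full.model_name!r}"
        )
    if reduced.n_trials != full.n_trials or reduced.data_key != full.data_key:
        raise ValueError("both fits must come from the same trials")
    stat = 2.0 * (full.llf - reduced.llf)
    if stat < -1e-6:
        raise ValueError("full-model likelihood below reduced: convergence failure")
    stat = max(stat, 0.0)
    df = full.n_free_params - reduced.n_free_params
    return LRTestResult(
        statistic=float(stat),
        df=int(df),
        p_value=float(chi2.sf(stat, df)),
        reduced_model=reduced.model_name,
        full_model=full.model_name,
    )


def proportion_matrix(trials, n_gloss: int | None = None, n_filter: int | None = None) -> ProportionMatrix:
    """Pairwise choice-proportion matrix, pooling left/right presentations."""
    trials = [t for t in trials if t.response is not None]
    if not trials:
        raise ValueError("no responded trials")
    ng = int(n_gloss if n_gloss is not None else max(max(t.left[0], t.right[0]) for t in trials) + 1)
    nf = int(n_filter if n_filter is not None else max(max(t.left[1], t.right[1]) for t in trials) + 1)
    S = ng * nf
    wins = np.zeros((S, S))
    counts = np.zeros((S, S), dtype=int)
    for t in trials:
        a = t.left[0] * nf + t.left[1]
        b = t.right[0] * nf + t.right[1]
        counts[a, b] += 1
        counts[b, a] += 1
        if t.response == 1:
            wins[a, b] += 1
        else:
            wins[b, a] += 1
    with np.errstate(invalid="ignore"):
        entries = np.where(counts > 0, wins / np.maximum(counts, 1), np.nan)
    return ProportionMatrix(entries=entries, counts=counts, n_gloss=ng, n_filter=nf)


def normalize_and_aggregate(fits: list[ConjointResults]) -> dict:
    """Average normalized scale estimates across observers.

    Each observer's estimates are divided by that observer's maximum
    estimate over both dimensions, then averaged level-wise; the spread is
    reported as SEM = sd / sqrt(n_observers).  Observers whose maximum
    estimate is <= 0 carry no usable scale and are excluded with a warning.
    """
    if not fits:
        raise ValueError("no fits to aggregate")
    ng, nf, mdl = fits[0].n_gloss, fits[0].n_filter, fits[0].model_name
    if any(f.n_gloss != ng or f.n_filter != nf or f.model_name != mdl for f in fits):
        raise ValueError("fits must share grid dimensions and model")
    g_rows, r_rows = [], []
    for k, f in enumerate(fits):
        pg = np.asarray(f.estimates.psi_g)
        pr = np.asarray(f.estimates.psi_r)
        mx = max(pg.max(), pr.max())
        if mx <= 0:
            logger.warning("observer %d excluded: maximum scale estimate <= 0", k)
            continue
        g_rows.append(pg / mx)
        r_rows.append(pr / mx)
    if not g_rows:
        raise ValueError("no observers with positive maximum estimate")
    G = np.vstack(g_rows)
    R = np.vstack(r_rows)
    n = G.shape[0]

    def _sem(a: np.ndarray) -> np.ndarray:
        if a.shape[0] < 2:
            return np.zeros(a.shape[1])
        return a.std(axis=0, ddof=1) / np.sqrt(a.shape[0])

    return {
        "gloss_mean": G.mean(axis=0),
        "gloss_sem": _sem(G),
        "filter_mean": R.mean(axis=0),
        "filter_sem": _sem(R),
        "n_observers": n,
    }
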