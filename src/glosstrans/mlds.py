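"""Maximum-likelihood difference scaling (MLDS).

Used to pre-scale a physical stimulus dimension (e.g. rendered specular
strength) into perceptually equal steps.  On each trial the observer sees
two stimulus pairs (a, b) and (c, d) with a < b <= c < d on the physical
axis and reports which pair looks more different.  Under the difference-
scale model the probability of choosing (a, b) is

    P = Phi( ((psi_b - psi_a) - (psi_d - psi_c)) / sigma )

and the scale values psi are estimated by maximum likelihood with the
endpoints anchored at psi_1 = 0 and psi_n = 1, sigma estimated.

The quadruple (non-overlapping pairs) protocol is implemented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import norm
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "MLDSTrial",
    "DifferenceScalingModel",
    "DifferenceScalingResults",
    "simulate_quadruples",
    "equal_step_levels",
]


@dataclass(frozen=True)
class MLDSTrial:
    """One quadruple judgment: response 1 = pair (a, b) looked more different."""

    a: int
    b: int
    c: int
    d: int
    response: int | None = None

    def __post_init__(self) -> None:
        if not (self.a < self.b <= self.c < self.d):
            raise ValueError("quadruple indices must satisfy a < b <= c < d")


def simulate_quadruples(
    n_levels: int,
    n_trials: int,
    psi_true,
    sigma: float,
    seed: int,
) -> list[MLDSTrial]:
    """Random non-overlapping quadruples answered by a simulated observer
    with true scale `psi_true` and decision noise `sigma`."""
    psi = np.asarray(psi_true, dtype=float)
    if psi.size != n_levels:
        raise ValueError("psi_true length must equal n_levels")
    if n_levels < 4:
        raise ValueError("need at least 4 levels for quadruples")
    rng = np.random.default_rng(seed)
    trials = []
    for _ in range(n_trials):
        a, b, c, d = np.sort(rng.choice(n_levels, size=4, replace=False))
        delta = (psi[b] - psi[a]) - (psi[d] - psi[c])
        resp = int(rng.random() < norm.cdf(delta / sigma))
        trials.append(MLDSTrial(int(a), int(b), int(c), int(d), resp))
    return trials


class DifferenceScalingModel:
    """Difference-scaling model for quadruple judgments."""

    def __init__(self, trials, n_levels: int):
        trials = list(trials)
        if not trials:
            raise ValueError("no trials provided")
        if any(t.response is None for t in trials):
            raise ValueError("all trials must carry responses")
        self.n_levels = int(n_levels)
        idx = np.array([[t.a, t.b, t.c, t.d] for t in trials])
        if idx.min() < 0 or idx.max() >= self.n_levels:
            raise ValueError("trial indices exceed n_levels")
        covered = set(idx.ravel().tolist())
        if covered != set(range(self.n_levels)):
            raise ValueError("under-identified: some level appears in no trial")
        self.idx = idx
        self.y = np.array([t.response for t in trials], dtype=float)

    # Free parameters: interior scale values psi_2..psi_{n-1} and, unless
    # sigma is held fixed, log sigma; psi_1 = 0 and psi_n = 1 are anchored.
    def _unpack(self, theta: np.ndarray, fixed_sigma: float | None):
        psi = np.empty(self.n_levels)
        psi[0], psi[-1] = 0.0, 1.0
        if fixed_sigma is None:
            psi[1:-1] = theta[:-1]
            return psi, float(np.exp(theta[-1]))
        psi[1:-1] = theta
        return psi, float(fixed_sigma)

    def _nll(self, theta: np.ndarray, fixed_sigma: float | None = None) -> float:
        psi, sigma = self._unpack(theta, fixed_sigma)
        a, b, c, d = self.idx.T
        delta = ((psi[b] - psi[a]) - (psi[d] - psi[c])) / sigma
        ll = self.y @ norm.logcdf(delta) + (1.0 - self.y) @ norm.logcdf(-delta)
        return -ll

    def loglike(self, psi, sigma: float) -> float:
        theta = np.concatenate([np.asarray(psi, float)[1:-1], [np.log(sigma)]])
        return -self._nll(theta)

    def fit(self, maxiter: int = 500, sigma: float | None = None) -> "DifferenceScalingResults":
        """Fit by maximum likelihood.

        With ``sigma=None`` (default) the noise SD is estimated jointly
        with the scale.  Passing a fixed ``sigma`` pins it, which keeps the
        scale identified even for signal-free data (with sigma free, pure
        guessing is explained equally well by any scale and a huge sigma).
        """
        n = self.n_levels
        x0 = np.linspace(0.0, 1.0, n)[1:-1]
        if sigma is None:
            x0 = np.concatenate([x0, [np.log(0.3)]])
        res = optimize.minimize(
            self._nll, x0, args=(sigma,), method="Nelder-Mead" if n <= 3 else "BFGS",
            options={"maxiter": maxiter},
        )
        psi, sigma = self._unpack(res.x, sigma)
        return DifferenceScalingResults(
            scale=psi,
            sigma=sigma,
            llf=float(-res.fun),
            converged=bool(res.success),
            n_trials=len(self.y),
        )


@dataclass(frozen=True)
class DifferenceScalingResults:
    """Estimated difference scale, anchored to scale[0] = 0, scale[-1] = 1.

    Monotonicity is not enforced during estimation; the scale is reported
    exactly as estimated (sampling noise can produce local dips).
    """

    scale: np.ndarray
    sigma: float
    llf: float
    converged: bool
    n_trials: int

    def summary(self) -> str:
        return "\n".join(
            [
                "Difference scaling fit",
                "=" * 40,
                f"Levels:          {len(self.scale)}",
                f"Trials:          {self.n_trials}",
                f"Log-likelihood:  {self.llf:.4f}",
                f"sigma:           {self.sigma:.4f}",
                "Scale: " + "  ".join(f"{v:.4f}" for v in self.scale),
            ]
        )


def equal_step_levels(physical: np.ndarray, fitted_scale: np.ndarray, n_steps: int) -> np.ndarray:
    """Physical values whose fitted perceptual values are equally spaced.

    The fitted scale over the fine physical grid is made monotone by
    isotonic projection, rescaled to [0, 1], then inverted by linear
    interpolation at n_steps equally spaced perceptual values.  A flat
    (non-invertible) scale raises a ValueError.
    """
    x = np.asarray(physical, dtype=float)
    psi = np.asarray(fitted_scale, dtype=float)
    if x.shape != psi.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("physical grid and fitted scale must be matching 1-D arrays")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    iso = IsotonicRegression(increasing=True)
    psi_mono = iso.fit_transform(x, psi)
    span = psi_mono[-1] - psi_mono[0]
    if span <= 0:
        raise ValueError("degenerate (flat) perceptual scale cannot be inverted")
    psi_norm = (psi_mono - psi_mono[0]) / span
    targets = np.linspace(0.0, 1.0, n_steps)
    # np.interp needs strictly increasing xp; collapse flat runs first.
    keep = np.concatenate([[True], np.diff(psi_norm) > 0])
    return np.interp(targets, psi_norm[keep], x[keep])
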