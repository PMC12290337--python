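"""Synthetic observers, trial designs and procedural stimuli.

Everything the analysis pipeline consumes can be generated here: the
paired-comparison trial design (every unordered pair of the gloss x filter
stimulus grid), binary responses from a simulated conjoint observer with
additive perceptual scales and Gaussian decision noise, lattice-quantized
matching responses with per-filter biases, and procedural glossy-object
images (diffuse blob + localized highlights on a checkerboard).

All generators take an explicit integer seed and draw from their own
``numpy.random.Generator``; identical inputs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "StimulusGrid",
    "ObserverModel",
    "ConjointTrial",
    "MatchTrial",
    "build_conjoint_design",
    "simulate_conjoint_responses",
    "simulate_matching",
    "generate_glossy_image",
    "conjoint_trials_to_frame",
    "conjoint_trials_from_frame",
    "match_trials_to_frame",
    "match_trials_from_frame",
]

CONDITIONS = ("albedo_only", "gloss_only", "both")


@dataclass(frozen=True)
class StimulusGrid:
    """The gloss-level x filter-level stimulus factorial.

    ``gloss_values`` and ``filter_specs`` optionally attach physical
    specularities and Metelli layer parameters to the level indices.
    """

    n_gloss: int
    n_filter: int
    gloss_values: tuple | None = None
    filter_specs: tuple | None = None

    def __post_init__(self) -> None:
        if self.n_gloss < 2:
            raise ValueError("need at least 2 gloss levels")
        if self.n_filter < 1:
            raise ValueError("need at least 1 filter level")
        if self.gloss_values is not None and len(self.gloss_values) != self.n_gloss:
            raise ValueError("gloss_values length must equal n_gloss")
        if self.filter_specs is not None and len(self.filter_specs) != self.n_filter:
            raise ValueError("filter_specs length must equal n_filter")

    @property
    def n_stimuli(self) -> int:
        return self.n_gloss * self.n_filter

    def stimuli(self) -> list[tuple[int, int]]:
        """All (gloss level, filter level) index pairs, filter fastest."""
        return [(i, j) for i in range(self.n_gloss) for j in range(self.n_filter)]


@dataclass(frozen=True)
class ObserverModel:
    """Ground-truth perceptual scales of a simulated conjoint observer.

    The perceived gloss of stimulus (i, j) is
    ``psi_g[i] + psi_r[j] (+ psi_gr[i, j])`` and a paired comparison is
    decided by the sign of the difference plus one Gaussian judgment error
    of standard deviation ``sigma``.  Scales are anchored with their first
    level at zero (first row/column of the interaction matrix for the full
    model), the standard identifiability convention.
    """

    psi_g: tuple
    psi_r: tuple
    psi_gr: tuple | None = None
    sigma: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "psi_g", tuple(float(v) for v in self.psi_g))
        object.__setattr__(self, "psi_r", tuple(float(v) for v in self.psi_r))
        if self.sigma <= 0:
            raise ValueError("decision noise sigma must be positive")
        if self.psi_g[0] != 0.0 or self.psi_r[0] != 0.0:
            raise ValueError("scales must be anchored: psi_g[0] = psi_r[0] = 0")
        if self.psi_gr is not None:
            gr = np.asarray(self.psi_gr, dtype=float)
            if gr.shape != (len(self.psi_g), len(self.psi_r)):
                raise ValueError("psi_gr must be n_gloss x n_filter")
            if np.any(gr[0, :] != 0.0) or np.any(gr[:, 0] != 0.0):
                raise ValueError("psi_gr first row and column must be zero")
            object.__setattr__(self, "psi_gr", tuple(map(tuple, gr)))

    def utility(self, gloss: np.ndarray, filt: np.ndarray) -> np.ndarray:
        """Deterministic perceived gloss of stimuli (gloss, filt)."""
        g = np.asarray(self.psi_g)[gloss]
        r = np.asarray(self.psi_r)[filt]
        if self.psi_gr is not None:
            return g + r + np.asarray(self.psi_gr)[gloss, filt]
        return g + r


@dataclass(frozen=True)
class ConjointTrial:
    """One paired comparison of two (gloss, filter) stimuli."""

    left: tuple[int, int]
    right: tuple[int, int]
    response: int | None = None  # 1 = left judged glossier

    def __post_init__(self) -> None:
        if tuple(self.left) == tuple(self.right):
            raise ValueError("self-comparisons are not allowed")


@dataclass(frozen=True)
class MatchTrial:
    """One asymmetric-matching trial on the 7-step material lattice."""

    condition: str
    target_albedo: int
    target_gloss: int
    filter_id: int
    target_shape: int = 1
    matched_albedo: int | None = None
    matched_gloss: int | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        for name in ("target_albedo", "target_gloss"):
            v = getattr(self, name)
            if not (1 <= v <= 7):
                raise ValueError(f"{name} must be a lattice level in 1..7, got {v}")
        if self.target_shape not in (1, 2):
            raise ValueError("target_shape must be 1 or 2")


# ---------------------------------------------------------------------------
# Trial design and response simulation

def build_conjoint_design(
    grid: StimulusGrid, repetitions: int, seed: int | None = None
) -> list[ConjointTrial]:
    """All unordered pairs of distinct stimuli, `repetitions` times each.

    A 4 x 4 grid yields C(16, 2) = 120 pairs per repetition (480 trials at
    4 repetitions).  Left/right assignment is randomized per trial under
    `seed`; with ``seed=None`` the first stimulus is always on the left.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    stimuli = grid.stimuli()
    if len(stimuli) < 2:
        raise ValueError("design needs at least 2 stimuli")
    pairs = list(combinations(stimuli, 2))
    rng = np.random.default_rng(seed) if seed is not None else None
    trials = []
    for _ in range(repetitions):
        for a, b in pairs:
            if rng is not None and rng.random() < 0.5:
                a, b = b, a
            trials.append(ConjointTrial(left=a, right=b))
    return trials


def simulate_conjoint_responses(
    trials: list[ConjointTrial], observer: ObserverModel, seed: int
) -> list[ConjointTrial]:
    """Fill in binary responses from a simulated observer.

    The left stimulus is judged glossier with probability
    ``Phi(delta / sigma)`` where ``delta`` is the deterministic utility
    difference — a single noise draw on the decision variable.
    """
    gl = np.array([t.left[0] for t in trials])
    fl = np.array([t.left[1] for t in trials])
    gr = np.array([t.right[0] for t in trials])
    fr = np.array([t.right[1] for t in trials])
    for arr, n in ((gl, len(observer.psi_g)), (gr, len(observer.psi_g)),
                   (fl, len(observer.psi_r)), (fr, len(observer.psi_r))):
        if arr.size and (arr.min() < 0 or arr.max() >= n):
            raise ValueError("trial indices exceed observer scale dimensions")
    delta = observer.utility(gl, fl) - observer.utility(gr, fr)
    p_left = norm.cdf(delta / observer.sigma)
    rng = np.random.default_rng(seed)
    responses = (rng.random(len(trials)) < p_left).astype(int)
    return [replace(t, response=int(r)) for t, r in zip(trials, responses)]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def simulate_matching(
    targets: list[MatchTrial],
    bias_albedo,
    bias_gloss,
    noise_sd: float,
    seed: int,
) -> list[MatchTrial]:
    """Simulate lattice-quantized matches with per-filter biases.

    The matched level is ``round(clip(target + bias[filter] + noise, 1, 7))``
    for each attribute the condition leaves free; the fixed attribute is
    copied unchanged (it was pre-set to its correct value in the task).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    bias_albedo = np.asarray(bias_albedo, dtype=float)
    bias_gloss = np.asarray(bias_gloss, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for t in targets:
        if t.filter_id >= bias_albedo.size or t.filter_id >= bias_gloss.size:
            raise ValueError("bias vectors must have one entry per filter level")
        ma, mg = t.target_albedo, t.target_gloss
        if t.condition in ("albedo_only", "both"):
            raw = t.target_albedo + bias_albedo[t.filter_id] + rng.normal(0.0, noise_sd)
            ma = int(_round_half_away(np.clip(raw, 1.0, 7.0)))
        if t.condition in ("gloss_only", "both"):
            raw = t.target_gloss + bias_gloss[t.filter_id] + rng.normal(0.0, noise_sd)
            mg = int(_round_half_away(np.clip(raw, 1.0, 7.0)))
        out.append(replace(t, matched_albedo=ma, matched_gloss=mg))
    return out


# ---------------------------------------------------------------------------
# Procedural stimulus images

def generate_glossy_image(
    size: int = 128,
    albedo: float = 0.5,
    gloss: float = 0.5,
    n_highlights: int = 5,
    seed: int = 0,
    n_checks: int = 8,
) -> np.ndarray:
    """Procedural glossy object on a checkerboard, as a luminance image.

    A smooth shaded blob of diffuse level `albedo` sits on an
    ``n_checks x n_checks`` checkerboard; `n_highlights` localized Gaussian
    highlights with peak amplitude proportional to `gloss` emulate specular
    reflections.  Values are clipped to [0, 1]; output is deterministic
    under `seed`.
    """
    if size < 16:
        raise ValueError("size must be >= 16 pixels")
    if not (0.0 <= albedo <= 1.0 and 0.0 <= gloss <= 1.0):
        raise ValueError("albedo and gloss must be in [0, 1]")
    if n_highlights < 0:
        raise ValueError("n_highlights must be >= 0")
    rng = np.random.default_rng(seed)

    check = max(size // n_checks, 1)
    yy, xx = np.mgrid[0:size, 0:size]
    img = np.where(((yy // check) + (xx // check)) % 2 == 0, 0.35, 0.65)

    # Shaded diffuse blob: sphere-like falloff toward the rim.
    c = (size - 1) / 2.0
    rad = size * 0.32
    r2 = ((yy - c) ** 2 + (xx - c) ** 2) / rad**2
    inside = r2 <= 1.0
    shading = np.sqrt(np.clip(1.0 - r2, 0.0, 1.0))  # 1 at centre, 0 at rim
    diffuse = albedo * (0.35 + 0.65 * shading)
    img = np.where(inside, diffuse, img)

    # Specular highlights: small Gaussian bumps at seeded positions
    # inside the blob; amplitude grows monotonically with `gloss`.
    if gloss > 0.0 and n_highlights > 0:
        amp = 0.9 * gloss
        sig = size * 0.02
        for _ in range(n_highlights):
            theta = rng.uniform(0.0, 2.0 * np.pi)
            rho = rad * 0.7 * np.sqrt(rng.uniform())
            hy, hx = c + rho * np.sin(theta), c + rho * np.cos(theta)
            bump = amp * np.exp(-(((yy - hy) ** 2 + (xx - hx) ** 2) / (2.0 * sig**2)))
            img = img + np.where(inside, bump, 0.0)

    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# CSV interchange

def conjoint_trials_to_frame(trials: list[ConjointTrial]) -> pd.DataFrame:
    """Conjoint trials as a tidy table (schema: trial_id, gloss_left,
    filter_left, gloss_right, filter_right, response)."""
    return pd.DataFrame(
        {
            "trial_id": np.arange(len(trials)),
            "gloss_left": [t.left[0] for t in trials],
            "filter_left": [t.left[1] for t in trials],
            "gloss_right": [t.right[0] for t in trials],
            "filter_right": [t.right[1] for t in trials],
            "response": [t.response if t.response is not None else -1 for t in trials],
        }
    )


def conjoint_trials_from_frame(df: pd.DataFrame) -> list[ConjointTrial]:
    return [
        ConjointTrial(
            left=(int(r.gloss_left), int(r.filter_left)),
            right=(int(r.gloss_right), int(r.filter_right)),
            response=None if int(r.response) < 0 else int(r.response),
        )
        for r in df.itertuples()
    ]


def match_trials_to_frame(trials: list[MatchTrial]) -> pd.DataFrame:
    """Matching trials as a tidy table (schema: trial_id, condition,
    target_albedo, target_gloss, filter_id, target_shape, matched_albedo,
    matched_gloss)."""
    return pd.DataFrame(
        {
            "trial_id": np.arange(len(trials)),
            "condition": [t.condition for t in trials],
            "target_albedo": [t.target_albedo for t in trials],
            "target_gloss": [t.target_gloss for t in trials],
            "filter_id": [t.filter_id for t in trials],
            "target_shape": [t.target_shape for t in trials],
            "matched_albedo": [t.matched_albedo if t.matched_albedo is not None else -1 for t in trials],
            "matched_gloss": [t.matched_gloss if t.matched_gloss is not None else -1 for t in trials],
        }
    )


def match_trials_from_frame(df: pd.DataFrame) -> list[MatchTrial]:
    return [
        MatchTrial(
            condition=str(r.condition),
            target_albedo=int(r.target_albedo),
            target_gloss=int(r.target_gloss),
            filter_id=int(r.filter_id),
            target_shape=int(r.target_shape),
            matched_albedo=None if int(r.matched_albedo) < 0 else int(r.matched_albedo),
            matched_gloss=None if int(r.matched_gloss) < 0 else int(r.matched_gloss),
        )
        for r in df.itertuples()
    ]
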