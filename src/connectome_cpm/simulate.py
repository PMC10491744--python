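"""Synthetic cohorts with planted predictive networks.

The generator is the test bed standing in for the (non-deposited) clinical
fMRI data.  Each cohort has: an integer mood-severity score per subject
drawn from a truncated, rounded normal matching the published scale moments
(HDRS-5-like 3.4 +/- 3.4 on 0-13; YMRS-like 6.5 +/- 6.1 on 0-23); a shared
group-mean Fisher-z connectome plus subject noise; and two disjoint sparse
planted edge sets whose weights track the standardized score with slope
+beta (positive network) or -beta (negative network).  beta is set from the
requested per-edge edge-score correlation.  Covariates (age, gender, mean
framewise displacement) are drawn independently of the edges unless the
age-confounding switch couples age to the score.  Everything is reproducible
from the seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .connectome import n_edges_for
from .scores import Cohort


class SimulationError(ValueError):
    pass


@dataclass
class ScoreSpec:
    """Truncated-rounded-normal score distribution for one rating scale."""

    name: str
    mean: float
    sd: float
    floor: int
    ceiling: int


#: Published scale moments the generator emulates by default.
HDRS5_LIKE = ScoreSpec("hdrs5", mean=3.4, sd=3.4, floor=0, ceiling=13)
YMRS_LIKE = ScoreSpec("ymrs", mean=6.5, sd=6.1, floor=0, ceiling=23)


def _clipped_moments(mu: float, sig: float, lo: int, hi: int) -> tuple[float, float]:
    """Mean and SD of round(clip(Normal(mu, sig), lo, hi)) over integers."""
    ks = np.arange(lo, hi + 1)
    upper = np.where(ks == hi, np.inf, ks + 0.5)
    lower = np.where(ks == lo, -np.inf, ks - 0.5)
    p = sps.norm.cdf((upper - mu) / sig) - sps.norm.cdf((lower - mu) / sig)
    m = float((p * ks).sum())
    return m, float(np.sqrt((p * (ks - m) ** 2).sum()))


@lru_cache(maxsize=None)
def _calibrate_latent(mean: float, sd: float, floor: int, ceiling: int) -> tuple[float, float]:
    """Latent-normal (mu, sigma) whose clipped-rounded moments hit the target.

    Floor clipping piles mass at the scale minimum (as real severity
    ratings do), so SD ~= mean is attainable even though a plainly
    truncated normal cannot reach it.
    """
    def residual(par):
        m, s = _clipped_moments(par[0], abs(par[1]), floor, ceiling)
        return [m - mean, s - sd]

    sol, _, ier, _ = optimize.fsolve(residual, [mean, sd], full_output=True)
    if ier != 1:
        raise SimulationError(
            f"cannot calibrate a clipped normal to mean={mean}, sd={sd} on "
            f"[{floor}, {ceiling}]"
        )
    return float(sol[0]), float(abs(sol[1]))


@dataclass
class GeneratorConfig:
    """Conditions for one synthetic cohort.

    ``effect_r`` is the target per-edge correlation between a planted
    edge's weight and the score; the injection slope is derived as
    ``beta = edge_noise_sd * effect_r / sqrt(1 - effect_r**2)``.
    ``hub_bias`` is the probability that a planted edge is forced to touch
    one of ``n_hubs`` designated hub nodes, so degree analysis has signal.
    ``background_loading_sd`` scatters each subject's loading on the shared
    group-mean connectome around 1, emulating individual differences in
    global connectivity expression (without it, between-subject similarity
    is unrealistically uniform and outlier fences become degenerate).
    ``subject_noise_scale_sd`` > 0 gives each subject a log-normal noise
    multiplier, emulating heterogeneous acquisition in validation samples.
    """

    n_subjects: int = 81
    n_nodes: int = 368
    n_pos_edges: int = 40
    n_neg_edges: int = 40
    hub_bias: float = 0.5
    n_hubs: int = 2
    effect_r: float = 0.3
    edge_noise_sd: float = 0.15
    background_mean: float = 0.25
    background_sd: float = 0.15
    background_loading_sd: float = 0.05
    score: ScoreSpec = field(default_factory=lambda: HDRS5_LIKE)
    age_mean: float = 29.3
    age_sd: float = 11.1
    prop_female: float = 0.63
    fd_mean: float = 0.12
    fd_sd: float = 0.03
    subject_noise_scale_sd: float = 0.0
    confound_age: bool = False
    confound_age_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.score, dict):
            self.score = ScoreSpec(**self.score)
        if self.n_subjects < 2 or self.n_nodes < 3:
            raise SimulationError("need n_subjects >= 2 and n_nodes >= 3")
        if not 0.0 <= self.hub_bias <= 1.0:
            raise SimulationError("hub_bias must be in [0, 1]")
        if not 0.0 <= self.effect_r < 1.0:
            raise SimulationError("effect_r must be in [0, 1)")
        if self.n_pos_edges + self.n_neg_edges > self.n_edges:
            raise SimulationError(
                f"{self.n_pos_edges}+{self.n_neg_edges} planted edges exceed "
                f"{self.n_edges} available"
            )

    @property
    def n_edges(self) -> int:
        return n_edges_for(self.n_nodes)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """What was planted: edge masks per sign, hub nodes, latent scores."""

    pos_mask: np.ndarray
    neg_mask: np.ndarray
    hub_nodes: tuple[int, ...]
    latent_scores: np.ndarray

    def to_dict(self) -> dict:
        return {
            "pos_edges": [int(i) for i in np.flatnonzero(self.pos_mask)],
            "neg_edges": [int(i) for i in np.flatnonzero(self.neg_mask)],
            "hub_nodes": list(self.hub_nodes),
            "latent_scores": [float(v) for v in self.latent_scores],
        }


def _edge_index_lookup(n_nodes: int) -> np.ndarray:
    """(i, j) -> canonical edge index for i < j."""
    idx = np.zeros((n_nodes, n_nodes), dtype=np.int64)
    ii, jj = np.triu_indices(n_nodes, k=1)
    idx[ii, jj] = np.arange(ii.size)
    idx[jj, ii] = idx[ii, jj]
    return idx


def plant_networks(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, tuple[int, ...]]:
    """Sample disjoint positive/negative planted edge sets.

    With probability ``hub_bias`` an edge is drawn incident to one of the
    designated hub nodes (hubs are the first ``n_hubs`` node ids), else
    uniformly over all node pairs; sampling is without replacement across
    both signs.  Returns (pos_mask, neg_mask, hub_nodes).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_nodes
    lookup = _edge_index_lookup(n)
    hubs = tuple(range(config.n_hubs))
    taken: set[int] = set()

    def draw() -> int:
        for _ in range(100 * config.n_edges):
            if config.n_hubs and rng.random() < config.hub_bias:
                a = int(rng.choice(hubs))
                b = int(rng.integers(n))
            else:
                a, b = (int(v) for v in rng.integers(n, size=2))
            if a == b:
                continue
            e = int(lookup[a, b])
            if e not in taken:
                taken.add(e)
                return e
        raise SimulationError("could not place planted edges without replacement")

    pos = np.zeros(config.n_edges, dtype=bool)
    neg = np.zeros(config.n_edges, dtype=bool)
    for _ in range(config.n_pos_edges):
        pos[draw()] = True
    for _ in range(config.n_neg_edges):
        neg[draw()] = True
    return pos, neg, hubs


def generate_cohort(
    config: GeneratorConfig,
    subject_prefix: str = "sub",
    planted: tuple[np.ndarray, np.ndarray, tuple[int, ...]] | None = None,
) -> tuple[Cohort, GroundTruth]:
    """Draw one synthetic cohort and its ground truth.

    Scores are truncated to the configured floor/ceiling and rounded to
    integers; the effect is injected linearly in the standardized observed
    score so edge-score correlations match ``effect_r`` in expectation.
    Pass ``planted=(pos_mask, neg_mask, hub_nodes)`` (e.g. from a training
    cohort's ground truth) to draw an independent sample from the same
    generative process — fresh subjects, identical planted networks — as a
    validation cohort requires.
    """
    rng = np.random.default_rng(config.seed)
    if planted is None:
        pos, neg, hubs = plant_networks(config, rng)
    else:
        pos, neg, hubs = planted
        pos = np.asarray(pos, dtype=bool)
        neg = np.asarray(neg, dtype=bool)
        if pos.size != config.n_edges or neg.size != config.n_edges:
            raise SimulationError("planted masks do not match config.n_nodes")
    n, p = config.n_subjects, config.n_edges

    spec = config.score
    mu, sig = _calibrate_latent(spec.mean, spec.sd, spec.floor, spec.ceiling)
    latent = rng.normal(mu, sig, size=n)
    observed = np.clip(np.rint(latent), spec.floor, spec.ceiling)
    sd = observed.std()
    if sd == 0.0:
        raise SimulationError("degenerate score draw: all scores identical")
    z = (observed - observed.mean()) / sd

    rho = config.effect_r
    beta = config.edge_noise_sd * rho / np.sqrt(1.0 - rho * rho)
    background = rng.normal(config.background_mean, config.background_sd, size=p)
    noise = rng.normal(0.0, config.edge_noise_sd, size=(n, p))
    if config.subject_noise_scale_sd > 0.0:
        scale = np.exp(rng.normal(0.0, config.subject_noise_scale_sd, size=n))
        noise *= scale[:, None]
    loading = rng.normal(1.0, config.background_loading_sd, size=n)
    X = loading[:, None] * background[None, :] + noise
    X[:, pos] += beta * z[:, None]
    X[:, neg] -= beta * z[:, None]

    age = rng.normal(config.age_mean, config.age_sd, size=n)
    if config.confound_age:
        age = age + config.confound_age_slope * z
    gender = (rng.random(n) < config.prop_female).astype(np.float64)
    fd = np.abs(rng.normal(config.fd_mean, config.fd_sd, size=n))

    ids = [f"{subject_prefix}{k + 1:03d}" for k in range(n)]
    scores = {config.score.name: observed.astype(np.float64)}
    covariates = pd.DataFrame({"age": age, "gender": gender, "mean_fd": fd})
    cohort = Cohort(ids, X, scores, covariates)
    truth = GroundTruth(pos_mask=pos, neg_mask=neg, hub_nodes=hubs, latent_scores=latent)
    return cohort, truth


def recovery_metrics(selected: np.ndarray, truth_mask: np.ndarray) -> dict[str, float]:
    """Confusion-matrix rates of selected edges against the planted mask.

    Returns sensitivity (TP / planted), specificity (TN / unplanted) and
    the false-discovery proportion FP / selected (0 by convention when
    nothing is selected).
    """
    selected = np.asarray(selected, dtype=bool)
    truth_mask = np.asarray(truth_mask, dtype=bool)
    if selected.shape != truth_mask.shape:
        raise SimulationError("selected and truth masks differ in length")
    tp = int(np.sum(selected & truth_mask))
    fp = int(np.sum(selected & ~truth_mask))
    fn = int(np.sum(~selected & truth_mask))
    tn = int(np.sum(~selected & ~truth_mask))
    n_sel = tp + fp
    return {
        "sensitivity": tp / (tp + fn) if (tp + fn) else 0.0,
        "specificity": tn / (tn + fp) if (tn + fp) else 0.0,
        "false_discovery_proportion": fp / n_sel if n_sel else 0.0,
    }
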