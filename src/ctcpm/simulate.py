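"""Synthetic connectome cohorts with known ground truth.

The generator emulates the statistical structure the prediction pipeline
assumes: trait scores drawn from a truncated normal matching the study
sample (n = 156, mean 61.35, SD 10.81, range 40..92), background Fisher-z
edges that are independent noise, and a sparse set of signal edges carrying
a linear effect of the standardized score with both association signs
(default split 88 positive / 101 negative, matching the reported network).
Everything is deterministic under a single integer seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from .atlas import synthetic_atlas
from .core import ConnectomeCohort, edge_index_for
from .errors import DomainError


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model.

    ``beta_magnitude`` is the edge-weight on the standardized score in
    Fisher-z units; with background SD ``noise_sd_edges`` the population
    edge-trait correlation at a signal edge is
    ``beta / sqrt(beta^2 + noise_sd_edges^2)``. ``noise_sd_score`` adds
    measurement noise to the recorded score relative to the latent score
    driving the edges (0 = scores observed exactly).
    """

    n_subjects: int = 156
    n_nodes: int = 268
    n_signal_edges_pos: int = 88
    n_signal_edges_neg: int = 101
    beta_magnitude: float = 0.1
    noise_sd_edges: float = 0.3
    noise_sd_score: float = 0.0
    score_mean: float = 61.35
    score_sd: float = 10.81
    score_range: tuple[float, float] = (40.0, 92.0)
    seed: int = 0

    def validate(self) -> None:
        p = self.n_nodes
        if p < 2 or self.n_subjects < 3:
            raise DomainError("need n_nodes >= 2 and n_subjects >= 3")
        e = p * (p - 1) // 2
        if self.n_signal_edges_pos < 0 or self.n_signal_edges_neg < 0:
            raise DomainError("signal edge counts must be nonnegative")
        if self.n_signal_edges_pos + self.n_signal_edges_neg > e:
            raise DomainError(
                f"{self.n_signal_edges_pos + self.n_signal_edges_neg} signal edges "
                f"exceed E={e} for P={p}"
            )
        if self.noise_sd_edges <= 0 or self.score_sd <= 0:
            raise DomainError("noise_sd_edges and score_sd must be > 0")
        if self.noise_sd_score < 0:
            raise DomainError("noise_sd_score must be >= 0")
        lo, hi = self.score_range
        if not (lo < self.score_mean < hi):
            raise DomainError("score_range must bracket score_mean")


@dataclass(frozen=True)
class GroundTruth:
    """The signal edges planted in a simulated cohort."""

    edge_ids: np.ndarray
    signs: np.ndarray  # +-1 per signal edge
    betas: np.ndarray  # signed effect in Fisher-z units per SD of score
    description: str = "additive linear signal on standardized score in Fisher-z space"

    @property
    def n_signal(self) -> int:
        return len(self.edge_ids)


def _truncnorm_scores(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.score_range
    a = (lo - cfg.score_mean) / cfg.score_sd
    b = (hi - cfg.score_mean) / cfg.score_sd
    return stats.truncnorm.rvs(
        a, b, loc=cfg.score_mean, scale=cfg.score_sd, size=cfg.n_subjects, random_state=rng
    )


def simulate_cohort(config: SimulationConfig) -> tuple[ConnectomeCohort, GroundTruth]:
    """Draw a cohort from the generative model.

    Scores come from the configured truncated normal; background edges are
    i.i.d. ``N(0, noise_sd_edges)``; each signal edge additionally receives
    ``sign * beta_magnitude * z`` where ``z`` is the standardized latent
    score. Same config (incl. seed) -> identical cohort.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_subjects, config.n_nodes
    ei = edge_index_for(p)
    e = ei.n_edges

    latent = _truncnorm_scores(config, rng)
    z = (latent - latent.mean()) / latent.std()
    if config.noise_sd_score > 0:
        y = latent + rng.normal(0.0, config.noise_sd_score, size=n)
    else:
        y = latent

    x = rng.normal(0.0, config.noise_sd_edges, size=(n, e))
    n_sig = config.n_signal_edges_pos + config.n_signal_edges_neg
    signal_ids = np.sort(rng.choice(e, size=n_sig, replace=False))
    signs = np.ones(n_sig, dtype=int)
    if n_sig:
        neg_pick = rng.choice(n_sig, size=config.n_signal_edges_neg, replace=False)
        signs[neg_pick] = -1
    betas = signs * config.beta_magnitude
    if n_sig and config.beta_magnitude != 0:
        x[:, signal_ids] += z[:, None] * betas[None, :]

    effective = betas != 0
    truth = GroundTruth(
        edge_ids=signal_ids[effective],
        signs=signs[effective],
        betas=betas[effective],
    )
    subjects = [f"sub-{i + 1:03d}" for i in range(n)]
    cohort = ConnectomeCohort(
        subjects=subjects, X=x, y=y, edge_index=ei, atlas=synthetic_atlas(p)
    )
    return cohort, truth


def simulate_null_cohort(n_subjects: int, n_nodes: int, seed: int = 0, **kwargs) -> ConnectomeCohort:
    """Cohort whose edges are all independent of the scores."""
    if n_subjects < 10:
        raise DomainError("null cohorts need n_subjects >= 10")
    cfg = SimulationConfig(
        n_subjects=n_subjects,
        n_nodes=n_nodes,
        n_signal_edges_pos=0,
        n_signal_edges_neg=0,
        beta_magnitude=0.0,
        seed=seed,
        **kwargs,
    )
    cohort, _ = simulate_cohort(cfg)
    return cohort


def simulate_collinear_block(
    n_subjects: int, block_size: int, rho: float, seed: int = 0
) -> np.ndarray:
    """Equicorrelated Gaussian feature block with pairwise correlation ``rho``.

    Built as ``sqrt(rho) * g + sqrt(1 - rho) * e_j`` for a shared factor g,
    giving population pairwise correlation exactly rho.
    """
    if not (0.0 <= rho < 1.0):
        raise DomainError("rho must lie in [0, 1)")
    if block_size < 1 or n_subjects < 2:
        raise DomainError("need block_size >= 1 and n_subjects >= 2")
    rng = np.random.default_rng(seed)
    g = rng.normal(size=(n_subjects, 1))
    e = rng.normal(size=(n_subjects, block_size))
    return np.sqrt(rho) * g + np.sqrt(1.0 - rho) * e


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["score_range"] = list(d["score_range"])
    return d
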