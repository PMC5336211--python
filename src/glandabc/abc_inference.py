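"""Rejection ABC with weighted summary statistics.

Likelihood-free inference of the growth parameters: draw parameters from the
prior, simulate a tumor and its observed summaries, and accept the draws
whose summaries are closest to the observed ones.  The distance is a
weighted Euclidean metric

    d(S', S) = || (S' - S) W^T ||_2

computed on standardized statistics (each statistic is divided by its
reference-table median absolute deviation so count-valued and
frequency-valued statistics are commensurable).

Three weighting schemes are provided for a target parameter θ_l:

* ``equal`` — every statistic gets weight 1/M.
* ``global`` — weight ∝ R² of the simple linear regression of θ_l on
  statistic s_m over the whole reference table.
* ``local`` — same, but each statistic's regression is restricted to the
  ceil(η·N) reference rows whose s_m is nearest the observed value.

Weights are normalized to sum to one over the M statistics for the target
parameter.  Acceptance is by quantile: the ``accept_fraction·N`` smallest
distances define ε.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace as _dc_replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .growth_model import GrowthParams, ParameterError, TumorSample, simulate_tumor
from .sequencing_model import SeqModel, sequence_sample
from .summaries import N_STATS, STAT_NAMES, summarize

__all__ = [
    "PriorSpec",
    "SimConfig",
    "ReferenceTable",
    "WeightVector",
    "PosteriorSample",
    "sample_prior",
    "build_reference_table",
    "statistic_scale",
    "weighted_distance",
    "equal_weights",
    "global_regression_weights",
    "local_regression_weights",
    "abc_reject",
    "posterior_summary",
]

PARAM_NAMES = ("alpha", "beta", "r")


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors on the inferred parameters.

    Defaults cover a range wider than the mutation rates typically reported
    for normal tissue (0.015-0.15 per division per exome), and constrain the
    asymmetric-division probability to at least one half.
    """

    bounds: dict = field(
        default_factory=lambda: {"alpha": (0.0, 5.0), "beta": (0.0, 1.0), "r": (0.5, 1.0)}
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ParameterError(f"prior for {name} needs lower < upper")

    @property
    def names(self) -> tuple:
        return tuple(self.bounds)

    def support(self, name: str) -> tuple[float, float]:
        return self.bounds[name]


@dataclass(frozen=True)
class SimConfig:
    """Everything except the inferred parameters needed to simulate a tumor."""

    base_params: GrowthParams = field(
        default_factory=lambda: GrowthParams(alpha=0.0, beta=0.0, r=1.0)
    )
    glands_per_half: int = 6
    seq_model: SeqModel = field(default_factory=SeqModel)
    fission_mode: str = "bottleneck"


@dataclass
class ReferenceTable:
    """N prior draws paired with their simulated summary statistics."""

    theta: np.ndarray  # (N, L)
    stats: np.ndarray  # (N, M)
    param_names: tuple
    stat_names: tuple = STAT_NAMES
    scale: np.ndarray | None = None  # per-statistic standardization scale
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.theta.shape[0] != self.stats.shape[0] or self.theta.shape[0] < 1:
            raise ParameterError("theta and stats must pair row-for-row, N >= 1")
        if self.scale is None:
            self.scale = statistic_scale(self.stats)

    @property
    def n(self) -> int:
        return self.theta.shape[0]

    def param_column(self, name: str) -> np.ndarray:
        return self.theta[:, self.param_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.hstack([self.theta, self.stats]),
            columns=list(self.param_names) + list(self.stat_names),
        )

    def save(self, path) -> None:
        """TSV of theta columns then statistics, plus a provenance sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        sidecar = dict(self.provenance)
        sidecar["scale"] = [float(s) for s in self.scale]
        sidecar["param_names"] = list(self.param_names)
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "ReferenceTable":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        names = tuple(sidecar["param_names"])
        return cls(
            theta=df[list(names)].to_numpy(),
            stats=df[list(STAT_NAMES)].to_numpy(),
            param_names=names,
            scale=np.asarray(sidecar["scale"], dtype=float),
            provenance={k: v for k, v in sidecar.items() if k not in ("scale", "param_names")},
        )


@dataclass
class WeightVector:
    """Normalized statistic weights for one target parameter."""

    w: np.ndarray
    scheme: str
    param: str | None = None
    r_squared: np.ndarray | None = None
    eta: float | None = None

    def __post_init__(self) -> None:
        if np.any(self.w < 0):
            raise ParameterError("weights must be non-negative")


@dataclass
class PosteriorSample:
    """Accepted parameter draws from rejection ABC."""

    draws: np.ndarray  # (n_accepted, L)
    param_names: tuple
    epsilon: float
    accept_fraction: float
    prior: PriorSpec | None = None

    def column(self, name: str) -> np.ndarray:
        return self.draws[:, self.param_names.index(name)]


def sample_prior(priors: PriorSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """n independent draws from the prior; columns follow ``priors.names``."""
    if n < 1:
        raise ParameterError("n must be at least 1")
    cols = [rng.uniform(lo, hi, size=n) for lo, hi in priors.bounds.values()]
    return np.column_stack(cols)


def statistic_scale(stats: np.ndarray) -> np.ndarray:
    """Per-statistic standardization scale: median absolute deviation, with a
    standard-deviation fallback when the MAD is 0 and a unit fallback when
    both vanish (constant statistic)."""
    mad = sp_stats.median_abs_deviation(stats, axis=0)
    sd = np.std(stats, axis=0)
    scale = np.where(mad > 0, mad, np.where(sd > 0, sd, 1.0))
    return scale.astype(float)


def simulate_summaries(
    theta_row: np.ndarray,
    priors: PriorSpec,
    sim_config: SimConfig,
    seed,
) -> np.ndarray:
    """Simulate one tumor at the given parameter values and summarize it."""
    values = dict(zip(priors.names, theta_row))
    params = _dc_replace(sim_config.base_params, **values)
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    ss_tumor, ss_seq = ss.spawn(2)
    sample = simulate_tumor(
        params, sim_config.glands_per_half, ss_tumor, fission_mode=sim_config.fission_mode
    )
    observed = sequence_sample(sample, sim_config.seq_model, np.random.default_rng(ss_seq))
    return summarize(observed)


def build_reference_table(
    priors: PriorSpec,
    sim_config: SimConfig,
    n: int,
    seed,
    *,
    max_retries: int = 100,
    progress: bool = False,
) -> ReferenceTable:
    """Draw n parameter vectors from the prior and simulate their summaries.

    A row whose simulation fails is resimulated with a fresh substream (the
    retry count lands in the provenance).
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    ss_prior, ss_sims = ss.spawn(2)
    theta = sample_prior(priors, n, np.random.default_rng(ss_prior))
    stats_rows = np.empty((n, N_STATS))
    retries = 0
    iterator = range(n)
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="reference table")
    for i in iterator:
        row_ss = ss_sims.spawn(1)[0]
        while True:
            try:
                stats_rows[i] = simulate_summaries(theta[i], priors, sim_config, row_ss)
                break
            except RuntimeError:
                retries += 1
                if retries > max_retries:
                    raise
                row_ss = ss_sims.spawn(1)[0]
    return ReferenceTable(
        theta=theta,
        stats=stats_rows,
        param_names=priors.names,
        provenance={
            "n": n,
            "retries": retries,
            "glands_per_half": sim_config.glands_per_half,
            "fission_mode": sim_config.fission_mode,
            "seq_mode": sim_config.seq_model.mode,
        },
    )


def weighted_distance(
    s_obs: np.ndarray, s_sim: np.ndarray, w: np.ndarray, scale: np.ndarray | None = None
) -> float | np.ndarray:
    """Weighted Euclidean distance between summary vectors.

    ``s_sim`` may be a matrix of reference rows; the result is then a vector.
    """
    s_obs = np.asarray(s_obs, dtype=float)
    s_sim = np.asarray(s_sim, dtype=float)
    w = np.asarray(w, dtype=float)
    if s_obs.shape[-1] != s_sim.shape[-1] or s_obs.shape[-1] != w.shape[-1]:
        raise ParameterError("summary vectors and weights must have equal length")
    if scale is None:
        scale = np.ones_like(w)
    scale = np.asarray(scale, dtype=float)
    if np.any(scale <= 0):
        raise ParameterError("scale entries must be positive")
    z = (s_sim - s_obs) / scale * w
    return np.sqrt(np.sum(z**2, axis=-1))


def equal_weights(m: int = N_STATS) -> WeightVector:
    """Baseline scheme: every statistic weighted 1/M."""
    if m < 1:
        raise ParameterError("need at least one statistic")
    return WeightVector(w=np.full(m, 1.0 / m), scheme="equal")


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    """R² of the simple linear regression of y on x (equals corr²); 0 when
    either variable is degenerate."""
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    if not np.isfinite(r):
        return 0.0
    return float(r**2)


#: R² values below this floor are indistinguishable from sampling noise on
#: the table sizes in play and are zeroed before normalization, so that a
#: parameter no statistic informs falls back to equal weights instead of
#: amplifying noise ratios.
R2_FLOOR = 0.01


def _normalize(r2: np.ndarray, scheme: str, param: str, eta: float | None = None) -> WeightVector:
    effective = np.where(r2 >= R2_FLOOR, r2, 0.0)
    total = effective.sum()
    # no statistic carries signal: fall back to equal weights rather than 0/0
    w = effective / total if total > 0 else np.full(len(r2), 1.0 / len(r2))
    return WeightVector(w=w, scheme=scheme, param=param, r_squared=r2, eta=eta)


def global_regression_weights(table: ReferenceTable, param: str) -> WeightVector:
    """Weights from the R² of θ_l on each statistic over the whole table."""
    if table.n < 3:
        raise ParameterError("global regression needs at least 3 rows")
    y = table.param_column(param)
    r2 = np.array([_r_squared(table.stats[:, m], y) for m in range(table.stats.shape[1])])
    return _normalize(r2, "global", param)


def local_regression_weights(
    table: ReferenceTable, param: str, s_obs: np.ndarray, eta: float = 0.1
) -> WeightVector:
    """Weights from per-statistic regressions restricted to the ceil(η·N)
    reference rows nearest the observed statistic value.

    Neighborhoods are one-dimensional (|s'_m − s_obs,m|), selected per
    statistic independently, ties broken by row index.
    """
    if not 0 < eta <= 1:
        raise ParameterError("eta must lie in (0, 1]")
    n_local = int(np.ceil(eta * table.n))
    if n_local < 3:
        raise ParameterError("local neighborhood smaller than 3 rows")
    y = table.param_column(param)
    s_obs = np.asarray(s_obs, dtype=float)
    r2 = np.empty(table.stats.shape[1])
    for m in range(table.stats.shape[1]):
        order = np.argsort(np.abs(table.stats[:, m] - s_obs[m]), kind="stable")[:n_local]
        r2[m] = _r_squared(table.stats[order, m], y[order])
    return _normalize(r2, "local", param, eta=eta)


def make_weights(
    table: ReferenceTable, param: str, scheme: str, s_obs: np.ndarray | None = None, eta: float = 0.1
) -> WeightVector:
    """Dispatch on the weighting scheme name."""
    if scheme == "equal":
        return equal_weights(table.stats.shape[1])
    if scheme == "global":
        return global_regression_weights(table, param)
    if scheme == "local":
        if s_obs is None:
            raise ParameterError("local weights need the observed summaries")
        return local_regression_weights(table, param, s_obs, eta)
    raise ParameterError(f"unknown weighting scheme {scheme!r}")


def abc_reject(
    table: ReferenceTable,
    s_obs: np.ndarray,
    weights: WeightVector,
    accept_fraction: float = 0.01,
    prior: PriorSpec | None = None,
) -> PosteriorSample:
    """Accept the ``accept_fraction`` of reference rows closest to ``s_obs``.

    Equivalent to choosing ε as the corresponding order statistic of the
    weighted distances.
    """
    if not 0 < accept_fraction <= 1:
        raise ParameterError("accept_fraction must lie in (0, 1]")
    n_accept = int(np.floor(accept_fraction * table.n))
    if n_accept < 1:
        raise ParameterError("acceptance set would be empty; increase accept_fraction")
    d = weighted_distance(s_obs, table.stats, weights.w, table.scale)
    order = np.argsort(d, kind="stable")[:n_accept]
    return PosteriorSample(
        draws=table.theta[order],
        param_names=table.param_names,
        epsilon=float(d[order[-1]]),
        accept_fraction=accept_fraction,
        prior=prior,
    )


def posterior_summary(
    posterior: PosteriorSample, param: str, grid_size: int = 512
) -> dict[str, float]:
    """Marginal posterior mean, sample standard deviation and mode.

    The mode is the argmax of a Gaussian kernel density estimate (Silverman
    bandwidth) on a ``grid_size``-point grid over the prior support (or the
    draw range when no prior is attached).  With fewer than two draws only
    the mean is reported; the mode needs at least five.
    """
    x = posterior.column(param)
    out: dict[str, float] = {"mean": float(np.mean(x))}
    if len(x) >= 2:
        out["sd"] = float(np.std(x, ddof=1))
    if len(x) >= 5:
        if out["sd"] == 0.0:
            out["mode"] = float(x[0])
        else:
            if posterior.prior is not None and param in posterior.prior.bounds:
                lo, hi = posterior.prior.support(param)
            else:
                lo, hi = float(x.min()), float(x.max())
            grid = np.linspace(lo, hi, grid_size)
            kde = sp_stats.gaussian_kde(x, bw_method="silverman")
            out["mode"] = float(grid[np.argmax(kde(grid))])
    return out
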