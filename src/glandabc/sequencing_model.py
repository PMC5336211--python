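"""Sequencing-noise model: depth, read sampling, detection and fixation calls.

True per-gland allele frequencies are converted into read-count observations
in two stages.  Sequencing depth at each locus is drawn from a negative
binomial — real capture data is overdispersed relative to the Poisson depth
of idealized models — parameterized by its mean ``m`` and variance ``v``
(``v > m``).  Given depth ``k``, the alternative-allele read count is
Binomial(``k``, ``q``) with ``q`` the true allele frequency.

Whether a mutation is "fixed" (carried by every cell, true diploid frequency
0.5) is then no longer observable directly, so it is decided by an exact
two-sided binomial test of H0: q = 0.5; the mutation is called fixed when the
test does NOT reject.  The same calling procedure is applied to simulated
reference-table data and to observed data, so the calling noise is part of
the generative model rather than a source of bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .growth_model import ParameterError, TumorSample

__all__ = [
    "SeqModel",
    "depth_params_from_moments",
    "nb_moments",
    "sample_depth",
    "sample_reads",
    "call_fixed",
    "binomial_fixed_pvalue",
    "apply_detection_threshold",
    "sequence_gland",
    "sequence_sample",
    "min_detectable_af",
]


@dataclass(frozen=True)
class SeqModel:
    """Observation model applied to true allele frequencies.

    Parameters
    ----------
    mode
        ``"perfect"`` passes exact frequencies through (fixed iff the
        frequency is exactly 0.5); ``"reads"`` simulates depths and read
        counts and calls fixation by the binomial test.
    mean_depth, depth_var
        Negative-binomial depth moments ``m`` and ``v`` (reads, reads²);
        requires ``v > m``.  Ignored in perfect mode.
    f_min
        Minimum detectable allele frequency; records below it are removed
        (applied to the observed frequency in reads mode, the true frequency
        in perfect mode).
    test_level
        Significance level of the fixation test.
    """

    mode: str = "perfect"
    mean_depth: float = 20.0
    depth_var: float | None = None
    f_min: float = 0.0
    test_level: float = 0.05

    def __post_init__(self) -> None:
        if self.mode not in ("perfect", "reads"):
            raise ParameterError("mode must be 'perfect' or 'reads'")
        if self.depth_var is None:
            object.__setattr__(self, "depth_var", 1.1 * self.mean_depth)
        if self.mode == "reads" and not self.depth_var > self.mean_depth > 0:
            raise ParameterError("negative-binomial depth requires v > m > 0")
        if not 0.0 <= self.f_min < 0.5:
            raise ParameterError("f_min must lie in [0, 0.5)")
        if not 0.0 < self.test_level < 1.0:
            raise ParameterError("test_level must lie in (0, 1)")


def depth_params_from_moments(m: float, v: float) -> tuple[float, float]:
    """Negative-binomial parameters ``(p, t)`` from mean ``m`` and variance ``v``.

    The depth pmf is ``f(k; t, p) = C(k+t-1, k) p^k (1-p)^t`` (number of
    successes before the ``t``-th failure with success probability ``p``),
    with mean ``pt/(1-p)`` and variance ``pt/(1-p)^2``.  Inverting gives
    ``p = 1 - m/v`` and ``t = m*v/(v-m) - m``.
    """
    if not v > m > 0:
        raise ParameterError("negative binomial requires v > m > 0 (overdispersion)")
    p = 1.0 - m / v
    t = m * v / (v - m) - m
    return p, t


def nb_moments(p: float, t: float) -> tuple[float, float]:
    """Mean and variance of the depth distribution — the inverse of
    :func:`depth_params_from_moments`."""
    return p * t / (1 - p), p * t / (1 - p) ** 2


def sample_depth(p: float, t: float, rng: np.random.Generator, size=None) -> np.ndarray | int:
    """Draw sequencing depth(s) from NB(p, t).

    numpy's ``negative_binomial(n, p_np)`` counts successes-before-the-n-th
    failure with *failure* probability ``p_np`` per trial, so ``p_np = 1 - p``.
    """
    return rng.negative_binomial(t, 1.0 - p, size=size)


def sample_reads(k, q, rng: np.random.Generator):
    """Alternative-allele read count ``n_a ~ Binomial(k, q)``; the remaining
    ``k - n_a`` reads carry the reference allele."""
    return rng.binomial(k, q)


def binomial_fixed_pvalue(n_a, k) -> np.ndarray:
    """Exact two-sided p-value of H0: q = 0.5 (vectorized).

    Uses the minimum-likelihood convention (sum of outcome probabilities no
    larger than the observed one); for the symmetric p = 0.5 null this equals
    twice the smaller tail, capped at 1.
    """
    n_a = np.asarray(n_a)
    k = np.asarray(k)
    lo = np.minimum(n_a, k - n_a)
    return np.minimum(1.0, 2.0 * stats.binom.cdf(lo, k, 0.5))


def call_fixed(n_a, k, test_level: float = 0.05):
    """Call a mutation (potentially) fixed iff the exact two-sided binomial
    test of H0: q = 0.5 does not reject at ``test_level``.

    Type II errors deliberately leak through: frequencies near 0.5 are called
    fixed, and the same anti-conservative call is used on simulated and
    observed data alike.
    """
    k_arr = np.asarray(k)
    if np.any(k_arr < 1):
        raise ParameterError("fixation call undefined at zero depth")
    return binomial_fixed_pvalue(n_a, k) >= test_level


def apply_detection_threshold(sample: TumorSample, f_min: float) -> TumorSample:
    """Drop every (gland, mutation) record with allele frequency below ``f_min``."""
    if not 0.0 <= f_min < 0.5:
        raise ParameterError("f_min must lie in [0, 0.5)")
    keep = sample.freq >= f_min
    return _subset_records(sample, keep)


def _subset_records(sample: TumorSample, keep: np.ndarray) -> TumorSample:
    return TumorSample(
        gland_ids=sample.gland_ids,
        halves=sample.halves,
        gland_index=sample.gland_index[keep],
        mutation_id=sample.mutation_id[keep],
        freq=sample.freq[keep],
        fixed=sample.fixed[keep],
        origin_phase=sample.origin_phase[keep],
        depth=None if sample.depth is None else sample.depth[keep],
        alt_reads=None if sample.alt_reads is None else sample.alt_reads[keep],
        constant_phase_restarts=sample.constant_phase_restarts,
    )


def sequence_gland(true_freqs: np.ndarray, model: SeqModel, rng: np.random.Generator):
    """Observe one gland's true allele frequencies under the noise model.

    Returns ``(keep_mask, obs_freq, fixed_call, depth, alt_reads)`` aligned
    with ``true_freqs``; ``depth``/``alt_reads`` are None in perfect mode.
    In reads mode, loci with zero alternative reads are undetected (a variant
    caller cannot emit them) and the detection threshold applies to the
    observed frequency ``n_a / k``.
    """
    true_freqs = np.asarray(true_freqs, dtype=float)
    if model.mode == "perfect":
        keep = true_freqs >= model.f_min
        return keep, true_freqs, true_freqs == 0.5, None, None
    p, t = depth_params_from_moments(model.mean_depth, model.depth_var)
    k = sample_depth(p, t, rng, size=true_freqs.shape)
    n_a = sample_reads(k, true_freqs, rng)
    detected = n_a > 0
    obs = np.divide(n_a, k, out=np.zeros_like(true_freqs), where=k > 0)
    keep = detected & (obs >= model.f_min)
    fixed = np.zeros_like(keep)
    if keep.any():
        fixed[keep] = call_fixed(n_a[keep], k[keep], model.test_level)
    return keep, obs, fixed, k, n_a


def sequence_sample(sample: TumorSample, model: SeqModel, rng: np.random.Generator | None = None) -> TumorSample:
    """Apply the observation model to every record of a simulated tumor sample.

    Depth is drawn independently per locus and per gland.  In perfect mode
    this reduces to the detection-threshold filter (and exact fixation flags);
    ``f_min = 0`` in perfect mode is the identity transform.
    """
    if model.mode == "perfect":
        out = _subset_records(sample, sample.freq >= model.f_min)
        return TumorSample(
            gland_ids=out.gland_ids,
            halves=out.halves,
            gland_index=out.gland_index,
            mutation_id=out.mutation_id,
            freq=out.freq,
            fixed=out.freq == 0.5,
            origin_phase=out.origin_phase,
            constant_phase_restarts=out.constant_phase_restarts,
        )
    if rng is None:
        raise ParameterError("reads mode requires a random generator")
    keep, obs, fixed, k, n_a = sequence_gland(sample.freq, model, rng)
    noisy = TumorSample(
        gland_ids=sample.gland_ids,
        halves=sample.halves,
        gland_index=sample.gland_index,
        mutation_id=sample.mutation_id,
        freq=obs,
        fixed=np.asarray(fixed, dtype=bool),
        origin_phase=sample.origin_phase,
        depth=np.asarray(k),
        alt_reads=np.asarray(n_a),
        constant_phase_restarts=sample.constant_phase_restarts,
    )
    return _subset_records(noisy, keep)


def min_detectable_af(depth: float) -> float:
    """Lowest allele frequency detectable at a given sequencing depth: a
    single supporting read out of ``depth`` (0.05 at depth 20)."""
    if depth <= 0:
        raise ParameterError("depth must be positive")
    return 1.0 / depth
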