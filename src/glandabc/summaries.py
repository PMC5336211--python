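"""Mutation classification and the nine ABC summary statistics.

A mutation detected in a multi-gland sample is classified on two axes:

* **fixed / non-fixed** — per gland, a mutation is fixed when present in
  every cell (exact frequency 0.5 in perfect data; a non-rejected binomial
  test in read data).  At the sample level a mutation is fixed when it is
  fixed in *every* gland where it is present: any segregating observation
  contradicts fixation.
* **gland-specific / shared** — detected in exactly one sampled gland versus
  more than one.

The summary vector S = (s1..s9) condenses the sample:

========  =======================================================
s1, s2    mean and variance of the allele frequencies of all
          non-fixed (gland, mutation) records
s3, s4    number of gland-specific mutations among non-fixed /
          fixed mutations (distinct mutations)
s5, s6    number of shared mutations among non-fixed / fixed
s7, s8    variance across glands of the per-gland counts of
          non-fixed / fixed mutations
s9        variance of the allele frequency of non-fixed records
          across the two tumor halves (variance of the two
          half-level means)
========  =======================================================

Degenerate categories use the conventions: an empty set has mean and
variance 0, a single value has variance 0; sample variances use denominator
``n - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .growth_model import TumorSample

__all__ = ["STAT_NAMES", "MutationClassification", "classify_mutations", "summarize"]

STAT_NAMES = ("s1", "s2", "s3", "s4", "s5", "s6", "s7", "s8", "s9")
N_STATS = len(STAT_NAMES)


class EmptySampleError(ValueError):
    pass


@dataclass
class MutationClassification:
    """Sample-level labels for each distinct detected mutation."""

    mutation_ids: np.ndarray  # distinct ids, sorted
    fixed_status: np.ndarray  # bool — fixed in every gland where present
    n_glands_present: np.ndarray  # int — size of the presence set
    record_index: np.ndarray  # maps each sample record to a row here

    @property
    def gland_specific(self) -> np.ndarray:
        return self.n_glands_present == 1


def classify_mutations(sample: TumorSample) -> MutationClassification:
    """Classify every distinct mutation in the sample.

    Presence means a surviving record after detection thresholding; the
    per-gland fixed flag comes from upstream (exact 0.5 or the test call).
    """
    if sample.n_glands < 1:
        raise EmptySampleError("sample has no glands")
    uids, inv = np.unique(sample.mutation_id, return_inverse=True)
    n_present = np.bincount(inv, minlength=len(uids))
    n_nonfixed_obs = np.bincount(inv, weights=~sample.fixed, minlength=len(uids))
    return MutationClassification(
        mutation_ids=uids,
        fixed_status=n_nonfixed_obs == 0,
        n_glands_present=n_present,
        record_index=inv,
    )


def _var(x: np.ndarray) -> float:
    """Sample variance (ddof=1); 0 for fewer than two values."""
    return float(np.var(x, ddof=1)) if len(x) >= 2 else 0.0


def summarize(sample: TumorSample, classification: MutationClassification | None = None) -> np.ndarray:
    """Compute the nine summary statistics of a sample (see module docstring).

    Returns a length-9 float array ordered as :data:`STAT_NAMES`.
    """
    if classification is None:
        classification = classify_mutations(sample)
    c = classification
    G = sample.n_glands

    rec_nonfixed = ~c.fixed_status[c.record_index]
    nf_freqs = sample.freq[rec_nonfixed]

    s1 = float(nf_freqs.mean()) if nf_freqs.size else 0.0
    s2 = _var(nf_freqs)

    specific = c.gland_specific
    s3 = int(np.sum(specific & ~c.fixed_status))
    s4 = int(np.sum(specific & c.fixed_status))
    s5 = int(np.sum(~specific & ~c.fixed_status))
    s6 = int(np.sum(~specific & c.fixed_status))

    per_gland_nf = np.bincount(sample.gland_index[rec_nonfixed], minlength=G)
    per_gland_fx = np.bincount(sample.gland_index[~rec_nonfixed], minlength=G)
    s7 = _var(per_gland_nf)
    s8 = _var(per_gland_fx)

    halves = np.asarray(sample.halves)
    half_means = []
    rec_halves = halves[sample.gland_index[rec_nonfixed]]
    for h in ("A", "B"):
        vals = nf_freqs[rec_halves == h]
        half_means.append(float(vals.mean()) if vals.size else 0.0)
    s9 = _var(np.asarray(half_means))

    return np.array([s1, s2, s3, s4, s5, s6, s7, s8, s9], dtype=float)
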