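"""Seeded reproductions of the method's simulation studies at desk scale.

Four designs probe how well rejection ABC recovers the generating
parameters (alpha, beta, r) from simulated single-gland data:

* ``weights``   — equal vs local-regression vs global-regression statistic
  weighting, perfect data.
* ``threshold`` — minimum detectable allele frequency 0.001 vs 0.05.
* ``glands``    — 1 vs 6 glands sampled per tumor half.
* ``depth``     — read-level data at mean depth 20 vs 80 (v = 1.1 m).

Test-tumor generating parameters are drawn from the priors.  All designs can
share one *tumor bank*: the same underlying simulated tumors observed under
each condition (reference and test banks are always disjoint).  This pairs
the conditions tumor-for-tumor, which removes most Monte-Carlo noise from
between-condition comparisons while leaving each condition's ABC analysis
valid on its own.

The module doubles as the synthetic fixture generator for the test suite
(:func:`make_fixtures`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .abc_inference import (
    PriorSpec,
    ReferenceTable,
    SimConfig,
    abc_reject,
    build_reference_table,
    equal_weights,
    global_regression_weights,
    local_regression_weights,
    sample_prior,
)
from .growth_model import GrowthParams, ParameterError, TumorSample, simulate_tumor
from .sequencing_model import SeqModel, sequence_sample
from .summaries import N_STATS, summarize

__all__ = [
    "Condition",
    "RecoveryConfig",
    "RecoveryResult",
    "run_recovery_study",
    "run_all_studies",
    "make_fixtures",
    "toy_sample",
]

DESIGNS = ("weights", "threshold", "glands", "depth")


@dataclass(frozen=True)
class Condition:
    """One observation condition applied to a simulated tumor."""

    name: str
    mode: str = "perfect"  # 'perfect' or 'reads'
    f_min: float = 0.001
    glands_per_half: int = 6
    mean_depth: float = 20.0
    depth_overdispersion: float = 1.1

    def seq_model(self) -> SeqModel:
        return SeqModel(
            mode=self.mode,
            mean_depth=self.mean_depth,
            depth_var=self.depth_overdispersion * self.mean_depth,
            f_min=self.f_min,
        )


@dataclass(frozen=True)
class RecoveryConfig:
    """Study configuration.

    The default problem sizes (40 test tumors, 2,000-row reference table) are
    chosen so all four designs run on one CPU core in a few minutes while the
    qualitative contrasts remain clear; ``full_scale`` restores the 300-tumor
    design.
    """

    n_test_tumors: int = 40
    n_reference: int = 2000
    glands_grid: tuple = (1, 6)
    f_min_grid: tuple = (0.001, 0.05)
    depth_grid: tuple = (20.0, 80.0)
    schemes: tuple = ("equal", "local", "global")
    accept_fraction: float = 0.02
    eta: float = 0.1
    glands_per_half: int = 6
    n_csc: int = 32
    t3: int = 100
    n_fission_gens: int = 19
    fission_mode: str = "bottleneck"
    depth_overdispersion: float = 1.1
    seed: int = 20170303
    priors: PriorSpec = field(default_factory=PriorSpec)

    @classmethod
    def full_scale(cls, **kw) -> "RecoveryConfig":
        return cls(n_test_tumors=300, n_reference=20000, **kw)

    def base_params(self) -> GrowthParams:
        return GrowthParams(
            alpha=0.0, beta=0.0, r=1.0,
            n_csc=self.n_csc, t3=self.t3, n_fission_gens=self.n_fission_gens,
        )

    def conditions_for(self, design: str) -> list[Condition]:
        g = self.glands_per_half
        if design == "weights":
            return [Condition("perfect", f_min=self.f_min_grid[0], glands_per_half=g)]
        if design == "threshold":
            return [
                Condition(f"fmin={f}", f_min=f, glands_per_half=g) for f in self.f_min_grid
            ]
        if design == "glands":
            return [
                Condition(f"glands={k}", f_min=self.f_min_grid[0], glands_per_half=k)
                for k in self.glands_grid
            ]
        if design == "depth":
            return [
                Condition(
                    f"depth={int(m)}", mode="reads", f_min=0.05, glands_per_half=g,
                    mean_depth=float(m), depth_overdispersion=self.depth_overdispersion,
                )
                for m in self.depth_grid
            ]
        raise ParameterError(f"unknown design {design!r}; choose from {DESIGNS}")


@dataclass
class RecoveryResult:
    """Per-tumor posterior summaries plus study-level aggregates."""

    design: str
    table: pd.DataFrame  # tumor, condition, scheme, param, truth, post_mean, post_sd
    config: RecoveryConfig
    failed_tumors: int = 0

    def aggregate(self) -> pd.DataFrame:
        """Per (condition, scheme, parameter): rank correlation of posterior
        mean with truth, mean |bias|, mean posterior sd, and the sd
        normalized by the prior sd (so parameters are comparable)."""
        rows = []
        for (cond, scheme, param), grp in self.table.groupby(
            ["condition", "scheme", "param"], sort=False
        ):
            lo, hi = self.config.priors.support(param)
            prior_sd = (hi - lo) / np.sqrt(12.0)
            rho = sp_stats.spearmanr(grp["truth"], grp["post_mean"]).statistic
            rows.append(
                {
                    "condition": cond,
                    "scheme": scheme,
                    "param": param,
                    "rank_corr": float(rho),
                    "mean_abs_bias": float(np.mean(np.abs(grp["post_mean"] - grp["truth"]))),
                    "mean_sd": float(grp["post_sd"].mean()),
                    "mean_norm_sd": float(grp["post_sd"].mean() / prior_sd),
                }
            )
        return pd.DataFrame(rows)


def _subset_glands(sample: TumorSample, glands_per_half: int, full_per_half: int) -> TumorSample:
    """Restrict a sample to the first ``glands_per_half`` glands of each half."""
    if glands_per_half == full_per_half:
        return sample
    keep_glands = np.concatenate(
        [np.arange(glands_per_half), full_per_half + np.arange(glands_per_half)]
    )
    remap = -np.ones(sample.n_glands, dtype=np.int64)
    remap[keep_glands] = np.arange(len(keep_glands))
    keep = remap[sample.gland_index] >= 0
    return TumorSample(
        gland_ids=sample.gland_ids[keep_glands],
        halves=sample.halves[keep_glands],
        gland_index=remap[sample.gland_index[keep]],
        mutation_id=sample.mutation_id[keep],
        freq=sample.freq[keep],
        fixed=sample.fixed[keep],
        origin_phase=sample.origin_phase[keep],
        constant_phase_restarts=sample.constant_phase_restarts,
    )


def _stat_bank(
    theta: np.ndarray,
    conditions: list[Condition],
    config: RecoveryConfig,
    seed_seq: np.random.SeedSequence,
    progress: bool = False,
) -> dict[str, np.ndarray]:
    """Simulate each parameter row once and summarize it under every condition."""
    base = config.base_params()
    names = config.priors.names
    out = {c.name: np.empty((len(theta), N_STATS)) for c in conditions}
    models = {c.name: c.seq_model() for c in conditions}
    iterator = range(len(theta))
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="tumor bank")
    for i in iterator:
        ss_tumor, ss_obs = seed_seq.spawn(1)[0].spawn(2)
        params = replace(base, **dict(zip(names, theta[i])))
        sample = simulate_tumor(
            params, config.glands_per_half, ss_tumor, fission_mode=config.fission_mode
        )
        obs_streams = ss_obs.spawn(len(conditions))
        for c, stream in zip(conditions, obs_streams):
            sub = _subset_glands(sample, c.glands_per_half, config.glands_per_half)
            observed = sequence_sample(sub, models[c.name], np.random.default_rng(stream))
            out[c.name][i] = summarize(observed)
    return out


def _analyze(
    ref_theta: np.ndarray,
    ref_bank: dict[str, np.ndarray],
    test_theta: np.ndarray,
    test_bank: dict[str, np.ndarray],
    conditions: list[Condition],
    schemes: tuple,
    config: RecoveryConfig,
) -> pd.DataFrame:
    priors = config.priors
    rows = []
    for cond in conditions:
        table = ReferenceTable(
            theta=ref_theta, stats=ref_bank[cond.name], param_names=priors.names
        )
        global_w = {p: global_regression_weights(table, p) for p in priors.names}
        eq_w = equal_weights(N_STATS)
        for i in range(len(test_theta)):
            s_obs = test_bank[cond.name][i]
            for scheme in schemes:
                for j, param in enumerate(priors.names):
                    if scheme == "equal":
                        w = eq_w
                    elif scheme == "global":
                        w = global_w[param]
                    else:
                        w = local_regression_weights(table, param, s_obs, config.eta)
                    post = abc_reject(table, s_obs, w, config.accept_fraction, prior=priors)
                    x = post.column(param)
                    rows.append(
                        {
                            "tumor": i,
                            "condition": cond.name,
                            "scheme": scheme,
                            "param": param,
                            "truth": test_theta[i, j],
                            "post_mean": float(np.mean(x)),
                            "post_sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
                        }
                    )
    return pd.DataFrame(rows)


def run_recovery_study(
    design: str, config: RecoveryConfig | None = None, progress: bool = False
) -> RecoveryResult:
    """Run one study design end to end (reference bank, test tumors, ABC)."""
    results = run_all_studies([design], config, progress=progress)
    return results[design]


def run_all_studies(
    designs=DESIGNS, config: RecoveryConfig | None = None, progress: bool = False
) -> dict[str, RecoveryResult]:
    """Run several designs off one shared tumor bank.

    The union of the observation conditions needed by the requested designs
    is applied to a single reference bank and a single, disjoint test bank.
    """
    config = config or RecoveryConfig()
    design_conditions = {d: config.conditions_for(d) for d in designs}
    union: dict[str, Condition] = {}
    for conds in design_conditions.values():
        for c in conds:
            union.setdefault(c.name, c)
    conditions = list(union.values())

    ss = np.random.SeedSequence(config.seed)
    ss_ref_theta, ss_ref_bank, ss_test_theta, ss_test_bank = ss.spawn(4)
    ref_theta = sample_prior(config.priors, config.n_reference, np.random.default_rng(ss_ref_theta))
    test_theta = sample_prior(
        config.priors, config.n_test_tumors, np.random.default_rng(ss_test_theta)
    )
    ref_bank = _stat_bank(ref_theta, conditions, config, ss_ref_bank, progress=progress)
    test_bank = _stat_bank(test_theta, conditions, config, ss_test_bank, progress=progress)

    out = {}
    for d in designs:
        schemes = config.schemes if d == "weights" else ("global",)
        table = _analyze(
            ref_theta, ref_bank, test_theta, test_bank, design_conditions[d], schemes, config
        )
        out[d] = RecoveryResult(design=d, table=table, config=config)
    return out


def plot_recovery(result: RecoveryResult, path) -> None:
    """Scatter of posterior mean vs generating value, one panel per
    (condition, parameter); diagnostics only, nothing is computed from it."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    params = list(dict.fromkeys(result.table["param"]))
    conds = list(dict.fromkeys(result.table["condition"]))
    fig, axes = plt.subplots(
        len(conds), len(params), figsize=(3.2 * len(params), 2.8 * len(conds)), squeeze=False
    )
    for i, cond in enumerate(conds):
        for j, param in enumerate(params):
            ax = axes[i][j]
            for scheme, grp in result.table.query(
                "condition == @cond and param == @param"
            ).groupby("scheme"):
                ax.scatter(grp["truth"], grp["post_mean"], s=8, label=scheme, alpha=0.6)
            lo, hi = result.config.priors.support(param)
            ax.plot([lo, hi], [lo, hi], "k--", lw=0.8)
            ax.set_title(f"{param} | {cond}", fontsize=8)
            if i == 0 and j == 0:
                ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Test fixtures


def toy_sample() -> TumorSample:
    """Two glands, one per half: gland A0 carries {A: 0.5, B: 0.25}, gland B0
    carries {A: 0.5, C: 0.125}.  Mutation A is shared fixed; B and C are
    gland-specific non-fixed."""
    return TumorSample(
        gland_ids=np.array(["A0", "B0"], dtype=object),
        halves=np.array(["A", "B"], dtype=object),
        gland_index=np.array([0, 0, 1, 1]),
        mutation_id=np.array([0, 1, 0, 2]),
        freq=np.array([0.5, 0.25, 0.5, 0.125]),
        fixed=np.array([True, False, True, False]),
        origin_phase=np.array(["na"] * 4, dtype=object),
    )


_MUTECT_COLUMNS = (
    "contig", "position", "ref_allele", "alt_allele",
    "t_ref_count", "t_alt_count", "judgement",
)


def _fixture_mutect_pair(rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Synthetic two-gland MuTect-style call-stats pair plus CN segments.

    Entirely synthetic stand-ins (no real tumor data): a handful of shared
    clonal variants, some private subclonal ones, and one REJECT row per
    file, on two contigs with copy numbers 2 and 3.
    """
    def rows(private_pos, shared_keep=True):
        data = []
        # shared clonal diploid variants on chr1 (CN 2)
        for pos, q in ((10_000, 0.5), (20_000, 0.5), (30_000, 0.25)):
            depth = 100
            alt = int(round(q * depth))
            data.append(("1", pos, "A", "T", depth - alt, alt, "KEEP"))
        # one clonal variant on the CN-3 segment of chr2: one mutated copy
        data.append(("2", 5_000, "G", "C", 67, 33, "KEEP"))
        # private subclonal variants
        for pos in private_pos:
            depth = int(rng.integers(60, 140))
            alt = int(rng.integers(5, depth // 4))
            data.append(("1", pos, "C", "G", depth - alt, alt, "KEEP"))
        # a rejected call that must be filtered out
        data.append(("1", 99_000, "T", "A", 50, 10, "REJECT"))
        return pd.DataFrame(data, columns=list(_MUTECT_COLUMNS))

    ua = rows((41_000, 42_000))
    ub = rows((55_000, 56_000, 57_000))
    cn = pd.DataFrame(
        {
            "contig": ["1", "2"],
            "start": [1, 1],
            "end": [1_000_000, 1_000_000],
            "copy_number": [2, 3],
        }
    )
    return ua, ub, cn


def make_fixtures(seed: int, outdir) -> dict[str, Path]:
    """Write the small deterministic fixtures used by the test suite.

    Produces a toy two-gland sample TSV, a 200-row reference table built on a
    reduced growth model, and a synthetic MuTect-format file pair with a CN
    segment table.  Byte-stable for a given seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    toy = toy_sample()
    paths["toy_sample"] = outdir / "toy_sample.tsv"
    toy.to_frame().to_csv(paths["toy_sample"], sep="\t", index=False)

    small = SimConfig(
        base_params=GrowthParams(alpha=0.0, beta=0.0, r=1.0, n_csc=8, t3=5, n_fission_gens=4),
        glands_per_half=2,
        seq_model=SeqModel(mode="perfect", f_min=0.0),
    )
    table = build_reference_table(PriorSpec(), small, 200, np.random.SeedSequence(seed))
    paths["reference_table"] = outdir / "reference_table.tsv"
    table.save(paths["reference_table"])

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    ua, ub, cn = _fixture_mutect_pair(rng)
    paths["mutect_half_a"] = outdir / "synthetic_gland_UA.call_stats.txt"
    paths["mutect_half_b"] = outdir / "synthetic_gland_UB.call_stats.txt"
    paths["cn_segments"] = outdir / "synthetic_cn_segments.tsv"
    for df, key in ((ua, "mutect_half_a"), (ub, "mutect_half_b")):
        with open(paths[key], "w") as fh:
            fh.write("## muTector v1.1.4 -- synthetic fixture, not real data\n")
            df.to_csv(fh, sep="\t", index=False)
    cn.to_csv(paths["cn_segments"], sep="\t", index=False)
    return paths
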