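"""Agent-based model of colorectal tumor growth at gland resolution.

The model tracks cancer stem cells (CSCs) through three phases:

1. *First-gland formation* — the founding transformed cell divides repeatedly
   (a balanced binary expansion) until the gland holds ``n_csc`` CSCs.  Every
   daughter cell created on the way acquires a Poisson(``alpha``) number of
   new point mutations (exome scale).
2. *Gland fission* — glands double in number each generation for
   ``n_fission_gens`` generations (19 generations yields 2**19 = 524,288
   glands, a ~4 cm^3 tumor at ~10,000 cells per gland).  Mutations arising
   after the first gland forms occur at rate ``beta``.
3. *Constant size* — fission stops and each gland is maintained by CSC
   division for ``t3`` generations: with probability ``r`` a CSC divides
   asymmetrically (one CSC daughter), otherwise symmetrically into two CSCs
   or two non-CSCs with equal probability.

Mutations follow the infinite-sites convention: every mutation event gets a
fresh integer id and is never created twice.  Differentiated (non-CSC) cells
are short-lived and are not tracked; allele frequencies are computed over the
CSC pool, so a mutation carried by every CSC of a gland has diploid allele
frequency exactly 0.5 ("fixed").

Only the lineages ancestral to the sampled glands are simulated.  Glands
evolve independently after fission, so pruning unsampled branches leaves the
joint distribution of the sampled glands unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthParams",
    "GlandState",
    "TumorSample",
    "MutationRegistry",
    "PHASES",
    "form_first_gland",
    "fission",
    "constant_phase_step",
    "simulate_tumor",
    "gland_allele_frequencies",
    "gland_count",
    "tumor_cell_count",
    "mutations_per_division",
    "daughter_cells_created",
]

#: mutation origin phases, indexed by the int8 code stored per mutation
PHASES = ("pre_gland", "fission", "constant")
_PHASE_CODE = {name: i for i, name in enumerate(PHASES)}


class ParameterError(ValueError):
    """Raised when a parameter is outside its domain."""


class StateError(RuntimeError):
    """Raised when an operation is applied to an invalid state (e.g. a dead gland)."""


@dataclass(frozen=True)
class GrowthParams:
    """Generative parameters of the tumor growth model.

    Parameters
    ----------
    alpha
        Expected new point mutations per daughter cell per division *before*
        first-gland formation (exome scale).
    beta
        Same, *after* first-gland formation.
    r
        Probability that a CSC division is asymmetric.  Symmetric divisions
        (probability ``1 - r``) produce two CSCs or two non-CSCs with equal
        probability, which keeps the expected CSC count constant.
    n_csc
        CSCs per gland.
    t3
        Length of the constant-size phase, in generations.
    n_fission_gens
        Length of the exponential gland-fission phase, in generations.
    gland_cells
        Nominal total cells per gland (reporting metadata only; allele
        frequencies are computed over the CSC pool).
    """

    alpha: float
    beta: float
    r: float
    n_csc: int = 32
    t3: int = 100
    n_fission_gens: int = 19
    gland_cells: int = 10_000

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ParameterError("mutation rates must be non-negative")
        if not 0.0 <= self.r <= 1.0:
            raise ParameterError("asymmetric-division probability r must lie in [0, 1]")
        if self.n_csc < 1:
            raise ParameterError("n_csc must be at least 1")
        if self.t3 < 0 or self.n_fission_gens < 0:
            raise ParameterError("phase lengths must be non-negative")


class MutationRegistry:
    """Allocates unique mutation ids and remembers each id's origin phase."""

    def __init__(self, start: int = 0) -> None:
        self._next = int(start)
        self._starts: list[int] = []
        self._codes: list[int] = []

    @property
    def n_allocated(self) -> int:
        return self._next

    def allocate(self, n: int, phase: str) -> np.ndarray:
        """Return ``n`` fresh ids tagged with ``phase``."""
        code = _PHASE_CODE[phase]
        ids = np.arange(self._next, self._next + n, dtype=np.int64)
        if n > 0:
            if not self._codes or self._codes[-1] != code:
                self._starts.append(self._next)
                self._codes.append(code)
            self._next += n
        return ids

    def phase_of(self, ids: np.ndarray) -> np.ndarray:
        """Origin phase (as strings from :data:`PHASES`) for each id."""
        ids = np.asarray(ids, dtype=np.int64)
        if not self._starts:
            if ids.size:
                raise KeyError("registry has no allocated ids")
            return np.empty(0, dtype=object)
        starts = np.asarray(self._starts)
        idx = np.searchsorted(starts, ids, side="right") - 1
        if ids.size and (idx.min() < 0 or ids.max() >= self._next):
            raise KeyError("id not allocated by this registry")
        codes = np.asarray(self._codes)[idx]
        return np.asarray(PHASES, dtype=object)[codes]


@dataclass
class GlandState:
    """CSC composition of one gland.

    Mutations carried by every CSC live in ``fixed``; the rest are rows of the
    boolean ``carriers`` matrix (one row per segregating mutation, one column
    per CSC).
    """

    fixed: np.ndarray  # int64 mutation ids carried by every CSC
    seg_ids: np.ndarray  # int64 ids of segregating mutations (rows of carriers)
    carriers: np.ndarray  # bool, shape (len(seg_ids), pool_size)
    gland_id: str = "g"
    half: str = "unassigned"

    @property
    def pool_size(self) -> int:
        return self.carriers.shape[1]

    @property
    def alive(self) -> bool:
        return self.pool_size > 0

    @property
    def max_id(self) -> int:
        m = -1
        if self.fixed.size:
            m = max(m, int(self.fixed.max()))
        if self.seg_ids.size:
            m = max(m, int(self.seg_ids.max()))
        return m

    def genotypes(self) -> list[frozenset[int]]:
        """Per-CSC genotypes as sets of mutation ids (small pools only)."""
        base = frozenset(int(i) for i in self.fixed)
        out = []
        for col in range(self.pool_size):
            extra = frozenset(int(i) for i in self.seg_ids[self.carriers[:, col]])
            out.append(base | extra)
        return out


def _empty_gland(gland_id: str = "g", half: str = "unassigned", pool: int = 1) -> GlandState:
    return GlandState(
        fixed=np.empty(0, dtype=np.int64),
        seg_ids=np.empty(0, dtype=np.int64),
        carriers=np.zeros((0, pool), dtype=bool),
        gland_id=gland_id,
        half=half,
    )


def _compact(gland: GlandState) -> GlandState:
    """Promote newly fixed mutations, drop lost ones."""
    if gland.seg_ids.size == 0:
        return gland
    counts = gland.carriers.sum(axis=1)
    pool = gland.pool_size
    fixed_mask = counts == pool
    keep = (counts > 0) & ~fixed_mask
    fixed = gland.fixed
    if fixed_mask.any():
        fixed = np.concatenate([fixed, gland.seg_ids[fixed_mask]])
    return replace(gland, fixed=fixed, seg_ids=gland.seg_ids[keep], carriers=gland.carriers[keep])


def daughter_cells_created(n_target: int, n_start: int = 1) -> int:
    """Daughter cells created by the balanced binary expansion from
    ``n_start`` to ``n_target`` cells (each division replaces one cell with
    two daughters; the last round divides only as many cells as needed,
    left to right)."""
    c, total = n_start, 0
    while c < n_target:
        d = min(c, n_target - c)
        total += 2 * d
        c += d
    return total


def _expand_population(
    carriers: np.ndarray,
    seg_ids: np.ndarray,
    n_target: int,
    rate: float,
    phase: str,
    registry: MutationRegistry,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Grow a cell population to ``n_target`` via balanced synchronous rounds.

    Each daughter cell acquires an independent Poisson(``rate``) number of new
    mutations (drawn as one pooled Poisson total assigned uniformly across the
    daughters, which is distributionally identical).
    """
    while carriers.shape[1] < n_target:
        c = carriers.shape[1]
        d = min(c, n_target - c)
        dividing = np.repeat(carriers[:, :d], 2, axis=1)
        carriers = np.concatenate([dividing, carriers[:, d:]], axis=1)
        n_new = rng.poisson(rate * 2 * d)
        if n_new:
            ids = registry.allocate(n_new, phase)
            rows = np.zeros((n_new, carriers.shape[1]), dtype=bool)
            rows[np.arange(n_new), rng.integers(0, 2 * d, size=n_new)] = True
            carriers = np.concatenate([carriers, rows], axis=0)
            seg_ids = np.concatenate([seg_ids, ids])
    return carriers, seg_ids


def form_first_gland(
    params: GrowthParams,
    rng: np.random.Generator,
    registry: MutationRegistry | None = None,
) -> GlandState:
    """Expand the first transformed cell into the first gland.

    The founder divides repeatedly (balanced binary schedule) until the pool
    holds ``params.n_csc`` CSCs; each daughter created en route gains
    Poisson(``alpha``) new mutations tagged ``pre_gland``.
    """
    if registry is None:
        registry = MutationRegistry()
    gland = _empty_gland(gland_id="g0")
    carriers, seg_ids = _expand_population(
        gland.carriers, gland.seg_ids, params.n_csc, params.alpha, "pre_gland", registry, rng
    )
    return _compact(replace(gland, carriers=carriers, seg_ids=seg_ids))


def _founder_gland(
    parent: GlandState, founder_col: int, params: GrowthParams,
    registry: MutationRegistry, rng: np.random.Generator, gland_id: str,
) -> GlandState:
    """Regrow a daughter gland from a single founder CSC (bottleneck mode)."""
    founder_fixed = np.concatenate([parent.fixed, parent.seg_ids[parent.carriers[:, founder_col]]])
    child = GlandState(
        fixed=founder_fixed,
        seg_ids=np.empty(0, dtype=np.int64),
        carriers=np.zeros((0, 1), dtype=bool),
        gland_id=gland_id,
        half=parent.half,
    )
    carriers, seg_ids = _expand_population(
        child.carriers, child.seg_ids, params.n_csc, params.beta, "fission", registry, rng
    )
    return _compact(replace(child, carriers=carriers, seg_ids=seg_ids))


def _fission_children(
    parent: GlandState,
    params: GrowthParams,
    rng: np.random.Generator,
    registry: MutationRegistry,
    mode: str,
    need: tuple[bool, bool],
    ids: tuple[str, str],
) -> tuple[GlandState | None, GlandState | None]:
    """Fission, simulating only the requested daughters (pruning).

    In bottleneck mode the two daughter founders are drawn uniformly without
    replacement from the parent pool, so when only one daughter is needed its
    founder is marginally a single uniform draw.
    """
    if not parent.alive:
        raise StateError("cannot fission a dead gland")
    pool = parent.pool_size
    if mode == "bottleneck":
        if need[0] and need[1]:
            # pool of one: the lone CSC founds both daughters
            f = rng.permutation(pool)[:2] if pool >= 2 else np.array([0, 0])
            return (
                _founder_gland(parent, int(f[0]), params, registry, rng, ids[0]),
                _founder_gland(parent, int(f[1]), params, registry, rng, ids[1]),
            )
        col = int(rng.integers(pool))
        child = None
        for side in (0, 1):
            if need[side]:
                child = _founder_gland(parent, col, params, registry, rng, ids[side])
        return (child, None) if need[0] else (None, child)
    if mode == "split":
        carriers, seg_ids = _expand_population(
            parent.carriers, parent.seg_ids, 2 * pool, params.beta, "fission", registry, rng
        )
        perm = rng.permutation(2 * pool)
        halves = (perm[:pool], perm[pool:])
        out: list[GlandState | None] = [None, None]
        for side in (0, 1):
            if need[side]:
                out[side] = _compact(
                    GlandState(
                        fixed=parent.fixed.copy(),
                        seg_ids=seg_ids.copy(),
                        carriers=carriers[:, halves[side]],
                        gland_id=ids[side],
                        half=parent.half,
                    )
                )
        return out[0], out[1]
    raise ParameterError(f"unknown fission mode {mode!r}")


def fission(
    gland: GlandState,
    params: GrowthParams,
    rng: np.random.Generator,
    *,
    mode: str = "bottleneck",
    registry: MutationRegistry | None = None,
) -> tuple[GlandState, GlandState]:
    """Split one gland into two daughter glands.

    ``bottleneck`` (default): each daughter is founded by one CSC drawn
    uniformly without replacement from the parent pool and regrown to
    ``n_csc`` by symmetric divisions (Poisson(``beta``) mutations per daughter
    cell).  Founder mutations are therefore fixed in the daughter gland.

    ``split``: every parent CSC divides once and the ``2 * n_csc`` daughters
    are partitioned uniformly at random into two glands.
    """
    if registry is None:
        registry = MutationRegistry(start=gland.max_id + 1)
    a, b = _fission_children(
        gland, params, rng, registry, mode, (True, True),
        (gland.gland_id + ".0", gland.gland_id + ".1"),
    )
    assert a is not None and b is not None
    return a, b


def constant_phase_step(
    gland: GlandState,
    params: GrowthParams,
    rng: np.random.Generator,
    *,
    registry: MutationRegistry | None = None,
    normalize: bool = False,
) -> GlandState:
    """One synchronous generation of the constant-size phase.

    Each CSC leaves 1 CSC daughter with probability ``r`` (asymmetric
    division), 2 with probability ``(1 - r) / 2`` and 0 otherwise.  Every
    retained CSC daughter gains Poisson(``beta``) new mutations; mutations in
    differentiating daughters are discarded since those lineages die out.
    Extinction (empty pool) is reported via the returned state's ``alive``
    flag, not an exception.

    With ``normalize=True`` the pool is resampled back to ``n_csc`` CSCs each
    generation (Wright-Fisher-like strictly constant pool).
    """
    if not gland.alive:
        raise StateError("constant-phase step on a dead gland")
    if registry is None:
        registry = MutationRegistry(start=gland.max_id + 1)
    pool = gland.pool_size
    u = rng.random(pool)
    offspring = np.where(u < params.r, 1, np.where(u < params.r + (1 - params.r) / 2, 2, 0))
    new_pool = int(offspring.sum())
    if new_pool == 0:
        return replace(gland, carriers=gland.carriers[:, :0])
    cols = np.repeat(np.arange(pool), offspring)
    carriers = gland.carriers[:, cols]
    seg_ids = gland.seg_ids
    n_new = rng.poisson(params.beta * new_pool)
    if n_new:
        ids = registry.allocate(n_new, "constant")
        rows = np.zeros((n_new, new_pool), dtype=bool)
        rows[np.arange(n_new), rng.integers(0, new_pool, size=n_new)] = True
        carriers = np.concatenate([carriers, rows], axis=0)
        seg_ids = np.concatenate([seg_ids, ids])
    if normalize and new_pool != params.n_csc:
        sel = rng.choice(new_pool, size=params.n_csc, replace=new_pool < params.n_csc)
        carriers = carriers[:, sel]
    return _compact(replace(gland, seg_ids=seg_ids, carriers=carriers))


def gland_allele_frequencies(gland: GlandState) -> dict[int, float]:
    """Diploid allele frequency of every mutation present in the gland.

    Frequency is ``carriers / pool_size / 2``; mutations carried by all CSCs
    map to exactly 0.5.
    """
    if not gland.alive:
        raise StateError("allele frequencies of a dead gland are undefined")
    out = {int(i): 0.5 for i in gland.fixed}
    if gland.seg_ids.size:
        counts = gland.carriers.sum(axis=1)
        for i, c in zip(gland.seg_ids, counts):
            out[int(i)] = float(c) / gland.pool_size / 2.0
    return out


@dataclass
class TumorSample:
    """Per-gland mutation observations for a set of sampled glands.

    The flat record arrays hold one entry per (gland, detected mutation) pair;
    ``gland_index`` indexes into the per-gland metadata arrays.
    """

    gland_ids: np.ndarray  # (G,) str
    halves: np.ndarray  # (G,) 'A' / 'B' / 'unassigned'
    gland_index: np.ndarray  # (R,) int
    mutation_id: np.ndarray  # (R,) int64
    freq: np.ndarray  # (R,) float — true (perfect mode) or observed AF
    fixed: np.ndarray  # (R,) bool — per-gland fixed flag
    origin_phase: np.ndarray  # (R,) object — phase name or 'na'
    depth: np.ndarray | None = None  # (R,) reads-mode total depth
    alt_reads: np.ndarray | None = None  # (R,) reads-mode alt-allele reads
    constant_phase_restarts: int = 0

    @property
    def n_glands(self) -> int:
        return len(self.gland_ids)

    @property
    def n_records(self) -> int:
        return len(self.mutation_id)

    def mutations_per_gland(self) -> np.ndarray:
        """K_g: number of detected mutations in each sampled gland."""
        return np.bincount(self.gland_index, minlength=self.n_glands)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "gland_id": self.gland_ids[self.gland_index],
                "half": self.halves[self.gland_index],
                "mutation_id": self.mutation_id,
                "origin_phase": self.origin_phase,
                "allele_freq": self.freq,
                "fixed_call": self.fixed,
            }
        )
        if self.depth is not None:
            df["depth"] = self.depth
            df["alt_reads"] = self.alt_reads
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, gland_order: Sequence[str] | None = None) -> "TumorSample":
        """Rebuild a sample from :meth:`to_frame` output (or the CLI TSV).

        A missing ``fixed_call`` column is filled with the perfect-data
        convention ``allele_freq == 0.5``.
        """
        if gland_order is None:
            gland_order = list(dict.fromkeys(df["gland_id"]))
        gland_ids = np.asarray(gland_order, dtype=object)
        index = {g: i for i, g in enumerate(gland_order)}
        gidx = df["gland_id"].map(index).to_numpy()
        halves = np.full(len(gland_ids), "unassigned", dtype=object)
        for g, h in zip(df["gland_id"], df["half"]):
            halves[index[g]] = h
        fixed = (
            df["fixed_call"].to_numpy(dtype=bool)
            if "fixed_call" in df
            else (df["allele_freq"].to_numpy() == 0.5)
        )
        phase = (
            df["origin_phase"].to_numpy(dtype=object)
            if "origin_phase" in df
            else np.full(len(df), "na", dtype=object)
        )
        return cls(
            gland_ids=gland_ids,
            halves=halves,
            gland_index=np.asarray(gidx, dtype=np.int64),
            mutation_id=df["mutation_id"].to_numpy(dtype=np.int64),
            freq=df["allele_freq"].to_numpy(dtype=float),
            fixed=fixed,
            origin_phase=phase,
            depth=df["depth"].to_numpy(dtype=np.int64) if "depth" in df else None,
            alt_reads=df["alt_reads"].to_numpy(dtype=np.int64) if "alt_reads" in df else None,
        )


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if isinstance(seed, np.random.Generator):
        # Derive a seed sequence from the generator; order-dependent but valid.
        return np.random.SeedSequence(int(seed.integers(0, 2**63)))
    return np.random.SeedSequence(int(seed))


def _sample_from_glands(
    glands: list[GlandState], registry: MutationRegistry, restarts: int
) -> TumorSample:
    gland_ids = np.asarray([g.gland_id for g in glands], dtype=object)
    halves = np.asarray([g.half for g in glands], dtype=object)
    gidx, mids, freqs, fixed = [], [], [], []
    for i, g in enumerate(glands):
        n_fix = g.fixed.size
        gidx.append(np.full(n_fix, i, dtype=np.int64))
        mids.append(g.fixed)
        freqs.append(np.full(n_fix, 0.5))
        fixed.append(np.ones(n_fix, dtype=bool))
        if g.seg_ids.size:
            counts = g.carriers.sum(axis=1)
            present = counts > 0  # _compact guarantees this, but stay safe
            gidx.append(np.full(int(present.sum()), i, dtype=np.int64))
            mids.append(g.seg_ids[present])
            freqs.append(counts[present] / g.pool_size / 2.0)
            fixed.append(np.zeros(int(present.sum()), dtype=bool))
    mutation_id = np.concatenate(mids) if mids else np.empty(0, dtype=np.int64)
    return TumorSample(
        gland_ids=gland_ids,
        halves=halves,
        gland_index=np.concatenate(gidx) if gidx else np.empty(0, dtype=np.int64),
        mutation_id=mutation_id,
        freq=np.concatenate(freqs) if freqs else np.empty(0, dtype=float),
        fixed=np.concatenate(fixed) if fixed else np.empty(0, dtype=bool),
        origin_phase=registry.phase_of(mutation_id),
        constant_phase_restarts=restarts,
    )


def simulate_tumor(
    params: GrowthParams,
    glands_per_half: int,
    seed,
    *,
    fission_mode: str = "bottleneck",
    normalize_constant: bool = False,
    max_restarts_per_gland: int = 1000,
) -> TumorSample:
    """Simulate a tumor and return exact diploid allele frequencies for
    ``glands_per_half`` glands sampled uniformly from each tumor half.

    The first fission of the first gland defines halves A and B; descendants
    inherit the label.  Only lineages ancestral to the sampled glands are
    simulated.  A sampled gland whose CSC pool goes extinct during the
    constant phase has that phase resimulated from its start (conditioning on
    survival); the number of restarts is recorded on the returned sample.

    ``seed`` may be an int, a :class:`numpy.random.SeedSequence`, or a
    :class:`numpy.random.Generator`.
    """
    if glands_per_half < 1:
        raise ParameterError("glands_per_half must be at least 1")
    g = params.n_fission_gens
    if 2**g < 2 * glands_per_half:
        raise ParameterError(
            f"cannot sample {glands_per_half} glands per half from 2**{g} glands"
        )
    ss = _as_seedseq(seed)
    ss_first, ss_leaves, ss_fission, ss_constant = ss.spawn(4)
    registry = MutationRegistry()

    first = form_first_gland(params, np.random.default_rng(ss_first), registry)
    first.gland_id = "0"

    half_leaves = 2 ** (g - 1)
    rng_leaves = np.random.default_rng(ss_leaves)
    leaves_a = np.sort(rng_leaves.choice(half_leaves, size=glands_per_half, replace=False))
    leaves_b = np.sort(rng_leaves.choice(half_leaves, size=glands_per_half, replace=False)) + half_leaves
    leaves = np.concatenate([leaves_a, leaves_b])

    current: dict[int, GlandState] = {0: first}
    for t in range(1, g + 1):
        needed = sorted({int(leaf) >> (g - t) for leaf in leaves})
        parents = sorted({n >> 1 for n in needed})
        streams = ss_fission.spawn(len(parents))
        nxt: dict[int, GlandState] = {}
        for p, stream in zip(parents, streams):
            rng = np.random.default_rng(stream)
            parent = current[p]
            if t == 1:  # the very first fission seeds the half labels
                ids = ("A0", "B0")
            else:
                ids = (parent.gland_id + ".0", parent.gland_id + ".1")
            need = (2 * p in needed, 2 * p + 1 in needed)
            c0, c1 = _fission_children(parent, params, rng, registry, fission_mode, need, ids)
            if t == 1:
                if c0 is not None:
                    c0.half = "A"
                if c1 is not None:
                    c1.half = "B"
            if c0 is not None:
                nxt[2 * p] = c0
            if c1 is not None:
                nxt[2 * p + 1] = c1
        current = nxt

    restarts = 0
    gland_streams = ss_constant.spawn(len(leaves))
    finals: list[GlandState] = []
    for slot, leaf in enumerate(leaves):
        start = current[int(leaf)]
        start.gland_id = f"{start.half}{slot % glands_per_half}"
        base = gland_streams[slot]
        while True:
            rng = np.random.default_rng(base.spawn(1)[0])
            state, ok = start, True
            for _ in range(params.t3):
                state = constant_phase_step(
                    state, params, rng, registry=registry, normalize=normalize_constant
                )
                if not state.alive:
                    ok = False
                    break
            if ok:
                finals.append(state)
                break
            restarts += 1
            if restarts > max_restarts_per_gland * len(leaves):
                raise RuntimeError("constant phase restarted too many times")
    return _sample_from_glands(finals, registry, restarts)


def gland_count(n_fission_gens: int) -> int:
    """Number of glands after ``n_fission_gens`` doubling generations."""
    return 2**n_fission_gens


def tumor_cell_count(n_fission_gens: int, gland_cells: int = 10_000) -> int:
    """Total tumor cells at the end of the exponential phase."""
    return gland_count(n_fission_gens) * gland_cells


def mutations_per_division(rate_per_base: float, n_bases: float = 3e9) -> float:
    """Expected new mutations per cell division given a per-base rate and a
    target size (whole genome ~3e9 bases; exome ~3e7)."""
    return rate_per_base * n_bases
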