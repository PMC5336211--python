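"""Real-data front end: MuTect call-stats ingestion and copy-number
adjustment.

Single-gland exome sequencing yields one MuTect call-stats file per gland
(tab-delimited, ``#``-prefixed header lines, named columns, a KEEP/REJECT
``judgement`` per variant).  Records kept by the caller are converted into a
:class:`~glandabc.growth_model.TumorSample` so the summary statistics and the
ABC machinery run unchanged on real tumors.

Tumors carry copy-number alterations, so the raw allele frequency of a
clonal mutation is 1/c in a c-copy region rather than the diploid 0.5.  A
mutation is therefore called fixed when an exact binomial test cannot reject
q = 1/c (one mutated copy carried by every cell; e.g. frequency 0.33 in a
copy-number-3 region is interpreted as fixed), and frequencies are rescaled
to the simulator's diploid convention as ``min(0.5, q * c / 2)``.  Integer
copy-number segments are a user-supplied input (1-based, closed intervals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .growth_model import ParameterError, TumorSample
from .sequencing_model import SeqModel

__all__ = [
    "VariantRecord",
    "CNSegment",
    "FormatError",
    "read_mutect_callstats",
    "read_cn_segments",
    "cn_adjust",
    "to_tumor_sample",
    "write_mutect_like",
]

REQUIRED_COLUMNS = (
    "contig",
    "position",
    "ref_allele",
    "alt_allele",
    "t_ref_count",
    "t_alt_count",
    "judgement",
)


class FormatError(ValueError):
    pass


@dataclass(frozen=True)
class VariantRecord:
    """One somatic SNV call with its supporting read counts."""

    contig: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    t_ref_count: int
    t_alt_count: int
    judgement: str = "KEEP"

    @property
    def depth(self) -> int:
        return self.t_ref_count + self.t_alt_count

    @property
    def frequency(self) -> float:
        return self.t_alt_count / self.depth


@dataclass(frozen=True)
class CNSegment:
    """Integer copy number over a 1-based closed interval."""

    contig: str
    start: int
    end: int
    copy_number: int


def read_mutect_callstats(path) -> pd.DataFrame:
    """Parse a MuTect call-stats file, keeping only ``judgement == "KEEP"``.

    Columns are located by name, so column order is irrelevant and extra
    call-stats columns are ignored.  Returns a DataFrame with the
    :data:`REQUIRED_COLUMNS`.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"contig": str})
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty call-stats file") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    if len(df) == 0:
        raise FormatError(f"{path}: no variant rows")
    kept = df.loc[df["judgement"] == "KEEP", list(REQUIRED_COLUMNS)].reset_index(drop=True)
    total = kept["t_ref_count"] + kept["t_alt_count"]
    if (total < 1).any():
        raise FormatError(f"{path}: retained record with zero total reads")
    return kept


def read_cn_segments(path) -> pd.DataFrame:
    """Read a BED-like copy-number segment table (contig, start, end,
    copy_number; 1-based closed intervals, non-overlapping per contig)."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    for c in ("contig", "start", "end", "copy_number"):
        if c not in df.columns:
            raise FormatError(f"{path}: missing column {c}")
    if (df["copy_number"] < 1).any():
        raise FormatError("copy numbers must be positive integers")
    for contig, grp in df.groupby("contig"):
        g = grp.sort_values("start")
        if (g["end"] < g["start"]).any():
            raise FormatError(f"segment with end < start on contig {contig}")
        if (g["start"].to_numpy()[1:] <= g["end"].to_numpy()[:-1]).any():
            raise FormatError(f"overlapping segments on contig {contig}")
    return df


def _segment_lookup(segments: pd.DataFrame):
    """contig -> (starts, ends, copy_numbers) sorted by start."""
    index = {}
    for contig, grp in segments.groupby("contig"):
        g = grp.sort_values("start")
        index[str(contig)] = (
            g["start"].to_numpy(),
            g["end"].to_numpy(),
            g["copy_number"].to_numpy(),
        )
    return index


def _copy_number_at(index, contig: str, position: int) -> int | None:
    entry = index.get(str(contig))
    if entry is None:
        return None
    starts, ends, cns = entry
    i = int(np.searchsorted(starts, position, side="right")) - 1
    if i < 0 or position > ends[i]:
        return None
    return int(cns[i])


def cn_adjust(record: VariantRecord, segment: CNSegment, test_level: float = 0.05,
              exact_frequency: bool = False) -> tuple[float, bool]:
    """Copy-number-adjusted diploid-equivalent frequency and fixed call.

    The fixed call tests H0: q = 1/copy_number (one mutated copy in every
    cell) with an exact two-sided binomial test; the mutation is called fixed
    when the test does not reject at ``test_level``.  The adjusted frequency
    ``min(0.5, q * c / 2)`` puts real data on the simulator's diploid scale.
    With ``exact_frequency=True`` the fixed call is instead an exact match of
    the adjusted frequency to 0.5 (perfect-data convention).
    """
    if not (segment.start <= record.position <= segment.end and record.contig == segment.contig):
        raise ParameterError("record does not lie inside the segment")
    c = segment.copy_number
    k = record.depth
    adjusted = min(0.5, record.frequency * c / 2.0)
    if exact_frequency:
        return adjusted, adjusted == 0.5
    pval = sp_stats.binomtest(record.t_alt_count, k, 1.0 / c).pvalue
    return adjusted, bool(pval >= test_level)


def to_tumor_sample(
    files_by_half: dict[str, list],
    cn_segments: pd.DataFrame | None,
    seq_model: SeqModel | None = None,
    *,
    missing_segment: str = "diploid",
) -> TumorSample:
    """Merge per-gland call-stats files into a TumorSample.

    ``files_by_half`` maps half label ('A'/'B') to the list of call-stats
    files, one per gland.  Mutations are keyed by (contig, position, ref,
    alt) across glands.  Each record's frequency is copy-number adjusted; the
    detection threshold ``seq_model.f_min`` applies to the raw observed
    frequency (what the caller saw).  Positions with no covering segment fall
    back to diploid with a warning (``missing_segment='error'`` raises).

    With one gland per half the between-half statistic s9 degenerates to the
    variance of two single-gland means; a caveat warning is emitted.
    """
    seq_model = seq_model or SeqModel(mode="reads", mean_depth=80.0, f_min=0.0)
    if missing_segment not in ("diploid", "error"):
        raise ParameterError("missing_segment must be 'diploid' or 'error'")
    seg_index = _segment_lookup(cn_segments) if cn_segments is not None else {}
    exact = seq_model.mode == "perfect"

    gland_ids: list[str] = []
    halves: list[str] = []
    frames = []
    for half in sorted(files_by_half):
        if not files_by_half[half]:
            raise ParameterError(f"half {half!r} has no call-stats files")
        for path in files_by_half[half]:
            df = read_mutect_callstats(path)
            df["gland_index"] = len(gland_ids)
            gland_ids.append(Path(str(path)).stem)
            halves.append(half)
            frames.append(df)
    merged = pd.concat(frames, ignore_index=True)

    key_cols = ["gland_index", "contig", "position", "ref_allele", "alt_allele"]
    if merged.duplicated(key_cols).any():
        dup = merged[merged.duplicated(key_cols)].iloc[0]
        raise FormatError(
            f"duplicate record for gland {gland_ids[dup['gland_index']]} at "
            f"{dup['contig']}:{dup['position']}"
        )

    variant_key = list(zip(merged["contig"], merged["position"],
                           merged["ref_allele"], merged["alt_allele"]))
    unique_keys = sorted(set(variant_key))
    key_to_id = {k: i for i, k in enumerate(unique_keys)}
    mutation_id = np.array([key_to_id[k] for k in variant_key], dtype=np.int64)

    n_missing = 0
    freqs = np.empty(len(merged))
    fixed = np.empty(len(merged), dtype=bool)
    for i, row in enumerate(merged.itertuples(index=False)):
        cn = _copy_number_at(seg_index, row.contig, row.position)
        if cn is None:
            if missing_segment == "error":
                raise ParameterError(
                    f"no copy-number segment covers {row.contig}:{row.position}"
                )
            n_missing += 1
            cn = 2
        rec = VariantRecord(
            contig=str(row.contig), position=int(row.position),
            ref_allele=row.ref_allele, alt_allele=row.alt_allele,
            t_ref_count=int(row.t_ref_count), t_alt_count=int(row.t_alt_count),
        )
        seg = CNSegment(contig=rec.contig, start=rec.position, end=rec.position, copy_number=cn)
        freqs[i], fixed[i] = cn_adjust(rec, seg, seq_model.test_level, exact_frequency=exact)
    if n_missing:
        warnings.warn(
            f"{n_missing} variant(s) had no covering copy-number segment; assumed diploid",
            stacklevel=2,
        )

    raw_freq = (merged["t_alt_count"] / (merged["t_alt_count"] + merged["t_ref_count"])).to_numpy()
    keep = raw_freq >= seq_model.f_min

    per_half = pd.Series(halves).value_counts()
    if (per_half == 1).all() and len(per_half) == 2:
        warnings.warn(
            "one gland per half: the between-half variance statistic is computed "
            "from two single-gland means",
            stacklevel=2,
        )

    return TumorSample(
        gland_ids=np.asarray(gland_ids, dtype=object),
        halves=np.asarray(halves, dtype=object),
        gland_index=merged["gland_index"].to_numpy(dtype=np.int64)[keep],
        mutation_id=mutation_id[keep],
        freq=freqs[keep],
        fixed=fixed[keep],
        origin_phase=np.full(int(keep.sum()), "na", dtype=object),
        depth=(merged["t_alt_count"] + merged["t_ref_count"]).to_numpy(dtype=np.int64)[keep],
        alt_reads=merged["t_alt_count"].to_numpy(dtype=np.int64)[keep],
    )


def write_mutect_like(sample: TumorSample, outdir, depth: int = 640) -> dict[str, Path]:
    """Export a simulated sample as per-gland MuTect-like call-stats files.

    Read counts are synthesized deterministically from the allele
    frequencies at the given depth (choose a multiple of twice the CSC pool
    for exact round trips).  Intended for fixtures and round-trip tests.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for gi, gland in enumerate(sample.gland_ids):
        mask = sample.gland_index == gi
        alt = np.rint(sample.freq[mask] * depth).astype(int)
        df = pd.DataFrame(
            {
                "contig": "1",
                "position": sample.mutation_id[mask] + 1,  # 1-based
                "ref_allele": "A",
                "alt_allele": "T",
                "t_ref_count": depth - alt,
                "t_alt_count": alt,
                "judgement": "KEEP",
            }
        )
        path = outdir / f"{gland}.call_stats.txt"
        with open(path, "w") as fh:
            fh.write("## muTector-like synthetic export\n")
            df.to_csv(fh, sep="\t", index=False)
        paths[str(gland)] = path
    return paths
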