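"""Genomic interval algebra on 0-based half-open (BED) coordinates.

All interval sets are plain :class:`pandas.DataFrame` objects with columns
``chrom`` (str), ``start`` (int, inclusive), ``end`` (int, exclusive) and an
optional ``id`` column.  Point loci (SNPs, methylation probes) use ``chrom`` /
``pos``.  A :class:`GenomeModel` carries chromosome sizes plus masked gaps and
defines both the validation domain and the space available to the region
shuffler used by the permutation enrichment test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INTERVAL_COLS = ["chrom", "start", "end"]


def as_intervals(records, ids=None) -> pd.DataFrame:
    """Build an interval frame from an iterable of (chrom, start, end[, id])."""
    rows = list(records)
    if not rows:
        df = pd.DataFrame({"chrom": pd.Series(dtype=str),
                           "start": pd.Series(dtype=np.int64),
                           "end": pd.Series(dtype=np.int64)})
        return df
    ncol = len(rows[0])
    cols = INTERVAL_COLS + (["id"] if ncol == 4 else [])
    df = pd.DataFrame(rows, columns=cols)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if ids is not None:
        df["id"] = list(ids)
    return df


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def interval_ids(df: pd.DataFrame) -> pd.Series:
    """Canonical ``chrom:start-end`` identifiers."""
    return df["chrom"].astype(str) + ":" + df["start"].astype(str) + "-" + df["end"].astype(str)


def validate_intervals(df: pd.DataFrame, genome: "GenomeModel | None" = None) -> None:
    if len(df) == 0:
        return
    bad = df[(df["start"] < 0) | (df["start"] >= df["end"])]
    if len(bad):
        r = bad.iloc[0]
        raise ValueError(f"invalid interval {r['chrom']}:{r['start']}-{r['end']} (need 0 <= start < end)")
    if genome is not None:
        sizes = genome.sizes
        unknown = df[~df["chrom"].isin(sizes)]
        if len(unknown):
            r = unknown.iloc[0]
            raise ValueError(f"interval {r['chrom']}:{r['start']}-{r['end']} on unknown chromosome {r['chrom']!r}")
        lim = df["chrom"].map(sizes)
        over = df[df["end"] > lim]
        if len(over):
            r = over.iloc[0]
            raise ValueError(
                f"interval {r['chrom']}:{r['start']}-{r['end']} exceeds chromosome length {sizes[r['chrom']]}")


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome sizes, masked gaps, and the autosome subset.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length)`` pairs.
    gaps
        Interval frame of masked (assembly-gap) regions excluded from
        shuffling; must lie within their chromosomes and be non-overlapping
        per chromosome.
    autosomes
        Chromosome names used for enrichment analyses.  Defaults to every
        chromosome whose name does not look like a sex/mito chromosome.
    """

    chromosomes: tuple
    gaps: pd.DataFrame = field(default_factory=lambda: as_intervals([]))
    autosomes: tuple = ()

    def __post_init__(self):
        chroms = tuple((str(c), int(n)) for c, n in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        if any(n <= 0 for _, n in chroms):
            raise ValueError("chromosome lengths must be > 0")
        if len(set(c for c, _ in chroms)) != len(chroms):
            raise ValueError("duplicate chromosome names")
        gaps = sort_intervals(self.gaps[INTERVAL_COLS].copy()) if len(self.gaps) else as_intervals([])
        validate_intervals(gaps, None)
        sizes = dict(chroms)
        for c, sub in gaps.groupby("chrom", sort=False):
            if c not in sizes:
                raise ValueError(f"gap on unknown chromosome {c!r}")
            if (sub["end"] > sizes[c]).any():
                raise ValueError(f"gap exceeds length of {c}")
            if (sub["start"].values[1:] < sub["end"].values[:-1]).any():
                raise ValueError(f"overlapping gaps on {c}")
        object.__setattr__(self, "gaps", gaps)
        if not self.autosomes:
            auto = tuple(c for c, _ in chroms
                         if c.removeprefix("chr").lower() not in {"x", "y", "m", "mt"})
            object.__setattr__(self, "autosomes", auto)
        else:
            object.__setattr__(self, "autosomes", tuple(str(c) for c in self.autosomes))
            missing = set(self.autosomes) - set(sizes)
            if missing:
                raise ValueError(f"autosomes not in genome: {sorted(missing)}")

    @property
    def sizes(self) -> dict:
        return dict(self.chromosomes)

    def unmasked_segments(self, chroms=None) -> pd.DataFrame:
        """Complement of the gaps: the shuffleable space, per chromosome."""
        use = list(chroms) if chroms is not None else [c for c, _ in self.chromosomes]
        sizes = self.sizes
        gaps_by = {c: sub for c, sub in self.gaps.groupby("chrom", sort=False)}
        rows = []
        for c in use:
            cursor = 0
            if c in gaps_by:
                for _, g in gaps_by[c].iterrows():
                    if g["start"] > cursor:
                        rows.append((c, cursor, int(g["start"])))
                    cursor = max(cursor, int(g["end"]))
            if cursor < sizes[c]:
                rows.append((c, cursor, sizes[c]))
        return as_intervals(rows)


def merge_intervals(intervals: pd.DataFrame, gap: int = 0,
                    genome: GenomeModel | None = None) -> pd.DataFrame:
    """Union-merge intervals, joining neighbours separated by <= ``gap`` bp.

    Follows ``bedtools merge -d`` semantics: book-ended intervals and
    intervals up to ``gap`` bp apart collapse into one.  Output is sorted,
    pairwise separated by more than ``gap`` bp within a chromosome, and
    carries ``chrom:start-end`` ids.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    validate_intervals(intervals, genome)
    if len(intervals) == 0:
        return as_intervals([])
    df = sort_intervals(intervals[INTERVAL_COLS])
    out = []
    for c, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].values
        ends = sub["end"].values
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e <= gap:
                cur_e = max(cur_e, e)
            else:
                out.append((c, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((c, cur_s, cur_e))
    merged = sort_intervals(as_intervals(out))
    merged["id"] = interval_ids(merged)
    return merged


def _positions_to_intervals(pos_df: pd.DataFrame) -> pd.DataFrame:
    df = as_intervals(zip(pos_df["chrom"], pos_df["pos"], pos_df["pos"] + 1))
    return df


def overlap(query: pd.DataFrame, subject: pd.DataFrame) -> pd.DataFrame:
    """All (query, subject) index pairs sharing at least one bp.

    ``subject`` may be an interval frame or a position frame (``chrom`` /
    ``pos``); a position overlaps an interval that contains it.  Pairs are
    returned query-sorted then subject-sorted; indices refer to row order of
    the inputs as given.
    """
    is_pos = "pos" in subject.columns and "end" not in subject.columns
    sub = _positions_to_intervals(subject) if is_pos else subject
    validate_intervals(query)
    validate_intervals(sub)
    q = query.reset_index(drop=True)
    s = sub.reset_index(drop=True)
    pairs_q, pairs_s = [], []
    s_by = {c: g for c, g in s.groupby("chrom", sort=False)}
    for c, qg in q.groupby("chrom", sort=False):
        if c not in s_by:
            continue
        sg = s_by[c]
        ss = sg["start"].values
        se = sg["end"].values
        sidx = sg.index.values
        order = np.argsort(ss, kind="mergesort")
        ss_o, se_o, sidx_o = ss[order], se[order], sidx[order]
        # prefix max of ends lets us bound the candidate window from the left
        run_max_end = np.maximum.accumulate(se_o)
        for qi, qs, qe in zip(qg.index.values, qg["start"].values, qg["end"].values):
            hi = np.searchsorted(ss_o, qe, side="left")  # subjects with start < qe
            if hi == 0:
                continue
            lo = np.searchsorted(run_max_end[:hi], qs, side="right")
            cand = slice(lo, hi)
            hit = se_o[cand] > qs
            for sj in sidx_o[cand][hit]:
                pairs_q.append(qi)
                pairs_s.append(sj)
    out = pd.DataFrame({"query": np.array(pairs_q, dtype=np.int64),
                        "subject": np.array(pairs_s, dtype=np.int64)})
    return out.sort_values(["query", "subject"], kind="mergesort").reset_index(drop=True)


def overlap_counts(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Number of subject hits for each query row (vector of len(query))."""
    hits = overlap(query, subject)
    counts = np.zeros(len(query), dtype=np.int64)
    if len(hits):
        idx, n = np.unique(hits["query"].values, return_counts=True)
        counts[idx] = n
    return counts


def count_positions_in_union(positions: pd.DataFrame, regions: pd.DataFrame) -> int:
    """Count point loci falling inside the union of ``regions``.

    A position covered by several (possibly mutually overlapping) regions is
    counted once, matching how foreground/background overlaps enter the
    permutation odds ratio.
    """
    if len(regions) == 0 or len(positions) == 0:
        return 0
    union = merge_intervals(regions, gap=0)
    total = 0
    u_by = {c: g for c, g in union.groupby("chrom", sort=False)}
    for c, pg in positions.groupby("chrom", sort=False):
        if c not in u_by:
            continue
        ug = u_by[c]
        starts = ug["start"].values
        ends = ug["end"].values
        pos = pg["pos"].values
        k = np.searchsorted(starts, pos, side="right") - 1
        inside = (k >= 0) & (pos < ends[np.clip(k, 0, len(ends) - 1)])
        total += int(inside.sum())
    return total


def shuffle_regions(regions: pd.DataFrame, genome: GenomeModel, seed,
                    chroms=None, chrom_matched: bool = False,
                    no_self_overlap: bool = False, max_tries: int = 1000) -> pd.DataFrame:
    """Place length-matched copies of ``regions`` uniformly into the unmasked genome.

    Mirrors ``bedtools shuffle`` against a gap-masked genome restricted to the
    autosomes: each output region keeps its input length, lies entirely inside
    an unmasked segment, and its start is uniform over all valid placements.
    By default placements are independent and may overlap one another;
    ``no_self_overlap`` enables rejection sampling against previously placed
    regions.  ``chrom_matched`` restricts each region to its source chromosome.

    ``seed`` may be an int or a :class:`numpy.random.Generator`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    use_chroms = list(chroms) if chroms is not None else list(genome.autosomes)
    segs = genome.unmasked_segments(use_chroms)
    if len(segs) == 0:
        raise ValueError("no unmasked segments available for shuffling")
    seg_chrom = segs["chrom"].values
    seg_start = segs["start"].values
    seg_len = (segs["end"] - segs["start"]).values
    lengths = (regions["end"] - regions["start"]).values
    out_rows = []
    placed = {}  # chrom -> list of (start, end), only when no_self_overlap

    def _place(L, mask, label):
        cap = np.where(mask, np.maximum(seg_len - L + 1, 0), 0)
        total = int(cap.sum())
        if total == 0:
            raise ValueError(f"region {label} (length {L}) does not fit in any unmasked segment")
        cum = np.cumsum(cap)
        for _ in range(max_tries):
            u = int(rng.integers(total))
            j = int(np.searchsorted(cum, u, side="right"))
            off = u - (cum[j - 1] if j else 0)
            c = seg_chrom[j]
            s = int(seg_start[j] + off)
            if no_self_overlap:
                clash = any(s < e0 and s + L > s0 for s0, e0 in placed.get(c, ()))
                if clash:
                    continue
                placed.setdefault(c, []).append((s, s + L))
            return c, s, s + L
        raise ValueError(f"could not place region {label} without self-overlap after {max_tries} tries")

    for i, L in enumerate(lengths):
        L = int(L)
        if chrom_matched:
            mask = seg_chrom == regions["chrom"].values[i]
        else:
            mask = np.ones(len(segs), dtype=bool)
        label = regions["id"].values[i] if "id" in regions.columns else f"#{i}"
        out_rows.append(_place(L, mask, label))
    out = as_intervals(out_rows)
    out["id"] = interval_ids(out)
    return out


class _FlatSpace:
    """Genome flattened to one axis for the shuffle/count hot loop.

    Chromosomes are laid end to end with one spacer bp so intervals can never
    merge across a boundary; unmasked segments and position sets are mapped
    once, after which each permutation round is pure vectorized numpy.
    """

    def __init__(self, genome: GenomeModel, chroms=None):
        use = list(chroms) if chroms is not None else list(genome.autosomes)
        sizes = genome.sizes
        self.offsets = {}
        off = 0
        for c in use:
            self.offsets[c] = off
            off += sizes[c] + 1
        segs = genome.unmasked_segments(use)
        self.seg_start = segs["start"].values + segs["chrom"].map(self.offsets).values
        self.seg_len = (segs["end"] - segs["start"]).values.astype(np.int64)

    def flatten_intervals(self, df: pd.DataFrame):
        keep = df["chrom"].isin(self.offsets)
        off = df.loc[keep, "chrom"].map(self.offsets).values
        return (df.loc[keep, "start"].values + off,
                (df.loc[keep, "end"] - df.loc[keep, "start"]).values.astype(np.int64))

    def flatten_positions(self, pos_df: pd.DataFrame) -> np.ndarray:
        keep = pos_df["chrom"].isin(self.offsets)
        off = pos_df.loc[keep, "chrom"].map(self.offsets).values
        return np.sort(pos_df.loc[keep, "pos"].values + off)

    def shuffle_starts(self, lengths: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Uniform valid placements for every length at once (may self-overlap)."""
        cap = self.seg_len[:, None] - lengths[None, :] + 1
        np.clip(cap, 0, None, out=cap)
        cum = np.cumsum(cap, axis=0)
        totals = cum[-1]
        if (totals == 0).any():
            i = int(np.flatnonzero(totals == 0)[0])
            raise ValueError(f"region #{i} (length {int(lengths[i])}) does not fit in "
                             "any unmasked segment")
        u = (rng.random(len(lengths)) * totals).astype(np.int64)
        j = (cum > u[None, :]).argmax(axis=0)
        prev = np.where(j > 0, cum[np.maximum(j - 1, 0), np.arange(len(lengths))], 0)
        return self.seg_start[j] + (u - prev)

    @staticmethod
    def count_in_union(sorted_pos: np.ndarray, starts: np.ndarray,
                       lengths: np.ndarray) -> int:
        """Positions covered by the union of flat intervals, each counted once."""
        if len(starts) == 0 or len(sorted_pos) == 0:
            return 0
        order = np.argsort(starts, kind="mergesort")
        s = starts[order]
        e = s + lengths[order]
        cmax = np.maximum.accumulate(e)
        new = np.empty(len(s), dtype=bool)
        new[0] = True
        new[1:] = s[1:] > cmax[:-1]
        us = s[new]
        ue = np.append(cmax[np.flatnonzero(new)[1:] - 1], cmax[-1])
        return int((np.searchsorted(sorted_pos, ue, side="left")
                    - np.searchsorted(sorted_pos, us, side="left")).sum())


@dataclass
class PositionSet:
    """Point loci (SNPs or methylation probes) with per-position attributes.

    ``positions`` holds ``chrom``/``pos`` plus any attribute columns (lead-SNP
    id, delta beta, ...).  ``role`` is ``"foreground"`` or ``"background"``;
    ``trait`` is a free label (e.g. the disease the loci are associated with).
    """

    positions: pd.DataFrame
    role: str = "foreground"
    trait: str = ""

    def __post_init__(self):
        if self.role not in ("foreground", "background"):
            raise ValueError("role must be 'foreground' or 'background'")
        df = self.positions.reset_index(drop=True).copy()
        df["pos"] = df["pos"].astype(np.int64)
        if df.duplicated(subset=["chrom", "pos"]).any() and len(df.columns) == 2:
            df = df.drop_duplicates().reset_index(drop=True)
        self.positions = df

    def validate(self, genome: GenomeModel) -> None:
        sizes = genome.sizes
        unknown = self.positions[~self.positions["chrom"].isin(sizes)]
        if len(unknown):
            r = unknown.iloc[0]
            raise ValueError(f"position {r['chrom']}:{r['pos']} on unknown chromosome")
        lim = self.positions["chrom"].map(sizes)
        if (self.positions["pos"] >= lim).any() or (self.positions["pos"] < 0).any():
            raise ValueError("position outside chromosome bounds")

    def restrict(self, chroms) -> "PositionSet":
        keep = self.positions[self.positions["chrom"].isin(set(chroms))].reset_index(drop=True)
        return PositionSet(keep, role=self.role, trait=self.trait)

    def __len__(self):
        return len(self.positions)
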