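"""Anchor-to-target Hi-C aggregation profiles and peak-overlap statistics.

The aggregation ("pile-up") analysis asks whether genomic bins carrying a
target factor (e.g. CP190 and/or Chromator) interact with anchor bins
carrying a DNA-specific factor (e.g. BEAF32) more often than expected
from the local chromatin context.  The procedure:

1. assign each binding site to the fixed-size bin containing its
   midpoint (restriction-fragment bins are approximated by uniform bins);
2. keep anchor/target site pairs on the same chromosome separated by
   15-60 kb (below 15 kb the distance-decay background dominates; above
   ~60 kb pairs start to straddle topological domains);
3. accumulate contact counts between the anchor bin and bins within
   +/-5 kb of the target midpoint in 500-bp offset bins, aligning all
   targets at offset 0, and divide each offset bin by the number of
   candidate sites (interacting or not) contributing at that offset;
4. build the same profile for feature-free target sites as an internal
   control, and compare per-pair central counts with a two-sided
   Wilcoxon rank-sum (Mann-Whitney) test.

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .errors import ConfigError, InputError

__all__ = [
    "PeakSet",
    "ContactTable",
    "AggregationProfile",
    "AnchorTargetPair",
    "assign_sites_to_bins",
    "select_anchor_target_pairs",
    "aggregate_profile",
    "control_profile",
    "feature_free_sites",
    "factor_bound_sites",
    "compare_profiles",
    "peak_overlap",
    "filter_overlapping",
]


@dataclass
class PeakSet:
    """A named set of genomic intervals (0-based, half-open).

    ``intervals`` is a list of ``(chrom, start, end)`` tuples, sorted per
    chromosome, with ``0 <= start < end``.
    """

    name: str
    intervals: list

    def __post_init__(self):
        cleaned = []
        for iv in self.intervals:
            chrom, start, end = iv
            start = int(start)
            end = int(end)
            if start < 0:
                raise InputError(f"negative coordinate in {self.name}: {iv}")
            if start >= end:
                raise InputError(f"empty or inverted interval in {self.name}: {iv}")
            cleaned.append((str(chrom), start, end))
        cleaned.sort()
        self.intervals = cleaned

    def __len__(self) -> int:
        return len(self.intervals)

    def midpoints(self) -> list:
        """Interval midpoints as ``(chrom, mid)`` tuples (integer floor)."""
        return [(c, (s + e) // 2) for c, s, e in self.intervals]

    def by_chrom(self) -> dict:
        out: dict = {}
        for c, s, e in self.intervals:
            out.setdefault(c, []).append((s, e))
        return out


@dataclass
class ContactTable:
    """Binned pairwise genomic contacts.

    ``df`` has columns ``chrom``, ``bin_i``, ``bin_j``, ``count`` with bin
    starts that are multiples of ``bin_size`` and canonical ordering
    ``bin_i <= bin_j`` (rows are swapped into canonical order on
    construction).  ``genome`` maps chromosome name to length in bp.
    """

    bin_size: int
    df: pd.DataFrame
    genome: dict

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ConfigError("bin_size must be positive")
        df = self.df.copy()
        required = {"chrom", "bin_i", "bin_j", "count"}
        if not required.issubset(df.columns):
            raise InputError(f"contact table must have columns {sorted(required)}")
        if len(df):
            if ((df["bin_i"] % self.bin_size != 0) | (df["bin_j"] % self.bin_size != 0)).any():
                raise InputError("bin starts must be multiples of bin_size")
            if not np.isfinite(df["count"]).all() or (df["count"] < 0).any():
                raise InputError("contact counts must be finite and non-negative")
            swap = df["bin_i"] > df["bin_j"]
            if swap.any():
                lo = df[["bin_i", "bin_j"]].min(axis=1)
                hi = df[["bin_i", "bin_j"]].max(axis=1)
                df["bin_i"], df["bin_j"] = lo, hi
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def total_counts(self) -> float:
        return float(self.df["count"].sum())


class AnchorTargetPair(NamedTuple):
    chrom: str
    anchor_mid: int
    target_mid: int

    @property
    def distance(self) -> int:
        return abs(self.target_mid - self.anchor_mid)


@dataclass
class AggregationProfile:
    """Normalized contact frequency vs offset from the aligned target site.

    ``offsets`` are offset-bin starts relative to the target midpoint's
    bin (half-open 500-bp bins from -5000 to +4500 by default).
    ``signal`` is the per-offset sum of contact counts divided by the
    number of candidate sites contributing at that offset; ``control`` is
    the same quantity for feature-free targets.  ``central_counts`` and
    ``central_counts_control`` hold the per-pair counts at offset 0 and
    feed the Wilcoxon comparison.
    """

    offsets: np.ndarray
    signal: np.ndarray
    control: np.ndarray | None = None
    n_pairs: int = 0
    n_pairs_control: int = 0
    p_value: float | None = None
    central_counts: np.ndarray | None = None
    central_counts_control: np.ndarray | None = None

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.offsets.shape != self.signal.shape:
            raise InputError("offsets and signal must have equal length")
        if self.control is not None:
            self.control = np.asarray(self.control, dtype=float)
            if self.control.shape != self.signal.shape:
                raise InputError("control must match signal length")


def assign_sites_to_bins(peaks: PeakSet, contacts: ContactTable):
    """Map each peak to the bin containing its midpoint.

    Returns ``(mapping, n_skipped)`` where ``mapping`` maps
    ``(chrom, midpoint)`` to the bin start, and ``n_skipped`` counts peaks
    whose midpoint falls outside the genome bounds (these are skipped with
    a warning).
    """
    bs = contacts.bin_size
    mapping = {}
    n_skipped = 0
    for chrom, mid in peaks.midpoints():
        size = contacts.genome.get(chrom)
        if size is None or mid >= size:
            n_skipped += 1
            continue
        mapping[(chrom, mid)] = (mid // bs) * bs
    if n_skipped:
        warnings.warn(
            f"{n_skipped} peak(s) in {peaks.name!r} fall outside the genome and were skipped",
            stacklevel=2,
        )
    return mapping, n_skipped


def select_anchor_target_pairs(anchors: PeakSet, targets: PeakSet,
                               d_min: int = 15000, d_max: int = 60000) -> list:
    """All same-chromosome anchor/target pairs with midpoint distance in [d_min, d_max].

    Both orientations (target upstream or downstream of the anchor) are
    kept.  The lower cutoff excludes the near-diagonal distance-decay
    background; the upper cutoff keeps pairs within typical topological
    domains.  Returns a list of :class:`AnchorTargetPair`.
    """
    if d_min < 0 or d_max < d_min:
        raise ConfigError("require 0 <= d_min <= d_max")
    t_by_chrom: dict = {}
    for chrom, mid in targets.midpoints():
        t_by_chrom.setdefault(chrom, []).append(mid)
    pairs = []
    for chrom, t_mids in t_by_chrom.items():
        t_mids = np.sort(np.asarray(t_mids))
        for a_chrom, a_mid in anchors.midpoints():
            if a_chrom != chrom:
                continue
            for lo, hi in ((a_mid - d_max, a_mid - d_min), (a_mid + d_min, a_mid + d_max)):
                i0 = np.searchsorted(t_mids, lo, side="left")
                i1 = np.searchsorted(t_mids, hi, side="right")
                for t_mid in t_mids[i0:i1]:
                    d = abs(int(t_mid) - a_mid)
                    if d_min <= d <= d_max:
                        pairs.append(AnchorTargetPair(chrom, int(a_mid), int(t_mid)))
    # The double-sided window can touch the same target twice when
    # d_min == 0 and target == anchor; deduplicate deterministically.
    pairs = sorted(set(pairs))
    return pairs


def aggregate_profile(pairs, contacts: ContactTable, window: int = 5000,
                      bin_size: int | None = None) -> AggregationProfile:
    """Aggregate contact counts around aligned target sites.

    For each pair, the contact counts between the anchor's bin and every
    bin within ``+/-window`` of the target midpoint are accumulated by
    offset (offset 0 is the bin whose start equals the target midpoint's
    bin start).  Each offset bin is then divided by the number of
    candidate sites -- interacting or not -- whose offset bin lies inside
    the chromosome, which normalizes for the number of sites found at
    each distance from the anchors.

    An empty pair list yields an all-NaN profile (with a warning), not an
    error.
    """
    bs = bin_size if bin_size is not None else contacts.bin_size
    if bs != contacts.bin_size:
        raise ConfigError("profile bin size must equal the contact-table bin size")
    if window % bs != 0:
        raise ConfigError("window must be a multiple of the bin size")
    offsets = np.arange(-window, window, bs)
    n_off = offsets.size
    if not pairs:
        warnings.warn("no anchor/target pairs to aggregate", stacklevel=2)
        return AggregationProfile(
            offsets=offsets, signal=np.full(n_off, np.nan), n_pairs=0,
            central_counts=np.array([]),
        )

    chroms = np.array([p.chrom for p in pairs])
    abin = (np.array([p.anchor_mid for p in pairs]) // bs) * bs
    tbin = (np.array([p.target_mid for p in pairs]) // bs) * bs
    sizes = np.array([contacts.genome[c] for c in chroms])

    n_pairs = len(pairs)
    long = pd.DataFrame({
        "pair": np.repeat(np.arange(n_pairs), n_off),
        "chrom": np.repeat(chroms, n_off),
        "offset": np.tile(offsets, n_pairs),
        "abin": np.repeat(abin, n_off),
        "jbin": np.repeat(tbin, n_off) + np.tile(offsets, n_pairs),
    })
    in_bounds = (long["jbin"] >= 0) & (long["jbin"] < np.repeat(sizes, n_off))
    long = long[in_bounds].copy()
    long["bin_i"] = np.minimum(long["abin"], long["jbin"])
    long["bin_j"] = np.maximum(long["abin"], long["jbin"])
    merged = long.merge(
        contacts.df[["chrom", "bin_i", "bin_j", "count"]],
        on=["chrom", "bin_i", "bin_j"],
        how="left",
    )
    merged["count"] = merged["count"].fillna(0.0)

    sums = merged.groupby("offset")["count"].sum()
    candidates = merged.groupby("offset")["count"].size()
    signal = np.zeros(n_off)
    for k, off in enumerate(offsets):
        n_cand = candidates.get(off, 0)
        signal[k] = sums.get(off, 0.0) / n_cand if n_cand else np.nan

    central = merged[merged["offset"] == 0].set_index("pair")["count"]
    central_counts = central.reindex(np.arange(n_pairs)).fillna(0.0).to_numpy()
    return AggregationProfile(
        offsets=offsets, signal=signal, n_pairs=n_pairs, central_counts=central_counts,
    )


def feature_free_sites(contacts: ContactTable, exclude: list, name: str = "feature_free",
                       stride: int = 1) -> PeakSet:
    """Pseudo-sites at the midpoints of bins containing none of the peaks.

    Every ``stride``-th feature-free bin (deterministic thinning) becomes
    a candidate control target of width 1 bp at the bin midpoint.
    """
    trees = {}
    for ps in exclude:
        for chrom, ivs in ps.by_chrom().items():
            tree = trees.setdefault(chrom, IntervalTree())
            for s, e in ivs:
                tree.addi(s, e)
    intervals = []
    bs = contacts.bin_size
    for chrom, size in contacts.genome.items():
        tree = trees.get(chrom)
        kept = 0
        for start in range(0, size - bs + 1, bs):
            if tree is not None and tree.overlap(start, start + bs):
                continue
            if kept % stride == 0:
                mid = start + bs // 2
                intervals.append((chrom, mid, mid + 1))
            kept += 1
    return PeakSet(name=name, intervals=intervals)


def factor_bound_sites(contacts: ContactTable, peak_sets: list, mode: str = "all",
                       name: str | None = None) -> PeakSet:
    """Pseudo-sites at midpoints of bins bound by the given factors.

    A bin carries a factor when it contains the midpoint of one of that
    factor's peaks; ``mode="all"`` requires every factor (co-bound bins),
    ``mode="any"`` at least one.  This is the bin-level notion of feature
    content used throughout the aggregation analysis.
    """
    if mode not in ("all", "any"):
        raise ConfigError("mode must be 'all' or 'any'")
    bs = contacts.bin_size
    per_factor = []
    for ps in peak_sets:
        bins = set()
        for chrom, mid in ps.midpoints():
            size = contacts.genome.get(chrom)
            if size is not None and mid < size:
                bins.add((chrom, (mid // bs) * bs))
        per_factor.append(bins)
    combined = set.intersection(*per_factor) if mode == "all" else set.union(*per_factor)
    intervals = [(c, b + bs // 2, b + bs // 2 + 1) for c, b in sorted(combined)]
    label = name or ("_and_" if mode == "all" else "_or_").join(ps.name for ps in peak_sets)
    return PeakSet(name=label, intervals=intervals)


def control_profile(anchors: PeakSet, control_targets: PeakSet, contacts: ContactTable,
                    d_min: int = 15000, d_max: int = 60000, window: int = 5000) -> AggregationProfile:
    """Aggregation profile over feature-free target sites.

    Runs the same pipeline as the signal profile but with targets that
    carry none of the features; the result reflects the background
    interaction level of the anchors' chromatin context.  An empty
    control set yields an all-NaN profile with a warning.
    """
    pairs = select_anchor_target_pairs(anchors, control_targets, d_min, d_max)
    return aggregate_profile(pairs, contacts, window=window)


def compare_profiles(signal_values, control_values) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses exact enumeration of the U distribution when both groups have at
    most 8 observations and no ties, and the tie-corrected normal
    approximation with continuity correction otherwise.  All-tied inputs
    return p = 1 with a warning.
    """
    x = np.asarray(signal_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 3 or y.size < 3:
        raise InputError("need at least 3 observations per group")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations tied; returning p = 1", stacklevel=2)
        return 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def build_aggregation(anchors: PeakSet, targets: PeakSet, contacts: ContactTable,
                      control_targets: PeakSet | None = None,
                      d_min: int = 15000, d_max: int = 60000,
                      window: int = 5000) -> AggregationProfile:
    """Signal + control aggregation profiles and their Wilcoxon p-value.

    Convenience wrapper running pair selection, signal aggregation, the
    feature-free control, and the per-pair central-count comparison.
    """
    pairs = select_anchor_target_pairs(anchors, targets, d_min, d_max)
    prof = aggregate_profile(pairs, contacts, window=window)
    if control_targets is not None:
        ctrl = control_profile(anchors, control_targets, contacts, d_min, d_max, window)
        prof.control = ctrl.signal
        prof.n_pairs_control = ctrl.n_pairs
        prof.central_counts_control = ctrl.central_counts
        if (prof.central_counts is not None and prof.central_counts.size >= 3
                and ctrl.central_counts is not None and ctrl.central_counts.size >= 3):
            prof.p_value = compare_profiles(prof.central_counts, ctrl.central_counts)
    return prof


def _overlap_tree(peaks: PeakSet) -> dict:
    trees: dict = {}
    for chrom, ivs in peaks.by_chrom().items():
        tree = IntervalTree()
        for s, e in ivs:
            tree.addi(s, e)
        trees[chrom] = tree
    return trees


def _overlaps_any(trees: dict, chrom: str, start: int, end: int) -> bool:
    tree = trees.get(chrom)
    return bool(tree is not None and tree.overlap(start, end))


def peak_overlap(*peak_sets: PeakSet) -> dict:
    """Pairwise and Venn-region overlap counts for two or three peak sets.

    Overlap is any shared base under half-open semantics (abutting
    intervals do not overlap).  Counts are reported per reference set --
    the number of A peaks overlapping B generally differs from the number
    of B peaks overlapping A.  Returns a dict with:

    * ``sets``: peak count per set name;
    * ``pairwise``: ``"A_in_B"`` -> number of A peaks overlapping >= 1 B peak;
    * ``venn``: per set, counts of its peaks by overlap pattern with the
      other sets (pattern keys like ``"A&B"``, ``"A&B&C"``).
    """
    if not 2 <= len(peak_sets) <= 3:
        raise InputError("peak_overlap takes two or three peak sets")
    names = [ps.name for ps in peak_sets]
    if len(set(names)) != len(names):
        raise InputError("peak sets must have distinct names")
    trees = {ps.name: _overlap_tree(ps) for ps in peak_sets}

    result = {"sets": {ps.name: len(ps) for ps in peak_sets}, "pairwise": {}, "venn": {}}
    for a in peak_sets:
        for b in peak_sets:
            if a.name == b.name:
                continue
            n = sum(
                1 for chrom, s, e in a.intervals
                if _overlaps_any(trees[b.name], chrom, s, e)
            )
            result["pairwise"][f"{a.name}_in_{b.name}"] = n

    for a in peak_sets:
        others = [ps.name for ps in peak_sets if ps.name != a.name]
        patterns: Counter = Counter()
        for chrom, s, e in a.intervals:
            hit = [o for o in others if _overlaps_any(trees[o], chrom, s, e)]
            patterns["&".join([a.name] + hit)] += 1
        result["venn"][a.name] = dict(patterns)
    return result


def filter_overlapping(peaks: PeakSet, other: PeakSet, invert: bool = False,
                       name: str | None = None) -> PeakSet:
    """Peaks of ``peaks`` that overlap (or, with ``invert``, avoid) ``other``.

    Useful to build co-bound target sets (e.g. CP190 peaks that also carry
    Chromator) or feature-free complements.
    """
    trees = _overlap_tree(other)
    kept = [
        (c, s, e) for c, s, e in peaks.intervals
        if _overlaps_any(trees, c, s, e) != invert
    ]
    label = name or (f"{peaks.name}_not_{other.name}" if invert else f"{peaks.name}_and_{other.name}")
    return PeakSet(name=label, intervals=kept)
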