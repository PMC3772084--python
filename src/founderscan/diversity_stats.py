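"""Partitioned diversity statistics, SFS, sliding windows, D statistic, NJ trees.

Pairwise nucleotide diversity is the expected per-site allele mismatch
between two diploid genotypes (identical homozygotes 0, opposite homozygotes
1, any heterozygote comparison 1/2), averaged over sites with data in both
samples.  Partitioning restricts the comparison to genomic windows where the
painting assigns the pair the same founding haplotype ("within") or
different ones ("among"); within-founder variation postdates the founding
event, among-founder variation is sorted ancestral polymorphism.
Confidence intervals come from block resampling so that linkage does not
fake precision.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from founderscan.errors import ConfigurationError, FittingError, ValidationError
from founderscan.genotype_model import MISSING, SELFER, GenotypeTable
from founderscan.haplotype_painting import (
    ALLOZYGOUS,
    DIFFERENT,
    SAME,
    Painting,
    PaintingConfig,
    pair_identity_stretches,
)


@dataclass
class DiversityEstimate:
    """A single diversity point estimate with a block-bootstrap interval."""

    scope: str
    pi: float
    n_sites: int
    n_pairs: int
    ci_low: float = np.nan
    ci_high: float = np.nan
    undefined: bool = False


@dataclass
class SfsCounts:
    """Derived-allele-count spectrum for a fixed sample subset.

    ``counts[i-1]`` is the number of sites with ``i`` derived copies
    (``i = 1..n-1`` at the haplotype level: selfer genotypes are homozygous,
    so each sample contributes one resolved haplotype).
    """

    n_samples: int
    counts: np.ndarray
    polarization: str
    site_class: str | None = None
    n_dropped_ties: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValidationError("negative SFS counts")
        if len(self.counts) != self.n_samples - 1:
            raise ValidationError("counts must have length n_samples - 1")

    @property
    def proportions(self) -> np.ndarray:
        tot = self.counts.sum()
        return self.counts / tot if tot else np.full_like(self.counts, np.nan, dtype=float)


# ---------------------------------------------------------------------------
# Pairwise diversity
# ---------------------------------------------------------------------------


def _pair_site_diff(table: GenotypeTable, ia: int, ib: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-site expected allele mismatch and comparability for one pair."""
    ga = table.genotypes[:, ia].astype(np.float64)
    gb = table.genotypes[:, ib].astype(np.float64)
    comp = (ga != MISSING) & (gb != MISSING)
    pa, pb = ga / 2.0, gb / 2.0
    diff = pa * (1 - pb) + pb * (1 - pa)
    diff[~comp] = 0.0
    return diff, comp


def _scope_mask(
    table: GenotypeTable, site_class: str | None, mask: np.ndarray | None
) -> np.ndarray:
    scope = np.ones(table.n_sites, dtype=bool)
    if site_class is not None:
        scope &= table.site_class_mask(site_class)
    if mask is not None:
        scope &= mask
    return scope


def _pairs_of(table, set_a, set_b):
    ia = [table.sample_index(s) for s in set_a]
    ib = [table.sample_index(s) for s in set_b]
    if list(set_a) == list(set_b):
        return list(itertools.combinations(ia, 2))
    return [(a, b) for a in ia for b in ib if a != b]


def pairwise_pi(
    table: GenotypeTable,
    set_a: list[str],
    set_b: list[str] | None = None,
    site_class: str | None = None,
    mask: np.ndarray | None = None,
    denominator_bp: float | None = None,
    n_boot: int = 0,
    block_bp: int = 100_000,
    seed: int = 0,
    scope: str = "",
) -> DiversityEstimate:
    """Mean pairwise diversity within ``set_a`` or between the two sets.

    The point estimate is the unweighted mean over sample pairs of the
    per-comparable-site mismatch.  With ``denominator_bp`` the estimate is
    rescaled to a per-base-pair diversity, ``pi_site * n_scope_sites /
    denominator_bp`` — unbiased when genotype missingness is independent of
    the alleles, since sites absent from the table are invariant.
    ``n_boot > 0`` adds a 95% block-bootstrap interval over ``block_bp``
    genomic blocks.
    """
    set_b = set_b if set_b is not None else set_a
    pairs = _pairs_of(table, set_a, set_b)
    if not pairs:
        raise ConfigurationError("no sample pairs to compare")
    sel = _scope_mask(table, site_class, mask)
    n_scope = int(sel.sum())
    scale = (n_scope / denominator_bp) if denominator_bp else 1.0

    diffs, comps = [], []
    for ia, ib in pairs:
        d, c = _pair_site_diff(table, ia, ib)
        diffs.append(d[sel])
        comps.append(c[sel])
    per_pair = []
    for d, c in zip(diffs, comps):
        n = c.sum()
        per_pair.append(d.sum() / n if n else np.nan)
    per_pair = np.array(per_pair)
    if np.isnan(per_pair).all():
        return DiversityEstimate(scope, np.nan, 0, len(pairs), undefined=True)
    pi = float(np.nanmean(per_pair)) * scale

    ci = (np.nan, np.nan)
    if n_boot > 0 and n_scope:
        blocks = _block_ids(table, sel, block_bp)
        n_blk = blocks.max() + 1
        d_blk = np.vstack([np.bincount(blocks, weights=d, minlength=n_blk) for d in diffs])
        c_blk = np.vstack([np.bincount(blocks, weights=c, minlength=n_blk) for c in comps])
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for r in range(n_boot):
            pick = rng.integers(0, n_blk, size=n_blk)
            with np.errstate(invalid="ignore"):
                pp = d_blk[:, pick].sum(axis=1) / c_blk[:, pick].sum(axis=1)
            reps[r] = np.nanmean(pp) * scale
        ci = tuple(np.nanquantile(reps, [0.025, 0.975]))
    est = DiversityEstimate(scope, pi, n_scope, len(pairs), ci[0], ci[1])
    return est


def _block_ids(table: GenotypeTable, sel: np.ndarray, block_bp: int) -> np.ndarray:
    """Contiguous genomic block index for every selected site."""
    chroms = table.sites["chrom"].to_numpy()[sel]
    pos = table.sites["pos"].to_numpy()[sel]
    ids = np.zeros(sel.sum(), dtype=np.int64)
    next_id = 0
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            local = (pos[start:i] - pos[start]) // block_bp
            ids[start:i] = next_id + local
            next_id = int(ids[start:i].max()) + 1 if i > start else next_id
            start = i
    return ids


# ---------------------------------------------------------------------------
# Partitioned diversity (within / among founding haplotypes)
# ---------------------------------------------------------------------------


def _site_window_index(table: GenotypeTable, painting: Painting) -> np.ndarray:
    """Painting-window index for every table site (-1 outside all windows)."""
    out = np.full(table.n_sites, -1, dtype=np.int64)
    win = painting.windows
    w_chrom = win["chrom"].to_numpy()
    w_start = win["start"].to_numpy()
    w_end = win["end"].to_numpy()
    slices = table.chrom_slices()
    pos_all = table.sites["pos"].to_numpy()
    offset = 0
    for chrom in win["chrom"].unique():
        wsel = np.nonzero(w_chrom == chrom)[0]
        sl = slices.get(chrom)
        if sl is None:
            continue
        pos = pos_all[sl]
        idx = np.searchsorted(w_start[wsel], pos, side="right") - 1
        ok = idx >= 0
        ok &= np.where(ok, pos < w_end[wsel[np.clip(idx, 0, None)]], False)
        res = np.where(ok, wsel[np.clip(idx, 0, None)], -1)
        out[sl] = res
    return out


def _pair_group(table: GenotypeTable, a: str, b: str) -> str:
    ga = table.samples[table.sample_index(a)].group
    gb = table.samples[table.sample_index(b)].group
    return "/".join(sorted([ga, gb]))


def partitioned_pi(
    table: GenotypeTable,
    painting: Painting,
    site_class: str | None = "4-fold",
    sample_subset: list[str] | None = None,
    class_fraction: float | None = None,
    painting_config: PaintingConfig | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Diversity within and among founding haplotypes, by geography class.

    Per pair, sites in windows with a direct SAME call are pooled into the
    "within" partition and DIFFERENT windows into "among"; ambiguous,
    unassigned and allozygous windows are excluded.  With ``class_fraction``
    (the fraction of genomic bases belonging to the site class) estimates
    are per class base pair: ``(sum diff / sum comparable) * n_class_sites /
    (window_bp * class_fraction)`` — sites absent from the table are
    invariant, and per-genotype missingness is corrected through the
    comparable-site ratio.  Without it the estimate is per comparable
    variant site (useful only for relative comparisons).  Confidence
    intervals resample assignment windows with replacement.

    Rows: (pair_class, partition) with pair_class "all" plus each geography
    combination.
    """
    samples = sample_subset or [
        s.sample_id for s in table.samples if s.species == SELFER
    ]
    painting_config = painting_config or PaintingConfig()
    sel = _scope_mask(table, site_class, None)
    swin = _site_window_index(table, painting)
    rng = np.random.default_rng(seed)
    win_bp = (painting.windows["end"] - painting.windows["start"]).to_numpy(float)
    site_count_by_win = np.bincount(
        swin[sel & (swin >= 0)], minlength=len(painting.windows)
    ).astype(float)

    # per (pair, partition): per-window diff/comp sums + class-site/bp totals
    per_part: dict[str, dict] = {"within": {}, "among": {}}
    groups: dict[tuple[str, str], str] = {}
    for a, b in itertools.combinations(samples, 2):
        ia, ib = table.sample_index(a), table.sample_index(b)
        d, c = _pair_site_diff(table, ia, ib)
        status = painting.pair_status(a, b)
        groups[(a, b)] = _pair_group(table, a, b)
        # within: SAME windows as called (true shared-founder regions carry
        # no visible differences, so no selection bias arises)
        w_ids = np.nonzero(status == SAME)[0]
        smask = sel & (swin >= 0)
        smask[smask] = (status == SAME)[swin[smask]]
        wids_site = swin[smask]
        d_sum = np.bincount(wids_site, weights=d[smask], minlength=len(win_bp))[w_ids]
        c_sum = np.bincount(
            wids_site, weights=c[smask].astype(float), minlength=len(win_bp)
        )[w_ids]
        per_part["within"][(a, b)] = (
            d_sum, c_sum, site_count_by_win[w_ids], win_bp[w_ids], w_ids
        )
        # among: a DIFFERENT interval spans exactly its supporting
        # differences, so its interior mismatch density is biased upward
        # wherever other founders contribute interleaved joint sites.  The
        # unbiased unit extends each DIFFERENT block to the midpoint of the
        # flanking evidence gap (the state transition is uniform there), and
        # across a whole gap bounded by DIFFERENT evidence on both sides —
        # unless the gap holds a pair-identity stretch, which anchors the
        # boundary like SAME evidence does.
        anchors = pair_identity_stretches(
            table, (a, b), painting_config,
            min_sites=painting_config.invariant_region_gr_snps,
            min_bp=painting_config.invariant_region_bp,
        )
        regions = _among_regions(painting.windows, status, anchors)
        per_part["among"][(a, b)] = _aggregate_regions(table, regions, sel, d, c)

    return _partition_rows(per_part, groups, class_fraction, n_boot, rng)


def _bp_runs(windows: pd.DataFrame, flag: np.ndarray) -> dict[str, list[tuple[int, int]]]:
    """Coordinate-contiguous bp blocks of flagged windows, per chromosome."""
    chrom = windows["chrom"].to_numpy()
    start = windows["start"].to_numpy()
    end = windows["end"].to_numpy()
    out: dict[str, list[tuple[int, int]]] = {}
    i = 0
    n = len(flag)
    while i < n:
        if not flag[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n and flag[j + 1]
            and chrom[j + 1] == chrom[j] and start[j + 1] == end[j]
        ):
            j += 1
        out.setdefault(chrom[i], []).append((int(start[i]), int(end[j])))
        i = j + 1
    return out


def _merge_bp(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not blocks:
        return []
    blocks = sorted(blocks)
    out = [list(blocks[0])]
    for s, e in blocks[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(b) for b in out]


def _among_regions(
    windows: pd.DataFrame, status: np.ndarray, anchors: pd.DataFrame
) -> list[tuple[str, int, int]]:
    """Midpoint-extended among-founder regions (chrom, start, end) for a pair.

    DIFFERENT evidence blocks extend into adjacent no-evidence gaps: to the
    gap midpoint when the far side holds SAME (or allozygous) evidence, an
    identity-stretch anchor, or the data edge, and across the whole gap when
    DIFFERENT evidence flanks both sides (in which case the blocks merge).
    """
    diff_by_chrom = _bp_runs(windows, status == DIFFERENT)
    same_by_chrom = _bp_runs(windows, (status == SAME) | (status == ALLOZYGOUS))
    if len(anchors):
        for chrom, grp in anchors.groupby("chrom", sort=False):
            same_by_chrom.setdefault(chrom, []).extend(
                zip(grp["start"].astype(int), grp["end"].astype(int))
            )
    w_chrom = windows["chrom"].to_numpy()
    regions: list[tuple[str, int, int]] = []
    for chrom, diff_b in diff_by_chrom.items():
        wsel = w_chrom == chrom
        data_lo = int(windows["start"].to_numpy()[wsel].min())
        data_hi = int(windows["end"].to_numpy()[wsel].max())
        same_b = _merge_bp(same_by_chrom.get(chrom, []))
        blocks = sorted(
            [(s, e, 0) for s, e in diff_b] + [(s, e, 1) for s, e in same_b]
        )
        cur = None  # open among region [lo, hi_of_last_diff)
        prev = None  # (end_bp, kind) of previous block
        for s, e, kind in blocks:
            if kind == 0:
                if cur is not None and prev is not None and prev[1] == 0:
                    cur = (cur[0], e)  # bridge gap between two diff blocks
                else:
                    if cur is not None:
                        regions.append((chrom, cur[0], cur[1]))
                    if prev is None:
                        lo = (data_lo + s) // 2
                    else:
                        lo = (prev[0] + s) // 2
                    cur = (lo, e)
            else:
                if cur is not None:
                    regions.append((chrom, cur[0], (cur[1] + s) // 2))
                    cur = None
            prev = (max(e, prev[0]) if prev and prev[0] > e else e, kind)
        if cur is not None:
            regions.append((chrom, cur[0], (cur[1] + data_hi) // 2))
    return regions


def _aggregate_regions(
    table: GenotypeTable,
    regions: list[tuple[str, int, int]],
    sel: np.ndarray,
    d: np.ndarray,
    c: np.ndarray,
):
    """Per-region (diff, comparable, class-site, bp) sums for bootstrap units."""
    n_r = len(regions)
    d_sum = np.zeros(n_r)
    c_sum = np.zeros(n_r)
    s_cnt = np.zeros(n_r)
    l_bp = np.zeros(n_r)
    slices = table.chrom_slices()
    pos_all = table.sites["pos"].to_numpy()
    for r_i, (chrom, lo, hi) in enumerate(regions):
        sl = slices.get(chrom)
        l_bp[r_i] = hi - lo
        if sl is None:
            continue
        pos = pos_all[sl]
        i0 = sl.start + np.searchsorted(pos, lo, side="left")
        i1 = sl.start + np.searchsorted(pos, hi, side="left")
        seg = slice(i0, i1)
        use = sel[seg]
        d_sum[r_i] = d[seg][use].sum()
        c_sum[r_i] = c[seg][use].sum()
        s_cnt[r_i] = use.sum()
    return d_sum, c_sum, s_cnt, l_bp, np.arange(n_r)


def _partition_rows(per_part, groups, class_fraction, n_boot, rng) -> pd.DataFrame:
    def estimate(d_tot, c_tot, s_tot, l_tot):
        if c_tot == 0:
            return np.nan
        pi_site = d_tot / c_tot
        if class_fraction is not None:
            if l_tot == 0:
                return np.nan
            return pi_site * s_tot / (l_tot * class_fraction)
        return pi_site

    rows = []
    classes = sorted(set(groups.values()))
    for part in ("within", "among"):
        for cls in ["all"] + classes:
            keys = [k for k in per_part[part] if cls == "all" or groups[k] == cls]
            arrs = [per_part[part][k] for k in keys]
            d_tot = sum(a[0].sum() for a in arrs)
            c_tot = sum(a[1].sum() for a in arrs)
            s_tot = sum(a[2].sum() for a in arrs)
            l_tot = sum(a[3].sum() for a in arrs)
            pi = estimate(d_tot, c_tot, s_tot, l_tot)
            if c_tot == 0:
                rows.append(
                    {"pair_class": cls, "partition": part, "pi": np.nan,
                     "n_sites": 0, "ci_low": np.nan, "ci_high": np.nan,
                     "undefined": True}
                )
                continue
            n_units = max(int(a[4].size) for a in arrs)
            reps = np.empty(n_boot)
            for r in range(n_boot):
                dd = cc = ss = ll = 0.0
                for a in arrs:
                    if a[4].size == 0:
                        continue
                    pick = rng.integers(0, a[4].size, size=a[4].size)
                    dd += a[0][pick].sum()
                    cc += a[1][pick].sum()
                    ss += a[2][pick].sum()
                    ll += a[3][pick].sum()
                reps[r] = estimate(dd, cc, ss, ll)
            ci = (
                tuple(np.nanquantile(reps, [0.025, 0.975]))
                if n_boot
                else (np.nan, np.nan)
            )
            rows.append(
                {"pair_class": cls, "partition": part, "pi": pi,
                 "n_sites": int(c_tot), "ci_low": ci[0], "ci_high": ci[1],
                 "undefined": False}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SFS within founding haplotypes
# ---------------------------------------------------------------------------


def sfs_within_founders(
    table: GenotypeTable,
    painting: Painting,
    sample_subset: list[str],
    polarization: str = "outcrosser_major",
    site_class: str | None = None,
) -> SfsCounts:
    """Derived-allele spectrum restricted to shared-founder regions.

    Only windows where every sample in the subset carries the same founder
    index contribute.  Polarization: the outcrosser major allele is taken as
    ancestral (ties dropped), or the true ancestral annotation
    (``polarization='ancestral'``, synthetic data only).
    """
    n = len(sample_subset)
    if n < 2:
        raise ConfigurationError("need at least two samples")
    s_idx = [painting.sample_ids.index(s) for s in sample_subset]
    lab = painting.labels[:, s_idx]
    mono_w = (lab > 0).all(axis=1) & (lab == lab[:, :1]).all(axis=1)
    if not mono_w.any():
        return SfsCounts(n, np.zeros(n - 1, dtype=np.int64), polarization, site_class)
    swin = _site_window_index(table, painting)
    smask = _scope_mask(table, site_class, None) & (swin >= 0)
    smask[smask] = mono_w[swin[smask]]

    cols = np.array([table.sample_index(s) for s in sample_subset])
    g = table.genotypes[:, cols]
    full = (g != MISSING).all(axis=1) & (g != 1).all(axis=1)
    smask &= full

    n_ties = 0
    if polarization == "ancestral":
        anc = table.sites["ancestral"].to_numpy()
        smask &= anc != "unknown"
        anc_alt = anc == "alt"
    elif polarization == "outcrosser_major":
        oc = table.genotypes[:, table.outcrosser_indices]
        called = oc != MISSING
        ac = np.where(called, oc, 0).sum(axis=1)
        an = 2 * called.sum(axis=1)
        tie = (2 * ac == an) | (an == 0)
        n_ties = int((tie & smask).sum())
        smask &= ~tie
        anc_alt = 2 * ac > an  # major allele is alt -> alt is ancestral
    else:
        raise ConfigurationError(f"unknown polarization {polarization!r}")

    derived = (g[smask] // 2).sum(axis=1)
    derived = np.where(anc_alt[smask], n - derived, derived)
    counts = np.bincount(derived, minlength=n + 1)[1:n]
    return SfsCounts(n, counts, polarization, site_class, n_ties)


# ---------------------------------------------------------------------------
# Sliding windows
# ---------------------------------------------------------------------------


def sliding_windows(
    table: GenotypeTable,
    painting: Painting,
    window_bp: int = 10_000,
    step_bp: int = 2_000,
    min_sites: int = 100,
    site_class: str | None = "4-fold",
) -> tuple[pd.DataFrame, float]:
    """Per-window mean pairwise diversity and major-founder frequency.

    Windows slide along each chromosome; a window needs at least
    ``min_sites`` comparable site-pairs.  The major-founder frequency is the
    bp-weighted frequency of the most common founder index among painted
    samples.  Returns the window frame and the Pearson correlation between
    the two series.
    """
    selfers = [s.sample_id for s in table.samples if s.species == SELFER]
    sel = _scope_mask(table, site_class, None)
    d_tot = np.zeros(table.n_sites)
    c_tot = np.zeros(table.n_sites)
    for a, b in itertools.combinations(selfers, 2):
        d, c = _pair_site_diff(table, table.sample_index(a), table.sample_index(b))
        d_tot += d
        c_tot += c
    d_tot[~sel] = 0.0
    c_tot[~sel] = 0.0

    maj = _major_founder_freq(painting)
    w_chrom = painting.windows["chrom"].to_numpy()
    w_start = painting.windows["start"].to_numpy()
    w_end = painting.windows["end"].to_numpy()

    pos_all = table.sites["pos"].to_numpy()
    rows = []
    for chrom, sl in table.chrom_slices().items():
        pos = pos_all[sl]
        cd = np.concatenate([[0.0], np.cumsum(d_tot[sl])])
        cc = np.concatenate([[0.0], np.cumsum(c_tot[sl])])
        wsel = np.nonzero(w_chrom == chrom)[0]
        lo_bp = int(pos[0])
        hi_bp = int(pos[-1])
        start = lo_bp
        while start + window_bp <= hi_bp + 1:
            end = start + window_bp
            i0 = np.searchsorted(pos, start, side="left")
            i1 = np.searchsorted(pos, end, side="left")
            n_comp = cc[i1] - cc[i0]
            if n_comp >= min_sites:
                pi = (cd[i1] - cd[i0]) / n_comp
                mf = _overlap_mean(maj, w_start, w_end, wsel, start, end)
                rows.append((chrom, start, end, pi, mf, n_comp))
            start += step_bp
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "pi", "major_freq", "n_comp"]
    )
    ok = df["major_freq"].notna()
    if ok.sum() >= 3 and df.loc[ok, "pi"].std() > 0 and df.loc[ok, "major_freq"].std() > 0:
        r = float(sps.pearsonr(df.loc[ok, "major_freq"], df.loc[ok, "pi"])[0])
    else:
        r = np.nan
    return df, r


def _major_founder_freq(painting: Painting) -> np.ndarray:
    """Per painting window: frequency of the most common founder index."""
    lab = painting.labels
    out = np.full(lab.shape[0], np.nan)
    for w in range(lab.shape[0]):
        painted = lab[w][lab[w] > 0]
        if painted.size:
            out[w] = np.bincount(painted).max() / painted.size
    return out


def _overlap_mean(values, w_start, w_end, wsel, start, end) -> float:
    """bp-weighted mean of per-window values over [start, end)."""
    tot = 0.0
    wsum = 0.0
    lo = np.searchsorted(w_end[wsel], start, side="right")
    for i in wsel[lo:]:
        if w_start[i] >= end:
            break
        ov = min(end, w_end[i]) - max(start, w_start[i])
        if ov > 0 and np.isfinite(values[i]):
            tot += ov * values[i]
            wsum += ov
    return tot / wsum if wsum else np.nan


# ---------------------------------------------------------------------------
# Patterson's D
# ---------------------------------------------------------------------------


@dataclass
class DStatResult:
    d: float
    z: float
    n_sites: int
    n_blocks: int
    block_d: np.ndarray = field(repr=False, default=None)


def d_statistic(
    table: GenotypeTable,
    p1_set: list[str],
    p2_set: list[str],
    p3_set: list[str],
    ancestral_source: str = "annotation",
    block_bp: int = 1_000_000,
    block_cm: float | None = None,
) -> DStatResult:
    """Frequency-based Patterson's D with a block jackknife Z score.

    ``D = sum[(1-p1) p2 p3 - p1 (1-p2) p3] / sum[(1-p1) p2 p3 + p1 (1-p2) p3]``
    over derived-allele frequencies of the three populations; the outgroup is
    the ancestral-allele annotation (``ancestral_source='annotation'`` uses
    the sites table).  Z comes from a delete-one jackknife over contiguous
    blocks of ``block_cm`` centimorgans when a genetic map is present, else
    ``block_bp`` base pairs.
    """
    if ancestral_source != "annotation":
        raise ConfigurationError("only annotation-based polarization is supported")
    anc = table.sites["ancestral"].to_numpy()
    ok = anc != "unknown"
    if not ok.any():
        raise FittingError("no polarizable sites (ancestral allele unknown everywhere)")

    freqs = []
    for s_set in (p1_set, p2_set, p3_set):
        cols = np.array([table.sample_index(s) for s in s_set])
        g = table.genotypes[:, cols]
        called = g != MISSING
        ac = np.where(called, g, 0).sum(axis=1).astype(float)
        an = 2 * called.sum(axis=1)
        with np.errstate(invalid="ignore"):
            f = ac / an
        ok &= an > 0
        freqs.append(f)
    p1, p2, p3 = freqs
    flip = anc == "alt"
    p1 = np.where(flip, 1 - p1, p1)
    p2 = np.where(flip, 1 - p2, p2)
    p3 = np.where(flip, 1 - p3, p3)

    num = (1 - p1) * p2 * p3 - p1 * (1 - p2) * p3
    den = (1 - p1) * p2 * p3 + p1 * (1 - p2) * p3
    num = np.where(ok, num, 0.0)
    den = np.where(ok, den, 0.0)
    tot_num, tot_den = num.sum(), den.sum()
    if tot_den == 0:
        raise FittingError("no ABBA/BABA-informative sites")
    d = tot_num / tot_den

    cm = table.sites["cM"].to_numpy()
    if block_cm is not None and np.isfinite(cm).all():
        units = cm
        block_size = block_cm
    else:
        units = table.sites["pos"].to_numpy().astype(float)
        block_size = float(block_bp)
    blocks = _block_ids_from_units(table.sites["chrom"].to_numpy(), units, block_size)
    n_blk = blocks.max() + 1
    num_b = np.bincount(blocks, weights=num, minlength=n_blk)
    den_b = np.bincount(blocks, weights=den, minlength=n_blk)
    use = den_b > 0
    num_b, den_b = num_b[use], den_b[use]
    g_n = len(num_b)
    if g_n < 2:
        return DStatResult(d, np.nan, int(ok.sum()), g_n, np.array([d]))
    d_j = (tot_num - num_b) / (tot_den - den_b)
    var = (g_n - 1) / g_n * np.sum((d_j - d_j.mean()) ** 2)
    z = d / np.sqrt(var) if var > 0 else np.nan
    return DStatResult(d, z, int(ok.sum()), g_n, d_j)


def _block_ids_from_units(chroms, units, block_size) -> np.ndarray:
    ids = np.zeros(len(chroms), dtype=np.int64)
    next_id = 0
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            local = ((units[start:i] - units[start]) // block_size).astype(np.int64)
            ids[start:i] = next_id + local
            next_id = int(ids[start:i].max()) + 1
            start = i
    return ids


def d_from_counts(n_abba: float, n_baba: float) -> float:
    """D from raw ABBA/BABA counts (single-haplotype limit of the formula)."""
    if n_abba + n_baba == 0:
        raise FittingError("no informative counts")
    return (n_abba - n_baba) / (n_abba + n_baba)


# ---------------------------------------------------------------------------
# Neighbor-joining trees
# ---------------------------------------------------------------------------


def nj_from_matrix(labels: list[str], matrix: np.ndarray) -> str:
    """Saitou–Nei neighbor joining on a distance matrix; newick string."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    dm = DistanceMatrix(matrix, ids=labels)
    return str(nj(dm)).strip()


def nj_trees(
    table: GenotypeTable,
    painting: Painting | None = None,
    site_class: str | None = "4-fold",
) -> dict[str, str]:
    """All-sites, within-founder and among-founder neighbor-joining trees.

    Distance = fraction of pairwise sequence differences per comparable
    site.  The within/among variants restrict selfer-selfer entries to
    windows painted SAME/DIFFERENT for the pair; all other entries always
    use all sites.  An entry with no comparable sites raises an error naming
    the pair and variant.
    """
    ids = table.sample_ids
    n = len(ids)
    sel = _scope_mask(table, site_class, None)
    selfer_set = {s.sample_id for s in table.samples if s.species == SELFER}
    swin = _site_window_index(table, painting) if painting is not None else None

    variants = ["all"] + (["within", "among"] if painting is not None else [])
    out = {}
    for variant in variants:
        m = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            a, b = ids[i], ids[j]
            d, c = _pair_site_diff(table, i, j)
            use = sel.copy()
            if (
                variant != "all"
                and a in selfer_set
                and b in selfer_set
            ):
                status = painting.pair_status(a, b)
                code = SAME if variant == "within" else DIFFERENT
                wmask = status == code
                keep = use & (swin >= 0)
                keep[keep] = wmask[swin[keep]]
                use = keep
            n_comp = c[use].sum()
            if n_comp == 0:
                raise FittingError(
                    f"undefined distance for pair ({a}, {b}) in variant {variant!r}"
                )
            m[i, j] = m[j, i] = d[use].sum() / n_comp
        out[variant] = nj_from_matrix(ids, m)
    return out
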