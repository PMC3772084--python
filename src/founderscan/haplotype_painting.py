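"""Founding-haplotype painting from jointly polymorphic sites.

Two selfer samples that carry the same founding haplotype in a region must
be identical there at sites segregating in both the selfer and the
outcrossing relative (jointly polymorphic sites), because such variation is
almost always incompletely sorted ancestral polymorphism.  Consistent
differences at jointly polymorphic sites therefore diagnose different
founding haplotypes, and runs of identity diagnose a shared one.

The painting proceeds in stages:

1. per pair, label each jointly polymorphic site SAME / DIFFERENT / MISSING;
2. build maximal runs: SAME runs need at least ``min_same_sites`` supporting
   sites spanning at least ``min_same_bp``; DIFFERENT runs need
   ``min_diff_sites`` sites (two independent joint differences cannot arise
   within one founding haplotype absent recurrent mutation);
3. long stretches where *all* selfers are identical at many
   outcrosser-polymorphic sites are called a single shared founder for
   everyone (invariant regions);
4. the genome is cut at every run boundary and, window by window, samples
   are grouped into founder classes by transitive closure of SAME relations;
   conflicting triples (A=B, B=C, A!=C) make the whole connected component
   ambiguous, as do samples with no informative relation when others have
   one; allozygous samples are excluded up front.

No labels are extrapolated beyond supporting sites: windows without any
informative relation stay unassigned.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from founderscan.errors import ConfigurationError, ValidationError
from founderscan.genotype_model import (
    MISSING,
    GenotypeTable,
    SegmentSet,
)

# site labels for a pair
SAME = 1
DIFFERENT = -1
NO_CALL = 0

# painting label codes (per window per sample); positive = founder index
UNASSIGNED = 0
AMBIGUOUS = -1
ALLOZYGOUS = -2


@dataclass
class PaintingConfig:
    """Thresholds of the painting algorithm.

    ``min_same_sites``/``min_same_bp`` gate SAME runs (defaults: 4 jointly
    polymorphic sites over 1.5 kb); ``min_diff_sites`` gates DIFFERENT runs;
    ``min_gr_count`` is the minimum outcrosser minor-allele count for a site
    to count as outcrosser-polymorphic; invariant regions need
    ``invariant_region_bp`` span and ``invariant_region_gr_snps``
    outcrosser SNPs.  The trio scan uses its own stricter minor-count
    threshold and diversity cutoffs.
    """

    min_same_sites: int = 4
    min_same_bp: int = 1500
    min_diff_sites: int = 2
    min_gr_count: int = 1
    invariant_region_bp: int = 25_000
    invariant_region_gr_snps: int = 10
    diff_split_gr_snps: int = 10
    diff_split_bp: int = 2_000
    trio_window_sites: int = 20
    trio_min_gr_count: int = 2
    trio_pi_diff_min: float = 0.01
    trio_pi_same_max: float = 0.001

    def __post_init__(self) -> None:
        for name in (
            "min_same_sites", "min_same_bp", "min_diff_sites", "min_gr_count",
            "invariant_region_bp", "invariant_region_gr_snps",
            "trio_window_sites", "trio_min_gr_count",
        ):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")


@dataclass
class PairwiseCall:
    """SAME / DIFFERENT intervals for one sample pair.

    Intervals are half-open, non-overlapping and ordered, each spanning
    exactly its first to last supporting site.
    """

    pair: tuple[str, str]
    intervals: pd.DataFrame  # chrom, start, end, label, n_sites

    def __post_init__(self) -> None:
        df = self.intervals
        for chrom, grp in df.groupby("chrom", sort=False):
            se = grp.sort_values("start")
            if (se["start"].to_numpy()[1:] < se["end"].to_numpy()[:-1]).any():
                raise ValidationError(f"overlapping intervals for pair {self.pair}")


@dataclass
class Painting:
    """Atomic-window painting: per window, per selfer sample, a label.

    ``labels[w, s]`` is a founder index (1..n) or one of the sentinel codes
    :data:`UNASSIGNED`, :data:`AMBIGUOUS`, :data:`ALLOZYGOUS` — the
    higher-order network assignment.  ``pair_rel[w, p]`` keeps the *direct*
    pairwise evidence (SAME / DIFFERENT / NO_CALL, with invariant regions
    counting as SAME) for the pair ``pair_ids[p]``; pairwise sharing
    statistics use it rather than equality of network indices, because two
    network groups that merely lack a connecting relation are not known to
    be different founders.
    """

    windows: pd.DataFrame  # chrom, start, end
    labels: np.ndarray
    sample_ids: list[str]
    pair_ids: list[tuple[str, str]] = field(default_factory=list)
    pair_rel: np.ndarray | None = None

    def to_segments(self) -> SegmentSet:
        """Flatten to a labelled SegmentSet (merging equal-label neighbours)."""
        names = {UNASSIGNED: "UNASSIGNED", AMBIGUOUS: "AMBIGUOUS", ALLOZYGOUS: "ALLOZYGOUS"}
        records = []
        chroms = self.windows["chrom"].to_numpy()
        starts = self.windows["start"].to_numpy()
        ends = self.windows["end"].to_numpy()
        for s_idx, sid in enumerate(self.sample_ids):
            lab = self.labels[:, s_idx]
            w = 0
            while w < len(lab):
                v = w
                while (
                    v + 1 < len(lab)
                    and lab[v + 1] == lab[w]
                    and chroms[v + 1] == chroms[w]
                    and starts[v + 1] == ends[v]
                ):
                    v += 1
                name = names.get(int(lab[w]), f"HAP{int(lab[w])}")
                records.append((sid, chroms[w], int(starts[w]), int(ends[v]), name))
                w = v + 1
        return SegmentSet.from_records(records)

    def pair_status(self, a: str, b: str) -> np.ndarray:
        """Per-window pair status: SAME / DIFFERENT / NO_CALL / ALLOZYGOUS.

        Direct pairwise evidence (intervals and invariant regions); windows
        where either sample is allozygous are flagged ALLOZYGOUS, everything
        without direct evidence is NO_CALL.
        """
        ia, ib = self.sample_ids.index(a), self.sample_ids.index(b)
        try:
            p = self.pair_ids.index((a, b))
        except ValueError:
            p = self.pair_ids.index((b, a))
        out = self.pair_rel[:, p].copy()
        la, lb = self.labels[:, ia], self.labels[:, ib]
        out[(la == ALLOZYGOUS) | (lb == ALLOZYGOUS)] = ALLOZYGOUS
        return out


# ---------------------------------------------------------------------------
# Site classification
# ---------------------------------------------------------------------------


def outcrosser_polymorphic_mask(table: GenotypeTable, min_count: int = 1) -> np.ndarray:
    """Sites whose outcrosser minor-allele count is at least ``min_count``."""
    idx = table.outcrosser_indices
    if len(idx) == 0:
        return np.zeros(table.n_sites, dtype=bool)
    g = table.genotypes[:, idx]
    called = g != MISSING
    ac = np.where(called, g, 0).sum(axis=1)
    an = 2 * called.sum(axis=1)
    minor = np.minimum(ac, an - ac)
    return minor >= min_count


def joint_polymorphic_mask(table: GenotypeTable, config: PaintingConfig) -> np.ndarray:
    """Jointly polymorphic sites: segregating in both species samples."""
    gr = outcrosser_polymorphic_mask(table, config.min_gr_count)
    idx = table.selfer_indices
    g = table.genotypes[:, idx]
    has_ref = ((g == 0) | (g == 1)).any(axis=1)
    has_alt = ((g == 2) | (g == 1)).any(axis=1)
    return gr & has_ref & has_alt


def classify_joint_sites(
    table: GenotypeTable,
    pair: tuple[str, str],
    config: PaintingConfig | None = None,
    joint_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Label jointly polymorphic sites for one selfer pair.

    Returns ``(site_indices, labels)`` with labels SAME (both homozygous for
    the same allele), DIFFERENT (both homozygous, different alleles) or
    NO_CALL (either genotype missing or heterozygous).
    """
    config = config or PaintingConfig()
    if joint_mask is None:
        joint_mask = joint_polymorphic_mask(table, config)
    ia, ib = table.sample_index(pair[0]), table.sample_index(pair[1])
    site_idx = np.nonzero(joint_mask)[0]
    ga = table.genotypes[site_idx, ia]
    gb = table.genotypes[site_idx, ib]
    hom = (ga != MISSING) & (gb != MISSING) & (ga != 1) & (gb != 1)
    labels = np.full(site_idx.size, NO_CALL, dtype=np.int8)
    labels[hom & (ga == gb)] = SAME
    labels[hom & (ga != gb)] = DIFFERENT
    return site_idx, labels


# ---------------------------------------------------------------------------
# Run construction
# ---------------------------------------------------------------------------


def _runs(values: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) index runs of constant value."""
    if values.size == 0:
        return []
    change = np.nonzero(np.diff(values))[0] + 1
    bounds = np.concatenate([[0], change, [values.size]])
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(len(bounds) - 1)]


def call_pairwise_runs(
    table: GenotypeTable,
    pair: tuple[str, str],
    config: PaintingConfig | None = None,
    joint_mask: np.ndarray | None = None,
) -> PairwiseCall:
    """Maximal SAME / DIFFERENT runs for a pair, thresholded into intervals.

    Missing labels are ignored when forming runs.  A qualifying run's
    interval spans its first to its last supporting site (half-open end one
    past the last site); no extrapolation into flanking regions.

    A DIFFERENT run is additionally split wherever the gap between two
    consecutive supporting sites contains at least ``diff_split_gr_snps``
    outcrosser-polymorphic sites at which the pair is identical: two
    distinct founding haplotypes agree at any one ancestral SNP with
    appreciable probability, but identity across many consecutive ones
    contradicts distinct founders, so a DIFFERENT call must not bridge such
    a stretch.  (The stretches themselves are deliberately not painted SAME:
    two distinct founding chromosomes that coalesce shortly before the
    founding are sequence-identical over long ranges, so identity alone
    cannot distinguish shared from near-identical founders; the stretches
    are exposed by :func:`pair_identity_stretches` for use as evidence
    boundaries in diversity estimation.)
    """
    config = config or PaintingConfig()
    site_idx, labels = classify_joint_sites(table, pair, config, joint_mask)
    keep = labels != NO_CALL
    site_idx, labels = site_idx[keep], labels[keep]
    chroms = table.sites["chrom"].to_numpy()[site_idx]
    pos = table.sites["pos"].to_numpy()[site_idx]
    gr_state = _pair_gr_states(table, pair, config)
    rows = []
    offset = 0
    for chrom, cstop in _chrom_extents(chroms):
        lab = labels[offset:cstop]
        p = pos[offset:cstop]
        csel = gr_state[0] == chrom
        gp, gident = gr_state[1][csel], gr_state[2][csel]
        ip = gp[gident]
        for lo, hi in _runs(lab):
            if lab[lo] == SAME:
                n = hi - lo
                span = int(p[hi - 1] - p[lo])
                if n >= config.min_same_sites and span >= config.min_same_bp:
                    rows.append((chrom, int(p[lo]), int(p[hi - 1]) + 1, "SAME", n))
            else:
                for flo, fhi in _split_on_identity(
                    p, lo, hi, ip, config.diff_split_gr_snps, config.diff_split_bp
                ):
                    if fhi - flo >= config.min_diff_sites:
                        rows.append(
                            (chrom, int(p[flo]), int(p[fhi - 1]) + 1,
                             "DIFFERENT", fhi - flo)
                        )
        offset = cstop
    intervals = pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "n_sites"])
    if len(intervals):
        intervals = intervals.sort_values(["chrom", "start"]).reset_index(drop=True)
    return PairwiseCall(pair=tuple(pair), intervals=intervals)


def pair_identity_stretches(
    table: GenotypeTable,
    pair: tuple[str, str],
    config: PaintingConfig | None = None,
    min_sites: int | None = None,
    min_bp: int | None = None,
) -> pd.DataFrame:
    """Maximal identity stretches for a pair (chrom, start, end, n_sites).

    Runs of at least ``min_sites`` consecutive pair-identical
    outcrosser-polymorphic sites spanning at least ``min_bp`` (defaults: the
    DIFFERENT-run split thresholds).  These mark sequence that is
    inconsistent with well-separated founders — either a truly shared
    founding haplotype or two founders that coalesced shortly before the
    founding — and serve as evidence boundaries when estimating
    among-founder diversity (there, the invariant-region scale is the
    appropriate threshold, so that chance diversity fluctuations between
    two distinct founders are not excised).
    """
    config = config or PaintingConfig()
    min_sites = config.diff_split_gr_snps if min_sites is None else min_sites
    min_bp = config.diff_split_bp if min_bp is None else min_bp
    g_chrom, g_pos, g_ident = _pair_gr_states(table, pair, config)
    rows = []
    for chrom, cstop in _chrom_extents(g_chrom):
        csel = g_chrom == chrom
        gp, gi = g_pos[csel], g_ident[csel]
        for lo, hi in _runs(gi.astype(np.int8)):
            if not gi[lo]:
                continue
            n = hi - lo
            span = int(gp[hi - 1] - gp[lo])
            if n >= min_sites and span >= min_bp:
                rows.append((chrom, int(gp[lo]), int(gp[hi - 1]) + 1, n))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites"])


def _pair_gr_states(
    table: GenotypeTable, pair: tuple[str, str], config: PaintingConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(chrom, pos, identical) over pair-informative outcrosser-polymorphic sites.

    Informative means both genotypes called and homozygous; ``identical``
    flags equality.  Differing sites break identity runs.
    """
    gr = outcrosser_polymorphic_mask(table, config.min_gr_count)
    ia, ib = table.sample_index(pair[0]), table.sample_index(pair[1])
    ga = table.genotypes[:, ia]
    gb = table.genotypes[:, ib]
    informative = gr & (ga != MISSING) & (gb != MISSING) & (ga != 1) & (gb != 1)
    idx = np.nonzero(informative)[0]
    return (
        table.sites["chrom"].to_numpy()[idx],
        table.sites["pos"].to_numpy()[idx],
        (ga[idx] == gb[idx]),
    )


def _split_on_identity(
    pos: np.ndarray,
    lo: int,
    hi: int,
    ident_pos: np.ndarray,
    max_snps: int,
    min_gap_bp: int,
) -> list[tuple[int, int]]:
    """Split the site-index run [lo, hi) at long identical stretches.

    A gap between consecutive supporting sites causes a split only when it
    holds at least ``max_snps`` pair-identical outcrosser-polymorphic sites
    *and* spans at least ``min_gap_bp``: short dense agreement is expected
    chance identity between two distinct founders, whereas a long identical
    stretch is positive evidence of sharing that a DIFFERENT call must not
    bridge.
    """
    if hi - lo < 2 or ident_pos.size == 0:
        return [(lo, hi)]
    counts = np.searchsorted(ident_pos, pos[lo:hi], side="left")
    gap_ident = np.diff(counts)  # identical gr sites between consecutive supports
    gap_bp = np.diff(pos[lo:hi])
    cut = np.nonzero((gap_ident >= max_snps) & (gap_bp >= min_gap_bp))[0]
    pieces = []
    start = lo
    for c in cut:
        pieces.append((start, lo + c + 1))
        start = lo + c + 1
    pieces.append((start, hi))
    return pieces


def _chrom_extents(chroms: np.ndarray) -> list[tuple[str, int]]:
    """(chrom, stop-index) pairs over a chromosome-sorted array."""
    out = []
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            out.append((chroms[start], i))
            start = i
    return out


def call_invariant_regions(
    table: GenotypeTable, config: PaintingConfig | None = None
) -> pd.DataFrame:
    """Long stretches where all selfers match at outcrosser-polymorphic sites.

    Maximal runs of outcrosser-polymorphic sites at which every selfer with
    data carries the same homozygous genotype; runs spanning at least
    ``invariant_region_bp`` with at least ``invariant_region_gr_snps`` sites
    are returned as single-shared-founder intervals (chrom, start, end,
    n_sites).
    """
    config = config or PaintingConfig()
    gr_mask = outcrosser_polymorphic_mask(table, config.min_gr_count)
    site_idx = np.nonzero(gr_mask)[0]
    g = table.genotypes[site_idx][:, table.selfer_indices]
    called_hom = (g != MISSING) & (g != 1)
    any_het = (g == 1).any(axis=1)
    first = np.where(
        called_hom.any(axis=1),
        g[np.arange(len(site_idx)), called_hom.argmax(axis=1)],
        -9,
    )
    mismatch = (called_hom & (g != first[:, None])).any(axis=1)
    identical = ~mismatch & ~any_het
    chroms = table.sites["chrom"].to_numpy()[site_idx]
    pos = table.sites["pos"].to_numpy()[site_idx]
    rows = []
    offset = 0
    for chrom, cstop in _chrom_extents(chroms):
        ident = identical[offset:cstop]
        p = pos[offset:cstop]
        for lo, hi in _runs(ident.astype(np.int8)):
            if not ident[lo]:
                continue
            n = hi - lo
            span = int(p[hi - 1] - p[lo])
            if n >= config.invariant_region_gr_snps and span >= config.invariant_region_bp:
                rows.append((chrom, int(p[lo]), int(p[hi - 1]) + 1, n))
        offset = cstop
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites"])


# ---------------------------------------------------------------------------
# Higher-order assembly
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # root at the smaller index so numbering is order-canonical
            lo, hi = (ra, rb) if ra < rb else (rb, ra)
            self.parent[hi] = lo


def assemble_founders(
    table: GenotypeTable,
    pairwise: list[PairwiseCall],
    invariant: pd.DataFrame,
    allo_mask: SegmentSet | None = None,
    config: PaintingConfig | None = None,
) -> Painting:
    """Partition every breakpoint-delimited window into founder classes.

    The genome is cut at the union of all pairwise-interval, invariant-region
    and allozygosity-segment boundaries.  Within each window, non-allozygous
    samples are grouped by transitive closure of SAME relations; a DIFFERENT
    relation inside a closed group marks the whole group (and everything
    SAME-connected to it) ambiguous, and samples with no informative relation
    are ambiguous whenever any relation exists in the window.  Windows with
    no relations at all stay unassigned.  Founder indices are assigned in
    first-sample order; the resulting partition does not depend on sample
    input order.
    """
    config = config or PaintingConfig()
    sample_ids = [s.sample_id for s in table.samples if s.species == "selfer"]
    n_s = len(sample_ids)
    pair_index = {}
    for idx, call in enumerate(pairwise):
        a, b = call.pair
        pair_index[(a, b)] = idx
        pair_index[(b, a)] = idx
    pairs = [
        (i, j, pair_index.get((sample_ids[i], sample_ids[j])))
        for i in range(n_s)
        for j in range(i + 1, n_s)
    ]
    if any(pi is None for _, _, pi in pairs):
        raise ConfigurationError("pairwise calls must cover every selfer pair")

    allo_df = (
        allo_mask.df[allo_mask.df["label"] == "ALLOZYGOUS"]
        if allo_mask is not None
        else pd.DataFrame(columns=SegmentSet.COLUMNS)
    )

    win_frames = []
    label_blocks = []
    rel_blocks = []
    for chrom in table.sites["chrom"].unique():
        cuts = set()
        per_pair_iv = []
        for call in pairwise:
            iv = call.intervals[call.intervals["chrom"] == chrom]
            per_pair_iv.append(iv)
            cuts.update(iv["start"].tolist())
            cuts.update(iv["end"].tolist())
        inv = invariant[invariant["chrom"] == chrom] if len(invariant) else invariant
        if len(inv):
            cuts.update(inv["start"].tolist())
            cuts.update(inv["end"].tolist())
        allo_c = allo_df[allo_df["chrom"] == chrom]
        cuts.update(allo_c["start"].tolist())
        cuts.update(allo_c["end"].tolist())
        if len(cuts) < 2:
            continue
        bounds = np.array(sorted(cuts), dtype=np.int64)
        n_w = len(bounds) - 1
        mids = (bounds[:-1] + bounds[1:]) // 2

        rel = np.zeros((len(pairwise), n_w), dtype=np.int8)
        for p_i, iv in enumerate(per_pair_iv):
            if not len(iv):
                continue
            lo = np.searchsorted(mids, iv["start"].to_numpy(), side="left")
            hi = np.searchsorted(mids, iv["end"].to_numpy(), side="left")
            for s, e, lab in zip(lo, hi, iv["label"]):
                rel[p_i, s:e] = SAME if lab == "SAME" else DIFFERENT
        inv_w = np.zeros(n_w, dtype=bool)
        if len(inv):
            lo = np.searchsorted(mids, inv["start"].to_numpy(), side="left")
            hi = np.searchsorted(mids, inv["end"].to_numpy(), side="left")
            for s, e in zip(lo, hi):
                inv_w[s:e] = True
        allo_w = np.zeros((n_s, n_w), dtype=bool)
        for _, row in allo_c.iterrows():
            if row["sample_id"] not in sample_ids:
                continue
            s_i = sample_ids.index(row["sample_id"])
            s = np.searchsorted(mids, row["start"], side="left")
            e = np.searchsorted(mids, row["end"], side="left")
            allo_w[s_i, s:e] = True

        labels = np.full((n_w, n_s), UNASSIGNED, dtype=np.int8)
        for w in range(n_w):
            _label_window(
                labels[w], rel[:, w], inv_w[w], allo_w[:, w], pairs, n_s
            )
        pair_rel = rel.T.copy()
        pair_rel[inv_w, :] = SAME  # all selfers share one founder there
        win_frames.append(
            pd.DataFrame({"chrom": chrom, "start": bounds[:-1], "end": bounds[1:]})
        )
        label_blocks.append(labels)
        rel_blocks.append(pair_rel)

    if win_frames:
        windows = pd.concat(win_frames, ignore_index=True)
        all_labels = np.vstack(label_blocks)
        all_rel = np.vstack(rel_blocks)
    else:
        windows = pd.DataFrame(columns=["chrom", "start", "end"])
        all_labels = np.zeros((0, n_s), dtype=np.int8)
        all_rel = np.zeros((0, len(pairs)), dtype=np.int8)
    pair_ids = [tuple(call.pair) for call in pairwise]
    return Painting(
        windows=windows,
        labels=all_labels,
        sample_ids=sample_ids,
        pair_ids=pair_ids,
        pair_rel=all_rel,
    )


def _label_window(
    out: np.ndarray,
    rel: np.ndarray,
    is_invariant: bool,
    allo: np.ndarray,
    pairs: list[tuple[int, int, int]],
    n_s: int,
) -> None:
    """Label one window in place (one entry per selfer sample)."""
    out[allo] = ALLOZYGOUS
    active = ~allo
    if is_invariant:
        out[active] = 1
        return
    uf = _UnionFind(n_s)
    has_edge = np.zeros(n_s, dtype=bool)
    diff_edges = []
    for i, j, p_i in pairs:
        if not (active[i] and active[j]):
            continue
        r = rel[p_i]
        if r == SAME:
            uf.union(i, j)
            has_edge[i] = has_edge[j] = True
        elif r == DIFFERENT:
            diff_edges.append((i, j))
            has_edge[i] = has_edge[j] = True
    if not has_edge.any():
        return  # no informative relations: everything stays UNASSIGNED
    roots = [uf.find(i) if active[i] else -1 for i in range(n_s)]
    conflicted = set()
    for i, j in diff_edges:
        if roots[i] == roots[j]:
            conflicted.add(roots[i])
    next_hap = 1
    hap_of_root: dict[int, int] = {}
    for i in range(n_s):
        if not active[i]:
            continue
        r = roots[i]
        if r in conflicted or not has_edge[i]:
            out[i] = AMBIGUOUS
            continue
        if r not in hap_of_root:
            hap_of_root[r] = next_hap
            next_hap += 1
        out[i] = hap_of_root[r]


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def sharing_summary(
    painting: Painting, gmap: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pair sharing fractions and SAME-block length distributions.

    Fractions of the assayable genome (windows where neither sample is
    allozygous) assigned same / different / ambiguous (the latter pooling
    explicit ambiguity with unassigned stretches); they sum to 1.
    ``same_frac_assigned`` conditions on an informative call.  Lengths are
    reported in bp and, when a genetic map (chrom, pos, cM) is given, in cM.
    """
    windows = painting.windows
    bp = (windows["end"] - windows["start"]).to_numpy(dtype=float)
    if gmap is not None:
        cm_start = _cm_at(gmap, windows["chrom"], windows["start"])
        cm_end = _cm_at(gmap, windows["chrom"], windows["end"])
        cm = cm_end - cm_start
    else:
        cm = np.full(len(windows), np.nan)
    rows = []
    blocks = []
    for a, b in itertools.combinations(painting.sample_ids, 2):
        status = painting.pair_status(a, b)
        assay = status != ALLOZYGOUS
        tot_bp = bp[assay].sum()
        same_bp = bp[assay & (status == SAME)].sum()
        diff_bp = bp[assay & (status == DIFFERENT)].sum()
        amb_bp = tot_bp - same_bp - diff_bp
        row = {
            "pair": f"{a}-{b}",
            "same_frac_bp": same_bp / tot_bp if tot_bp else np.nan,
            "diff_frac_bp": diff_bp / tot_bp if tot_bp else np.nan,
            "ambig_frac_bp": amb_bp / tot_bp if tot_bp else np.nan,
            "same_frac_assigned": same_bp / (same_bp + diff_bp)
            if same_bp + diff_bp
            else np.nan,
        }
        if gmap is not None:
            tot_cm = np.nansum(cm[assay])
            row["same_frac_cM"] = np.nansum(cm[assay & (status == SAME)]) / tot_cm
            row["diff_frac_cM"] = np.nansum(cm[assay & (status == DIFFERENT)]) / tot_cm
            row["ambig_frac_cM"] = 1.0 - row["same_frac_cM"] - row["diff_frac_cM"]
        n_trans = int(
            np.sum(np.abs(np.diff((status == SAME).astype(int))) > 0)
        )
        row["n_transitions"] = n_trans
        rows.append(row)
        blocks.extend(_same_blocks(painting, a, b, status, cm))
    block_df = pd.DataFrame(
        blocks, columns=["pair", "chrom", "start", "end", "bp", "cM"]
    )
    return pd.DataFrame(rows), block_df


def _same_blocks(painting, a, b, status, cm) -> list[tuple]:
    out = []
    chroms = painting.windows["chrom"].to_numpy()
    starts = painting.windows["start"].to_numpy()
    ends = painting.windows["end"].to_numpy()
    w = 0
    n = len(status)
    while w < n:
        if status[w] != SAME:
            w += 1
            continue
        v = w
        while (
            v + 1 < n
            and status[v + 1] == SAME
            and chroms[v + 1] == chroms[w]
            and starts[v + 1] == ends[v]
        ):
            v += 1
        cm_len = float(np.nansum(cm[w : v + 1]))
        out.append(
            (f"{a}-{b}", chroms[w], int(starts[w]), int(ends[v]),
             int(ends[v] - starts[w]), cm_len)
        )
        w = v + 1
    return out


def _cm_at(gmap: pd.DataFrame, chrom: pd.Series, pos: pd.Series) -> np.ndarray:
    out = np.full(len(chrom), np.nan)
    cvals = chrom.to_numpy()
    pvals = pos.to_numpy()
    for c, grp in gmap.groupby("chrom", sort=False):
        sel = cvals == str(c)
        if not sel.any():
            continue
        mp = grp.sort_values("pos")
        out[sel] = np.interp(pvals[sel], mp["pos"].to_numpy(), mp["cM"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Trio scan for regions with more than two founding haplotypes
# ---------------------------------------------------------------------------


def trio_scan_multihap(
    table: GenotypeTable,
    config: PaintingConfig | None = None,
) -> pd.DataFrame:
    """Sliding-window trio scan for regions with three or more founders.

    For every trio of selfer samples, windows of ``trio_window_sites``
    outcrosser-common sites (minor count >= ``trio_min_gr_count``), advanced
    one site at a time, are candidates when all three per-base-pair pairwise
    diversities over the window span are at least ``trio_pi_diff_min`` (well
    above within-founder levels) and at least one trio member matches some
    non-trio sample at ``trio_pi_same_max`` per bp or below (guarding
    against misassembly-like artifacts).  Overlapping candidates are merged
    per trio.

    Returns a frame (trio, chrom, start, end, pi_ab, pi_ac, pi_bc) with the
    per-bp diversities of the merged region.
    """
    config = config or PaintingConfig()
    selfers = [s.sample_id for s in table.samples if s.species == "selfer"]
    if len(selfers) < 4:
        raise ConfigurationError("trio scan needs at least 4 selfer samples")
    scan_mask = outcrosser_polymorphic_mask(table, config.trio_min_gr_count)
    cols_out = ["trio", "chrom", "start", "end", "pi_ab", "pi_ac", "pi_bc"]
    if not scan_mask.any():
        return pd.DataFrame(columns=cols_out)

    # per-pair mismatch cumsums over *all* table sites, indexed by position
    n_sel = len(selfers)
    cols = [table.sample_index(s) for s in selfers]
    g = table.genotypes[:, cols].astype(float)
    g[g == MISSING] = np.nan
    p_all = g / 2.0
    pair_diff = {}
    for i in range(n_sel):
        for j in range(i + 1, n_sel):
            d = p_all[:, i] * (1 - p_all[:, j]) + p_all[:, j] * (1 - p_all[:, i])
            pair_diff[(i, j)] = np.nan_to_num(d)

    w = config.trio_window_sites
    pos_all = table.sites["pos"].to_numpy()
    chrom_all = table.sites["chrom"].to_numpy()
    scan_idx = np.nonzero(scan_mask)[0]
    scan_chrom = chrom_all[scan_idx]
    scan_pos = pos_all[scan_idx]
    rows = []
    offset = 0
    for chrom, cstop in _chrom_extents(scan_chrom):
        n_c = cstop - offset
        if n_c < w:
            offset = cstop
            continue
        sp = scan_pos[offset:cstop]
        all_sel = chrom_all == chrom
        pos_c = pos_all[all_sel]
        cums = {
            key: np.concatenate([[0.0], np.cumsum(pair_diff[key][all_sel])])
            for key in pair_diff
        }

        def pi_bp(key, s_bp, e_bp):
            i0 = np.searchsorted(pos_c, s_bp, side="left")
            i1 = np.searchsorted(pos_c, e_bp, side="left")
            return (cums[key][i1] - cums[key][i0]) / (e_bp - s_bp)

        win_start = sp[: n_c - w + 1]
        win_end = sp[w - 1 :] + 1
        n_w = n_c - w + 1
        span = (win_end - win_start).astype(float)
        win_pi = {}
        for key in pair_diff:
            c = cums[key]
            i0 = np.searchsorted(pos_c, win_start, side="left")
            i1 = np.searchsorted(pos_c, win_end, side="left")
            win_pi[key] = (c[i1] - c[i0]) / span
        for trio in itertools.combinations(range(n_sel), 3):
            a, b, c3 = trio
            keys = [(a, b), (a, c3), (b, c3)]
            hi = np.ones(n_w, dtype=bool)
            for key in keys:
                hi &= win_pi[key] >= config.trio_pi_diff_min
            if not hi.any():
                continue
            near = np.zeros(n_w, dtype=bool)
            for m in trio:
                for other in range(n_sel):
                    if other in trio:
                        continue
                    key = (m, other) if m < other else (other, m)
                    near |= win_pi[key] <= config.trio_pi_same_max
            cand = hi & near
            if not cand.any():
                continue
            for lo, hi_i in _runs(cand.astype(np.int8)):
                if not cand[lo]:
                    continue
                s_bp = int(win_start[lo])
                e_bp = int(win_end[hi_i - 1])
                # a historical-recombination transition between two-founder
                # tracts mimics a three-founder region over the straddling
                # span, but then some pair is undifferentiated in one half;
                # a genuine region is differentiated throughout
                mid = (s_bp + e_bp) // 2
                halves_ok = all(
                    pi_bp(key, lo_bp, hi_bp) >= config.trio_pi_diff_min
                    for key in keys
                    for lo_bp, hi_bp in ((s_bp, mid), (mid, e_bp))
                )
                if not halves_ok:
                    continue
                rows.append(
                    (
                        "-".join(selfers[t] for t in trio),
                        chrom, s_bp, e_bp,
                        pi_bp(keys[0], s_bp, e_bp),
                        pi_bp(keys[1], s_bp, e_bp),
                        pi_bp(keys[2], s_bp, e_bp),
                    )
                )
        offset = cstop
    return pd.DataFrame(rows, columns=cols_out)


# ---------------------------------------------------------------------------
# Convenience driver
# ---------------------------------------------------------------------------


def paint_genome(
    table: GenotypeTable,
    allo_mask: SegmentSet | None = None,
    config: PaintingConfig | None = None,
) -> tuple[Painting, list[PairwiseCall], pd.DataFrame]:
    """Run the full painting stack: pairwise runs, invariant regions, assembly."""
    config = config or PaintingConfig()
    selfers = [s.sample_id for s in table.samples if s.species == "selfer"]
    joint = joint_polymorphic_mask(table, config)
    calls = [
        call_pairwise_runs(table, (a, b), config, joint)
        for a, b in itertools.combinations(selfers, 2)
    ]
    invariant = call_invariant_regions(table, config)
    painting = assemble_founders(table, calls, invariant, allo_mask, config)
    return painting, calls, invariant
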