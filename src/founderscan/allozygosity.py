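"""Segmentation of selfer genomes into autozygous and allozygous tracts.

In a predominantly selfing individual most of the genome is autozygous (the
two homologous chromosomes are identical by descent) and observed
heterozygosity there is almost entirely genotyping error, distributed
uniformly along the genome.  Residual allozygous tracts from a recent
outcrossing event instead show clustered heterozygosity at a rate close to
the pairwise diversity between individuals.  This module makes that visual
criterion explicit: a two-state chain (autozygous / allozygous) with
Bernoulli heterozygosity emissions at informative sites, fitted per sample
and decoded with the Viterbi path.

Informative sites are non-singleton polymorphic sites (total minor allele
count >= 2 across the full two-species sample); singletons are strongly
error-enriched and carry no tract signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from founderscan.errors import FittingError, ValidationError
from founderscan.genotype_model import (
    MISSING,
    SELFER,
    GenotypeTable,
    SampleRecord,
    SegmentSet,
)


@dataclass
class AlloModel:
    """Two-state heterozygosity model for one selfer sample.

    ``p_auto``/``p_allo`` are per-informative-site heterozygosity
    probabilities in the autozygous (error-driven) and allozygous
    (diversity-driven) states; the switch parameters are per-site transition
    probabilities of the chain.
    """

    p_auto: float
    p_allo: float
    switch_auto_to_allo: float
    switch_allo_to_auto: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_auto < self.p_allo < 1.0):
            raise ValidationError(
                f"need 0 < p_auto ({self.p_auto}) < p_allo ({self.p_allo}) < 1"
            )
        for name in ("switch_auto_to_allo", "switch_allo_to_auto"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must be in (0,1), got {v}")


def informative_site_mask(table: GenotypeTable) -> np.ndarray:
    """Non-singleton polymorphic sites over the full sample."""
    g = table.genotypes
    called = g != MISSING
    ac = np.where(called, g, 0).sum(axis=1)
    an = 2 * called.sum(axis=1)
    minor = np.minimum(ac, an - ac)
    return minor >= 2


def _sample_obs(table: GenotypeTable, sample_id: str):
    """Informative-site observations for one sample, per chromosome."""
    j = table.sample_index(sample_id)
    mask = informative_site_mask(table) & (table.genotypes[:, j] != MISSING)
    het = table.genotypes[:, j] == 1
    out = []
    for chrom, sl in sorted(table.chrom_slices().items()):
        m = mask[sl]
        if not m.any():
            continue
        pos = table.sites["pos"].to_numpy()[sl][m]
        out.append((chrom, pos, het[sl][m]))
    return out


def _selfer_pairwise_rate(table: GenotypeTable, mask: np.ndarray) -> float:
    """Mean per-comparable-site pairwise difference among selfers at masked sites."""
    idx = table.selfer_indices
    g = table.genotypes[mask][:, idx].astype(float)
    g[g == MISSING] = np.nan
    p = g / 2.0
    tot = 0.0
    n = 0.0
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            d = p[:, a] * (1 - p[:, b]) + p[:, b] * (1 - p[:, a])
            tot += np.nansum(d)
            n += np.isfinite(d).sum()
    if n == 0:
        raise FittingError("no comparable selfer site pairs")
    return tot / n


def fit_allo_model(
    table: GenotypeTable,
    sample: SampleRecord | str,
    mean_tract_bp: float = 200_000.0,
    prior_allo_frac: float = 0.05,
    min_sites: int = 100,
) -> AlloModel:
    """Initialize and EM-refine the two-state heterozygosity model.

    ``p_allo`` starts at the sample-averaged pairwise selfer diversity per
    informative site; ``p_auto`` at the genome-wide heterozygosity rate after
    excluding the densest decile of 50-site windows (which absorb true
    tracts).  Transitions start from the prior mean tract length and a prior
    allozygous fraction.  One round of expectation-maximization refines all
    four parameters.

    Raises :class:`FittingError` for samples with too few informative sites
    or no heterozygous calls at all.
    """
    sample_id = sample.sample_id if isinstance(sample, SampleRecord) else sample
    j = table.sample_index(sample_id)
    if table.samples[j].species != SELFER:
        raise FittingError(f"{sample_id} is not a selfer sample")
    obs = _sample_obs(table, sample_id)
    het_all = np.concatenate([h for _, _, h in obs]) if obs else np.array([], bool)
    if het_all.size < min_sites:
        raise FittingError(
            f"{sample_id}: only {het_all.size} informative sites (< {min_sites})"
        )
    if not het_all.any():
        raise FittingError(f"{sample_id}: no heterozygous genotypes to model")

    mask = informative_site_mask(table)
    p_allo = _selfer_pairwise_rate(table, mask)
    # error rate: density-trimmed heterozygosity (drop densest decile of
    # 50-site windows, which contain the true allozygous tracts)
    # error rate: heterozygosity outside tract-like 50-site windows (those
    # with het density approaching p_allo are allozygous, not error)
    n_blocks = max(1, het_all.size // 50)
    blocks = np.array_split(het_all.astype(float), n_blocks)
    dens = np.array([b.mean() for b in blocks])
    keep = dens < 0.5 * p_allo
    if not keep.any():
        keep = dens <= np.quantile(dens, 0.9)
    p_auto = float(np.concatenate([b for b, k in zip(blocks, keep) if k]).mean())
    if p_auto <= 0.75 / het_all.size:
        # the trim removed essentially every heterozygote (single hets already
        # exceed the density cut when p_allo is small): fall back to the
        # genome-wide rate, which the EM step then refines downward
        p_auto = float(het_all.mean())
    p_auto = max(p_auto, 0.5 / het_all.size)
    if p_allo <= p_auto:
        p_allo = min(10.0 * p_auto, 0.5)

    genome_bp = sum(pos[-1] - pos[0] + 1 for _, pos, _ in obs)
    density = het_all.size / max(genome_bp, 1)
    sites_per_tract = max(mean_tract_bp * density, 2.0)
    a2l = min(prior_allo_frac / (1 - prior_allo_frac) / sites_per_tract, 0.4)
    l2a = min(1.0 / sites_per_tract, 0.4)
    model = AlloModel(p_auto, p_allo, a2l, l2a)
    return _em_step(obs, model)


def _chain_matrices(model: AlloModel):
    trans = np.array(
        [
            [1 - model.switch_auto_to_allo, model.switch_auto_to_allo],
            [model.switch_allo_to_auto, 1 - model.switch_allo_to_auto],
        ]
    )
    emit = np.array([model.p_auto, model.p_allo])
    a, l = model.switch_auto_to_allo, model.switch_allo_to_auto
    init = np.array([l / (a + l), a / (a + l)])  # stationary
    return trans, emit, init


def _em_step(obs, model: AlloModel) -> AlloModel:
    """One forward-backward pass; re-estimate emissions and transitions."""
    trans, emit, init = _chain_matrices(model)
    g_sum = np.zeros(2)
    g_het = np.zeros(2)
    xi_sum = np.zeros((2, 2))
    g_nonlast = np.zeros(2)
    for _, _, het in obs:
        n = het.size
        b = np.where(het[:, None], emit[None, :], 1 - emit[None, :])  # n x 2
        alpha = np.zeros((n, 2))
        c = np.zeros(n)
        alpha[0] = init * b[0]
        c[0] = alpha[0].sum()
        alpha[0] /= c[0]
        for t in range(1, n):
            alpha[t] = (alpha[t - 1] @ trans) * b[t]
            c[t] = alpha[t].sum()
            alpha[t] /= c[t]
        beta = np.zeros((n, 2))
        beta[-1] = 1.0
        for t in range(n - 2, -1, -1):
            beta[t] = (trans @ (b[t + 1] * beta[t + 1])) / c[t + 1]
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        g_sum += gamma.sum(axis=0)
        g_het += (gamma * het[:, None]).sum(axis=0)
        g_nonlast += gamma[:-1].sum(axis=0)
        for t in range(n - 1):
            xi = (alpha[t][:, None] * trans) * (b[t + 1] * beta[t + 1])[None, :]
            xi /= xi.sum()
            xi_sum += xi

    eps = 1e-9
    p_auto = float(np.clip(g_het[0] / max(g_sum[0], eps), eps, 1 - eps))
    p_allo = float(np.clip(g_het[1] / max(g_sum[1], eps), eps, 1 - eps))
    if p_allo <= p_auto:  # degenerate refit: keep the initialized separation
        p_auto, p_allo = model.p_auto, model.p_allo
    a2l = float(np.clip(xi_sum[0, 1] / max(g_nonlast[0], eps), eps, 1 - eps))
    l2a = float(np.clip(xi_sum[1, 0] / max(g_nonlast[1], eps), eps, 1 - eps))
    return AlloModel(p_auto, p_allo, a2l, l2a)


def segment_allozygous(
    table: GenotypeTable,
    sample: SampleRecord | str,
    model: AlloModel,
    merge_gap_bp: int = 50_000,
) -> SegmentSet:
    """Viterbi decoding; maximal allozygous runs become ALLOZYGOUS segments.

    Segment boundaries are placed at the midpoints between the last inside
    and first outside informative site (unbiased under symmetric
    information); at chain edges the boundary is the outermost site itself.

    A genuine tract is a mosaic: where its two haplotypes carry the same
    founding haplotype the heterozygosity signal vanishes, so the decoded
    path fragments into the signal-dense stretches.  Calls separated by
    less than ``merge_gap_bp`` are therefore merged, mirroring the visual
    smoothing a human annotator applies to cumulative-heterozygosity plots.
    """
    sample_id = sample.sample_id if isinstance(sample, SampleRecord) else sample
    trans, emit, init = _chain_matrices(model)
    log_trans = np.log(trans)
    records = []
    for chrom, pos, het in _sample_obs(table, sample_id):
        n = het.size
        log_b = np.where(
            het[:, None], np.log(emit)[None, :], np.log1p(-emit)[None, :]
        )
        v = np.zeros((n, 2))
        ptr = np.zeros((n, 2), dtype=np.int8)
        v[0] = np.log(init) + log_b[0]
        for t in range(1, n):
            cand = v[t - 1][:, None] + log_trans
            ptr[t] = cand.argmax(axis=0)
            v[t] = cand.max(axis=0) + log_b[t]
        state = np.zeros(n, dtype=np.int8)
        state[-1] = v[-1].argmax()
        for t in range(n - 2, -1, -1):
            state[t] = ptr[t + 1][state[t + 1]]
        # maximal runs of the allozygous state
        padded = np.concatenate([[0], state, [0]])
        starts = np.where(np.diff(padded) == 1)[0]
        ends = np.where(np.diff(padded) == -1)[0]  # exclusive site index
        chrom_recs = []
        for s, e in zip(starts, ends):
            left = pos[s] if s == 0 else (pos[s - 1] + pos[s]) // 2 + 1
            right = pos[e - 1] + 1 if e == n else (pos[e - 1] + pos[e]) // 2 + 1
            chrom_recs.append([int(left), int(right)])
        merged: list[list[int]] = []
        for left, right in chrom_recs:
            if merged and left - merged[-1][1] < merge_gap_bp:
                merged[-1][1] = right
            else:
                merged.append([left, right])
        records.extend(
            (sample_id, chrom, left, right, "ALLOZYGOUS") for left, right in merged
        )
    return SegmentSet.from_records(records)


def allo_summary(masks: SegmentSet, table: GenotypeTable) -> pd.DataFrame:
    """Per-sample allozygous fraction and het rates inside/outside tracts.

    The genome extent is the site-spanned length per chromosome; het rates
    are per called table site, on the same basis as ``pi_between`` (mean
    pairwise selfer difference per comparable site), so the two are directly
    comparable.
    """
    genome_bp = 0
    pos_all = table.sites["pos"].to_numpy()
    for chrom, sl in table.chrom_slices().items():
        genome_bp += int(pos_all[sl.stop - 1] - pos_all[sl.start] + 1)
    pi_between = _selfer_pairwise_rate(table, np.ones(table.n_sites, dtype=bool))
    rows = []
    for j in table.selfer_indices:
        sid = table.samples[j].sample_id
        allo_bp = masks.total_bp(sid, "ALLOZYGOUS")
        in_mask = masks.site_mask(table, sid, "ALLOZYGOUS")
        g = table.genotypes[:, j]
        called = g != MISSING
        het = g == 1
        n_in = int((called & in_mask).sum())
        n_out = int((called & ~in_mask).sum())
        rows.append(
            {
                "sample_id": sid,
                "allo_bp": allo_bp,
                "genome_bp": genome_bp,
                "allo_fraction": allo_bp / genome_bp if genome_bp else 0.0,
                "het_rate_inside": (het & in_mask).sum() / n_in if n_in else np.nan,
                "het_rate_outside": (het & ~in_mask).sum() / n_out if n_out else np.nan,
                "pi_between": pi_between,
            }
        )
    return pd.DataFrame(rows)
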