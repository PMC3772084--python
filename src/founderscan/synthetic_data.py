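"""Two-species coalescent simulator for the founding-bottleneck model.

Each genomic window is an unlinked, internally non-recombining locus.  Going
backwards in time, selfer lineages (one haplotype per predominantly selfing
sample) follow a Kingman coalescent with pair rate 1 in units of ``N_R``
generations until the scaled founding time ``T``; surviving lineages are
assigned uniformly at random to ``k`` founding chromosomes and lineages
sharing a founder merge instantly.  Founder lineages then join the ancestral
outcrossing population, where they and the outcrossing samples' lineages
(two haplotypes per diploid) coalesce at the ancestral rate.  Mutations are
dropped on branches under infinite sites at phase-appropriate rates:
``theta_selfer = 2 N_R mu`` per site inside the selfing phase and
``theta_anc = 2 N_A mu`` in the ancestral/outcrosser phase (calibrated so
expected outcrosser diversity matches a target, 1.86% at synonymous sites
by default).

Selfing is modelled through its consequences: samples are rendered
homozygous from a single haplotype, except inside injected allozygous
tracts (residual heterozygosity from a recent outcrossing event), where a
second, independently simulated haplotype produces genuine heterozygotes.
Genotyping noise adds spurious heterozygotes at a small per-genotype rate
and per-genotype missingness.  A :class:`TruthBundle` records founder labels
per window and sample, true allozygous tracts, and true ancestral alleles,
so every downstream stage can be scored against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from founderscan.errors import ConfigurationError, ValidationError
from founderscan.genotype_model import (
    MISSING,
    OUTCROSSER,
    SELFER,
    GenotypeTable,
    SampleRecord,
    SegmentSet,
    write_genotypes,
    write_segments,
)

#: Probability that the reference allele is the derived one (exercises
#: polarization: the VCF REF is then not the ancestral state).
P_REF_DERIVED = 0.3


@dataclass
class SimParams:
    """Study conditions for one synthetic genome.

    Defaults emulate the statistical structure of a recently derived selfer
    and its outcrossing relative: ancestral synonymous diversity ~1.86%,
    founding at scaled time 1.7 from many founders, within-founder diversity
    roughly an order of magnitude below genome-wide selfer diversity,
    ~7% allozygous genome fraction, 0.13% error heterozygosity, and 5%
    missingness.
    """

    n_selfer: int = 6
    n_outcrosser: int = 5
    k_founders: int = 100
    t_scaled: float = 1.7
    theta_anc: float = 0.0186
    theta_selfer: float = 0.0005
    n_windows: int = 500
    window_bp: int = 5000
    frac_fourfold: float = 0.4
    err_het: float = 0.0013
    miss_rate: float = 0.05
    f_allo: float = 0.07
    allo_mean_len: float = 200_000.0
    cm_per_mb: float = 2.7
    n_chroms: int = 8
    allo_placement: str = "random"  # or "fixed": one centred tract per chromosome
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_fourfold", "err_het", "miss_rate", "f_allo"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.k_founders < 1:
            raise ConfigurationError("k_founders must be >= 1")
        if self.t_scaled < 0:
            raise ConfigurationError("t_scaled must be >= 0")
        if self.n_windows < 1 or self.window_bp < 10:
            raise ConfigurationError("need n_windows >= 1 and window_bp >= 10")
        if self.n_selfer < 1 or self.n_outcrosser < 0:
            raise ConfigurationError("need n_selfer >= 1, n_outcrosser >= 0")


@dataclass
class TruthBundle:
    """Simulator ground truth for acceptance testing.

    ``founder`` is a window x selfer-sample table of founder indices
    (1..k_founders); ``windows`` gives each window's coordinates;
    ``allo_truth`` the injected allozygous tracts; ``ancestral`` the true
    ancestral allele per site; ``site_window`` maps each site row of the
    companion table to its window index.
    """

    windows: pd.DataFrame
    founder: pd.DataFrame
    allo_truth: SegmentSet
    ancestral: pd.DataFrame
    site_window: np.ndarray
    params: SimParams

    def __post_init__(self) -> None:
        vals = self.founder.drop(columns=["window"], errors="ignore").to_numpy()
        if vals.size and ((vals < 1) | (vals > self.params.k_founders)).any():
            raise ValidationError("founder indices outside 1..k_founders")


# ---------------------------------------------------------------------------
# Genealogy simulation
# ---------------------------------------------------------------------------


def _coalesce(
    active: list[np.ndarray],
    rng: np.random.Generator,
    t_max: float | None,
    branches: list,
    phase: str,
) -> list[np.ndarray]:
    """Kingman coalescent (pair rate 1) on leaf-set masks, truncated at t_max.

    Appends (mask, duration, phase) branch segments; returns surviving masks.
    """
    elapsed = 0.0
    active = list(active)
    while len(active) > 1:
        j = len(active)
        dt = rng.exponential(1.0 / (j * (j - 1) / 2.0))
        if t_max is not None and elapsed + dt > t_max:
            rem = t_max - elapsed
            if rem > 0:
                for mask in active:
                    branches.append((mask, rem, phase))
            return active
        for mask in active:
            branches.append((mask, dt, phase))
        elapsed += dt
        a, b = rng.choice(j, size=2, replace=False)
        merged = active[a] | active[b]
        active = [m for idx, m in enumerate(active) if idx not in (a, b)] + [merged]
    # fully coalesced before t_max: the surviving lineage still accumulates
    # mutations (shared by all its leaves) until the end of the phase
    if t_max is not None and elapsed < t_max:
        branches.append((active[0], t_max - elapsed, phase))
    return active


def simulate_window_genealogy(
    params: SimParams,
    rng: np.random.Generator,
    allo_extra: int = 0,
) -> dict:
    """Simulate one window's genealogy under the founding model.

    Haplotype (leaf) layout: indices ``0..n_selfer-1`` are the selfer
    samples' primary haplotypes, the next ``allo_extra`` are second
    haplotypes for samples allozygous in this window, and the final
    ``2 * n_outcrosser`` are outcrosser haplotypes.

    Returns a dict with ``branches`` (mask, duration, phase) where phase
    selects the mutation rate, ``founder`` (founder index per selfer-phase
    haplotype, 1-based), and ``n_haps``.
    """
    n_s = params.n_selfer + allo_extra
    n_o = 2 * params.n_outcrosser
    n_haps = n_s + n_o

    def leaf(i: int) -> np.ndarray:
        m = np.zeros(n_haps, dtype=bool)
        m[i] = True
        return m

    branches: list = []
    # Selfing phase: haploid-like lineages, pair rate 1 per N_R generations.
    selfer_active = _coalesce(
        [leaf(i) for i in range(n_s)], rng, params.t_scaled, branches, "selfer"
    )
    # Founder assignment: uniform multinomial; shared founders merge at T.
    founders = rng.integers(1, params.k_founders + 1, size=len(selfer_active))
    founder_of_hap = np.zeros(n_s, dtype=np.int64)
    merged: dict[int, np.ndarray] = {}
    for f, mask in zip(founders, selfer_active):
        founder_of_hap[mask[:n_s]] = f
        merged[f] = merged[f] | mask if f in merged else mask

    # Ancestral phase stage 1: outcrosser lineages coalesce from the present
    # back to the founding time, measured in N_A generations.
    tau_f = params.t_scaled * params.theta_selfer / params.theta_anc
    out_active = [leaf(n_s + i) for i in range(n_o)]
    if out_active:
        out_active = _coalesce(out_active, rng, tau_f, branches, "anc")
    # Stage 2: founder lineages join the ancestral pool; run to the MRCA.
    pool = list(merged.values()) + out_active
    _coalesce(pool, rng, None, branches, "anc")

    return {"branches": branches, "founder": founder_of_hap, "n_haps": n_haps}


def drop_mutations(
    genealogy: dict,
    theta_anc: float,
    theta_selfer: float,
    window_bp: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Infinite-sites mutations: boolean (site x haplotype) carrier matrix.

    Each branch receives Poisson mutations at rate ``theta_phase / 2`` per
    site per unit time; a mutation's derived allele is carried by all leaf
    haplotypes below the branch.  Row order is unordered (positions are
    assigned by the caller).
    """
    branches = genealogy["branches"]
    if not branches:
        return np.zeros((0, genealogy["n_haps"]), dtype=bool)
    masks = np.array([b[0] for b in branches], dtype=bool)
    durs = np.array([b[1] for b in branches], dtype=float)
    theta = np.where(
        np.array([b[2] for b in branches]) == "selfer", theta_selfer, theta_anc
    )
    lam = 0.5 * theta * durs * window_bp
    counts = rng.poisson(lam)
    if counts.sum() == 0:
        return np.zeros((0, genealogy["n_haps"]), dtype=bool)
    return np.repeat(masks, counts, axis=0)


# ---------------------------------------------------------------------------
# Allozygous tract injection
# ---------------------------------------------------------------------------


def _draw_allo_tracts(
    params: SimParams, chrom_lengths: dict[str, int], sample_ids: list[str],
    rng: np.random.Generator,
) -> SegmentSet:
    """Alternating exponential tracts with stationary allozygous fraction f_allo.

    With ``allo_placement='fixed'`` every selfer instead carries exactly one
    tract of length ``allo_mean_len`` centred on each chromosome (a
    controlled layout for tract-recovery evaluation).
    """
    if params.allo_placement == "fixed":
        records = []
        half = int(params.allo_mean_len) // 2
        for sid in sample_ids:
            for chrom, clen in chrom_lengths.items():
                mid = clen // 2
                start = max(1, mid - half)
                end = min(clen + 1, mid + half)
                if end > start:
                    records.append((sid, chrom, start, end, "ALLOZYGOUS"))
        return SegmentSet.from_records(records)
    if params.f_allo <= 0:
        return SegmentSet()
    mean_allo = params.allo_mean_len
    mean_auto = mean_allo * (1.0 - params.f_allo) / params.f_allo
    records = []
    for sid in sample_ids:
        for chrom, clen in chrom_lengths.items():
            pos = 1
            state_allo = rng.random() < params.f_allo
            while pos <= clen:
                length = max(1, int(rng.exponential(mean_allo if state_allo else mean_auto)))
                end = min(pos + length, clen + 1)
                if state_allo and end > pos:
                    records.append((sid, chrom, pos, end, "ALLOZYGOUS"))
                pos = end
                state_allo = not state_allo
    return SegmentSet.from_records(records)


# ---------------------------------------------------------------------------
# Genotype rendering
# ---------------------------------------------------------------------------


def _window_layout(params: SimParams) -> pd.DataFrame:
    wpc = math.ceil(params.n_windows / params.n_chroms)
    rows = []
    for w in range(params.n_windows):
        c = w // wpc
        i = w % wpc
        rows.append((w, f"chr{c + 1}", i * params.window_bp + 1, (i + 1) * params.window_bp + 1))
    return pd.DataFrame(rows, columns=["window", "chrom", "start", "end"])


def simulate_bundle(params: SimParams) -> tuple[GenotypeTable, TruthBundle]:
    """Simulate a full genotype bundle plus ground truth.

    Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    windows = _window_layout(params)
    selfer_ids = [f"R{i + 1}" for i in range(params.n_selfer)]
    out_ids = [f"G{i + 1}" for i in range(params.n_outcrosser)]
    n_greek = (params.n_selfer + 1) // 2
    samples = [
        SampleRecord(sid, SELFER, "Greek" if i < n_greek else "OutOfGreece")
        for i, sid in enumerate(selfer_ids)
    ] + [SampleRecord(sid, OUTCROSSER, "outcrosser") for sid in out_ids]
    n_samples = len(samples)

    chrom_lengths = {
        chrom: int(grp["end"].max()) - 1 for chrom, grp in windows.groupby("chrom", sort=False)
    }
    allo_truth = _draw_allo_tracts(params, chrom_lengths, selfer_ids, rng)
    allo_by_sample_chrom: dict[tuple[str, str], np.ndarray] = {}
    for (sid, chrom), grp in allo_truth.df.groupby(["sample_id", "chrom"], sort=False):
        allo_by_sample_chrom[(sid, chrom)] = grp[["start", "end"]].to_numpy()

    site_chrom: list[np.ndarray] = []
    site_pos: list[np.ndarray] = []
    site_win: list[np.ndarray] = []
    genos: list[np.ndarray] = []
    founder_rows = np.zeros((params.n_windows, params.n_selfer), dtype=np.int64)

    for w, chrom, wstart, wend in windows.itertuples(index=False):
        # which selfer samples are allozygous somewhere in this window
        allo_samples: list[tuple[int, np.ndarray]] = []
        for s_idx, sid in enumerate(selfer_ids):
            ivals = allo_by_sample_chrom.get((sid, chrom))
            if ivals is None:
                continue
            hit = ivals[(ivals[:, 0] < wend) & (ivals[:, 1] > wstart)]
            if len(hit):
                allo_samples.append((s_idx, hit))
        gen = simulate_window_genealogy(params, rng, allo_extra=len(allo_samples))
        founder_rows[w] = gen["founder"][: params.n_selfer]
        carriers = drop_mutations(
            gen, params.theta_anc, params.theta_selfer, params.window_bp, rng
        )
        n_sites = carriers.shape[0]
        if n_sites == 0:
            continue
        n_sites = min(n_sites, params.window_bp)
        # shuffle carrier rows so each mutation's position is independent of
        # its branch (rows are produced in branch order)
        carriers = carriers[rng.permutation(carriers.shape[0])[:n_sites]]
        offsets = np.sort(rng.choice(params.window_bp, size=n_sites, replace=False))
        positions = wstart + offsets

        a = carriers.astype(np.int8)
        g = np.empty((n_sites, n_samples), dtype=np.int8)
        extra_base = params.n_selfer + len(allo_samples)
        for s_idx in range(params.n_selfer):
            g[:, s_idx] = 2 * a[:, s_idx]
        for extra_i, (s_idx, ivals) in enumerate(allo_samples):
            h2 = params.n_selfer + extra_i
            in_tract = np.zeros(n_sites, dtype=bool)
            for t_start, t_end in ivals:
                in_tract |= (positions >= t_start) & (positions < t_end)
            g[in_tract, s_idx] = a[in_tract, s_idx] + a[in_tract, h2]
        for o_idx in range(params.n_outcrosser):
            h1 = extra_base + 2 * o_idx
            g[:, params.n_selfer + o_idx] = a[:, h1] + a[:, h1 + 1]

        poly = g.max(axis=1) != g.min(axis=1)
        if not poly.any():
            continue
        genos.append(g[poly])
        site_pos.append(positions[poly])
        site_chrom.append(np.full(int(poly.sum()), chrom, dtype=object))
        site_win.append(np.full(int(poly.sum()), w, dtype=np.int64))

    if genos:
        g_all = np.vstack(genos)
        pos_all = np.concatenate(site_pos)
        chrom_all = np.concatenate(site_chrom)
        win_all = np.concatenate(site_win)
    else:
        g_all = np.empty((0, n_samples), dtype=np.int8)
        pos_all = np.empty(0, dtype=np.int64)
        chrom_all = np.empty(0, dtype=object)
        win_all = np.empty(0, dtype=np.int64)
    n_sites = len(pos_all)

    # reference polarity: with prob P_REF_DERIVED the REF allele is derived
    ref_derived = rng.random(n_sites) < P_REF_DERIVED
    g_all = np.where(ref_derived[:, None], 2 - g_all, g_all).astype(np.int8)
    ancestral = np.where(ref_derived, "alt", "ref")

    # genotyping noise: spurious selfer heterozygotes, then missingness
    if params.err_het > 0 and n_sites:
        sel = slice(0, params.n_selfer)
        hom = g_all[:, sel] != 1
        flip = (rng.random(hom.shape) < params.err_het) & hom
        block = g_all[:, sel]
        block[flip] = 1
        g_all[:, sel] = block
    if params.miss_rate > 0 and n_sites:
        miss = rng.random(g_all.shape) < params.miss_rate
        g_all[miss] = MISSING

    degeneracy = np.where(rng.random(n_sites) < params.frac_fourfold, "4-fold", "0-fold")
    cm = np.empty(n_sites)
    for chrom in windows["chrom"].unique():
        m = chrom_all == chrom
        cm[m] = pos_all[m] / 1e6 * params.cm_per_mb
    sites = pd.DataFrame(
        {
            "chrom": chrom_all.astype(str),
            "pos": pos_all,
            "ref": "A",
            "alt": "C",
            "cM": cm,
            "degeneracy": degeneracy,
            "ancestral": ancestral,
        }
    )
    table = GenotypeTable(sites=sites, samples=samples, genotypes=g_all)
    founder = pd.DataFrame(founder_rows, columns=selfer_ids)
    founder.insert(0, "window", windows["window"])
    truth = TruthBundle(
        windows=windows,
        founder=founder,
        allo_truth=allo_truth,
        ancestral=pd.DataFrame(
            {"chrom": sites["chrom"], "pos": sites["pos"], "ancestral": ancestral}
        ),
        site_window=win_all,
        params=params,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Truth-based observables for the demographic model
# ---------------------------------------------------------------------------


def observations_from_truth(
    table: GenotypeTable,
    truth: TruthBundle,
    sample_ids: list[str] | None = None,
    site_class: str | None = None,
) -> tuple[np.ndarray, int, int]:
    """Within-founder SFS and single-founder region count from ground truth.

    Restricted to windows where all requested samples carry the same founder
    label; derived alleles are polarized by the true ancestral allele.
    Returns ``(sfs_counts[1..n-1], x_mono_windows, n_windows)``.
    """
    if sample_ids is None:
        sample_ids = [s.sample_id for s in table.samples if s.species == SELFER]
    n = len(sample_ids)
    if n < 2:
        raise ConfigurationError("need at least two samples for an SFS")
    fv = truth.founder[sample_ids].to_numpy()
    mono_windows = (fv == fv[:, :1]).all(axis=1)
    x = int(mono_windows.sum())

    cols = np.array([table.sample_index(s) for s in sample_ids])
    g = table.genotypes[:, cols]
    keep = mono_windows[truth.site_window]
    if site_class is not None:
        keep &= table.site_class_mask(site_class)
    keep &= (g != MISSING).all(axis=1) & (g != 1).all(axis=1)
    derived = (g[keep] // 2).sum(axis=1)
    anc_alt = (table.sites["ancestral"].to_numpy() == "alt")[keep]
    derived = np.where(anc_alt, n - derived, derived)
    counts = np.bincount(derived, minlength=n + 1)[1:n]
    return counts.astype(np.int64), x, len(truth.windows)


# ---------------------------------------------------------------------------
# Bundle output
# ---------------------------------------------------------------------------


def write_bundle(table: GenotypeTable, truth: TruthBundle, out_dir: str | Path) -> dict:
    """Write VCF + sidecar TSVs + ground-truth tables; deterministic given seed."""
    import yaml

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = write_genotypes(table, out_dir)
    truth_founder = out_dir / "founder_labels.tsv"
    truth.founder.to_csv(truth_founder, sep="\t", index=False)
    truth_windows = out_dir / "windows.tsv"
    truth.windows.to_csv(truth_windows, sep="\t", index=False)
    truth_anc = out_dir / "ancestral.tsv"
    truth.ancestral.to_csv(truth_anc, sep="\t", index=False)
    truth_allo = out_dir / "allo_truth.bed"
    write_segments(truth.allo_truth, truth_allo)
    params_path = out_dir / "params.yaml"
    with open(params_path, "w") as fh:
        yaml.safe_dump(asdict(truth.params), fh, sort_keys=True)
    paths.update(
        {
            "founder_labels": truth_founder,
            "windows": truth_windows,
            "ancestral": truth_anc,
            "allo_truth": truth_allo,
            "params": params_path,
        }
    )
    return paths
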