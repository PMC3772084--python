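"""End-to-end orchestration: genotypes -> masking -> painting -> statistics -> fit.

A run is described by a single YAML config with either an ``inputs`` block
(VCF + sidecar TSV paths) or a ``simulate`` block (:class:`SimParams`
fields).  Stages execute in a fixed order, each consuming the previous
stage's output; every artifact is listed in a manifest with its SHA-256
digest, and a rerun with the same config and seed reproduces the digests.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from founderscan import diversity_stats as ds
from founderscan.allozygosity import allo_summary, fit_allo_model, segment_allozygous
from founderscan.demographic_inference import (
    DEFAULT_MU,
    InferenceConfig,
    fit_grid,
    resolve_natural_scale,
)
from founderscan.errors import ConfigurationError, FittingError, FounderscanError
from founderscan.genotype_model import (
    SELFER,
    GenotypeTable,
    SegmentSet,
    apply_qc,
    mask_heterozygotes_in_autozygous,
    read_genotypes,
    write_segments,
)
from founderscan.haplotype_painting import (
    PaintingConfig,
    paint_genome,
    sharing_summary,
    trio_scan_multihap,
)
from founderscan.synthetic_data import SimParams, simulate_bundle, write_bundle

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated run description (one of ``inputs`` / ``simulate``)."""

    out_dir: Path
    seed: int = 0
    inputs: dict | None = None
    simulate: dict | None = None
    painting: PaintingConfig = field(default_factory=PaintingConfig)
    inference: dict = field(default_factory=dict)
    qc_min_depth: int = 10
    qc_min_qual: float = 30.0
    site_class: str = "4-fold"
    class_fraction: float | None = None
    mu: float = DEFAULT_MU
    generation_years: float = 1.0

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ConfigurationError(
                "config must have exactly one of 'inputs' or 'simulate'"
            )
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        painting = PaintingConfig(**raw.pop("painting", {}))
        return cls(painting=painting, **raw)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_digest(config: RunConfig) -> str:
    payload = {
        "inputs": config.inputs,
        "simulate": config.simulate,
        "painting": asdict(config.painting),
        "inference": config.inference,
        "seed": config.seed,
        "qc": [config.qc_min_depth, config.qc_min_qual],
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the artifact manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    t_start = time.time()

    def stage(name):
        logger.info("stage %s (t=%.1fs)", name, time.time() - t_start)

    try:
        # -- 1. data -------------------------------------------------------
        stage("data")
        truth = None
        if config.simulate is not None:
            params = SimParams(**{**config.simulate, "seed": config.seed})
            table, truth = simulate_bundle(params)
            bundle_paths = write_bundle(table, truth, out / "bundle")
            artifacts.update({f"bundle_{k}": Path(v) for k, v in bundle_paths.items()})
        else:
            table = read_genotypes(**config.inputs)

        # -- 2. QC ---------------------------------------------------------
        stage("qc")
        if table.depth is not None or table.qual is not None:
            table = apply_qc(table, config.qc_min_depth, config.qc_min_qual)

        # -- 3. allozygosity mask + het masking -----------------------------
        stage("allozygosity")
        seg_frames = []
        for s in table.samples:
            if s.species != SELFER:
                continue
            try:
                model = fit_allo_model(table, s.sample_id)
                seg_frames.append(segment_allozygous(table, s.sample_id, model).df)
            except FittingError as exc:
                logger.warning("allozygosity skipped for %s: %s", s.sample_id, exc)
        allo = (
            SegmentSet(pd.concat(seg_frames, ignore_index=True))
            if seg_frames
            else SegmentSet()
        )
        allo_path = out / "allozygous.bed"
        write_segments(allo, allo_path)
        artifacts["allozygous_mask"] = allo_path
        summary_path = out / "allozygosity_summary.tsv"
        try:
            allo_summary(allo, table).to_csv(summary_path, sep="\t", index=False)
            artifacts["allozygosity_summary"] = summary_path
        except FittingError:
            pass
        table = mask_heterozygotes_in_autozygous(table, allo)

        # -- 4. painting ----------------------------------------------------
        stage("painting")
        painting, calls, invariant = paint_genome(table, allo, config.painting)
        paint_path = out / "painting.bed"
        write_segments(painting.to_segments(), paint_path)
        artifacts["painting"] = paint_path
        gmap = None
        cm = table.sites["cM"]
        if cm.notna().any():
            gmap = table.sites.loc[cm.notna(), ["chrom", "pos", "cM"]]
        summary, blocks = sharing_summary(painting, gmap)
        sharing_path = out / "sharing_summary.tsv"
        summary.to_csv(sharing_path, sep="\t", index=False)
        artifacts["sharing_summary"] = sharing_path
        blocks_path = out / "same_blocks.tsv"
        blocks.to_csv(blocks_path, sep="\t", index=False)
        artifacts["same_blocks"] = blocks_path

        # -- 5. diversity ---------------------------------------------------
        stage("diversity")
        part = ds.partitioned_pi(
            table,
            painting,
            config.site_class,
            class_fraction=config.class_fraction,
            painting_config=config.painting,
            seed=config.seed,
        )
        part_path = out / "partitioned_pi.tsv"
        part.to_csv(part_path, sep="\t", index=False)
        artifacts["partitioned_pi"] = part_path

        selfers = [s.sample_id for s in table.samples if s.species == SELFER]
        sfs = ds.sfs_within_founders(table, painting, selfers, site_class=config.site_class)
        sfs_path = out / "sfs_within_founders.tsv"
        pd.DataFrame(
            {"derived_count": np.arange(1, sfs.n_samples), "n_sites": sfs.counts}
        ).to_csv(sfs_path, sep="\t", index=False)
        artifacts["sfs"] = sfs_path

        windows, pearson_r = ds.sliding_windows(table, painting, site_class=config.site_class)
        win_path = out / "sliding_windows.tsv"
        windows.to_csv(win_path, sep="\t", index=False)
        artifacts["sliding_windows"] = win_path

        # -- 6. trio scan, D, NJ -------------------------------------------
        stage("scan_tests")
        extras = {"pearson_r_major_freq_vs_pi": pearson_r}
        if len(selfers) >= 4:
            trio = trio_scan_multihap(table, config.painting)
            trio_path = out / "trio_scan.tsv"
            trio.to_csv(trio_path, sep="\t", index=False)
            artifacts["trio_scan"] = trio_path
        outcrossers = [s.sample_id for s in table.samples if s.species != SELFER]
        groups = {s.sample_id: s.group for s in table.samples}
        g1 = [s for s in selfers if groups[s] == "Greek"] or selfers[: len(selfers) // 2]
        g2 = [s for s in selfers if s not in g1]
        if outcrossers and g1 and g2 and (table.sites["ancestral"] != "unknown").any():
            try:
                dres = ds.d_statistic(table, g1, g2, outcrossers)
                extras["d_statistic"] = dres.d
                extras["d_z"] = dres.z
            except FittingError as exc:
                logger.warning("D statistic skipped: %s", exc)
        try:
            trees = ds.nj_trees(table, painting, config.site_class)
            nj_path = out / "nj_trees.nwk"
            with open(nj_path, "w") as fh:
                for name, nwk in trees.items():
                    fh.write(f"#{name}\n{nwk}\n")
            artifacts["nj_trees"] = nj_path
        except FittingError as exc:
            logger.warning("NJ trees skipped: %s", exc)

        # -- 7. demographic inference ----------------------------------------
        stage("inference")
        inf_kwargs = dict(config.inference)
        n_regions = inf_kwargs.pop("n_regions", None)
        if n_regions is None:
            # one independent region per cM of map, the conservative unit
            if gmap is not None:
                n_regions = max(1, int(round(gmap.groupby("chrom")["cM"].max().sum())))
            else:
                n_regions = 339
        subset = selfers[: min(4, len(selfers))]
        sfs4 = ds.sfs_within_founders(table, painting, subset, site_class=config.site_class)
        frac_mono = _all_shared_fraction(painting, subset)
        x = int(round(frac_mono * n_regions))
        inf_cfg = InferenceConfig(
            n_samples=len(subset), n_regions=n_regions,
            seed=config.seed + 1, **inf_kwargs,
        )
        fit = fit_grid(sfs4.counts, (x, n_regions), inf_cfg)
        grid_path = out / "grid_fit.tsv"
        fit.table.to_csv(grid_path, sep="\t", index=False)
        artifacts["grid_fit"] = grid_path
        within = part[(part.pair_class == "all") & (part.partition == "within")]
        resolved = {}
        pi_within = float(within["pi"].iloc[0]) if len(within) else float("nan")
        if config.class_fraction is not None and np.isfinite(pi_within) and pi_within > 0:
            r = resolve_natural_scale(
                fit, pi_within, config.mu, config.generation_years, seed=config.seed + 2
            )
            resolved = {
                "n_r": r.n_r, "t_f_years": r.t_f_years,
                "t_f_years_ci": list(r.t_f_years_ci), "g": r.g,
            }
        demo_path = out / "demography.json"
        with open(demo_path, "w") as fh:
            json.dump(
                {
                    "t_hat": fit.t_hat, "k_hat": fit.k_hat,
                    "ci_t": list(fit.ci_t), "ci_k": list(fit.ci_k),
                    "x_mono": x, "n_regions": n_regions,
                    "pi_within": pi_within,
                    **resolved, **extras,
                },
                fh, indent=2, default=float,
            )
        artifacts["demography"] = demo_path
    except FounderscanError as exc:
        raise FounderscanError(f"pipeline halted in stage with error: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "config_digest": _config_digest(config),
        "artifacts": {
            k: {"path": str(v), "sha256": _digest(v)} for k, v in artifacts.items()
        },
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _all_shared_fraction(painting, subset: list[str]) -> float:
    """bp fraction of fully-painted windows where all subset samples share one founder."""
    idx = [painting.sample_ids.index(s) for s in subset]
    lab = painting.labels[:, idx]
    bp = (painting.windows["end"] - painting.windows["start"]).to_numpy(float)
    painted = (lab > 0).all(axis=1)
    mono = painted & (lab == lab[:, :1]).all(axis=1)
    tot = bp[painted].sum()
    return float(bp[mono].sum() / tot) if tot else 0.0


def sensitivity_sweep(
    config: RunConfig,
    same_sites_grid: tuple[int, ...] = (3, 4, 6, 8),
    same_bp_grid: tuple[int, ...] = (1000, 1500, 3000),
) -> pd.DataFrame:
    """Headline outputs across painting-stringency settings.

    Re-runs site classification, painting and the partitioned statistics for
    every (min_same_sites, min_same_bp) combination on the same data,
    reporting sharing fractions, within/among diversity and the
    within-founder singleton fraction.
    """
    if config.simulate is None:
        table = read_genotypes(**config.inputs)
        truth = None
    else:
        params = SimParams(**{**config.simulate, "seed": config.seed})
        table, truth = simulate_bundle(params)
    rows = []
    selfers = [s.sample_id for s in table.samples if s.species == SELFER]
    for n_sites, n_bp in itertools.product(same_sites_grid, same_bp_grid):
        pc = PaintingConfig(
            **{
                **asdict(config.painting),
                "min_same_sites": n_sites,
                "min_same_bp": n_bp,
            }
        )
        painting, _, _ = paint_genome(table, None, pc)
        summary, _ = sharing_summary(painting)
        part = ds.partitioned_pi(
            table, painting, config.site_class,
            class_fraction=config.class_fraction, painting_config=pc, n_boot=0,
        )
        sfs = ds.sfs_within_founders(table, painting, selfers, site_class=config.site_class)
        tot = sfs.counts.sum()
        w = part[(part.pair_class == "all") & (part.partition == "within")]["pi"]
        a = part[(part.pair_class == "all") & (part.partition == "among")]["pi"]
        rows.append(
            {
                "min_same_sites": n_sites,
                "min_same_bp": n_bp,
                "same_frac": summary["same_frac_bp"].mean(),
                "diff_frac": summary["diff_frac_bp"].mean(),
                "ambig_frac": summary["ambig_frac_bp"].mean(),
                "pi_within": float(w.iloc[0]) if len(w) else np.nan,
                "pi_among": float(a.iloc[0]) if len(a) else np.nan,
                "sfs_singleton_frac": sfs.counts[0] / tot if tot else np.nan,
            }
        )
    return pd.DataFrame(rows)
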