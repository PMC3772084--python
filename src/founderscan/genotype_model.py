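"""Core data types, standard-format I/O, and QC masking.

Genotypes are stored as an integer matrix (sites x samples) of alternate
allele counts {0, 1, 2}, with :data:`MISSING` (-1) as a distinguished
sentinel.  Internal coordinates are 1-based positions; intervals are
half-open ``[start, end)``.  On disk, segments use a BED-like 5-column
dialect (chrom, start-1, end, sample_id, label) with a header row.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from founderscan.errors import ConfigurationError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Sentinel genotype code for a missing call; never conflated with 0.
MISSING: int = -1

SELFER = "selfer"
OUTCROSSER = "outcrosser"

#: Columns of the per-site annotation frame.
SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "cM", "degeneracy", "ancestral"]

DEGENERACY_LABELS = frozenset({"0-fold", "2-fold", "4-fold", "other"})
ANCESTRAL_LABELS = frozenset({"ref", "alt", "unknown"})


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced individual: identifier, species, free-form group label."""

    sample_id: str
    species: str
    group: str = ""

    def __post_init__(self) -> None:
        if self.species not in (SELFER, OUTCROSSER):
            raise ValidationError(
                f"sample {self.sample_id!r}: species must be "
                f"{SELFER!r} or {OUTCROSSER!r}, got {self.species!r}"
            )


@dataclass
class GenotypeTable:
    """Biallelic SNP x sample matrix with per-site annotation.

    Attributes
    ----------
    sites : pandas.DataFrame
        One row per site with columns ``chrom, pos, ref, alt, cM,
        degeneracy, ancestral``; positions strictly increasing within each
        chromosome.  ``cM`` is NaN where no genetic-map value is known.
    samples : list of SampleRecord
        Column order of the genotype matrix.
    genotypes : numpy.ndarray
        ``(n_sites, n_samples)`` int8 array of alternate-allele counts in
        {0, 1, 2} or :data:`MISSING`.
    depth, qual : numpy.ndarray or None
        Optional per-genotype DP and GQ values (same shape as genotypes).
    """

    sites: pd.DataFrame
    samples: list[SampleRecord]
    genotypes: np.ndarray
    depth: np.ndarray | None = None
    qual: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        n_sites, n_samples = self.genotypes.shape
        if len(self.sites) != n_sites or len(self.samples) != n_samples:
            raise ValidationError(
                f"genotype grid {self.genotypes.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        ok = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not ok.all():
            bad = np.unique(self.genotypes[~ok])
            raise ValidationError(f"invalid genotype codes {bad.tolist()}")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValidationError(f"positions not strictly increasing on {chrom}")
        bad_deg = set(self.sites["degeneracy"]) - DEGENERACY_LABELS
        if bad_deg:
            raise ValidationError(f"unknown degeneracy labels {sorted(bad_deg)}")

    # -- conveniences ------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample_index(self, sample_id: str) -> int:
        for i, s in enumerate(self.samples):
            if s.sample_id == sample_id:
                return i
        raise KeyError(sample_id)

    def indices_of(self, species: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if s.species == species], dtype=int
        )

    @property
    def selfer_indices(self) -> np.ndarray:
        return self.indices_of(SELFER)

    @property
    def outcrosser_indices(self) -> np.ndarray:
        return self.indices_of(OUTCROSSER)

    def site_class_mask(self, site_class: str) -> np.ndarray:
        """Boolean site mask for a degeneracy class ('4-fold', '0-fold', ...)."""
        return (self.sites["degeneracy"] == site_class).to_numpy()

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(
            sites=self.sites.copy(),
            samples=list(self.samples),
            genotypes=self.genotypes.copy(),
            depth=None if self.depth is None else self.depth.copy(),
            qual=None if self.qual is None else self.qual.copy(),
        )

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous row slice per chromosome (sites are chromosome-sorted)."""
        out: dict[str, slice] = {}
        chroms = self.sites["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.samples == other.samples
            and np.array_equal(self.genotypes, other.genotypes)
            and self.sites.reset_index(drop=True).equals(other.sites.reset_index(drop=True))
        )


@dataclass
class SegmentSet:
    """Per-sample labelled genomic intervals, 1-based half-open ``[start, end)``.

    Backed by a DataFrame with columns ``sample_id, chrom, start, end, label``.
    Intervals with the same label for the same sample and chromosome must not
    overlap.
    """

    COLUMNS = ["sample_id", "chrom", "start", "end", "label"]

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=SegmentSet.COLUMNS))

    def __post_init__(self) -> None:
        if list(self.df.columns) != self.COLUMNS:
            self.df = self.df.reindex(columns=self.COLUMNS)
        if len(self.df):
            self.df = self.df.astype(
                {"sample_id": str, "chrom": str, "start": np.int64, "end": np.int64, "label": str}
            )
            self.df = self.df.sort_values(["sample_id", "chrom", "start", "end"]).reset_index(
                drop=True
            )
        self.validate()

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, int, int, str]]
    ) -> "SegmentSet":
        return cls(pd.DataFrame(list(records), columns=cls.COLUMNS))

    def validate(self) -> None:
        if not len(self.df):
            return
        if (self.df["start"] >= self.df["end"]).any():
            bad = self.df[self.df["start"] >= self.df["end"]].iloc[0]
            raise ValidationError(f"empty or inverted interval {bad.to_dict()}")
        for (sid, chrom, label), grp in self.df.groupby(
            ["sample_id", "chrom", "label"], sort=False
        ):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if (starts[1:] < ends[:-1]).any():
                raise ValidationError(
                    f"overlapping {label!r} intervals for sample {sid} on {chrom}"
                )

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SegmentSet):
            return NotImplemented
        return self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))

    def for_sample(self, sample_id: str, label: str | None = None) -> pd.DataFrame:
        sel = self.df["sample_id"] == sample_id
        if label is not None:
            sel &= self.df["label"] == label
        return self.df[sel]

    def total_bp(self, sample_id: str | None = None, label: str | None = None) -> int:
        df = self.df
        if sample_id is not None:
            df = df[df["sample_id"] == sample_id]
        if label is not None:
            df = df[df["label"] == label]
        return int((df["end"] - df["start"]).sum())

    def site_mask(self, table: GenotypeTable, sample_id: str, label: str | None = None) -> np.ndarray:
        """Boolean mask over ``table`` sites covered by this sample's segments."""
        mask = np.zeros(table.n_sites, dtype=bool)
        segs = self.for_sample(sample_id, label)
        if not len(segs):
            return mask
        slices = table.chrom_slices()
        pos_all = table.sites["pos"].to_numpy()
        for chrom, grp in segs.groupby("chrom", sort=False):
            sl = slices.get(chrom)
            if sl is None:
                continue
            pos = pos_all[sl]
            for start, end in zip(grp["start"], grp["end"]):
                lo = np.searchsorted(pos, start, side="left")
                hi = np.searchsorted(pos, end, side="left")
                mask[sl.start + lo : sl.start + hi] = True
        return mask


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _read_samples_tsv(samples_path: Path) -> dict[str, SampleRecord]:
    df = pd.read_csv(samples_path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "species"}
    if not required.issubset(df.columns):
        raise FormatError(f"{samples_path}: needs columns sample_id, species")
    out = {}
    for _, row in df.iterrows():
        out[row["sample_id"]] = SampleRecord(
            sample_id=row["sample_id"], species=row["species"], group=row.get("group", "")
        )
    return out


def read_genotypes(
    vcf_path: str | Path,
    samples_path: str | Path,
    sites_path: str | Path,
    map_path: str | Path | None = None,
) -> GenotypeTable:
    """Read a VCF plus sidecar TSVs into a :class:`GenotypeTable`.

    Only biallelic SNP records are retained (multi-allelic and indel records
    are dropped with a logged count).  Sites absent from the annotation TSV
    are kept with ``degeneracy='other'`` and ``ancestral='unknown'``; sites
    without a genetic-map value get ``cM=NaN``.

    Raises
    ------
    FormatError
        If the VCF cannot be parsed.
    ConfigurationError
        If a VCF sample is missing from the sample metadata.
    """
    from cyvcf2 import VCF

    vcf_path = Path(vcf_path)
    try:
        vcf = VCF(str(vcf_path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise FormatError(f"cannot parse VCF {vcf_path}: {exc}") from exc

    meta = _read_samples_tsv(Path(samples_path))
    missing_meta = [s for s in vcf.samples if s not in meta]
    if missing_meta:
        raise ConfigurationError(
            f"VCF samples absent from metadata: {missing_meta}"
        )
    samples = [meta[s] for s in vcf.samples]

    rows: list[tuple] = []
    genos: list[np.ndarray] = []
    depths: list[np.ndarray] = []
    quals: list[np.ndarray] = []
    has_dp = has_gq = False
    n_dropped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_dropped += 1
            continue
        # with gts012=True: 0=hom ref, 1=het, 2=hom alt, 3=unknown
        g = var.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        genos.append(g)
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            has_dp = True
            depths.append(dp.reshape(-1).astype(np.int32))
        else:
            depths.append(np.full(len(samples), -1, dtype=np.int32))
        try:
            gq = var.format("GQ")
        except KeyError:
            gq = None
        if gq is not None:
            has_gq = True
            quals.append(gq.reshape(-1).astype(np.float32))
        else:
            quals.append(np.full(len(samples), np.nan, dtype=np.float32))
    if n_dropped:
        logger.info("read_genotypes: dropped %d non-biallelic-SNP records", n_dropped)

    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    sites["chrom"] = sites["chrom"].astype(str)

    ann = pd.read_csv(sites_path, sep="\t", dtype={"chrom": str, "pos": np.int64})
    if not {"chrom", "pos", "degeneracy"}.issubset(ann.columns):
        raise FormatError(f"{sites_path}: needs columns chrom, pos, degeneracy")
    if "ancestral" not in ann.columns:
        ann["ancestral"] = "unknown"
    sites = sites.merge(
        ann[["chrom", "pos", "degeneracy", "ancestral"]], on=["chrom", "pos"], how="left"
    )
    sites["degeneracy"] = sites["degeneracy"].fillna("other")
    sites["ancestral"] = sites["ancestral"].fillna("unknown")

    if map_path is not None:
        gmap = pd.read_csv(map_path, sep="\t", dtype={"chrom": str})
        sites["cM"] = _interpolate_cm(sites, gmap)
    else:
        sites["cM"] = np.nan
    sites = sites[SITE_COLUMNS]

    table = GenotypeTable(
        sites=sites,
        samples=samples,
        genotypes=np.vstack(genos) if genos else np.empty((0, len(samples)), dtype=np.int8),
        depth=np.vstack(depths) if has_dp else None,
        qual=np.vstack(quals) if has_gq else None,
    )
    table.n_dropped_records = n_dropped  # type: ignore[attr-defined]
    return table


def _interpolate_cm(sites: pd.DataFrame, gmap: pd.DataFrame) -> np.ndarray:
    """Linear interpolation of cM positions per chromosome; NaN off the map."""
    out = np.full(len(sites), np.nan)
    for chrom, grp in gmap.groupby("chrom", sort=False):
        sel = (sites["chrom"] == str(chrom)).to_numpy()
        if not sel.any():
            continue
        mp = grp.sort_values("pos")
        out[sel] = np.interp(
            sites.loc[sel, "pos"].to_numpy(),
            mp["pos"].to_numpy(),
            mp["cM"].to_numpy(),
            left=np.nan,
            right=np.nan,
        )
    return out


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_genotypes(table: GenotypeTable, out_dir: str | Path, prefix: str = "bundle") -> dict:
    """Write a table as VCF 4.2 text plus samples/sites/map sidecar TSVs.

    Returns a dict of the paths written.  Round-trips through
    :func:`read_genotypes` bit-identically on the genotype grid.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcf_path = out_dir / f"{prefix}.vcf"
    samples_path = out_dir / "samples.tsv"
    sites_path = out_dir / "sites.tsv"
    map_path = out_dir / "map.tsv"

    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    has_dp = table.depth is not None
    has_gq = table.qual is not None
    fmt = "GT" + (":DP" if has_dp else "") + (":GQ" if has_gq else "")
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=founderscan\n")
        for chrom, grp in table.sites.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if has_gq:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.sample_ids)
            + "\n"
        )
        sites = table.sites
        for i in range(table.n_sites):
            cells = []
            for j in range(table.n_samples):
                cell = gt_str[int(table.genotypes[i, j])]
                if has_dp:
                    cell += f":{int(table.depth[i, j])}"
                if has_gq:
                    q = table.qual[i, j]
                    cell += f":{int(q) if np.isfinite(q) else '.'}"
                cells.append(cell)
            fh.write(
                f"{sites['chrom'].iat[i]}\t{sites['pos'].iat[i]}\t.\t"
                f"{sites['ref'].iat[i]}\t{sites['alt'].iat[i]}\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )

    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in table.samples],
            "species": [s.species for s in table.samples],
            "group": [s.group for s in table.samples],
        }
    ).to_csv(samples_path, sep="\t", index=False)
    table.sites[["chrom", "pos", "degeneracy", "ancestral"]].to_csv(
        sites_path, sep="\t", index=False
    )
    paths = {"vcf": vcf_path, "samples": samples_path, "sites": sites_path}
    cm = table.sites["cM"]
    if cm.notna().any():
        table.sites.loc[cm.notna(), ["chrom", "pos", "cM"]].to_csv(
            map_path, sep="\t", index=False
        )
        paths["map"] = map_path
    return paths


def write_segments(segs: SegmentSet, path: str | Path) -> None:
    """Write segments as BED-like text: chrom, start-1, end, sample_id, label."""
    df = segs.df.copy()
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"] - 1,
            "end": df["end"],
            "sample_id": df["sample_id"],
            "label": df["label"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_segments(path: str | Path) -> SegmentSet:
    """Read a BED-like segments file written by :func:`write_segments`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str, "label": str})
    required = {"chrom", "start", "end", "sample_id", "label"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: needs columns {sorted(required)}")
    internal = pd.DataFrame(
        {
            "sample_id": df["sample_id"],
            "chrom": df["chrom"],
            "start": df["start"] + 1,
            "end": df["end"],
            "label": df["label"],
        }
    )
    return SegmentSet(internal)


# ---------------------------------------------------------------------------
# QC operations
# ---------------------------------------------------------------------------


def apply_qc(table: GenotypeTable, min_depth: int = 10, min_qual: float = 30.0) -> GenotypeTable:
    """Set genotypes with depth < min_depth or quality < min_qual to MISSING.

    Thresholds are inclusive: a genotype at exactly the threshold is kept.
    When the table has no depth/quality annotations the filter is a no-op
    with a warning.  Idempotent.
    """
    if min_depth < 0 or min_qual < 0:
        raise ConfigurationError("QC thresholds must be non-negative")
    if table.depth is None and table.qual is None:
        warnings.warn("apply_qc: table has no depth/quality annotations; no-op")
        return table.copy()
    out = table.copy()
    fail = np.zeros(out.genotypes.shape, dtype=bool)
    if out.depth is not None:
        fail |= out.depth < min_depth
    if out.qual is not None:
        with np.errstate(invalid="ignore"):
            fail |= np.nan_to_num(out.qual, nan=np.inf) < min_qual
    out.genotypes[fail] = MISSING
    return out


def mask_heterozygotes_in_autozygous(
    table: GenotypeTable, allo_mask: SegmentSet
) -> GenotypeTable:
    """Mask selfer heterozygosity: allozygous segments and isolated error hets.

    For every selfer sample, all genotypes inside that sample's allozygous
    segments become MISSING (the segment is unphased residual heterozygosity),
    and any remaining heterozygous genotype outside the segments (putative
    genotyping error) also becomes MISSING.  Outcrosser genotypes are
    untouched.  Idempotent.
    """
    out = table.copy()
    for j in out.selfer_indices:
        sid = out.samples[j].sample_id
        seg_mask = allo_mask.site_mask(out, sid)
        out.genotypes[seg_mask, j] = MISSING
        het = out.genotypes[:, j] == 1
        out.genotypes[het, j] = MISSING
    return out
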