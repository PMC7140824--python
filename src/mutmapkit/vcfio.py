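"""Reading and writing the standard formats the pipeline touches.

VCF and GFF3 coordinates are 1-based inclusive internally; BED output is
converted to 0-based half-open on write and back on read.  Only biallelic
sites with both alleles <= 50 bp enter the variant stream: the pooled
allele-frequency filter operates on a single alternate allele, and large
structural events are handled by coverage scanning instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

MAX_ALLELE_LEN = 50


@dataclass(frozen=True)
class SampleCounts:
    """Per-sample allele depths at one site: reads supporting ref and alt."""

    ref_count: int
    alt_count: int
    depth: int
    missing: bool = False

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("allele depths must be non-negative")
        if self.depth < self.ref_count + self.alt_count:
            raise ValueError("total depth below ref+alt depth")


@dataclass
class VariantRecord:
    """One biallelic site with per-sample allele depths."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    samples: dict[str, SampleCounts]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt or self.ref == self.alt:
            raise ValueError("ref and alt must be non-empty and different")


@dataclass(frozen=True)
class SampleRoles:
    """Binding of VCF sample names to the four pedigree roles.

    parent_wt      -- the unmutagenized parent individual
    mutant_line    -- the homozygous mutant line (pooled siblings)
    f2_mut_pool    -- F2 plants selected for the mutant phenotype
    f2_wt_pool     -- F2 plants with wild-type phenotype
    """

    parent_wt: str
    mutant_line: str
    f2_mut_pool: str
    f2_wt_pool: str

    def __post_init__(self) -> None:
        names = self.as_tuple()
        if len(set(names)) != 4:
            raise ValueError(f"role sample names must be distinct, got {names}")

    def as_tuple(self) -> tuple[str, str, str, str]:
        return (self.parent_wt, self.mutant_line, self.f2_mut_pool, self.f2_wt_pool)

    def as_dict(self) -> dict[str, str]:
        return {
            "parent_wt": self.parent_wt,
            "mutant_line": self.mutant_line,
            "f2_mut_pool": self.f2_mut_pool,
            "f2_wt_pool": self.f2_wt_pool,
        }


DEFAULT_ROLES = SampleRoles(
    parent_wt="ML10", mutant_line="E1-9", f2_mut_pool="F2-mutant-pool", f2_wt_pool="F2-WT-pool"
)


@dataclass(frozen=True)
class GeneFeature:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")


@dataclass
class DepthTrack:
    """Per-base read depth for one sample over a contiguous 1-based interval."""

    sample: str
    chrom: str
    start: int  # 1-based position of depths[0]
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if self.depths.ndim != 1:
            raise ValueError("depths must be one-dimensional")
        if len(self.depths) and self.depths.min() < 0:
            raise ValueError("depths must be non-negative")

    @property
    def end(self) -> int:
        """Last covered 1-based position (inclusive)."""
        return self.start + len(self.depths) - 1

    def covers(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end


# ---------------------------------------------------------------------------
# VCF


def _counts_from_ad(ad, depth) -> SampleCounts:
    if ad is None or len(ad) < 2 or ad[0] is None:
        return SampleCounts(0, 0, 0, missing=True)
    ref_c, alt_c = int(ad[0]), int(ad[1])
    dp = int(depth) if depth is not None else ref_c + alt_c
    dp = max(dp, ref_c + alt_c)
    return SampleCounts(ref_c, alt_c, dp)


def read_vcf(path: str | Path, roles: SampleRoles | None = None) -> Iterator[VariantRecord]:
    """Stream biallelic simple variants from a VCF (plain or bgzipped).

    Multi-allelic sites and sites where either allele exceeds 50 bp are
    dropped (counted and logged).  A sample with missing AD yields zero
    counts flagged ``missing``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with pysam.VariantFile(str(path)) as vcf:
        header_samples = list(vcf.header.samples)
        if roles is not None:
            for role, name in roles.as_dict().items():
                if name not in header_samples:
                    raise KeyError(
                        f"role {role} sample {name!r} not in VCF header "
                        f"(samples: {header_samples})"
                    )
        n_multi = n_long = 0
        for i, rec in enumerate(vcf, start=1):
            alts = rec.alts
            if alts is None or len(alts) != 1:
                n_multi += 1
                continue
            ref, alt = rec.ref, alts[0]
            if len(ref) > MAX_ALLELE_LEN or len(alt) > MAX_ALLELE_LEN or alt in ("*", "<*>"):
                n_long += 1
                continue
            try:
                samples = {
                    name: _counts_from_ad(rec.samples[name].get("AD"), rec.samples[name].get("DP"))
                    for name in header_samples
                }
                yield VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt,
                    qual=float(rec.qual) if rec.qual is not None else 0.0,
                    samples=samples,
                )
            except ValueError as exc:
                raise ValueError(f"{path}: malformed record #{i} at {rec.chrom}:{rec.pos}: {exc}")
        if n_multi or n_long:
            log.info(
                "%s: dropped %d multi-allelic and %d long-allele records", path, n_multi, n_long
            )


def load_vcf(path: str | Path, roles: SampleRoles | None = None) -> list[VariantRecord]:
    return list(read_vcf(path, roles))


def write_vcf(
    records: Iterable[VariantRecord],
    sample_names: Sequence[str],
    contigs: Sequence[tuple[str, int]],
    path: str | Path,
) -> Path:
    """Write records to a VCF v4.2 file with AD/DP FORMAT fields."""
    path = Path(path)
    header = pysam.VariantHeader()
    for name, length in contigs:
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths for the ref and alt alleles")
    header.formats.add("DP", 1, "Integer", "Read depth")
    for name in sample_names:
        header.add_sample(name)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            vrec = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                stop=rec.pos - 1 + len(rec.ref),
                alleles=(rec.ref, rec.alt),
                qual=rec.qual,
            )
            for name in sample_names:
                counts = rec.samples[name]
                vrec.samples[name]["AD"] = (counts.ref_count, counts.alt_count)
                vrec.samples[name]["DP"] = counts.depth
                if counts.missing:
                    vrec.samples[name]["GT"] = (None, None)
                elif counts.ref_count == 0 and counts.alt_count > 0:
                    vrec.samples[name]["GT"] = (1, 1)
                elif counts.alt_count == 0:
                    vrec.samples[name]["GT"] = (0, 0)
                else:
                    vrec.samples[name]["GT"] = (0, 1)
            out.write(vrec)
    return path


# ---------------------------------------------------------------------------
# GFF3


def read_gff(path: str | Path) -> list[GeneFeature]:
    """Extract features of type ``gene`` from a GFF3 file.

    Returns 1-based inclusive coordinates sorted by (chrom, start).
    """
    import gffutils

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genes: list[GeneFeature] = []
    if path.stat().st_size == 0:
        return genes
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    for feat in db.features_of_type("gene"):
        if feat.end < feat.start:
            raise ValueError(f"{path}: gene {feat.id} has end < start")
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        genes.append(
            GeneFeature(chrom=feat.seqid, start=feat.start, end=feat.end, strand=strand,
                        gene_id=feat.id)
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def read_gff_exons(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Exon intervals (1-based inclusive) keyed by parent gene id, if present."""
    import gffutils

    db = gffutils.create_db(
        str(Path(path)), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    for gene in db.features_of_type("gene"):
        ivals = [
            (e.start, e.end)
            for e in db.children(gene, featuretype="exon", order_by="start")
        ]
        if ivals:
            exons[gene.id] = ivals
    return exons


# ---------------------------------------------------------------------------
# BED and depth TSV


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> Path:
    """Write (chrom, start, end) 1-based inclusive intervals as BED3 (0-based half-open)."""
    path = Path(path)
    rows = [(chrom, start - 1, end) for chrom, start, end in intervals]
    pd.DataFrame(rows, columns=["chrom", "start", "end"]).to_csv(
        path, sep="\t", header=False, index=False
    )
    return path


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED3 back to 1-based inclusive intervals (inverse of :func:`write_bed`)."""
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"], comment="#")
    return [(str(r.chrom), int(r.start) + 1, int(r.end)) for r in df.itertuples()]


def write_depth_tsv(track: DepthTrack, path: str | Path) -> Path:
    """Write a per-base depth track as chrom / pos (1-based) / depth TSV."""
    path = Path(path)
    pd.DataFrame(
        {
            "chrom": track.chrom,
            "pos": np.arange(track.start, track.start + len(track.depths)),
            "depth": track.depths,
        }
    ).to_csv(path, sep="\t", header=False, index=False)
    return path


def read_depth_tsv(path: str | Path, sample: str) -> DepthTrack:
    """Read a chrom/pos/depth TSV covering one contiguous interval."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "depth"])
    if df.empty:
        raise ValueError(f"{path}: empty depth track")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError(f"{path}: depth track spans multiple chromosomes: {chroms}")
    pos = df["pos"].to_numpy()
    if not np.array_equal(pos, np.arange(pos[0], pos[0] + len(pos))):
        raise ValueError(f"{path}: depth positions are not contiguous")
    return DepthTrack(sample=sample, chrom=str(chroms[0]), start=int(pos[0]),
                      depths=df["depth"].to_numpy())
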