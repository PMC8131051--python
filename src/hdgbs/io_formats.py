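"""Readers/writers for on-disk formats and the in-memory genotype containers.

Conventions
-----------
* Coordinates are 0-based half-open everywhere in memory; VCF positions
  (1-based) are converted at the boundary.
* Genome sequences are uppercased on load and restricted to {A,C,G,T,N}.
* Genotype dosages are stored as int8 with ``MISSING`` (-1) for no-calls.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

MISSING = -1
_VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """A file violated the subset of its format this toolkit defines."""


class Variant(NamedTuple):
    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str


@dataclass
class Genome:
    """An ordered collection of named chromosome/contig sequences."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        upper: list[tuple[str, str]] = []
        for i, (name, seq) in enumerate(self.records):
            if not name:
                raise FormatError(f"record {i + 1}: empty sequence name")
            if name in seen:
                raise FormatError(f"record {i + 1}: duplicate sequence name {name!r}")
            seen.add(name)
            seq = seq.upper()
            if not seq:
                raise FormatError(f"record {i + 1} ({name}): empty sequence")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise FormatError(
                    f"record {i + 1} ({name}): illegal character(s) "
                    f"{sorted(bad)}; expected A/C/G/T/N"
                )
            upper.append((name, seq))
        self.records = upper

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.records]

    def __getitem__(self, name: str) -> str:
        for n, s in self.records:
            if n == name:
                return s
        raise KeyError(name)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.records)


@dataclass
class GenotypeMatrix:
    """Samples x variants biallelic dosage matrix with a missing mask.

    ``dosage`` entries are 0/1/2 (alternate-allele count) or ``MISSING``.
    ``depth`` is an optional samples x variants matrix of read counts
    supporting each call.
    """

    sample_ids: list[str]
    variants: list[Variant]
    dosage: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        shape = (len(self.sample_ids), len(self.variants))
        if self.dosage.shape != shape:
            raise ValueError(
                f"dosage shape {self.dosage.shape} != (samples, variants) {shape}"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(
                f"dosage entries must be 0/1/2/{MISSING}; found "
                f"{np.unique(self.dosage[bad])}"
            )
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=np.int32)
            if self.depth.shape != shape:
                raise ValueError("depth shape does not match dosage shape")
            if (self.depth < 0).any():
                raise ValueError("depth entries must be non-negative")
            if self.depth.size == 0:  # empty matrix: depth carries no information
                self.depth = None

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids),
            list(self.variants),
            self.dosage.copy(),
            None if self.depth is None else self.depth.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        if self.sample_ids != other.sample_ids or self.variants != other.variants:
            return False
        if not np.array_equal(self.dosage, other.dosage):
            return False
        if (self.depth is None) != (other.depth is None):
            return False
        return self.depth is None or np.array_equal(self.depth, other.depth)


@dataclass
class HaplotypePanel:
    """A reference panel: haplotypes x variants matrix of 0/1 alleles.

    No missing entries are allowed; monomorphic variants are flagged rather
    than rejected.
    """

    haplotype_ids: list[str]
    alleles: np.ndarray
    variants: list[Variant]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        shape = (len(self.haplotype_ids), len(self.variants))
        if self.alleles.shape != shape:
            raise ValueError(
                f"alleles shape {self.alleles.shape} != (haplotypes, variants) {shape}"
            )
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("panel alleles must be 0/1 with no missing entries")

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def monomorphic(self) -> np.ndarray:
        """Boolean flag per variant: all panel haplotypes carry one allele."""
        return self.alleles.min(axis=0) == self.alleles.max(axis=0)


# ---------------------------------------------------------------------------
# FASTA


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, mode)
        return open(path, mode)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> Genome:
    """Load a FASTA file (plain or gzip) into a :class:`Genome`.

    Sequences are uppercased; any character outside A/C/G/T/N raises a
    :class:`FormatError` identifying the offending record.
    """
    records: list[tuple[str, str]] = []
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fasta"):
                records.append((rec.id, str(rec.seq)))
        except ValueError as exc:
            raise FormatError(f"{path}: not valid FASTA ({exc})") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return Genome(records)


def write_fasta(genome: Genome, path: str | Path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in genome:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path, return_skipped: bool = False):
    """Read a VCF 4.x into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are kept; multi-allelic and indel records are
    skipped with a logged count. GT is required; per-genotype depth is taken
    from the AD sum when present, else DP, else omitted.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[Variant] = []
    dosage_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    any_depth = False
    n_skipped = 0

    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        if "GT" not in (v.FORMAT or []):
            raise FormatError(
                f"{path}: record {v.CHROM}:{v.POS} has no GT format field"
            )
        row = np.full(len(samples), MISSING, dtype=np.int8)
        for si, gt in enumerate(v.genotypes):
            alleles = gt[:-1]
            if len(alleles) == 2 and alleles[0] >= 0 and alleles[1] >= 0:
                row[si] = alleles[0] + alleles[1]
        dosage_rows.append(row)

        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if ad is not None:
            d = np.clip(ad, 0, None).sum(axis=1).astype(np.int32)
            any_depth = True
        else:
            try:
                dp = v.format("DP")
            except KeyError:
                dp = None
            if dp is not None:
                d = np.clip(dp.reshape(-1), 0, None).astype(np.int32)
                any_depth = True
            else:
                d = np.zeros(len(samples), dtype=np.int32)
        depth_rows.append(d)
        variants.append(Variant(v.CHROM, v.POS, v.REF, v.ALT[0]))

    if n_skipped:
        logger.info("read_vcf(%s): skipped %d non-biallelic-SNP records", path, n_skipped)

    dosage = (
        np.array(dosage_rows, dtype=np.int8).T
        if dosage_rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    depth = (
        np.array(depth_rows, dtype=np.int32).T
        if (depth_rows and any_depth)
        else None
    )
    matrix = GenotypeMatrix(samples, variants, dosage, depth)
    if return_skipped:
        return matrix, n_skipped
    return matrix


def write_vcf(
    matrix: GenotypeMatrix, path: str | Path, extra_header: Sequence[str] = ()
) -> None:
    """Write a GenotypeMatrix as an unphased VCF 4.2 (round-trips with read_vcf)."""
    has_depth = matrix.depth is not None
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in extra_header:
            fh.write(line.rstrip("\n") + "\n")
        for chrom in dict.fromkeys(v.chrom for v in matrix.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_depth:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        fmt = "GT:DP" if has_depth else "GT"
        for j, var in enumerate(matrix.variants):
            cells = []
            for i in range(matrix.n_samples):
                cell = gt_map[int(matrix.dosage[i, j])]
                if has_depth:
                    cell += f":{int(matrix.depth[i, j])}"
                cells.append(cell)
            fh.write(
                f"{var.chrom}\t{var.pos}\t.\t{var.ref}\t{var.alt}\t.\t.\t.\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )


def write_panel_vcf(
    panel: HaplotypePanel, path: str | Path, extra_header: Sequence[str] = ()
) -> None:
    """Write a haplotype panel as a phased diploid VCF (haplotypes paired in order).

    An odd trailing haplotype is paired with itself and dropped on read, so
    panels written this way should have an even number of haplotypes.
    """
    if panel.n_haplotypes % 2:
        raise ValueError("panel VCF export requires an even number of haplotypes")
    sample_ids = [
        f"{panel.haplotype_ids[2 * i]}|{panel.haplotype_ids[2 * i + 1]}"
        for i in range(panel.n_haplotypes // 2)
    ]
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in extra_header:
            fh.write(line.rstrip("\n") + "\n")
        for chrom in dict.fromkeys(v.chrom for v in panel.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for j, var in enumerate(panel.variants):
            cells = [
                f"{panel.alleles[2 * i, j]}|{panel.alleles[2 * i + 1, j]}"
                for i in range(panel.n_haplotypes // 2)
            ]
            fh.write(
                f"{var.chrom}\t{var.pos}\t.\t{var.ref}\t{var.alt}\t.\t.\t.\tGT\t"
                + "\t".join(cells)
                + "\n"
            )


def read_panel_vcf(path: str | Path) -> HaplotypePanel:
    """Read a phased VCF as a haplotype panel (two haplotypes per sample)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    hap_ids: list[str] = []
    for s in samples:
        if "|" in s:
            hap_ids.extend(s.split("|", 1))
        else:
            hap_ids.extend([f"{s}_h1", f"{s}_h2"])
    variants: list[Variant] = []
    cols: list[np.ndarray] = []
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        col = np.empty(2 * len(samples), dtype=np.uint8)
        for si, gt in enumerate(v.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                raise FormatError(
                    f"{path}: panel VCF has a missing genotype at {v.CHROM}:{v.POS}"
                )
            col[2 * si], col[2 * si + 1] = a, b
        cols.append(col)
        variants.append(Variant(v.CHROM, v.POS, v.REF, v.ALT[0]))
    alleles = (
        np.array(cols, dtype=np.uint8).T
        if cols
        else np.zeros((len(hap_ids), 0), dtype=np.uint8)
    )
    return HaplotypePanel(hap_ids, alleles, variants)


# ---------------------------------------------------------------------------
# BED


def write_bed(fragments: Sequence, path: str | Path, header: Sequence[str] = ()) -> None:
    """Write digestion fragments as BED3+ (name = leftEnzyme|rightEnzyme, score = length).

    Fragments must already be sorted by (chrom, start); unsorted input is an
    error — the caller sorts.
    """
    keys = [(f.chrom, f.start) for f in fragments]
    if keys != sorted(keys):
        raise ValueError("fragments must be sorted by (chrom, start) before export")
    with _open_text(path, "wt") as fh:
        for line in header:
            fh.write(line.rstrip("\n") + "\n")
        for f in fragments:
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t"
                f"{f.left_enzyme}|{f.right_enzyme}\t{f.end - f.start}\n"
            )


def read_bed(path: str | Path) -> list:
    """Read a BED3+ file written by :func:`write_bed` back into fragments."""
    from .digestion import Fragment

    fragments = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            left, right = (parts[3].split("|", 1) + ["NA"])[:2] if len(parts) > 3 else ("NA", "NA")
            fragments.append(Fragment(chrom, start, end, left, right))
    return fragments
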