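"""GBS library simulation: barcoded paired-end reads, demultiplexing, and
skim-seq-style read subsampling.

The simulator is deliberately minimal: the sample's inline well barcode is
prepended to read 1 (standard GBS layout), the plate barcode lives in
file/lane metadata rather than in the read, quality strings are constant, and
the only error model is an optional uniform substitution rate (default 0).
Depth and demultiplexing logic — not base accuracy — is what downstream
analyses exercise.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .digestion import Fragment, reverse_complement
from .io_formats import Genome, _open_text

_BASES = np.array(list("ACGT"))


class ReadPair(NamedTuple):
    name: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


@dataclass
class BarcodeSet:
    """sample_id -> (well barcode, optional plate barcode).

    Within a plate, no well barcode may be a prefix of another (decodability)
    and (well, plate) pairs must be unique.
    """

    entries: dict[str, tuple[str, str | None]]

    def __post_init__(self) -> None:
        pairs: set[tuple[str, str | None]] = set()
        by_plate: dict[str | None, list[str]] = {}
        for sample, (well, plate) in self.entries.items():
            if not 4 <= len(well) <= 10 or set(well) - set("ACGT"):
                raise ValueError(
                    f"{sample}: well barcode must be 4-10 bp over A/C/G/T, got {well!r}"
                )
            if (well, plate) in pairs:
                raise ValueError(f"duplicate (well, plate) barcode pair for {sample}")
            pairs.add((well, plate))
            by_plate.setdefault(plate, []).append(well)
        for plate, wells in by_plate.items():
            wells = sorted(wells)
            for a, b in zip(wells, wells[1:]):
                if b.startswith(a):
                    raise ValueError(
                        f"plate {plate!r}: barcode {a} is a prefix of {b} "
                        "(ambiguous demultiplexing)"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.entries)

    def plate_entries(self, plate: str | None = None) -> dict[str, str]:
        """sample -> well barcode for one plate (None selects samples with no plate)."""
        return {
            s: well for s, (well, p) in self.entries.items() if p == plate
        }

    @property
    def plates(self) -> list[str | None]:
        return sorted({p for _, p in self.entries.values()}, key=lambda p: (p is not None, p))


def make_barcode_set(
    sample_ids: Sequence[str],
    barcode_length: int = 6,
    plate_size: int = 96,
    seed: int = 0,
) -> BarcodeSet:
    """Generate distinct fixed-length well barcodes, assigning plates of
    ``plate_size`` samples (plate barcode omitted when one plate suffices)."""
    n = len(sample_ids)
    n_plates = -(-n // plate_size)
    per_plate = min(n, plate_size)
    rng = np.random.default_rng(seed)
    space = 4**barcode_length
    if per_plate > space:
        raise ValueError("barcode_length too short for plate_size")
    codes = rng.permutation(space)[:per_plate]
    digits = (codes[:, None] // 4 ** np.arange(barcode_length)[::-1]) % 4
    wells = ["".join(_BASES[d]) for d in digits]
    entries: dict[str, tuple[str, str | None]] = {}
    for i, sample in enumerate(sample_ids):
        plate = None if n_plates == 1 else f"P{i // plate_size + 1:02d}"
        entries[sample] = (wells[i % plate_size], plate)
    return BarcodeSet(entries)


def write_barcode_tsv(barcodes: BarcodeSet, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("sample\twell_barcode\tplate_barcode\n")
        for sample, (well, plate) in barcodes.entries.items():
            fh.write(f"{sample}\t{well}\t{plate or '.'}\n")


def read_barcode_tsv(path: str | Path) -> BarcodeSet:
    entries: dict[str, tuple[str, str | None]] = {}
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#") or line.startswith("sample\t"):
                continue
            parts = line.rstrip("\n").split("\t")
            sample, well = parts[0], parts[1]
            plate = parts[2] if len(parts) > 2 and parts[2] not in (".", "") else None
            entries[sample] = (well, plate)
    return BarcodeSet(entries)


# ---------------------------------------------------------------------------
# simulation


def simulate_reads(
    genome: Genome,
    fragments: Sequence[Fragment],
    barcodes: BarcodeSet,
    pairs_per_sample: int,
    read_length: int = 150,
    seed: int = 0,
    substitution_rate: float = 0.0,
) -> list[ReadPair]:
    """Simulate one lane of barcoded paired-end GBS reads.

    For each sample, ``pairs_per_sample`` fragments are drawn uniformly with
    replacement. Read 1 is the well barcode followed by the fragment's 5'
    prefix; read 2 is the reverse complement of the fragment's 3' suffix.
    Reads are truncated (not padded) at short fragments. Deterministic for a
    given seed; read names encode sample, fragment index and copy number.
    """
    if not barcodes.entries:
        raise ValueError("barcode set is empty")
    if not fragments:
        raise ValueError("no fragments to simulate from")
    frag_seqs = [genome[f.chrom][f.start : f.end] for f in fragments]
    rng = np.random.default_rng(seed)
    reads: list[ReadPair] = []
    for sample, (well, _plate) in barcodes.entries.items():
        draws = rng.integers(0, len(fragments), size=pairs_per_sample)
        for copy, fi in enumerate(draws):
            frag = frag_seqs[fi]
            seq1 = (well + frag)[:read_length]
            seq2 = reverse_complement(frag[-read_length:])
            if substitution_rate > 0:
                seq1 = _mutate(seq1, substitution_rate, rng)
                seq2 = _mutate(seq2, substitution_rate, rng)
            name = f"{sample}:{fi}:{copy}"
            reads.append(ReadPair(name, seq1, "I" * len(seq1), seq2, "I" * len(seq2)))
    return reads


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def write_fastq_pair(
    reads: Iterable[ReadPair], path1: str | Path, path2: str | Path
) -> None:
    """Write mate files (gzip if the path ends in .gz)."""
    op = lambda p: gzip.open(p, "wt") if str(p).endswith(".gz") else open(p, "w")
    with op(path1) as f1, op(path2) as f2:
        for r in reads:
            f1.write(f"@{r.name}/1\n{r.seq1}\n+\n{r.qual1}\n")
            f2.write(f"@{r.name}/2\n{r.seq2}\n+\n{r.qual2}\n")


def read_fastq_pair(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Iterate synchronized mates from a FASTQ file pair (plain or gzip)."""
    with _open_text(path1) as f1, _open_text(path2) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        for (t1, s1, q1), (t2, s2, q2) in zip(it1, it2, strict=True):
            name = t1.split()[0].removesuffix("/1")
            yield ReadPair(name, s1, q1, s2, q2)


# ---------------------------------------------------------------------------
# demultiplexing


@dataclass
class DemuxResult:
    per_sample: dict[str, list[ReadPair]]
    undetermined: list[ReadPair]
    counts: pd.DataFrame  # columns: sample, n_pairs

    @property
    def n_undetermined(self) -> int:
        return len(self.undetermined)

    @property
    def mean_pairs(self) -> float:
        return float(self.counts["n_pairs"].mean())

    @property
    def cv_pairs(self) -> float:
        """Coefficient of variation of per-sample pair counts."""
        m = self.counts["n_pairs"].mean()
        return float(self.counts["n_pairs"].std(ddof=0) / m) if m else float("nan")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: Iterable[ReadPair],
    barcodes: BarcodeSet,
    max_mismatch: int = 0,
    plate: str | None = None,
) -> DemuxResult:
    """Assign read pairs to samples by the inline barcode at the start of read 1.

    The plate barcode is lane/file metadata: ``plate`` selects which plate's
    well barcodes apply. A read matching no barcode — or, at
    ``max_mismatch=1``, matching two or more equally well — goes to the
    undetermined bin. Barcodes are trimmed from assigned reads. Per-sample
    counts, their mean and coefficient of variation are tabulated.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    wells = barcodes.plate_entries(plate)
    if not wells and plate is None and len(barcodes.plates) == 1:
        wells = barcodes.plate_entries(barcodes.plates[0])
    if not wells:
        raise ValueError(f"no barcodes for plate {plate!r}")
    exact = {well: sample for sample, well in wells.items()}
    lengths = sorted({len(w) for w in exact})

    per_sample: dict[str, list[ReadPair]] = {s: [] for s in wells}
    undetermined: list[ReadPair] = []
    for r in reads:
        assigned: list[tuple[str, str]] = []  # (sample, well)
        for ell in lengths:
            prefix = r.seq1[:ell]
            hit = exact.get(prefix)
            if hit is not None:
                assigned.append((hit, prefix))
        if not assigned and max_mismatch == 1:
            for sample, well in wells.items():
                if _hamming(r.seq1[: len(well)], well) <= 1:
                    assigned.append((sample, well))
        if len(assigned) == 1:
            sample, well = assigned[0]
            ell = len(well)
            per_sample[sample].append(
                ReadPair(r.name, r.seq1[ell:], r.qual1[ell:], r.seq2, r.qual2)
            )
        else:
            undetermined.append(r)

    counts = pd.DataFrame(
        {"sample": list(per_sample), "n_pairs": [len(v) for v in per_sample.values()]}
    )
    return DemuxResult(per_sample, undetermined, counts)


def demultiplex_files(
    path1: str | Path,
    path2: str | Path,
    barcodes: BarcodeSet,
    out_dir: str | Path,
    max_mismatch: int = 0,
    plate: str | None = None,
    gzip_output: bool = False,
) -> DemuxResult:
    """File-level demultiplexer: per-sample FASTQ pairs plus a count table."""
    result = demultiplex(read_fastq_pair(path1, path2), barcodes, max_mismatch, plate)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".fastq.gz" if gzip_output else ".fastq"
    for sample, pairs in result.per_sample.items():
        write_fastq_pair(pairs, out_dir / f"{sample}_R1{ext}", out_dir / f"{sample}_R2{ext}")
    write_fastq_pair(
        result.undetermined,
        out_dir / f"undetermined_R1{ext}",
        out_dir / f"undetermined_R2{ext}",
    )
    return result


# ---------------------------------------------------------------------------
# subsampling


def subsample_pairs(
    reads: Iterable[ReadPair], fraction: float, seed: int = 0
) -> list[ReadPair]:
    """Keep each read pair independently with probability ``fraction`` (seeded).

    Mates are kept or dropped together — this is the skim-seq construction of
    emulating low-coverage sequencing by randomly sampling raw reads.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    return [r for r in reads if rng.random() < fraction]


def subsample_files(
    path1: str | Path,
    path2: str | Path,
    out1: str | Path,
    out2: str | Path,
    fraction: float,
    seed: int = 0,
) -> int:
    kept = subsample_pairs(read_fastq_pair(path1, path2), fraction, seed)
    write_fastq_pair(kept, out1, out2)
    return len(kept)
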