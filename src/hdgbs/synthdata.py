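"""Synthetic-data generators: random genomes with controllable cut-site
density and recombining haplotype panels with tunable allele-frequency and LD
structure.

Every generator is a pure function of its seed, so downstream digestion,
library-simulation and imputation stages are testable — with exact oracles
where construction permits — without any external download.

The panel model is a mosaic of founders: founder haplotypes are drawn
per-variant from an allele-frequency distribution, and each descendant
haplotype copies founder segments separated by a Poisson number of
recombination breakpoints. Fewer breakpoints mean longer shared segments,
i.e. longer-range linkage disequilibrium and easier imputation — the one
control knob the imputation-accuracy analyses need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .digestion import (
    IUPAC,
    Enzyme,
    Fragment,
    find_match_starts,
    motif_reverse_complement,
)
from .io_formats import Genome, GenotypeMatrix, HaplotypePanel, Variant

_BASES = np.array(list("ACGT"))
_BASE_ORDER = "ACGT"


def random_genome(
    length: int, gc: float = 0.5, seed: int = 0, name: str = "chr1"
) -> Genome:
    """An i.i.d. random genome with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(_BASES[rng.choice(4, size=length, p=p)])
    return Genome([(name, seq)])


def _expand_motif(motif: str, rng: np.random.Generator) -> str:
    """One concrete instance of an IUPAC motif, degenerate positions sampled uniformly."""
    return "".join(
        c if len(IUPAC[c]) == 1 else IUPAC[c][rng.integers(0, len(IUPAC[c]))]
        for c in motif
    )


def _all_match_starts(seq: str, enzyme: Enzyme) -> list[int]:
    starts = set(find_match_starts(seq, enzyme.recognition))
    if not enzyme.is_palindromic:
        starts.update(find_match_starts(seq, motif_reverse_complement(enzyme.recognition)))
    return sorted(starts)


def genome_with_sites(
    length: int,
    enzyme: Enzyme,
    mean_fragment: float,
    seed: int = 0,
    name: str = "chr1",
) -> tuple[Genome, list[int]]:
    """A genome whose cut sites for ``enzyme`` are exactly known by construction.

    Motif instances are planted at approximately exponential(mean_fragment)
    spacings on a background scrubbed of accidental motif occurrences
    (rewritten with the lexicographically next base until motif-free). The
    exact planted cut coordinates are returned alongside, so a digest of the
    result has a construction oracle.
    """
    motif_len = len(enzyme.recognition)
    if mean_fragment <= motif_len:
        raise ValueError("mean_fragment must exceed the motif length")
    rng = np.random.default_rng(seed)

    # plant positions with exponential spacings, enforcing a gap > motif_len
    # so planted instances cannot overlap or abut
    positions: list[int] = []
    pos = 0
    while True:
        gap = max(int(round(rng.exponential(mean_fragment))), motif_len + 1)
        pos += gap
        if pos + motif_len > length:
            break
        positions.append(pos)

    chars = list("".join(_BASES[rng.integers(0, 4, size=length)]))
    planted_span = np.zeros(length, dtype=bool)
    for p in positions:
        instance = _expand_motif(enzyme.recognition, rng)
        chars[p : p + motif_len] = list(instance)
        planted_span[p : p + motif_len] = True
    planted_starts = set(positions)

    # scrub accidental matches (background or junction-spanning), never
    # touching a planted span
    motifs = {enzyme.recognition}
    if not enzyme.is_palindromic:
        motifs.add(motif_reverse_complement(enzyme.recognition))

    def _window_matches(window: str) -> bool:
        return any(
            all(b in IUPAC[c] for b, c in zip(window, m)) for m in motifs
        )

    for _ in range(100):
        seq = "".join(chars)
        unwanted = [s for s in _all_match_starts(seq, enzyme) if s not in planted_starts]
        if not unwanted:
            break
        for s in unwanted:
            free = [i for i in range(s, s + motif_len) if not planted_span[i]]
            # pick the first (position, next base) that breaks this window;
            # a free position always exists because planted gaps > motif_len
            for i in free:
                original = chars[i]
                start = _BASE_ORDER.index(original)
                done = False
                for step in range(1, 4):
                    chars[i] = _BASE_ORDER[(start + step) % 4]
                    if not _window_matches("".join(chars[s : s + motif_len])):
                        done = True
                        break
                if done:
                    break
                chars[i] = original
    else:
        raise RuntimeError("failed to scrub accidental motif matches")

    genome = Genome([(name, "".join(chars))])
    cuts = sorted(p + enzyme.cut_offset for p in positions)
    return genome, cuts


@dataclass(frozen=True)
class PanelSimConfig:
    """Parameters of the founder-mosaic haplotype panel simulator.

    ``af_distribution`` is ``("uniform", lo, hi)`` or ``("beta", a, b)``;
    ``recombinations_per_haplotype`` is the Poisson mean number of founder
    switches per descendant haplotype; ``genotyping_error`` is a per-allele
    flip probability.
    """

    n_founders: int = 20
    n_haplotypes: int = 100
    n_variants: int = 500
    af_distribution: tuple = ("uniform", 0.01, 0.5)
    recombinations_per_haplotype: float = 3.0
    genotyping_error: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders > self.n_haplotypes:
            raise ValueError("n_founders must be <= n_haplotypes")
        if not 0 <= self.genotyping_error <= 1:
            raise ValueError("genotyping_error must be a probability")
        if self.af_distribution[0] not in ("uniform", "beta"):
            raise ValueError("af_distribution must be ('uniform', lo, hi) or ('beta', a, b)")


def simulate_panel(config: PanelSimConfig) -> tuple[HaplotypePanel, GenotypeMatrix]:
    """Simulate a haplotype panel and its paired diploid truth matrix.

    Founder haplotypes are drawn per-variant from the allele-frequency
    distribution; each of the ``n_haplotypes`` descendants is a founder mosaic
    with Poisson breakpoints at uniform variant positions, then per-allele
    flip noise. Consecutive haplotype pairs (0,1), (2,3), ... form the diploid
    truth matrix.
    """
    rng = np.random.default_rng(config.seed)
    kind, a, b = config.af_distribution
    af = (
        rng.uniform(a, b, config.n_variants)
        if kind == "uniform"
        else rng.beta(a, b, config.n_variants)
    )
    founders = (rng.random((config.n_founders, config.n_variants)) < af).astype(np.uint8)

    haps = np.empty((config.n_haplotypes, config.n_variants), dtype=np.uint8)
    for h in range(config.n_haplotypes):
        n_breaks = rng.poisson(config.recombinations_per_haplotype)
        breaks = np.sort(rng.integers(0, config.n_variants, size=n_breaks))
        bounds = [0, *breaks.tolist(), config.n_variants]
        for i in range(len(bounds) - 1):
            lo, hi = bounds[i], bounds[i + 1]
            if lo < hi:
                haps[h, lo:hi] = founders[rng.integers(0, config.n_founders), lo:hi]
    if config.genotyping_error > 0:
        flips = rng.random(haps.shape) < config.genotyping_error
        haps = np.where(flips, 1 - haps, haps).astype(np.uint8)

    variants = [
        Variant("1", 100 * (j + 1), "A", "C") for j in range(config.n_variants)
    ]
    panel = HaplotypePanel(
        [f"hap{h:04d}" for h in range(config.n_haplotypes)], haps, variants
    )
    n_samples = config.n_haplotypes // 2
    dosage = (
        haps[: 2 * n_samples : 2].astype(np.int8) + haps[1 : 2 * n_samples : 2].astype(np.int8)
    )
    truth = GenotypeMatrix(
        [f"S{i:03d}" for i in range(n_samples)], variants, dosage
    )
    return panel, truth


def plant_variants_on_fragments(
    fragments: Sequence[Fragment], density: float, seed: int = 0
) -> list[Variant]:
    """Place variants uniformly within fragments at ``density`` variants/kb.

    Counts per fragment are Poisson(density * length / 1000); positions are
    returned sorted and 1-based. Alleles are fixed (A->C): position structure,
    not allele content, is what downstream stages consume.
    """
    if density < 0:
        raise ValueError("density must be non-negative")
    rng = np.random.default_rng(seed)
    variants: list[Variant] = []
    for f in fragments:
        n = rng.poisson(density * f.length / 1000.0)
        offsets = np.unique(rng.integers(f.start, f.end, size=n))
        variants.extend(Variant(f.chrom, int(p) + 1, "A", "C") for p in offsets)
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return variants
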