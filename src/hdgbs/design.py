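"""HD-GBS design math: size selection, binning, uniformity, the enzyme screen,
and the depth / multiplex / cost / barcode-capacity models.

The design goal for a high-density GBS assay is an enzyme (or pair) producing
on the order of one million fragments inside the sequenced size window
(100-800 bp) with an approximately uniform size distribution: enough loci for
dense marker coverage, few enough that each is sequenced at usable depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import digestion
from .digestion import Enzyme, Fragment
from .io_formats import Genome


@dataclass(frozen=True)
class SizeWindow:
    """Inclusive fragment-length window with a fixed histogram bin size.

    Bins are half-open ``[lo, lo + bin_size)`` except the last, which is
    closed at ``max_len`` so the window bounds are inclusive on both ends.
    When ``bin_size`` does not divide the window span the last bin is
    truncated at ``max_len``.
    """

    min_len: int = 100
    max_len: int = 800
    bin_size: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.min_len < self.max_len:
            raise ValueError("require 0 < min_len < max_len")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def bins(self) -> list[tuple[int, int]]:
        """(lo, hi) per bin; all half-open except the last, closed at max_len."""
        starts = list(range(self.min_len, self.max_len, self.bin_size))
        out = [(lo, min(lo + self.bin_size, self.max_len)) for lo in starts]
        return out

    def contains(self, length: int, adapter_length: int = 0) -> bool:
        return self.min_len <= length + adapter_length <= self.max_len

    def bin_index(self, length: int) -> int | None:
        if not self.contains(length):
            return None
        idx = (length - self.min_len) // self.bin_size
        return min(idx, len(self.bins) - 1)  # max_len falls in the last, closed bin


@dataclass
class DigestSummary:
    """Screen output for one enzyme combination."""

    enzyme_combo: str
    n_fragments_total: int
    n_fragments_in_window: int
    histogram: list[tuple[int, int, int]]  # (bin_start, bin_end, count)
    uniformity: float

    def __post_init__(self) -> None:
        if sum(c for *_, c in self.histogram) != self.n_fragments_in_window:
            raise ValueError("histogram counts must sum to n_fragments_in_window")


@dataclass(frozen=True)
class DepthModel:
    """Sequencing-depth arithmetic for a multiplexed GBS lane."""

    lane_read_pairs: float
    multiplex: int
    on_target_fraction: float = 1.0
    n_selected_fragments: int | None = None

    def __post_init__(self) -> None:
        if self.lane_read_pairs <= 0:
            raise ValueError("lane_read_pairs must be positive")
        if self.multiplex <= 0:
            raise ValueError("multiplex must be a positive sample count")
        if not 0 < self.on_target_fraction <= 1:
            raise ValueError("on_target_fraction must be in (0, 1]")
        if self.n_selected_fragments is not None and self.n_selected_fragments <= 0:
            raise ValueError("n_selected_fragments must be positive when given")


@dataclass(frozen=True)
class CostModel:
    """Per-sample genotyping cost: library prep plus a multiplexed lane share."""

    lane_cost: float
    library_cost_per_sample: float
    multiplex: int

    def __post_init__(self) -> None:
        if self.lane_cost < 0 or self.library_cost_per_sample < 0:
            raise ValueError("costs must be non-negative")
        if self.multiplex < 1:
            raise ValueError("multiplex must be >= 1")


def size_select(
    fragments: Sequence[Fragment], window: SizeWindow, adapter_length: int = 0
) -> list[Fragment]:
    """Keep fragments with ``min_len <= length + adapter_length <= max_len``.

    ``adapter_length`` converts insert length to library-molecule length, so a
    200-600 bp instrument trace window can be applied to insert fragments;
    the default 0 reproduces the plain in silico 100-800 bp insert window.
    """
    return [f for f in fragments if window.contains(f.length, adapter_length)]


def bin_fragments(fragments: Sequence[Fragment], window: SizeWindow) -> np.ndarray:
    """Histogram of in-window fragment lengths; out-of-window fragments excluded."""
    counts = np.zeros(len(window.bins), dtype=np.int64)
    for f in fragments:
        idx = window.bin_index(f.length)
        if idx is not None:
            counts[idx] += 1
    return counts


def uniformity_score(histogram: Sequence[int]) -> float:
    """min(bin count) / max(bin count): 1 iff perfectly uniform, 0 if any bin empty."""
    counts = np.asarray(histogram)
    if counts.size == 0:
        raise ValueError("histogram must have at least one bin")
    if counts.max() == 0:
        raise ValueError("uniformity undefined for an all-zero histogram")
    return float(counts.min() / counts.max())


def parse_combo(
    spec: str, registry: dict[str, Enzyme] | None = None
) -> tuple[Enzyme, ...]:
    """Parse an enzyme-combination spec like ``"BfaI"`` or ``"MspI+MseI"``.

    ``/`` is accepted as a separator too, matching the common digest notation.
    """
    registry = digestion.builtin_enzymes() if registry is None else registry
    names = [n.strip() for n in spec.replace("/", "+").split("+") if n.strip()]
    if not 1 <= len(names) <= 2:
        raise ValueError(f"combo {spec!r} must name one or two enzymes")
    missing = [n for n in names if n not in registry]
    if missing:
        raise ValueError(
            f"unknown enzyme(s) {missing}; known: {sorted(registry)}"
        )
    return tuple(registry[n] for n in names)


def digest_combo(
    genome: Genome,
    combo: str,
    registry: dict[str, Enzyme] | None = None,
    selection: str = "AB_only",
    keep_terminal: bool = False,
) -> list[Fragment]:
    """Digest with a 1- or 2-enzyme combination spec."""
    enzymes = parse_combo(combo, registry)
    if len(enzymes) == 1:
        return digestion.digest_single(genome, enzymes[0], keep_terminal=keep_terminal)
    return digestion.digest_double(
        genome, enzymes[0], enzymes[1], selection=selection, keep_terminal=keep_terminal
    )


def enzyme_screen(
    genome: Genome,
    combos: Sequence[str],
    window: SizeWindow,
    registry: dict[str, Enzyme] | None = None,
    selection: str = "AB_only",
) -> list[DigestSummary]:
    """In silico screen of enzyme combinations, sorted by in-window fragment count.

    For each combination the genome is digested, fragment lengths are binned
    over the window, and a min/max uniformity score summarises the shape of
    the size distribution.
    """
    summaries: list[DigestSummary] = []
    for combo in combos:
        fragments = digest_combo(genome, combo, registry, selection=selection)
        counts = bin_fragments(fragments, window)
        in_window = int(counts.sum())
        uniformity = (
            uniformity_score(counts) if counts.max() > 0 else 0.0
        )
        summaries.append(
            DigestSummary(
                enzyme_combo=combo,
                n_fragments_total=len(fragments),
                n_fragments_in_window=in_window,
                histogram=[
                    (lo, hi, int(c)) for (lo, hi), c in zip(window.bins, counts)
                ],
                uniformity=uniformity,
            )
        )
    summaries.sort(key=lambda s: s.n_fragments_in_window)
    return summaries


def screen_table(summaries: Sequence[DigestSummary]) -> pd.DataFrame:
    """Tabulate screen summaries (one row per combination, one column per bin)."""
    rows = []
    for s in summaries:
        row = {
            "enzyme_combo": s.enzyme_combo,
            "n_fragments_total": s.n_fragments_total,
            "n_fragments_in_window": s.n_fragments_in_window,
            "uniformity": s.uniformity,
        }
        for lo, hi, c in s.histogram:
            row[f"bin_{lo}_{hi}"] = c
        rows.append(row)
    return pd.DataFrame(rows)


def plot_histograms(summaries: Sequence[DigestSummary], path: str) -> None:
    """Bar plots of the binned size distributions, one panel per combination."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(summaries)
    fig, axes = plt.subplots(1, max(n, 1), figsize=(3 * max(n, 1), 3), squeeze=False)
    for ax, s in zip(axes[0], summaries):
        lows = [lo for lo, _, _ in s.histogram]
        counts = [c for _, _, c in s.histogram]
        width = lows[1] - lows[0] if len(lows) > 1 else 100
        ax.bar(lows, counts, width=width * 0.9, align="edge")
        ax.set_title(s.enzyme_combo, fontsize=9)
        ax.set_xlabel("fragment length (bp)")
    axes[0][0].set_ylabel("fragments")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# depth / cost / capacity arithmetic


def reads_per_sample(model: DepthModel) -> float:
    """Expected read pairs per sample after demultiplexing.

    ``lane_read_pairs * on_target_fraction / multiplex``: e.g. a 320M-pair
    lane at 96-plex yields ~3.3M pairs per sample.
    """
    return model.lane_read_pairs * model.on_target_fraction / model.multiplex


def expected_fragment_depth(model: DepthModel) -> float:
    """Expected read pairs per selected fragment per sample (uniform coverage)."""
    if not model.n_selected_fragments:
        raise ValueError("expected_fragment_depth requires n_selected_fragments > 0")
    return reads_per_sample(model) / model.n_selected_fragments


def cost_per_sample(model: CostModel) -> float:
    """Per-sample cost: library prep plus the sample's share of the lane."""
    return model.library_cost_per_sample + model.lane_cost / model.multiplex


def barcode_capacity(n_well_barcodes: int, n_plate_barcodes: int) -> int:
    """Samples identifiable by a unique (well barcode, plate barcode) pair.

    96 well barcodes x 48 plate barcodes = 4608 samples on one lane, which is
    what makes >4500-plex GBS feasible on the largest flow cells.
    """
    if n_well_barcodes < 1 or n_plate_barcodes < 1:
        raise ValueError("barcode counts must be >= 1")
    return n_well_barcodes * n_plate_barcodes
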