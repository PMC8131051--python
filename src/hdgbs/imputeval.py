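"""Platform-evaluation metrics and imputation-accuracy analysis.

Low-cost genotyping platforms (GBS variants, skim sequencing, SNP arrays)
differ in how many variants they type directly; the rest must be imputed from
a reference haplotype panel. This module provides the evaluation loop: mask a
truth matrix down to a platform's marker density, impute the untyped variants
back, and report the squared Pearson correlation (R²) between imputed and
true dosages per allele-frequency bin.

Allele frequency for binning is always computed on the reference panel, where
it is defined even for fully masked variants. R² is pooled across variants
within a bin by default (one curve per platform); a per-variant-averaged mode
is available.

The built-in imputer is deliberately simple — windowed nearest-haplotype
copying — so the harness stays self-contained; externally imputed VCFs can be
evaluated through the same metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import CostModel, cost_per_sample
from .io_formats import MISSING, GenotypeMatrix, HaplotypePanel, _open_text

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AFBinning:
    """Allele-frequency bins over [0, 1]: half-open [lo, hi), last bin closed."""

    edges: tuple = tuple(np.round(np.arange(0, 1.01, 0.1), 10))

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if len(e) < 2 or (np.diff(e) <= 0).any():
            raise ValueError("bin edges must be strictly increasing")
        if e[0] != 0.0 or e[-1] != 1.0:
            raise ValueError("bin edges must span [0, 1]")
        object.__setattr__(self, "edges", tuple(e))

    @classmethod
    def with_width(cls, width: float) -> "AFBinning":
        edges = np.round(np.arange(0, 1 + width / 2, width), 10)
        if edges[-1] != 1.0:
            edges = np.append(edges, 1.0)
        return cls(tuple(edges))

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def assign(self, af: np.ndarray) -> np.ndarray:
        """Bin index per AF value (NaN -> -1)."""
        e = np.asarray(self.edges)
        idx = np.searchsorted(e, af, side="right") - 1
        idx = np.clip(idx, 0, self.n_bins - 1)  # af == 1.0 into the closed last bin
        return np.where(np.isnan(af), -1, idx).astype(int)

    def labels(self) -> list[str]:
        return [
            f"[{self.edges[i]:g},{self.edges[i + 1]:g})"
            if i < self.n_bins - 1
            else f"[{self.edges[i]:g},{self.edges[i + 1]:g}]"
            for i in range(self.n_bins)
        ]


# ---------------------------------------------------------------------------
# basic metrics


def missingness(matrix: GenotypeMatrix) -> float:
    """Proportion of missing genotype entries."""
    if matrix.n_samples == 0 or matrix.n_variants == 0:
        raise ValueError("missingness undefined for an empty matrix")
    return float(matrix.missing_mask.mean())


def depth_distribution(
    matrix: GenotypeMatrix, thresholds: Sequence[int]
) -> tuple[dict[int, float], np.ndarray]:
    """Fraction of non-missing calls with depth > k, for each threshold k.

    Also returns the per-variant mean depth (over non-missing calls), the
    quantity histogrammed in variant depth-of-coverage figures.
    """
    if matrix.depth is None:
        raise ValueError("matrix has no depth information")
    called = ~matrix.missing_mask
    n_called = called.sum()
    fractions = {
        int(k): float((called & (matrix.depth > k)).sum() / n_called) if n_called else float("nan")
        for k in thresholds
    }
    with np.errstate(invalid="ignore"):
        per_variant = np.where(
            called.sum(axis=0) > 0,
            (matrix.depth * called).sum(axis=0) / np.maximum(called.sum(axis=0), 1),
            np.nan,
        )
    return fractions, per_variant


def allele_frequency(data: GenotypeMatrix | HaplotypePanel) -> np.ndarray:
    """Alternate-allele frequency per variant (NaN where all calls are missing)."""
    if isinstance(data, HaplotypePanel):
        return data.alleles.mean(axis=0)
    called = ~data.missing_mask
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        af = np.where(n > 0, (data.dosage * called).sum(axis=0) / (2 * n), np.nan)
    return af


# ---------------------------------------------------------------------------
# masking


@dataclass
class MaskRecord:
    """Bookkeeping for a platform mask: which variants stayed typed."""

    kept_indices: np.ndarray
    masked_indices: np.ndarray
    n_variants: int

    def true_dosages(self, truth: GenotypeMatrix) -> np.ndarray:
        """Samples x masked-variants slice of the truth matrix."""
        return truth.dosage[:, self.masked_indices]


def mask_to_platform(
    truth: GenotypeMatrix,
    kept_variants: int | Sequence[int],
    seed: int = 0,
) -> tuple[GenotypeMatrix, MaskRecord]:
    """Emulate a lower-density platform by masking variants to fully missing.

    ``kept_variants`` is either a count (kept set drawn uniformly, seeded) or
    an explicit list of variant indices. All genotypes at non-kept (untyped)
    variants are set missing; the returned record lets callers recover the
    masked truth.
    """
    m = truth.n_variants
    if isinstance(kept_variants, (int, np.integer)):
        k = int(kept_variants)
        if not 0 < k <= m:
            raise ValueError(f"kept count must be in [1, {m}], got {k}")
        rng = np.random.default_rng(seed)
        kept = np.sort(rng.choice(m, size=k, replace=False))
    else:
        kept = np.unique(np.asarray(kept_variants, dtype=int))
        if kept.size == 0:
            raise ValueError("kept variant list is empty")
        if kept.min() < 0 or kept.max() >= m:
            raise ValueError("kept variant index out of range")
    masked = np.setdiff1d(np.arange(m), kept)
    typed = truth.copy()
    typed.dosage[:, masked] = MISSING
    if typed.depth is not None:
        typed.depth[:, masked] = 0
    return typed, MaskRecord(kept, masked, m)


def write_mask_tsv(
    record: MaskRecord, truth: GenotypeMatrix, path: str | Path, header: Sequence[str] = ()
) -> None:
    """Masked entries as TSV (chrom, pos, sample, true_dosage)."""
    with _open_text(path, "wt") as fh:
        for line in header:
            fh.write(line.rstrip("\n") + "\n")
        fh.write("chrom\tpos\tsample\ttrue_dosage\n")
        for j in record.masked_indices:
            var = truth.variants[j]
            for i, sample in enumerate(truth.sample_ids):
                fh.write(f"{var.chrom}\t{var.pos}\t{sample}\t{int(truth.dosage[i, j])}\n")


def read_mask_tsv(path: str | Path, truth: GenotypeMatrix) -> MaskRecord:
    """Rebuild a MaskRecord from its TSV against the truth matrix it masked."""
    keys = {(v.chrom, v.pos): j for j, v in enumerate(truth.variants)}
    masked: set[int] = set()
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("chrom\t") or not line.strip():
                continue
            chrom, pos, *_ = line.rstrip("\n").split("\t")
            masked.add(keys[(chrom, int(pos))])
    masked_idx = np.array(sorted(masked), dtype=int)
    kept = np.setdiff1d(np.arange(truth.n_variants), masked_idx)
    return MaskRecord(kept, masked_idx, truth.n_variants)


# ---------------------------------------------------------------------------
# imputation


def impute_panel_af(typed: GenotypeMatrix, panel: HaplotypePanel) -> np.ndarray:
    """Baseline imputer: every missing entry gets the panel expected dosage 2*AF.

    Returns a float samples x variants array (observed entries kept as-is).
    No haplotype information is used, so this is the floor any real imputer
    must beat.
    """
    af = allele_frequency(panel)
    out = typed.dosage.astype(float)
    miss = typed.missing_mask
    out[miss] = np.broadcast_to(2 * af, out.shape)[miss]
    return out


def impute_nearest_haplotype(
    typed: GenotypeMatrix, panel: HaplotypePanel, flank: int = 10
) -> GenotypeMatrix:
    """Impute missing genotypes by windowed nearest-haplotype copying.

    For each variant with missing calls, the ``flank`` nearest typed variants
    on each side form a window. Per sample, the panel haplotype with minimum
    mismatch against the sample's dosages on that window is chosen (hom-ref
    dosage conflicts with allele 1, hom-alt with allele 0, het with neither);
    a second haplotype is then chosen greedily against the residual (at het
    sites it must carry the complementary allele). The imputed dosage is the
    sum of the two copied alleles. Ties break to the lowest panel index.

    Variants with no typed variants in reach fall back to the panel major
    allele (logged).
    """
    if typed.n_variants != panel.n_variants:
        raise ValueError(
            "typed matrix and panel must share one variant list "
            f"({typed.n_variants} vs {panel.n_variants})"
        )
    dosage = typed.dosage
    miss = typed.missing_mask
    out = dosage.copy()
    if not miss.any():
        return GenotypeMatrix(list(typed.sample_ids), list(typed.variants), out)

    typed_cols = np.nonzero(~miss.all(axis=0))[0]
    target_cols = np.nonzero(miss.any(axis=0))[0]
    A = panel.alleles  # (H, V)
    af = allele_frequency(panel)
    n_fallback = 0

    # group target variants by their typed-neighbour window
    windows: dict[tuple[int, ...], list[int]] = {}
    for j in target_cols:
        pos = np.searchsorted(typed_cols, j)
        lo = max(pos - flank, 0)
        hi = min(pos + flank, len(typed_cols))
        sites = tuple(int(c) for c in typed_cols[lo:hi] if c != j)
        windows.setdefault(sites, []).append(int(j))

    for sites, cols in windows.items():
        if not sites:
            for j in cols:
                fill = 2 if af[j] > 0.5 else 0
                out[miss[:, j], j] = fill
            n_fallback += len(cols)
            continue
        s = np.asarray(sites)
        Aw = A[:, s].astype(np.int8)  # (H, w)
        D = dosage[:, s]  # (S, w)
        hom_ref = (D == 0).astype(np.int16)
        hom_alt = (D == 2).astype(np.int16)
        het = D == 1
        # mismatches of each haplotype vs observed hom constraints
        mm1 = hom_ref @ Aw.T.astype(np.int16) + hom_alt @ (1 - Aw).T.astype(np.int16)
        h1 = np.argmin(mm1, axis=1)  # (S,)
        # second haplotype: hom constraints plus complementarity at het sites
        required = 1 - Aw[h1]  # (S, w) allele h2 must carry at het sites
        het_mm = ((Aw[None, :, :] != required[:, None, :]) & het[:, None, :]).sum(axis=2)
        mm2 = mm1 + het_mm
        h2 = np.argmin(mm2, axis=1)
        for j in cols:
            imput = A[h1, j].astype(np.int8) + A[h2, j].astype(np.int8)
            rows = miss[:, j]
            out[rows, j] = imput[rows]

    if n_fallback:
        logger.info(
            "impute_nearest_haplotype: %d variants imputed from panel AF "
            "(no typed variants in reach)",
            n_fallback,
        )
    return GenotypeMatrix(list(typed.sample_ids), list(typed.variants), out)


# ---------------------------------------------------------------------------
# accuracy


@dataclass
class ImputationReport:
    """Per-AF-bin and overall imputation R² for one platform/density scenario."""

    scenario: str
    table: pd.DataFrame  # columns: bin, af_lo, af_hi, n_variants, r2
    overall_r2: float

    def bin_r2(self, lo: float, hi: float) -> float:
        """Pooled R² over bins whose range falls inside [lo, hi]."""
        sel = self.table[(self.table.af_lo >= lo) & (self.table.af_hi <= hi)]
        sel = sel.dropna(subset=["r2"])
        if sel.empty:
            return float("nan")
        return float(np.average(sel.r2, weights=np.maximum(sel.n_variants, 1)))


def _pearson_r2(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or np.var(x) == 0 or np.var(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def imputation_accuracy(
    imputed: GenotypeMatrix | np.ndarray,
    truth: GenotypeMatrix,
    record: MaskRecord,
    panel: HaplotypePanel,
    bins: AFBinning | None = None,
    scenario: str = "",
    mode: str = "pooled",
) -> ImputationReport:
    """R² between imputed and true dosages over masked entries, per AF bin.

    AF per variant comes from the reference panel. ``mode="pooled"`` (default)
    computes one Pearson correlation over all masked entries in a bin;
    ``mode="per_variant"`` averages per-variant correlations instead. Bins
    where truth or imputation has zero dosage variance are flagged undefined
    (NaN) and excluded from the overall R²; monomorphic-within-bin variants
    are likewise excluded in per_variant mode with a logged count.
    """
    if mode not in ("pooled", "per_variant"):
        raise ValueError("mode must be 'pooled' or 'per_variant'")
    bins = AFBinning() if bins is None else bins
    if record.masked_indices.size == 0:
        raise ValueError("no masked entries to evaluate")
    imp = imputed.dosage if isinstance(imputed, GenotypeMatrix) else np.asarray(imputed)
    if imp.shape != truth.dosage.shape:
        raise ValueError("imputed and truth matrices are not congruent")

    af = allele_frequency(panel)
    bin_of = bins.assign(af)
    rows = []
    pooled_x: list[np.ndarray] = []
    pooled_y: list[np.ndarray] = []
    all_per_variant: list[float] = []
    n_mono_excluded = 0
    for b in range(bins.n_bins):
        cols = record.masked_indices[bin_of[record.masked_indices] == b]
        lo, hi = bins.edges[b], bins.edges[b + 1]
        if cols.size == 0:
            rows.append((bins.labels()[b], lo, hi, 0, float("nan")))
            continue
        t = truth.dosage[:, cols].astype(float)
        x = imp[:, cols].astype(float)
        if mode == "pooled":
            r2 = _pearson_r2(t.ravel(), x.ravel())
        else:
            per = []
            for c in range(cols.size):
                v = _pearson_r2(t[:, c], x[:, c])
                if np.isnan(v):
                    n_mono_excluded += 1
                else:
                    per.append(v)
            r2 = float(np.mean(per)) if per else float("nan")
            all_per_variant.extend(per)
        if not np.isnan(r2):
            pooled_x.append(t.ravel())
            pooled_y.append(x.ravel())
        rows.append((bins.labels()[b], lo, hi, int(cols.size), r2))

    # overall: pooled correlation over entries in defined bins, or (in
    # per_variant mode) the mean of per-variant R² — binning-independent
    if mode == "per_variant":
        overall = float(np.mean(all_per_variant)) if all_per_variant else float("nan")
    elif pooled_x:
        overall = _pearson_r2(np.concatenate(pooled_x), np.concatenate(pooled_y))
    else:
        overall = float("nan")
    if n_mono_excluded:
        logger.info(
            "imputation_accuracy: %d monomorphic-within-bin variants excluded",
            n_mono_excluded,
        )
    table = pd.DataFrame(rows, columns=["bin", "af_lo", "af_hi", "n_variants", "r2"])
    return ImputationReport(scenario, table, overall)


def platform_report(
    scenarios: Sequence[tuple],
    truth: GenotypeMatrix,
    panel: HaplotypePanel,
    bins: AFBinning | None = None,
    mode: str = "pooled",
) -> pd.DataFrame:
    """Compare genotyping platforms: variants typed, missingness, cost, R².

    Each scenario is ``(label, typed_matrix, imputed, mask_record,
    cost_model_or_None)``. Ordering is preserved; duplicate labels are an
    error. Columns: label, n_variants (typed), missingness (of the typed
    matrix), cost_per_sample, overall_r2, then one R² column per AF bin.
    """
    if not scenarios:
        raise ValueError("at least one scenario required")
    labels = [s[0] for s in scenarios]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate scenario labels")
    bins = AFBinning() if bins is None else bins
    rows = []
    for label, typed, imputed, record, cost in scenarios:
        report = imputation_accuracy(
            imputed, truth, record, panel, bins, scenario=label, mode=mode
        )
        row = {
            "label": label,
            "n_variants": int(record.kept_indices.size),
            "missingness": missingness(typed),
            "cost_per_sample": cost_per_sample(cost) if cost is not None else float("nan"),
            "overall_r2": report.overall_r2,
        }
        for _, r in report.table.iterrows():
            row[f"r2_{r['bin']}"] = r["r2"]
        rows.append(row)
    return pd.DataFrame(rows)
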