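"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive digestion semantics with plain
position-by-position loops (no regex, no pooled-cut bookkeeping) so they can
stand as independent references for the optimized implementations.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

# IUPAC expansion used by the oracles — written out rather than imported so a
# typo in the package table cannot hide in the oracle too.
ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_expand(motif: str) -> set[str]:
    """All concrete ACGT strings an IUPAC motif matches."""
    out = [""]
    for c in motif:
        out = [p + b for p in out for b in ORACLE_IUPAC[c]]
    return set(out)


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def naive_match_starts(seq: str, motif: str) -> list[int]:
    """Position-by-position IUPAC matcher (N in the sequence never matches)."""
    L = len(motif)
    return [
        i
        for i in range(len(seq) - L + 1)
        if all(seq[i + k] in ORACLE_IUPAC[motif[k]] for k in range(L))
    ]


def naive_cut_sites(seq: str, enzyme) -> list[int]:
    """Both-strand brute-force cut coordinates."""
    motif, off = enzyme.recognition, enzyme.cut_offset
    cuts = {s + off for s in naive_match_starts(seq, motif)}
    rc = "".join(
        {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
         "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
         "N": "N"}[c]
        for c in reversed(motif)
    )
    if rc != motif:
        cuts |= {s + (len(motif) - off) for s in naive_match_starts(seq, rc)}
    return sorted(cuts)


def naive_fragment_intervals(seq: str, enzymes, keep_terminal: bool = False):
    """(start, end, left_label, right_label) tuples from pooled naive cuts."""
    label: dict[int, str] = {}
    for e in enzymes:
        for c in naive_cut_sites(seq, e):
            label[c] = "both" if c in label and label[c] != e.name else label.get(c, e.name)
    cuts = sorted(label)
    bounds = ([0] if keep_terminal else []) + cuts + ([len(seq)] if keep_terminal else [])
    labels = (["terminal"] if keep_terminal else []) + [label[c] for c in cuts] + (
        ["terminal"] if keep_terminal else []
    )
    out = []
    for i in range(len(bounds) - 1):
        if bounds[i] < bounds[i + 1]:
            out.append((bounds[i], bounds[i + 1], labels[i], labels[i + 1]))
    return out


def naive_in_window_count(seq: str, enzymes, min_len: int, max_len: int,
                          ab_only: bool = False) -> int:
    n = 0
    for start, end, left, right in naive_fragment_intervals(seq, enzymes):
        if ab_only and (left == right != "both"):
            continue
        if min_len <= end - start <= max_len:
            n += 1
    return n


@pytest.fixture(scope="session")
def enzymes():
    from hdgbs.digestion import builtin_enzymes

    return builtin_enzymes()


@pytest.fixture(scope="session")
def small_genome():
    """A 60 kb soybean-like (GC 0.35) random genome, shared across tests."""
    from hdgbs.synthdata import random_genome

    return random_genome(60_000, gc=0.35, seed=1234)
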