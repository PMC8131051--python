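"""Restriction-enzyme modelling and in silico digestion.

An enzyme is a named IUPAC recognition motif plus a cut offset (the top-strand
cut position relative to the motif start). Digesting a genome turns the sorted
cut coordinates on each chromosome into fragments; GBS library chemistry
requires a ligatable cut end on both sides, so terminal (chromosome-end)
pieces are excluded by default.

Recognition sites and offsets of the built-in enzymes follow the REBASE
registry: ApeKI G^CWGC, MseI T^TAA, MspI C^CGG, NlaIII CATG^, BfaI C^TAG.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .io_formats import Genome

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# complement of each IUPAC code (complement of the base set it expands to)
_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a plain A/C/G/T/N sequence."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def motif_reverse_complement(motif: str) -> str:
    """Reverse complement of an IUPAC motif, code-wise."""
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(motif))


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: IUPAC recognition motif + top-strand cut offset."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        motif = self.recognition.upper()
        object.__setattr__(self, "recognition", motif)
        if len(motif) < 3:
            raise ValueError(f"{self.name}: motif must be at least 3 bases")
        bad = set(motif) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC code(s) {sorted(bad)}")
        if not 0 <= self.cut_offset <= len(motif):
            raise ValueError(
                f"{self.name}: cut_offset {self.cut_offset} outside [0, {len(motif)}]"
            )

    @property
    def is_palindromic(self) -> bool:
        """True if the motif equals its own reverse complement under IUPAC expansion."""
        return motif_reverse_complement(self.recognition) == self.recognition

    def __str__(self) -> str:
        m = self.recognition
        return f"{self.name}({m[: self.cut_offset]}^{m[self.cut_offset :]})"


@dataclass(frozen=True)
class Fragment:
    """A genomic interval produced by digestion (0-based half-open)."""

    chrom: str
    start: int
    end: int
    left_enzyme: str
    right_enzyme: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid fragment interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


# Terminal (chromosome-end) fragment ends carry this label.
TERMINAL = "terminal"
# Label for a cut coordinate produced by both enzymes of a double digest.
BOTH = "both"


def builtin_enzymes() -> dict[str, Enzyme]:
    """The enzymes screened for the HD-GBS design, keyed by name."""
    enzymes = [
        Enzyme("ApeKI", "GCWGC", 1),
        Enzyme("MseI", "TTAA", 1),
        Enzyme("MspI", "CCGG", 1),
        Enzyme("NlaIII", "CATG", 4),
        Enzyme("BfaI", "CTAG", 1),
    ]
    return {e.name: e for e in enzymes}


def load_enzymes(path: str | Path, base: dict[str, Enzyme] | None = None) -> dict[str, Enzyme]:
    """Load user enzymes from JSON or TSV, added to (and overriding) the built-ins.

    JSON: list of {"name", "recognition", "cut_offset"} objects.
    TSV: columns name, recognition, cut_offset (header optional).
    """
    registry = dict(builtin_enzymes() if base is None else base)
    text = Path(path).read_text()
    rows: list[tuple[str, str, int]] = []
    if text.lstrip().startswith(("[", "{")):
        data = json.loads(text)
        if isinstance(data, dict):
            data = data.get("enzymes", [])
        for obj in data:
            rows.append((obj["name"], obj["recognition"], int(obj["cut_offset"])))
    else:
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() == "name":
                continue
            rows.append((parts[0], parts[1], int(parts[2])))
    for name, recognition, offset in rows:
        registry[name] = Enzyme(name, recognition, offset)
    return registry


def _motif_regex(motif: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported; IUPAC N matches
    # A/C/G/T only — an N in the sequence never matches any motif position
    return re.compile("(?=" + "".join(f"[{IUPAC[c]}]" for c in motif) + ")")


def find_match_starts(sequence: str, motif: str) -> list[int]:
    """Top-strand start positions of all (overlapping) IUPAC motif occurrences."""
    return [m.start() for m in _motif_regex(motif).finditer(sequence)]


def find_cut_sites(sequence: str, enzyme: Enzyme) -> list[int]:
    """Sorted, deduplicated double-stranded cut coordinates in ``sequence``.

    Every top-strand motif occurrence cuts at ``start + cut_offset``. For a
    non-palindromic enzyme the bottom strand is scanned too (as the motif's
    reverse complement on the top strand), cutting at
    ``start + (len(motif) - cut_offset)``.
    """
    sequence = sequence.upper()
    motif = enzyme.recognition
    cuts = {s + enzyme.cut_offset for s in find_match_starts(sequence, motif)}
    if not enzyme.is_palindromic:
        rc = motif_reverse_complement(motif)
        offset = len(motif) - enzyme.cut_offset
        cuts.update(s + offset for s in find_match_starts(sequence, rc))
    return sorted(cuts)


def _fragments_from_cuts(
    chrom: str,
    length: int,
    cuts: Sequence[int],
    labels: dict[int, str],
    keep_terminal: bool,
) -> list[Fragment]:
    frags: list[Fragment] = []
    if keep_terminal:
        bounds = [0, *cuts, length]
        ends = [TERMINAL, *(labels[c] for c in cuts), TERMINAL]
    else:
        bounds = list(cuts)
        ends = [labels[c] for c in cuts]
    for i in range(len(bounds) - 1):
        start, end = bounds[i], bounds[i + 1]
        if start < end:  # cuts at 0 or L would otherwise give empty pieces
            frags.append(Fragment(chrom, start, end, ends[i], ends[i + 1]))
    return frags


def digest_single(
    genome: Genome, enzyme: Enzyme, keep_terminal: bool = False
) -> list[Fragment]:
    """Digest every chromosome with one enzyme.

    Consecutive cut coordinates define internal fragments labelled
    (enzyme, enzyme); chromosome-end pieces are excluded unless
    ``keep_terminal`` (with which the fragments tile each chromosome exactly).
    """
    fragments: list[Fragment] = []
    for chrom, seq in genome:
        cuts = find_cut_sites(seq, enzyme)
        labels = {c: enzyme.name for c in cuts}
        fragments.extend(
            _fragments_from_cuts(chrom, len(seq), cuts, labels, keep_terminal)
        )
    return fragments


def digest_double(
    genome: Genome,
    enzyme_a: Enzyme,
    enzyme_b: Enzyme,
    selection: str = "AB_only",
    keep_terminal: bool = False,
) -> list[Fragment]:
    """Digest with two enzymes simultaneously.

    Cut coordinates of both enzymes are pooled; each fragment end is labelled
    by the enzyme that created it (or ``"both"`` when the two enzymes cut the
    same coordinate, which then satisfies either end requirement).

    ``selection="AB_only"`` (default) keeps only fragments whose two ends can
    be attributed to *different* enzymes, mirroring two-enzyme GBS library
    chemistry; ``"all"`` keeps every internal fragment.
    """
    if enzyme_a.name == enzyme_b.name:
        raise ValueError(
            "identical enzymes in a double digest — use digest_single instead"
        )
    if selection not in ("AB_only", "all"):
        raise ValueError(f"selection must be 'AB_only' or 'all', got {selection!r}")

    fragments: list[Fragment] = []
    for chrom, seq in genome:
        cuts_a = set(find_cut_sites(seq, enzyme_a))
        cuts_b = set(find_cut_sites(seq, enzyme_b))
        labels = {c: enzyme_a.name for c in cuts_a}
        for c in cuts_b:
            labels[c] = BOTH if c in cuts_a else enzyme_b.name
        cuts = sorted(labels)
        frags = _fragments_from_cuts(chrom, len(seq), cuts, labels, keep_terminal)
        if selection == "AB_only":
            frags = [f for f in frags if is_ab_fragment(f)]
        fragments.extend(frags)
    return fragments


def is_ab_fragment(fragment: Fragment) -> bool:
    """True if the fragment's ends can be assigned to two different enzymes."""
    left, right = fragment.left_enzyme, fragment.right_enzyme
    if TERMINAL in (left, right):
        return False
    return left != right or left == BOTH


def count_by_end_type(fragments: Iterable[Fragment]) -> dict[str, int]:
    """Classify double-digest fragments as AA / AB / BB (a "both" end prefers AB).

    Every internal fragment falls in exactly one class, so the counts sum to
    the total.
    """
    counts = {"AA": 0, "AB": 0, "BB": 0}
    names = sorted(
        {
            e
            for f in fragments
            for e in (f.left_enzyme, f.right_enzyme)
            if e not in (BOTH, TERMINAL)
        }
    )
    for f in fragments:
        if TERMINAL in (f.left_enzyme, f.right_enzyme):
            continue
        if is_ab_fragment(f):
            counts["AB"] += 1
        elif names and f.left_enzyme == names[0]:
            counts["AA"] += 1
        else:
            counts["BB"] += 1
    return counts


def filter_n_fraction(
    fragments: Sequence[Fragment], genome: Genome, max_n_fraction: float = 0.5
) -> list[Fragment]:
    """Drop fragments whose sequence exceeds ``max_n_fraction`` of N bases.

    Off by default in all pipelines; assembly gaps (runs of N) should not
    silently inflate fragment counts when it is on.
    """
    kept = []
    for f in fragments:
        seq = genome[f.chrom][f.start : f.end]
        if seq.count("N") / len(seq) <= max_n_fraction:
            kept.append(f)
    return kept
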