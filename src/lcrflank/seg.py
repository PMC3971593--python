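"""Low-complexity region (LCR) detection in protein sequences.

A sliding window of W residues is scored by its Shannon entropy
K = -sum_i (n_i/W) * log2(n_i/W) over residue counts n_i.  Every residue
covered by at least one window whose entropy falls below the threshold K0
is marked low-complexity, and maximal runs of marked residues are merged
into intervals.  This is a single-threshold mark-and-merge variant of the
classic SEG filter: the trigger/extension two-threshold scheme and SEG's
probability-minimising boundary refinement are intentionally not used, so
the detector is controlled by exactly one window size and one entropy
threshold (defaults 15 residues and 1.9 bits).

The window is measured in residues.  Descriptions of this parameterisation
sometimes quote the window in "bp"; SEG operates on amino acids, so the
window here is 15 residues, not 15 nucleotides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: 'X' (unknown/ambiguous) is kept as a 21st symbol so windows keep length W
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")


@dataclass(frozen=True)
class SegParams:
    """Window length (residues) and entropy threshold (bits)."""

    window: int = 15
    threshold: float = 1.9

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2 residues")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence; residues restricted to the 20 amino acids + 'X'."""

    id: str
    residues: str
    cds_id: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"protein {self.id!r} is empty")
        bad = set(self.residues) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(f"protein {self.id!r} has invalid residues: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class LcrInterval:
    """A low-complexity segment, 0-based half-open residue coordinates."""

    protein_id: str = field(compare=False)
    start: int
    end: int
    entropy_min: float = field(compare=False)

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def window_entropy(window: str) -> float:
    """Shannon entropy (bits) of the residue composition of one window.

    Raises ValueError on an empty window; callers fix the length W and this
    function scores whatever full window it is given.
    """
    if not window:
        raise ValueError("empty window")
    w = len(window)
    counts: dict[str, int] = {}
    for r in window:
        counts[r] = counts.get(r, 0) + 1
    return -sum((c / w) * math.log2(c / w) for c in counts.values()) or 0.0


def detect_lcrs(protein: ProteinRecord, params: SegParams = SegParams()) -> list[LcrInterval]:
    """Detect low-complexity intervals on one protein.

    Only fully contained windows are scored (no partial windows at the
    termini), so proteins shorter than the window return no intervals.
    Returned intervals are disjoint, sorted, and each at least one window
    long. ``entropy_min`` is the minimum entropy among the windows that
    marked residues of the interval.
    """
    seq = protein.residues
    n = len(seq)
    w = params.window
    if n < w:
        return []
    marked = [False] * n
    # lowest triggering-window entropy seen at each residue
    min_at = [math.inf] * n
    for i in range(n - w + 1):
        h = window_entropy(seq[i : i + w])
        if h < params.threshold:
            for j in range(i, i + w):
                marked[j] = True
                if h < min_at[j]:
                    min_at[j] = h
    intervals: list[LcrInterval] = []
    i = 0
    while i < n:
        if marked[i]:
            j = i
            while j < n and marked[j]:
                j += 1
            intervals.append(
                LcrInterval(protein.id, i, j, min(min_at[i:j]))
            )
            i = j
        else:
            i += 1
    return intervals
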