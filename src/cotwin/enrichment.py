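"""Gene-set overlap enrichment by Fisher's exact test on a shared background.

The statistic mirrors the GeneOverlap convention: a 2x2 table of membership
in set A vs set B over a background universe, two-sided exact
hypergeometric p, odds ratio, and fold enrichment = observed overlap /
expected overlap under independence.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from cotwin.errors import ValidationError

__all__ = ["OverlapResult", "fisher_overlap", "read_gene_set"]


@dataclass
class OverlapResult:
    """Overlap of two gene sets on a common background."""

    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int
    odds_ratio: float
    fold_enrichment: float
    p: float
    background_size: int

    @property
    def table(self) -> list[list[int]]:
        return [[self.n_both, self.n_a_only], [self.n_b_only, self.n_neither]]


def fisher_overlap(set_a, set_b, background) -> OverlapResult:
    """Two-sided Fisher exact test of overlap between two gene sets.

    Both sets must be subsets of ``background``. Fold enrichment is
    (both/|A|) / (|B|/|background|), i.e. observed over expected overlap
    under independence.
    """
    background = set(background)
    if not background:
        raise ValidationError("background gene universe is empty")
    a, b = set(set_a), set(set_b)
    stray = (a | b) - background
    if stray:
        raise ValidationError(f"sets contain genes outside the background: {sorted(stray)[:5]}")
    both = len(a & b)
    a_only = len(a - b)
    b_only = len(b - a)
    neither = len(background) - both - a_only - b_only
    odds, p = stats.fisher_exact([[both, a_only], [b_only, neither]], alternative="two-sided")
    if a and b:
        fold = (both / len(a)) / (len(b) / len(background))
    else:
        fold = float("nan")
    return OverlapResult(
        n_both=both,
        n_a_only=a_only,
        n_b_only=b_only,
        n_neither=neither,
        odds_ratio=float(odds),
        fold_enrichment=float(fold),
        p=float(p),
        background_size=len(background),
    )


def read_gene_set(path) -> set[str]:
    """Read a one-symbol-per-line gene set file."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
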