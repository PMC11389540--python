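"""5' fragment-end trinucleotide composition and its Gini-Simpson diversity.

For each fragment both 5' ends contribute one trinucleotide, read from the
*reference* at the mapped positions (so the measurement is independent of
sequencing errors): the plus-strand end is the three bases starting at the
fragment start, the minus-strand end is the reverse complement of the three
bases ending at the fragment end.  Ends touching non-ACGT reference bases
and fragments shorter than 3 bp are skipped and counted separately.

Diversity over the 64 trinucleotide fractions P_i uses the Gini-Simpson
index G = 1 - sum_i P_i^2, maximal (63/64) at the uniform composition and 0
when a single trinucleotide carries all ends.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .fragments import as_fragments
from .genome import Genome

#: The 64 trinucleotides in lexicographic order over {A, C, G, T}; fixed for all I/O.
TRINUCLEOTIDES: tuple[str, ...] = tuple(a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT")


@dataclasses.dataclass
class TrinucleotideProfile:
    sample_id: str
    counts: np.ndarray  # 64 end counts, AAA..TTT
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (64,):
            raise ValueError("trinucleotide counts must have 64 entries")
        if (self.counts < 0).any():
            raise ValueError("negative trinucleotide counts")

    @property
    def n_ends(self) -> int:
        return int(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray:
        n = self.n_ends
        if n == 0:
            return np.zeros(64)
        return self.counts / n

    @property
    def gini(self) -> float:
        return gini_index(self.fractions)

    def to_series(self) -> pd.Series:
        return pd.Series(self.fractions, index=list(TRINUCLEOTIDES), name=self.sample_id)


def gini_index(fractions: Sequence[float], tol: float = 1e-6) -> float:
    """Gini-Simpson diversity ``1 - sum(P_i**2)`` of a composition vector."""
    p = np.asarray(fractions, dtype=float)
    if abs(p.sum() - 1.0) > tol:
        raise ValueError(f"fractions sum to {p.sum():.6g}, not 1")
    return float(1.0 - np.sum(p * p))


def trinucleotide_profile(fragments, genome: Genome, sample_id: str | None = None,
                          both_ends: bool = True) -> TrinucleotideProfile:
    """Count 5'-end trinucleotides of a fragment set against a reference.

    ``both_ends=False`` restricts to the plus-strand (leftmost) end only.
    """
    frags = as_fragments(fragments)
    counts = np.zeros(64, dtype=np.int64)
    skipped = 0
    too_short = frags.length < 3
    skipped += int(too_short.sum()) * (2 if both_ends else 1)
    valid = ~too_short
    for ci in np.unique(frags.contig_idx[valid]):
        name = frags.contig_names[ci]
        if name not in genome:
            raise KeyError(f"contig {name!r} missing from genome")
        g = genome.codes_int(name)
        sel = valid & (frags.contig_idx == ci)
        s = frags.start[sel]
        e = s + frags.length[sel]
        if (s < 0).any() or (e > len(g)).any():
            raise ValueError(f"fragment outside contig bounds on {name}")
        b5 = np.stack([g[s], g[s + 1], g[s + 2]])
        ok5 = (b5 < 4).all(axis=0)
        c5 = b5[0] * 16 + b5[1] * 4 + b5[2]
        counts += np.bincount(c5[ok5], minlength=64)
        skipped += int((~ok5).sum())
        if both_ends:
            b3 = np.stack([3 - g[e - 1], 3 - g[e - 2], 3 - g[e - 3]])
            ok3 = ((b3 >= 0) & (b3 < 4)).all(axis=0)
            c3 = b3[0] * 16 + b3[1] * 4 + b3[2]
            counts += np.bincount(c3[ok3], minlength=64)
            skipped += int((~ok3).sum())
    return TrinucleotideProfile(
        sample_id=sample_id if sample_id is not None else frags.sample_id,
        counts=counts,
        n_skipped=skipped,
    )


def combine_profiles(profiles: Sequence[TrinucleotideProfile], sample_id: str = "pooled") -> TrinucleotideProfile:
    """Pool end counts across profiles (count-weighted merge)."""
    if not profiles:
        raise ValueError("no profiles to combine")
    counts = np.sum([p.counts for p in profiles], axis=0)
    return TrinucleotideProfile(sample_id, counts, n_skipped=sum(p.n_skipped for p in profiles))


def profile_matrix(profiles: Sequence[TrinucleotideProfile]) -> pd.DataFrame:
    """Samples x 64 fraction matrix (columns = trinucleotides AAA..TTT)."""
    return pd.DataFrame([p.to_series() for p in profiles])
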