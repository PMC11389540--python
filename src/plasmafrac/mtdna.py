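"""Mitochondrial-DNA fraction of a sequencing sample.

The fraction is computed at the *read* level, as a percentage:
``mtDNA_fraction = reads on the mitochondrial contig / aligned reads * 100``.
The fragment-level proportion is also reported for transparency (for proper
pairs it equals the read-level value).
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from collections.abc import Sequence

from .fragments import FilterPolicy, count_reads
from .genome import DEFAULT_MITO_NAMES


@dataclasses.dataclass(frozen=True)
class MtDnaResult:
    sample_id: str
    chrm_reads: int
    aligned_reads: int

    def __post_init__(self) -> None:
        if not 0 <= self.chrm_reads <= self.aligned_reads:
            raise ValueError("chrM reads must lie in [0, aligned reads]")

    @property
    def fraction_percent(self) -> float:
        return self.chrm_reads / self.aligned_reads * 100.0


def mtdna_fraction(
    aligned_reads: int,
    per_contig: Counter | dict,
    sample_id: str = "",
    mito_names: Sequence[str] = DEFAULT_MITO_NAMES,
) -> MtDnaResult:
    """Build an MtDnaResult from read counts (as returned by count_reads).

    Mitochondrial contigs are matched case-insensitively against
    ``mito_names``.
    """
    if aligned_reads <= 0:
        raise ValueError("no aligned reads: mtDNA fraction undefined")
    lowered = {m.lower() for m in mito_names}
    chrm = sum(c for name, c in per_contig.items() if name and name.lower() in lowered)
    return MtDnaResult(sample_id=sample_id, chrm_reads=chrm, aligned_reads=aligned_reads)


def mtdna_fraction_from_file(path, policy: FilterPolicy | None = None, sample_id: str = "",
                             mito_names: Sequence[str] = DEFAULT_MITO_NAMES) -> MtDnaResult:
    total, per_contig = count_reads(path, policy)
    return mtdna_fraction(total, per_contig, sample_id=sample_id, mito_names=mito_names)
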