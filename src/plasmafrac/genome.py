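"""Reference sequences: generation, FASTA I/O, and fast base-code access.

Sequences are held as ``uint8`` code arrays (A=0, C=1, G=2, T=3, anything
else 4) so fragment-end trinucleotides and rejection sampling can be
computed with vectorised gathers instead of per-base string slicing.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pyfaidx

DEFAULT_MITO_NAMES = ("chrM", "MT")

_CODE_OF_BASE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF_BASE[_b] = _i
    _CODE_OF_BASE[_b + 32] = _i  # lower case
_BASE_OF_CODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str | bytes) -> np.ndarray:
    """Map a nucleotide string to the internal 0..4 code array."""
    raw = seq.encode() if isinstance(seq, str) else bytes(seq)
    return _CODE_OF_BASE[np.frombuffer(raw, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _BASE_OF_CODE[codes].tobytes().decode()


@dataclasses.dataclass(frozen=True)
class GenomeSpec:
    """Blueprint for a small synthetic reference.

    Parameters
    ----------
    contigs:
        Ordered ``(name, length_bp)`` pairs. Exactly one name must equal
        ``mito_contig``; the rest are treated as autosome-like.
    mito_contig:
        Name of the mitochondrial-like contig.
    base_composition:
        Optional per-contig ACGT weights; defaults to uniform.
    seed:
        Seed for the base sampler; identical specs give byte-identical FASTA.
    """

    contigs: tuple[tuple[str, int], ...]
    mito_contig: str = "chrM"
    base_composition: Mapping[str, Sequence[float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        names = [n for n, _ in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate contig names in GenomeSpec")
        if any(length <= 0 for _, length in self.contigs):
            raise ValueError("zero- or negative-length contig in GenomeSpec")
        if self.mito_contig not in names:
            raise ValueError(
                f"mitochondrial contig {self.mito_contig!r} not among contigs"
            )

    @property
    def autosomes(self) -> tuple[tuple[str, int], ...]:
        return tuple((n, l) for n, l in self.contigs if n != self.mito_contig)


class Genome:
    """In-memory reference: ordered contigs of base-code arrays."""

    def __init__(
        self,
        sequences: Mapping[str, np.ndarray],
        mito_contig: str | None = None,
    ) -> None:
        self.names: tuple[str, ...] = tuple(sequences)
        self._codes = {n: np.asarray(c, dtype=np.uint8) for n, c in sequences.items()}
        self._codes_int: dict[str, np.ndarray] = {}
        if mito_contig is None:
            lowered = {n.lower(): n for n in self.names}
            mito_contig = next(
                (lowered[m.lower()] for m in DEFAULT_MITO_NAMES if m.lower() in lowered),
                None,
            )
        self.mito_contig = mito_contig

    def __contains__(self, name: str) -> bool:
        return name in self._codes

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(c) for n, c in self._codes.items()}

    def codes(self, name: str) -> np.ndarray:
        return self._codes[name]

    def codes_int(self, name: str) -> np.ndarray:
        """Base codes widened to int64 (cached); safe for index arithmetic."""
        if name not in self._codes_int:
            self._codes_int[name] = self._codes[name].astype(np.int64)
        return self._codes_int[name]

    def sequence(self, name: str, start: int | None = None, end: int | None = None) -> str:
        return decode(self._codes[name][start:end])

    @classmethod
    def from_fasta(cls, path, mito_contig: str | None = None) -> "Genome":
        fa = pyfaidx.Fasta(str(path), as_raw=True, rebuild=True)
        seqs = {name: encode(str(fa[name][:])) for name in fa.keys()}
        fa.close()
        return cls(seqs, mito_contig=mito_contig)

    def write_fasta(self, path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name in self.names:
                fh.write(f">{name}\n")
                seq = decode(self._codes[name])
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def generate_reference(spec: GenomeSpec, path=None) -> Genome:
    """Sample a reference genome from *spec*; optionally write it as FASTA.

    Deterministic for a given spec: each contig is drawn from its own
    child stream of ``spec.seed`` so contig content does not depend on
    the order or presence of other contigs.
    """
    seqs: dict[str, np.ndarray] = {}
    for idx, (name, length) in enumerate(spec.contigs):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, idx]))
        weights = None
        if spec.base_composition and name in spec.base_composition:
            w = np.asarray(spec.base_composition[name], dtype=float)
            if w.shape != (4,) or w.sum() <= 0 or (w < 0).any():
                raise ValueError(f"bad base composition for contig {name!r}")
            weights = w / w.sum()
        seqs[name] = rng.choice(4, size=length, p=weights).astype(np.uint8)
    genome = Genome(seqs, mito_contig=spec.mito_contig)
    if path is not None:
        genome.write_fasta(path)
    return genome
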