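"""Synthetic plasma-DNA cohorts with the statistical structure of SEC-fractionated
cell-free DNA sequencing experiments.

The generator emulates, per patient, five sequencing samples: unfractionated
plasma cfDNA and four pooled size-exclusion-chromatography (SEC) fractions
(1-5 = small-EV rich, 7-11, 12-15, 16-20 = EV poor).  Each sample is a set of
paired-end alignment records over a small synthetic reference, with:

* a fragment-length mixture whose mono-nucleosomal component peaks at 167 bp,
  a sub-150 bp short component (stronger in EV-poor fractions), a
  di-nucleosomal component, and a >1,000 bp long component present only in
  fractions 1-5;
* mitochondrial-contig sampling probability per group (EV-rich fractions
  relatively enriched in mtDNA);
* a shared per-patient copy-number-aberration profile mixed into read depth
  at a settable tumor fraction -- the per-bp sampling weight on autosomes is
  ``TF * CN + (1 - TF) * 2``, so binned depth carries the usual
  ``log2((TF*CN + (1-TF)*2) / 2)`` copy-number signal;
* a 64-component 5' fragment-end trinucleotide bias applied by rejection
  sampling against the reference sequence at both fragment ends.

Long fragments in fractions 1-5 are placed copy-number neutrally, emulating
extracellular-vesicle-associated long DNA that is poor in tumor signal.
"""

from __future__ import annotations

import dataclasses
import os
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .fragments import Fragments
from .genome import Genome, GenomeSpec, generate_reference

GROUPS = ("cfDNA", "fr1_5", "fr7_11", "fr12_15", "fr16_20")
SIZE_KINDS = ("short", "mono", "di", "long")

#: Rejection-sampling budget per fragment (total proposals); fragments still
#: unplaced after this many proposals are accepted unconditionally.  The
#: budget is generous because a bias concentrated on one trinucleotide at
#: both fragment ends only accepts ~1 proposal in (1/64)^-2.
_REJECTION_BUDGET = 100_000
#: Upper bound on proposals drawn in one vectorised batch.
_BATCH_LIMIT = 4_000_000


# ---------------------------------------------------------------------------
# profile types
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SizeComponent:
    """One fragment-length mixture component.

    ``family`` is "normal" (discretised normal with sd ``spread``) or
    "peaked" (discretised asymmetric Laplace with left scale ``spread`` and
    right scale ``spread_right``).  The peaked family models the sharp
    mono-nucleosomal maximum, whose modal bin must dominate its neighbours;
    a symmetric normal leaves the 166/167 bp bins in a near-tie.
    """

    kind: str
    weight: float
    mode: int
    spread: float
    family: str = "normal"
    spread_right: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in SIZE_KINDS:
            raise ValueError(f"unknown size component kind {self.kind!r}")
        if self.family not in ("normal", "peaked"):
            raise ValueError(f"unknown length family {self.family!r}")
        if self.weight < 0:
            raise ValueError("negative component weight")
        if self.spread <= 0 or (self.spread_right is not None and self.spread_right <= 0):
            raise ValueError("component spread must be positive")
        if self.kind == "long" and self.mode <= 1000:
            raise ValueError("long component mode must exceed 1,000 bp")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "normal":
            raw = rng.normal(self.mode, self.spread, size=n)
        else:
            b_left, b_right = self.spread, self.spread_right or self.spread
            left = rng.random(n) < b_left / (b_left + b_right)
            off = rng.exponential(np.where(left, b_left, b_right))
            raw = self.mode + np.where(left, -off, off)
        return np.maximum(np.rint(raw).astype(np.int64), 20)


@dataclasses.dataclass(frozen=True)
class SizeMixture:
    """Fragment-length mixture: discretised normals truncated at 20 bp."""

    components: tuple[SizeComponent, ...]

    def __post_init__(self) -> None:
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component weights sum to {total}, not 1")

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    def component_weight(self, kind: str) -> float:
        return sum(c.weight for c in self.components if c.kind == kind)


@dataclasses.dataclass(frozen=True)
class CNASegment:
    """A constant-copy-number interval; 0-based half-open coordinates."""

    contig: str
    start: int
    end: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.start >= self.end or self.start < 0:
            raise ValueError("CNASegment requires 0 <= start < end")
        if self.copy_number not in (1, 2, 3):
            raise ValueError("copy_number must be one of {1, 2, 3}")


@dataclasses.dataclass(frozen=True)
class SampleProfile:
    """Generator parameters for one sequencing sample."""

    patient_id: str
    group: str
    tumor_fraction: float
    cna_segments: tuple[CNASegment, ...]
    size_mixture: SizeMixture
    mtdna_prob: float
    end_bias: tuple[float, ...]  # 64 weights, trinucleotides AAA..TTT
    n_fragments: int
    seed: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction outside [0, 1]")
        if not 0.0 <= self.mtdna_prob <= 1.0:
            raise ValueError("mtdna_prob outside [0, 1]")
        if self.n_fragments <= 0:
            raise ValueError("n_fragments must be positive")
        bias = np.asarray(self.end_bias, dtype=float)
        if bias.shape != (64,):
            raise ValueError("end_bias must have exactly 64 entries")
        if (bias < 0).any() or bias.sum() == 0:
            raise ValueError("end_bias must be non-negative and not all zero")
        _check_segments(self.cna_segments)

    @property
    def sample_id(self) -> str:
        return f"{self.patient_id}_{self.group}"


def _check_segments(segments: Sequence[CNASegment]) -> None:
    by_contig: dict[str, list[CNASegment]] = {}
    for seg in segments:
        by_contig.setdefault(seg.contig, []).append(seg)
    for segs in by_contig.values():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if a.end > b.start:
                raise ValueError(f"overlapping CNA segments on {a.contig}")


# ---------------------------------------------------------------------------
# group defaults
# ---------------------------------------------------------------------------

def _mono(weight: float) -> SizeComponent:
    # sharp asymmetric mono-nucleosomal peak at 167 bp
    return SizeComponent("mono", weight, 167, 6.0, family="peaked", spread_right=4.0)


#: Fragment-length mixtures per group.  Modes: short sub-nucleosomal DNA at
#: 145 bp, mono-nucleosomal 167 bp, di-nucleosomal 334 bp, EV-associated long
#: DNA at 1,500 bp (fractions 1-5 only).  EV-poor fractions carry more of the
#: short component, which drives their higher P20_150.
DEFAULT_MIXTURES: dict[str, tuple[SizeComponent, ...]] = {
    "cfDNA": (SizeComponent("short", 0.10, 145, 15.0), _mono(0.82), SizeComponent("di", 0.08, 334, 25.0)),
    "fr1_5": (SizeComponent("short", 0.08, 145, 15.0), _mono(0.72), SizeComponent("di", 0.08, 334, 25.0),
              SizeComponent("long", 0.12, 1500, 300.0)),
    "fr7_11": (SizeComponent("short", 0.22, 145, 15.0), _mono(0.72), SizeComponent("di", 0.06, 334, 25.0)),
    "fr12_15": (SizeComponent("short", 0.25, 145, 15.0), _mono(0.69), SizeComponent("di", 0.06, 334, 25.0)),
    "fr16_20": (SizeComponent("short", 0.24, 145, 15.0), _mono(0.70), SizeComponent("di", 0.06, 334, 25.0)),
}

#: Mitochondrial sampling probability per group: cohort medians of 0.69% for
#: total plasma cfDNA and 3.1% for the small-EV-rich fractions; the EV-poor
#: fractions behave like unfractionated cfDNA.
DEFAULT_MTDNA_PROB: dict[str, float] = {
    "cfDNA": 0.0069,
    "fr1_5": 0.031,
    "fr7_11": 0.0069,
    "fr12_15": 0.0069,
    "fr16_20": 0.0069,
}


def default_mixture(group: str) -> SizeMixture:
    return SizeMixture(DEFAULT_MIXTURES[group])


def default_end_bias(group: str) -> tuple[float, ...]:
    """Mild C-start preference at fragment 5' ends, stronger in plasma cfDNA
    than in SEC fractions (end composition differs between unfractionated
    cfDNA and the fractions, but not among fractions)."""
    bias = np.ones(64)
    c_start = slice(16, 32)  # trinucleotides beginning with C in AAA..TTT order
    bias[c_start] = 1.8 if group == "cfDNA" else 1.3
    return tuple(bias)


def default_genome_spec(seed: int = 0) -> GenomeSpec:
    """Three 8-Mb autosome-like contigs (240 bins at 100 kb) plus a 16-kb
    mitochondrial-like contig."""
    return GenomeSpec(
        contigs=(("chr1", 8_000_000), ("chr2", 8_000_000), ("chr3", 8_000_000), ("chrM", 16_000)),
        mito_contig="chrM",
        seed=seed,
    )


# ---------------------------------------------------------------------------
# single-sample simulation
# ---------------------------------------------------------------------------


def _interval_table(genome: Genome, profile_segments: Sequence[CNASegment], mito: str):
    """Autosome intervals (contig_idx, start, end, copy_number) covering every
    non-mitochondrial contig, CN=2 outside the profile's segments."""
    rows: list[tuple[int, int, int, int]] = []
    for ci, name in enumerate(genome.names):
        if name == mito:
            continue
        length = len(genome.codes(name))
        segs = sorted((s for s in profile_segments if s.contig == name), key=lambda s: s.start)
        pos = 0
        for seg in segs:
            if seg.end > length:
                raise ValueError(f"CNA segment beyond contig bounds on {name}")
            if seg.start > pos:
                rows.append((ci, pos, seg.start, 2))
            rows.append((ci, seg.start, seg.end, seg.copy_number))
            pos = seg.end
        if pos < length:
            rows.append((ci, pos, length, 2))
    return np.array(rows, dtype=np.int64)


def _draw_positions(rng, table: np.ndarray, weights_per_bp: np.ndarray, n: int):
    """Sample n genome positions, per-bp weight piecewise constant on table."""
    span = table[:, 2] - table[:, 1]
    w = span.astype(float) * weights_per_bp
    cum = np.cumsum(w)
    u = rng.random(n) * cum[-1]
    iv = np.searchsorted(cum, u, side="right")
    offset = ((u - (cum[iv] - w[iv])) / weights_per_bp[iv]).astype(np.int64)
    offset = np.minimum(offset, span[iv] - 1)
    return table[iv, 0], table[iv, 1] + offset


def simulate_sample(
    profile: SampleProfile,
    genome: Genome,
    out_path=None,
    read_length: int = 150,
) -> Fragments:
    """Draw ``profile.n_fragments`` aligned fragments; optionally write a
    coordinate-sorted SAM file of proper read pairs.

    Fragments are assigned to the mitochondrial contig with probability
    ``mtdna_prob`` and otherwise placed on autosome-like contigs with per-bp
    weight ``TF*CN + (1-TF)*2`` from the patient's copy-number profile
    (long fragments in group fr1_5 and all mitochondrial fragments are placed
    copy-number neutrally).  Fragment 5'-end placement is biased by
    ``end_bias`` via rejection sampling on the reference trinucleotide at
    both ends, capped at 1,000 rounds.
    """
    mito = genome.mito_contig
    if mito is None or mito not in genome:
        raise ValueError("genome lacks a mitochondrial contig")
    for seg in profile.cna_segments:
        if seg.contig not in genome:
            raise ValueError(f"CNA segment contig {seg.contig!r} missing from genome")

    rng = np.random.default_rng(profile.seed)
    n = profile.n_fragments
    comps = profile.size_mixture.components
    lengths_by_name = genome.lengths
    mito_idx = genome.names.index(mito)
    mito_len = lengths_by_name[mito]

    comp_idx = rng.choice(len(comps), size=n, p=profile.size_mixture.weights)
    lengths = np.empty(n, dtype=np.int64)
    for j, comp in enumerate(comps):
        sel = comp_idx == j
        lengths[sel] = comp.draw(rng, int(sel.sum()))

    is_mito = rng.random(n) < profile.mtdna_prob
    is_long = np.array([c.kind == "long" for c in comps])[comp_idx]
    # EV-associated long DNA in the sEV-rich fraction carries no tumor signal
    neutral = is_mito | (is_long & (profile.group == "fr1_5"))

    lengths[is_mito] = np.minimum(lengths[is_mito], mito_len)

    table = _interval_table(genome, profile.cna_segments, mito)
    tf = profile.tumor_fraction
    cna_w = tf * table[:, 3].astype(float) + (1.0 - tf) * 2.0
    flat_w = np.ones(len(table))

    contig_idx = np.empty(n, dtype=np.int64)
    start = np.empty(n, dtype=np.int64)
    contig_len = np.array([lengths_by_name[name] for name in genome.names], dtype=np.int64)

    def propose(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Draw one candidate (contig, start) per entry of idx."""
        ci = np.empty(len(idx), dtype=np.int64)
        pos = np.empty(len(idx), dtype=np.int64)
        m = is_mito[idx]
        if m.any():
            ci[m] = mito_idx
            pos[m] = rng.integers(0, mito_len - lengths[idx[m]] + 1)
        a = ~m
        if a.any():
            flat = neutral[idx] & a
            cnaw = ~neutral[idx] & a
            for mask, w in ((flat, flat_w), (cnaw, cna_w)):
                if not mask.any():
                    continue
                c, p = _draw_positions(rng, table, w, int(mask.sum()))
                p = np.clip(p, 0, contig_len[c] - lengths[idx[mask]])
                ci[mask] = c
                pos[mask] = p
        return ci, pos

    def end_accept_prob(ci: np.ndarray, pos: np.ndarray, lens: np.ndarray,
                        bias: np.ndarray) -> np.ndarray:
        wmax = bias.max()
        out = np.empty(len(ci))
        for c in np.unique(ci):
            sel = ci == c
            g = genome.codes_int(genome.names[c])
            s = pos[sel]
            e = s + lens[sel]
            b5 = np.stack([g[s], g[s + 1], g[s + 2]])
            b3 = np.stack([3 - g[e - 1], 3 - g[e - 2], 3 - g[e - 3]])
            ok = (b5 < 4).all(axis=0) & (b3 >= 0).all(axis=0) & (b3 < 4).all(axis=0)
            c5 = np.where(ok, b5[0] * 16 + b5[1] * 4 + b5[2], 0)
            c3 = np.where(ok, b3[0] * 16 + b3[1] * 4 + b3[2], 0)
            p = (bias[c5] / wmax) * (bias[c3] / wmax)
            out[sel] = np.where(ok, p, 1.0)  # ambiguous bases: accept
        return out

    bias = np.asarray(profile.end_bias, dtype=float)
    uniform_bias = np.allclose(bias, bias[0])
    active = np.arange(n)
    if uniform_bias:
        contig_idx[active], start[active] = propose(active)
    else:
        # adaptive batched rejection: each round draws `reps` candidate
        # placements per unplaced fragment and keeps the first acceptance
        reps, spent = 1, 0
        while len(active) and spent < _REJECTION_BUDGET:
            reps = int(min(reps, max(1, _BATCH_LIMIT // len(active))))
            tiled = np.repeat(active, reps)
            ci, pos = propose(tiled)
            p = end_accept_prob(ci, pos, lengths[tiled], bias)
            hit = (rng.random(len(tiled)) < p).reshape(len(active), reps)
            first = np.argmax(hit, axis=1)
            won = hit.any(axis=1)
            rows = np.flatnonzero(won)
            flat = rows * reps + first[won]
            contig_idx[active[won]] = ci[flat]
            start[active[won]] = pos[flat]
            active = active[~won]
            spent += reps
            reps = min(reps * 8, 1024)
        if len(active):  # budget exhausted: accept the next proposal as-is
            contig_idx[active], start[active] = propose(active)

    frags = Fragments(
        contig_names=genome.names,
        contig_idx=contig_idx,
        start=start,
        length=lengths,
        sample_id=profile.sample_id,
    )
    if out_path is not None:
        write_sam(frags, genome, out_path, read_length=read_length)
    return frags


def write_sam(frags: Fragments, genome: Genome, path, read_length: int = 150, mapq: int = 60) -> None:
    """Write fragments as coordinate-sorted proper read pairs in SAM format.

    Each fragment yields two primary records: the plus-strand mate at the
    fragment start with positive template length, the minus-strand mate
    ending at the fragment end with the negated template length.  Sequences
    are omitted ('*'): downstream analyses work from coordinates and the
    reference, as fragment-end motifs are defined by mapped positions.
    """
    n = len(frags)
    lengths = frags.length
    rl = np.minimum(lengths, read_length).astype(np.int64)
    # two records per fragment
    tid = np.repeat(frags.contig_idx, 2)
    pos = np.empty(2 * n, dtype=np.int64)
    pos[0::2] = frags.start
    pos[1::2] = frags.start + lengths - rl
    flag = np.empty(2 * n, dtype=np.int64)
    flag[0::2] = 99   # paired, proper, mate reverse, first of pair
    flag[1::2] = 147  # paired, proper, reverse, second of pair
    tlen = np.empty(2 * n, dtype=np.int64)
    tlen[0::2] = lengths
    tlen[1::2] = -lengths
    mate_pos = np.empty(2 * n, dtype=np.int64)
    mate_pos[0::2] = pos[1::2]
    mate_pos[1::2] = pos[0::2]
    qname_idx = np.repeat(np.arange(n), 2)
    rlen2 = np.repeat(rl, 2)

    order = np.lexsort((pos, tid))
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": genome.lengths[name]} for name in genome.names],
        }
    )
    sample = frags.sample_id or "sample"
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i in order:
            a = pysam.AlignedSegment(header)
            a.query_name = f"{sample}:{qname_idx[i]}"
            a.flag = int(flag[i])
            a.reference_id = int(tid[i])
            a.reference_start = int(pos[i])
            a.mapping_quality = mapq
            a.cigarstring = f"{int(rlen2[i])}M"
            a.next_reference_id = int(tid[i])
            a.next_reference_start = int(mate_pos[i])
            a.template_length = int(tlen[i])
            out.write(a)


def inject_noise(in_path, out_path, dup_rate: float, lowmapq_rate: float, seed: int):
    """Flag a deterministic proportion of pairs as PCR duplicates and rewrite
    MAPQ below 5 for another proportion; record count is unchanged.

    Whole pairs are affected (both mates), mirroring coordinate-based
    duplicate marking.  Exactly ``round(rate * n_pairs)`` pairs are chosen
    per rate, without replacement, from a seeded stream.
    """
    for name, rate in (("dup_rate", dup_rate), ("lowmapq_rate", lowmapq_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    with pysam.AlignmentFile(str(in_path)) as fh:
        header = fh.header
        records = list(fh)
    qnames: list[str] = []
    seen: set[str] = set()
    for r in records:
        if r.query_name not in seen:
            seen.add(r.query_name)
            qnames.append(r.query_name)
    n_pairs = len(qnames)
    rng = np.random.default_rng(seed)
    n_dup = int(round(dup_rate * n_pairs))
    n_low = int(round(lowmapq_rate * n_pairs))
    dup_set = {qnames[i] for i in rng.choice(n_pairs, size=n_dup, replace=False)} if n_dup else set()
    low_set = {qnames[i] for i in rng.choice(n_pairs, size=n_low, replace=False)} if n_low else set()
    with pysam.AlignmentFile(str(out_path), "w", header=header) as out:
        for r in records:
            if r.query_name in dup_set:
                r.flag |= 0x400
            if r.query_name in low_set:
                r.mapping_quality = 3
            out.write(r)
    return out_path


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Study-level generator settings.

    Defaults emulate the study conditions: 16 patients, five samples per
    patient, 200,000 fragments per sample, patients with clearly detectable
    tumor fraction (0.08-0.40), mtDNA probabilities of 0.69% (plasma cfDNA
    and EV-poor fractions) and 3.1% (sEV-rich fraction).
    """

    seed: int = 0
    n_patients: int = 16
    n_fragments: int = 200_000
    genome_spec: GenomeSpec | None = None
    tumor_fraction_range: tuple[float, float] = (0.08, 0.40)
    mtdna_prob: dict[str, float] | None = None
    n_panel_normals: int = 8
    cna_segment_bins: tuple[int, int] = (15, 25)  # segment length range, 100-kb units

    def resolved_genome_spec(self) -> GenomeSpec:
        return self.genome_spec or default_genome_spec(seed=self.seed)

    def group_mtdna_prob(self, group: str) -> float:
        table = dict(DEFAULT_MTDNA_PROB)
        if self.mtdna_prob:
            table.update(self.mtdna_prob)
        return table[group]


def _sample_seed(master: int, patient_idx: int, group_idx: int) -> int:
    """Per-sample seed rule: a child stream of the master seed keyed by
    (patient, group), folded below 2**31 so samples are independently
    reproducible."""
    ss = np.random.SeedSequence([int(master), int(patient_idx), int(group_idx)])
    return int(ss.generate_state(1)[0] >> 1)


def _patient_cna(rng, genome_spec: GenomeSpec, segment_bins: tuple[int, int]) -> tuple[CNASegment, ...]:
    """One gain (CN=3) and one loss (CN=1) segment per patient on distinct
    autosome-like contigs, aligned to 100-kb boundaries."""
    autos = genome_spec.autosomes
    order = rng.permutation(len(autos))
    segs = []
    for cn, which in ((3, order[0]), (1, order[1 % len(autos)])):
        name, length = autos[which]
        n_bins = int(rng.integers(segment_bins[0], segment_bins[1] + 1))
        n_bins = min(n_bins, length // 100_000)  # cap at contig size
        if n_bins < 1:
            continue
        seg_len = n_bins * 100_000
        max_start = (length - seg_len) // 100_000
        start = int(rng.integers(0, max_start + 1)) * 100_000
        segs.append(CNASegment(name, start, start + seg_len, cn))
    return tuple(segs)


def build_cohort(n_patients: int, config: CohortConfig | None = None) -> list[SampleProfile]:
    """Five profiles per patient sharing patient_id, tumor fraction and the
    patient's copy-number profile, with group-specific defaults."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    config = config or CohortConfig()
    spec = config.resolved_genome_spec()
    profiles: list[SampleProfile] = []
    for p in range(n_patients):
        prng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919, p]))
        tf = float(prng.uniform(*config.tumor_fraction_range))
        cna = _patient_cna(prng, spec, config.cna_segment_bins)
        patient_id = f"P{p + 1:02d}"
        for g, group in enumerate(GROUPS):
            profiles.append(
                SampleProfile(
                    patient_id=patient_id,
                    group=group,
                    tumor_fraction=tf,
                    cna_segments=cna,
                    size_mixture=default_mixture(group),
                    mtdna_prob=config.group_mtdna_prob(group),
                    end_bias=default_end_bias(group),
                    n_fragments=config.n_fragments,
                    seed=_sample_seed(config.seed, p, g),
                )
            )
    return profiles


def build_panel_profiles(config: CohortConfig | None = None, n_normals: int | None = None) -> list[SampleProfile]:
    """Tumor-free unfractionated profiles for the copy-number panel of normals."""
    config = config or CohortConfig()
    n_normals = config.n_panel_normals if n_normals is None else n_normals
    return [
        SampleProfile(
            patient_id=f"N{i + 1:02d}",
            group="cfDNA",
            tumor_fraction=0.0,
            cna_segments=(),
            size_mixture=default_mixture("cfDNA"),
            mtdna_prob=config.group_mtdna_prob("cfDNA"),
            end_bias=default_end_bias("cfDNA"),
            n_fragments=config.n_fragments,
            seed=_sample_seed(config.seed, 100_000 + i, 0),
        )
        for i in range(n_normals)
    ]


def cohort_manifest(profiles: Iterable[SampleProfile], rel_dir: str = ".") -> pd.DataFrame:
    """Manifest table with sample paths relative to the manifest location,
    so identical seeds give byte-identical manifests wherever they land."""
    rows = [
        {
            "sample_id": p.sample_id,
            "patient_id": p.patient_id,
            "group": p.group,
            "path": os.path.normpath(os.path.join(rel_dir, f"{p.sample_id}.sam")),
            "seed": p.seed,
        }
        for p in profiles
    ]
    return pd.DataFrame(rows, columns=["sample_id", "patient_id", "group", "path", "seed"])


def simulate_cohort(
    profiles: Sequence[SampleProfile],
    genome: Genome,
    sample_dir,
    manifest_path=None,
) -> pd.DataFrame:
    """Simulate every profile into ``sample_dir`` and write the manifest
    (default ``sample_dir/manifest.tsv``; paths relative to the manifest)."""
    sample_dir = str(sample_dir)
    os.makedirs(sample_dir, exist_ok=True)
    manifest_path = str(manifest_path) if manifest_path else os.path.join(sample_dir, "manifest.tsv")
    base = os.path.dirname(os.path.abspath(manifest_path))
    manifest = cohort_manifest(profiles, os.path.relpath(os.path.abspath(sample_dir), base))
    for profile in profiles:
        simulate_sample(profile, genome, out_path=os.path.join(sample_dir, f"{profile.sample_id}.sam"))
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return manifest


__all__ = [
    "GROUPS",
    "SizeComponent",
    "SizeMixture",
    "CNASegment",
    "SampleProfile",
    "CohortConfig",
    "default_mixture",
    "default_end_bias",
    "default_genome_spec",
    "simulate_sample",
    "write_sam",
    "inject_noise",
    "build_cohort",
    "build_panel_profiles",
    "simulate_cohort",
    "cohort_manifest",
    "generate_reference",
    "Genome",
    "GenomeSpec",
]
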