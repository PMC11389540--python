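"""Binned copy-number analysis and constrained tumor-fraction estimation
from shallow whole-genome sequencing depth.

Pipeline: fragments are counted into fixed-width genomic bins (default
100 kb, mitochondrial contig excluded); per-bin depth is normalised against
a panel of tumor-free normals; the resulting log2 ratios are modelled with a
three-state Gaussian hidden Markov model over copy numbers CN in {1, 2, 3}
whose state means are tied to a single tumor-fraction parameter

    mu_CN(TF) = log2( (TF * CN + (1 - TF) * 2) / 2 ),

i.e. a two-population mixture of tumor (copy number CN) and normal (CN = 2)
DNA around diploid ploidy.  The tumor fraction is selected by profiling the
HMM log-likelihood over a grid of TF values seeded at the conventional
high-purity non-tumor restarts (0.95, 0.99, 0.995, 0.999, i.e. TF 0.05,
0.01, 0.005, 0.001) plus a dense grid on [0, 0.6]; the highest
log-likelihood solution wins, with ties broken toward the smaller TF.
This is a deliberately small estimator: ploidy is fixed at 2, the maximum
copy number is capped at 3, there are no subclonal states, and no GC or
mappability correction is applied.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .fragments import as_fragments
from .genome import DEFAULT_MITO_NAMES, Genome

CN_STATES = np.array([1, 2, 3])

#: Non-tumor fraction restart values; equivalently TF restarts 0.05..0.001.
NON_TUMOR_RESTARTS = (0.95, 0.99, 0.995, 0.999)


def default_tf_grid() -> np.ndarray:
    dense = np.round(np.arange(0.0, 0.6 + 1e-12, 0.005), 4)
    restarts = np.round(1.0 - np.asarray(NON_TUMOR_RESTARTS), 4)
    return np.unique(np.concatenate([dense, restarts]))


# ---------------------------------------------------------------------------
# binning and normalisation
# ---------------------------------------------------------------------------


def make_bins(genome, bin_width: int = 100_000, exclude=DEFAULT_MITO_NAMES) -> pd.DataFrame:
    """Tile every non-mitochondrial contig with fixed-width bins.

    Trailing partial bins are kept and flagged in the ``partial`` column.
    """
    if bin_width < 1_000:
        raise ValueError("bin_width must be >= 1,000 bp")
    lengths = genome.lengths if isinstance(genome, Genome) else dict(genome)
    excluded = {e.lower() for e in exclude}
    rows = []
    for contig, length in lengths.items():
        if contig.lower() in excluded:
            continue
        for start in range(0, length, bin_width):
            end = min(start + bin_width, length)
            rows.append((contig, start, end, end - start < bin_width))
    if not rows:
        raise ValueError("no autosome-like contigs to bin")
    return pd.DataFrame(rows, columns=["contig", "start", "end", "partial"])


@dataclasses.dataclass
class BinnedCounts:
    sample_id: str
    bins: pd.DataFrame
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.bins):
            raise ValueError("counts do not match bins")

    def to_frame(self) -> pd.DataFrame:
        out = self.bins.copy()
        out["count"] = self.counts
        return out


def bin_counts(fragments, genome, bin_width: int = 100_000,
               exclude=DEFAULT_MITO_NAMES, bins: pd.DataFrame | None = None) -> BinnedCounts:
    """Count fragments per bin, assigning each fragment to the bin that
    contains its midpoint."""
    frags = as_fragments(fragments)
    if bins is None:
        bins = make_bins(genome, bin_width=bin_width, exclude=exclude)
    lengths = genome.lengths if isinstance(genome, Genome) else dict(genome)
    for name in frags.contig_names:
        if name not in lengths:
            raise KeyError(f"contig {name!r} absent from genome")
    counts = np.zeros(len(bins), dtype=np.int64)
    mid = frags.start + frags.length // 2
    bin_index = {contig: grp for contig, grp in bins.groupby("contig", sort=False)}
    for ci, name in enumerate(frags.contig_names):
        grp = bin_index.get(name)
        if grp is None:
            continue  # excluded contig (e.g. chrM)
        sel = frags.contig_idx == ci
        if not sel.any():
            continue
        idx = grp.index.to_numpy()
        width = int(grp["end"].iloc[0] - grp["start"].iloc[0]) if len(grp) == 1 else int(
            grp["start"].iloc[1] - grp["start"].iloc[0]
        )
        which = np.clip(mid[sel] // width, 0, len(idx) - 1).astype(np.int64)
        counts += np.bincount(idx[which], minlength=len(bins))
    return BinnedCounts(sample_id=frags.sample_id, bins=bins, counts=counts)


@dataclasses.dataclass
class PanelOfNormals:
    """Per-bin reference: median of depth-normalised counts across normals.

    ``mask`` marks bins whose median is zero; these are excluded from log2
    ratios and the likelihood.
    """

    bins: pd.DataFrame
    reference: np.ndarray
    mask: np.ndarray

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())


def build_panel_of_normals(normals: list[BinnedCounts]) -> PanelOfNormals:
    if len(normals) < 3:
        raise ValueError("panel of normals requires at least 3 samples")
    bins = normals[0].bins
    for s in normals[1:]:
        if len(s.bins) != len(bins):
            raise ValueError("panel samples use different binnings")
    depth_norm = np.stack([s.counts / s.counts.mean() for s in normals])
    reference = np.median(depth_norm, axis=0)
    return PanelOfNormals(bins=bins, reference=reference, mask=reference == 0)


def log2_ratios(sample: BinnedCounts, panel: PanelOfNormals) -> np.ndarray:
    """Per-bin log2((sample depth / sample mean) / panel reference); masked
    bins propagate as NaN."""
    if len(sample.bins) != len(panel.bins):
        raise ValueError("sample and panel use different binnings")
    usable = ~panel.mask
    if not usable.any():
        raise ValueError("all bins masked in the panel")
    mean = sample.counts[usable].mean()
    if mean == 0:
        raise ValueError("sample has no fragments in unmasked bins")
    out = np.full(len(sample.bins), np.nan)
    out[usable] = np.log2(
        np.maximum(sample.counts[usable] / mean, 1e-12) / panel.reference[usable]
    )
    return out


# ---------------------------------------------------------------------------
# tumor-fraction HMM
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TumorFractionEstimate:
    sample_id: str
    tumor_fraction: float
    log_likelihood: float
    tf_grid: np.ndarray
    grid_log_likelihood: np.ndarray
    sigma: float

    @property
    def selected_solution(self) -> str:
        return f"tf={self.tumor_fraction:.3f}"


@dataclasses.dataclass
class CNAProfile:
    sample_id: str
    log2ratio: np.ndarray
    state: np.ndarray  # copy-number call per bin; neutral (2) where masked


def state_means(tf: float | np.ndarray) -> np.ndarray:
    """HMM emission means for CN in {1,2,3} at tumor fraction ``tf``."""
    tf = np.asarray(tf, dtype=float)
    return np.log2((tf[..., None] * CN_STATES + (1.0 - tf[..., None]) * 2.0) / 2.0)


class TumorFractionHMM:
    """Three-state Gaussian HMM with TF-tied means, fit by grid profiling.

    Parameters
    ----------
    tf_grid:
        Candidate tumor fractions; defaults to the 0.005-step grid on
        [0, 0.6] plus the high-purity restarts.
    self_transition:
        Probability of staying in the same copy-number state between
        adjacent bins (off-diagonal mass split evenly).
    sigma_floor:
        Lower bound on the shared emission standard deviation; guards
        noiseless inputs.

    Attributes (after :meth:`fit`)
    ------------------------------
    tumor_fraction_, log_likelihood_, sigma_, states_, grid_log_likelihood_
    """

    def __init__(self, tf_grid=None, self_transition: float = 0.99, sigma_floor: float = 1e-3):
        self.tf_grid = default_tf_grid() if tf_grid is None else np.sort(np.asarray(tf_grid, dtype=float))
        if not 0.0 < self_transition < 1.0:
            raise ValueError("self_transition must lie in (0, 1)")
        self.self_transition = self_transition
        self.sigma_floor = sigma_floor

    # -- internals ---------------------------------------------------------

    def _transition(self) -> np.ndarray:
        off = (1.0 - self.self_transition) / (len(CN_STATES) - 1)
        A = np.full((3, 3), off)
        np.fill_diagonal(A, self.self_transition)
        return A

    @staticmethod
    def _emission_loglik(x: np.ndarray, means: np.ndarray, sigma: np.ndarray) -> np.ndarray:
        # x: (n,), means: (G,3), sigma: (G,) -> (G, n, 3)
        resid = x[None, :, None] - means[:, None, :]
        s = sigma[:, None, None]
        return -0.5 * (resid / s) ** 2 - np.log(s) - 0.5 * np.log(2 * np.pi)

    def _forward(self, E: np.ndarray, also_backward: bool = False):
        """Scaled forward (and optionally backward) pass, vectorised over the
        grid axis.  Returns per-grid log-likelihood and, if requested, the
        posterior state probabilities gamma (G, n, 3)."""
        G, n, K = E.shape
        A = self._transition()
        Emax = E.max(axis=2)  # (G, n)
        e = np.exp(E - Emax[:, :, None])
        pi = np.full(K, 1.0 / K)
        alpha = np.empty((G, n, K)) if also_backward else None
        a = pi[None, :] * e[:, 0, :]
        c = np.empty((G, n))
        c[:, 0] = a.sum(axis=1)
        a = a / c[:, 0][:, None]
        if also_backward:
            alpha[:, 0, :] = a
        for t in range(1, n):
            a = (a @ A) * e[:, t, :]
            c[:, t] = a.sum(axis=1)
            a = a / c[:, t][:, None]
            if also_backward:
                alpha[:, t, :] = a
        loglik = np.log(c).sum(axis=1) + Emax.sum(axis=1)
        if not also_backward:
            return loglik, None
        b = np.ones((G, K))
        gamma = np.empty((G, n, K))
        gamma[:, n - 1, :] = alpha[:, n - 1, :]
        for t in range(n - 2, -1, -1):
            b = ((e[:, t + 1, :] * b) @ A.T) / c[:, t + 1][:, None]
            g = alpha[:, t, :] * b
            gamma[:, t, :] = g / g.sum(axis=1, keepdims=True)
        return loglik, gamma

    def _viterbi(self, x: np.ndarray, means: np.ndarray, sigma: float) -> np.ndarray:
        n = len(x)
        logA = np.log(self._transition())
        E = (-0.5 * ((x[:, None] - means[None, :]) / sigma) ** 2 - np.log(sigma))
        delta = np.log(1.0 / 3.0) + E[0]
        back = np.zeros((n, 3), dtype=np.int64)
        for t in range(1, n):
            cand = delta[:, None] + logA
            back[t] = cand.argmax(axis=0)
            delta = cand.max(axis=0) + E[t]
        path = np.empty(n, dtype=np.int64)
        path[-1] = int(delta.argmax())
        for t in range(n - 2, -1, -1):
            path[t] = back[t + 1, path[t + 1]]
        return CN_STATES[path]

    # -- API ---------------------------------------------------------------

    def fit(self, log2ratio: np.ndarray) -> "TumorFractionHMM":
        x = np.asarray(log2ratio, dtype=float)
        finite = np.isfinite(x)
        xf = x[finite]
        if len(xf) < 50:
            raise ValueError(f"need at least 50 usable bins, got {len(xf)}")
        if np.ptp(xf) == 0:
            raise ValueError("degenerate input: zero variance in log2 ratios")
        grid = self.tf_grid
        means = state_means(grid)  # (G, 3)
        # the shared spread is held common across the whole TF grid: letting
        # each candidate TF refit its own spread lets near-zero TF solutions
        # mimic heavy-tailed noise with three barely separated states and
        # overrules genuine copy-number signal
        mad = np.median(np.abs(xf - np.median(xf)))
        sigma0 = max(1.4826 * mad, self.sigma_floor)  # robust, neutral-bin dominated
        E = self._emission_loglik(xf, means, np.full(len(grid), sigma0))
        loglik0, _ = self._forward(E)
        best0 = int(np.argmax(loglik0))
        # one refinement pass at the provisional optimum, from its posteriors
        E_best = self._emission_loglik(xf, means[[best0]], np.array([sigma0]))
        _, gamma = self._forward(E_best, also_backward=True)
        resid_sq = (xf[None, :, None] - means[[best0], None, :]) ** 2
        sigma1 = max(float(np.sqrt((gamma * resid_sq).sum() / len(xf))), self.sigma_floor)
        E = self._emission_loglik(xf, means, np.full(len(grid), sigma1))
        loglik, _ = self._forward(E)
        best = int(np.argmax(loglik))  # ascending grid: ties go to smaller TF
        tf = float(grid[best])
        sigma = sigma1
        states_f = (
            np.full(len(xf), 2, dtype=np.int64)
            if tf == 0.0
            else self._viterbi(xf, state_means(tf), sigma)
        )
        states = np.full(len(x), 2, dtype=np.int64)
        states[finite] = states_f
        self.tumor_fraction_ = tf
        self.log_likelihood_ = float(loglik[best])
        self.sigma_ = sigma
        self.states_ = states
        self.grid_log_likelihood_ = loglik
        return self


def estimate_tumor_fraction(log2ratio: np.ndarray, sample_id: str = "",
                            **hmm_kwargs) -> tuple[TumorFractionEstimate, CNAProfile]:
    """Fit the constrained HMM and return the highest-likelihood solution."""
    hmm = TumorFractionHMM(**hmm_kwargs).fit(log2ratio)
    estimate = TumorFractionEstimate(
        sample_id=sample_id,
        tumor_fraction=hmm.tumor_fraction_,
        log_likelihood=hmm.log_likelihood_,
        tf_grid=hmm.tf_grid,
        grid_log_likelihood=hmm.grid_log_likelihood_,
        sigma=hmm.sigma_,
    )
    profile = CNAProfile(sample_id=sample_id, log2ratio=np.asarray(log2ratio, dtype=float),
                         state=hmm.states_)
    return estimate, profile
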