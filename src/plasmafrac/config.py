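"""Run configuration for the command-line pipeline (YAML-backed)."""

from __future__ import annotations

import dataclasses

import yaml

from .genome import DEFAULT_MITO_NAMES, GenomeSpec
from .simulate import GROUPS, CohortConfig


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration (usage error, exit code 1)."""


@dataclasses.dataclass(frozen=True)
class AnalysisConfig:
    bin_width: int = 100_000
    size_low: int = 20
    size_high: int = 2000
    pseudocount: float = 1e-6
    mito_names: tuple[str, ...] = DEFAULT_MITO_NAMES
    min_mapq: int = 5


@dataclasses.dataclass(frozen=True)
class CompareConfig:
    alpha: float = 0.05
    adjust: bool = False
    group_pairs: tuple[tuple[str, str], ...] | None = None


@dataclasses.dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    workdir: str = "plasmafrac_run"
    n_patients: int = 4
    n_fragments: int = 20_000
    n_panel_normals: int = 4
    genome: GenomeSpec | None = None
    tumor_fraction_range: tuple[float, float] = (0.08, 0.40)
    mtdna_prob: dict | None = None
    analysis: AnalysisConfig = dataclasses.field(default_factory=AnalysisConfig)
    compare: CompareConfig = dataclasses.field(default_factory=CompareConfig)

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            seed=self.seed,
            n_patients=self.n_patients,
            n_fragments=self.n_fragments,
            genome_spec=self.genome,
            tumor_fraction_range=self.tumor_fraction_range,
            mtdna_prob=self.mtdna_prob,
            n_panel_normals=self.n_panel_normals,
        )


def _genome_from_dict(d: dict) -> GenomeSpec:
    try:
        contigs = tuple((str(n), int(l)) for n, l in d["contigs"])
        return GenomeSpec(
            contigs=contigs,
            mito_contig=str(d.get("mito_contig", "chrM")),
            seed=int(d.get("seed", 0)),
        )
    except (KeyError, TypeError, ValueError) as err:
        raise ConfigError(f"bad genome section: {err}") from err


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(raw)
    if "genome" in kwargs and kwargs["genome"] is not None:
        kwargs["genome"] = _genome_from_dict(kwargs["genome"])
    if "mtdna_prob" in kwargs and kwargs["mtdna_prob"]:
        bad = set(kwargs["mtdna_prob"]) - set(GROUPS)
        if bad:
            raise ConfigError(f"mtdna_prob for unknown groups: {sorted(bad)}")
        kwargs["mtdna_prob"] = {g: float(v) for g, v in kwargs["mtdna_prob"].items()}
    if "tumor_fraction_range" in kwargs:
        lo, hi = kwargs["tumor_fraction_range"]
        if not 0 <= lo <= hi <= 1:
            raise ConfigError("tumor_fraction_range must satisfy 0 <= lo <= hi <= 1")
        kwargs["tumor_fraction_range"] = (float(lo), float(hi))
    if "analysis" in kwargs and kwargs["analysis"] is not None:
        sub = dict(kwargs["analysis"])
        if "mito_names" in sub:
            sub["mito_names"] = tuple(sub["mito_names"])
        try:
            kwargs["analysis"] = AnalysisConfig(**sub)
        except TypeError as err:
            raise ConfigError(f"bad analysis section: {err}") from err
    if "compare" in kwargs and kwargs["compare"] is not None:
        sub = dict(kwargs["compare"])
        if sub.get("group_pairs"):
            sub["group_pairs"] = tuple((str(a), str(b)) for a, b in sub["group_pairs"])
        try:
            kwargs["compare"] = CompareConfig(**sub)
        except TypeError as err:
            raise ConfigError(f"bad compare section: {err}") from err
    try:
        cfg = RunConfig(**kwargs)
    except (TypeError, ValueError) as err:
        raise ConfigError(str(err)) from err
    if cfg.n_patients < 1:
        raise ConfigError("n_patients must be >= 1")
    if cfg.n_fragments < 1:
        raise ConfigError("n_fragments must be >= 1")
    return cfg
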