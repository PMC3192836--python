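"""Simulation configuration.

One root seed drives every generator.  Each stage draws from its own child
RNG, derived from ``(seed, stage offset)`` via :class:`numpy.random.SeedSequence`,
so adding draws to one stage never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .errors import ConfigError

#: canonical species names, in tree order: the first two are the ingroup
#: pair whose divergence the pipeline measures, the third the outgroup.
SPECIES_NAMES = ("human", "chimpanzee", "macaque")

#: fixed per-stage offsets for child RNG derivation (documented contract:
#: identical seed => byte-identical outputs per stage, independent stages).
STAGE_OFFSETS = {
    "reads": 1,
    "expression": 2,
    "transfection": 3,
    "snp": 4,
    "targets": 5,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults emulate the study design the pipeline was built for: three
    primate species, two technical replicates of pooled small-RNA libraries
    per species, negative-binomial read counts with a small implanted
    differentially expressed fraction, and target genes shifted down in the
    species where the targeting miRNA is up.
    """

    seed: int = 0
    n_mirna: int = 200
    n_genes: int = 2000
    n_species: int = 3
    n_replicates: int = 2
    #: expected total mapped miRNA reads per sample
    depth: float = 1_000_000.0
    #: fraction of miRNA implanted as differentially expressed
    de_fraction: float = 0.1
    #: multiplicative fold applied to implanted DE miRNA in the up-species
    de_fold: float = 4.0
    #: expected number of target genes per miRNA
    target_density: float = 3.0
    #: log2 down-shift of true targets in the species where the miRNA is up
    target_effect: float = 1.0
    #: negative-binomial dispersion (gamma-Poisson); near-Poisson by default,
    #: matching technical replicates of pooled libraries
    nb_dispersion: float = 1e-4
    #: Gaussian noise sd on log2 expression values
    noise_sd: float = 0.2
    #: sd of the log-normal miRNA abundance distribution
    abundance_sigma: float = 1.0
    #: length (bp) of the simulated SNP region (the synthetic "genome")
    snp_region_length: int = 150_000
    #: expected SNPs per bp in the simulated region
    snp_density: float = 0.005
    #: background fraction of SNPs classified human-derived
    background_derived_fraction: float = 0.15
    #: implanted sweep windows: (start0, end0, derived_excess_fraction)
    sweep_windows: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_mirna", "n_genes", "n_species", "n_replicates"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {v!r}")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigError(f"de_fraction must be in [0, 1], got {self.de_fraction!r}")
        if self.de_fold <= 1.0:
            raise ConfigError(f"de_fold must be > 1, got {self.de_fold!r}")
        if self.depth <= 0:
            raise ConfigError(f"depth must be > 0, got {self.depth!r}")
        if self.nb_dispersion <= 0:
            raise ConfigError(f"nb_dispersion must be > 0, got {self.nb_dispersion!r}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd!r}")
        if self.target_density < 0:
            raise ConfigError(f"target_density must be >= 0, got {self.target_density!r}")
        if self.snp_region_length < 1:
            raise ConfigError(f"snp_region_length must be >= 1, got {self.snp_region_length!r}")
        if not 0.0 <= self.background_derived_fraction <= 1.0:
            raise ConfigError(
                f"background_derived_fraction must be in [0, 1], "
                f"got {self.background_derived_fraction!r}"
            )
        for w in self.sweep_windows:
            s, e, x = w
            if not (0 <= s < e <= self.snp_region_length):
                raise ConfigError(f"sweep_windows entry {w!r} outside [0, {self.snp_region_length})")
            if not 0.0 <= x <= 1.0 - self.background_derived_fraction:
                raise ConfigError(
                    f"sweep_windows excess {x!r} pushes derived fraction outside [0, 1]"
                )
        ws = sorted((s, e) for s, e, _ in self.sweep_windows)
        for (s1, e1), (s2, e2) in zip(ws, ws[1:]):
            if s2 < e1:
                raise ConfigError(f"sweep_windows overlap: [{s1},{e1}) and [{s2},{e2})")

    def species(self) -> tuple[str, ...]:
        names = list(SPECIES_NAMES[: self.n_species])
        names += [f"species{i + 1}" for i in range(len(names), self.n_species)]
        return tuple(names)

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Child RNG for one pipeline stage (see module docstring)."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), STAGE_OFFSETS[stage]])
        )

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration field(s): {sorted(unknown)}")
        cfg = cls(**d)
        cfg.sweep_windows = [tuple(w) for w in cfg.sweep_windows]
        return cfg

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["sweep_windows"] = [list(w) for w in self.sweep_windows]
        return d
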