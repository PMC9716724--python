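"""Simulation configuration for synthetic panda-style populations.

The simulator emulates a high-density population of a solitary,
bamboo-eating mammal in which males are philopatric and females disperse
from their natal range (female-biased dispersal). Every knob that shapes
the statistical structure of the synthetic data — pedigree depth, dispersal
probabilities, the microsatellite panel, genotyping error rates, survey
effort, and fecal-fragment size distributions per age class — lives in
:class:`SimConfig` so downstream stages can be exercised under controlled
conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "Locus",
    "FragmentDist",
    "SimConfig",
    "ConfigError",
    "default_loci",
    "DEFAULT_FRAGMENT_PARAMS",
]

_FREQ_TOL = 1e-9


class ConfigError(ValueError):
    """Raised when a simulation configuration is invalid or degenerate."""


@dataclass(frozen=True)
class Locus:
    """One microsatellite locus: a name, its allele labels and frequencies.

    Allele labels are opaque strings; the default panel uses zero-padded
    numerals ("01".."08") so that label order coincides with numeric order.
    """

    name: str
    frequencies: tuple[float, ...]

    @property
    def n_alleles(self) -> int:
        return len(self.frequencies)

    @property
    def alleles(self) -> tuple[str, ...]:
        return tuple(f"{i + 1:02d}" for i in range(len(self.frequencies)))

    def validate(self) -> None:
        if self.n_alleles < 2:
            raise ConfigError(f"locus {self.name}: need >= 2 alleles")
        if any(f < 0 for f in self.frequencies):
            raise ConfigError(f"locus {self.name}: negative allele frequency")
        if abs(sum(self.frequencies) - 1.0) > _FREQ_TOL:
            raise ConfigError(
                f"locus {self.name}: allele frequencies sum to "
                f"{sum(self.frequencies)!r}, not 1"
            )


def default_loci(n_loci: int = 15, n_alleles: int = 8) -> tuple[Locus, ...]:
    """Equifrequent default panel: 15 loci x 8 alleles.

    The panel size matches the microsatellite panel used for fecal
    genotyping in the study system; per-locus allele frequencies are not
    published, so a uniform default is used and can be overridden.
    """
    freq = tuple([1.0 / n_alleles] * n_alleles)
    return tuple(Locus(f"L{i + 1:02d}", freq) for i in range(n_loci))


@dataclass(frozen=True)
class FragmentDist:
    """Normal length/width distribution (mm) of bamboo-leaf fragments in feces."""

    length_mean: float
    length_sd: float
    width_mean: float
    width_sd: float


#: Defaults are anchored to the scale of published per-individual fragment
#: means: adults ~28 mm long, sub-adults ~21 mm; elderly animals chew poorly
#: (tooth wear) and leave markedly longer fragments. Defaults, not truth.
DEFAULT_FRAGMENT_PARAMS: dict[str, FragmentDist] = {
    "sub-adult": FragmentDist(21.0, 2.0, 7.0, 1.0),
    "adult": FragmentDist(28.0, 4.0, 8.0, 1.2),
    "elderly": FragmentDist(38.0, 4.0, 10.0, 1.5),
}

_AGE_CLASSES = ("cub", "sub-adult", "adult", "elderly")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic population and sampling process.

    Dispersal is female-biased: sons stay in the study area with
    ``male_philopatry_prob`` while daughters emigrate with
    ``female_emigration_prob``; each generation additionally receives
    ``immigrant_females_per_gen`` unrelated adult females, mirroring the
    turnover that balances emigration in an open population.
    """

    n_founders: int = 10
    n_generations: int = 4
    male_philopatry_prob: float = 0.9
    female_emigration_prob: float = 0.9
    immigrant_females_per_gen: int = 4
    mean_offspring_per_female: float = 1.5
    cub_fraction: float = 0.0
    loci: tuple[Locus, ...] = field(default_factory=default_loci)
    dropout_rate: float = 0.05
    false_allele_rate: float = 0.02
    locus_failure_rate: float = 0.0
    n_replicates: int = 3
    n_surveys: int = 6
    detection_prob: float = 0.4
    n_sex_replicates: int = 3
    sexing_error: float = 0.02
    n_fragments: int = 40
    fragment_params: dict[str, FragmentDist] = field(
        default_factory=lambda: dict(DEFAULT_FRAGMENT_PARAMS)
    )
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_founders < 2:
            raise ConfigError("n_founders must be >= 2")
        if self.n_generations < 1:
            raise ConfigError("n_generations must be >= 1")
        for name in (
            "male_philopatry_prob",
            "female_emigration_prob",
            "dropout_rate",
            "false_allele_rate",
            "locus_failure_rate",
            "detection_prob",
            "sexing_error",
            "cub_fraction",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p!r} outside [0, 1]")
        if not self.loci:
            raise ConfigError("loci must be non-empty")
        for locus in self.loci:
            locus.validate()
        if not 3 <= self.n_replicates <= 5:
            raise ConfigError("n_replicates must be in 3..5")
        if self.n_sex_replicates < 3:
            raise ConfigError("n_sex_replicates must be >= 3")
        if self.n_surveys < 0:
            raise ConfigError("n_surveys must be >= 0")
        if self.mean_offspring_per_female < 0:
            raise ConfigError("mean_offspring_per_female must be >= 0")
        unknown = set(self.fragment_params) - set(_AGE_CLASSES)
        if unknown:
            raise ConfigError(f"fragment_params for unknown age classes: {unknown}")
        return self

    # -- YAML round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["loci"] = [
            {"name": l.name, "frequencies": list(l.frequencies)} for l in self.loci
        ]
        d["fragment_params"] = {
            k: asdict(v) for k, v in self.fragment_params.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "loci" in d:
            d["loci"] = tuple(
                Locus(l["name"], tuple(l["frequencies"])) for l in d["loci"]
            )
        if "fragment_params" in d:
            d["fragment_params"] = {
                k: FragmentDist(**v) for k, v in d["fragment_params"].items()
            }
        return cls(**d).validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def replace(self, **kwargs) -> "SimConfig":
        d = asdict(self)
        d["loci"] = self.loci
        d["fragment_params"] = self.fragment_params
        d.update(kwargs)
        return SimConfig(**d).validate()
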