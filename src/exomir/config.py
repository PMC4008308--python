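"""Pipeline configuration.

Every numeric threshold the pipeline uses lives here, so that a single
YAML/JSON file documents a run.  Energies are in kcal/mol under the
package's own nearest-neighbor model (see :mod:`exomir.rnafold`);
coordinates and lengths are nucleotides unless noted.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates an invariant."""


@dataclass
class PipelineConfig:
    """Tunable parameters for the small-RNA discovery pipeline.

    Attributes
    ----------
    mature_len_min, mature_len_max:
        Accepted mature miRNA length window (nt).
    read_len_min, read_len_max:
        Read length window retained by cleaning (nt); must contain the
        mature window.
    hairpin_mfe_max:
        Maximal (i.e. least negative) fold energy for a precursor
        hairpin, kcal/mol.
    pseudo_mfe_max, pseudo_p_max:
        Pseudo-hairpin filter: candidates with fold energy above
        ``pseudo_mfe_max`` or randomization p-value above
        ``pseudo_p_max`` are discarded.
    arm_gap_max:
        Maximal spacing between the mature and star arms on the hairpin.
    flank_len:
        Genomic flank (nt) required / excised around a precursor.
    cluster_gap:
        Genomic distance (bp) under which two precursor loci belong to
        the same cluster (strict ``<``).
    seed_start, seed_end:
        1-based inclusive seed positions on the mature (default 2..8).
    duplex_mfe_max:
        Maximal miRNA:target duplex energy for an accepted site.
    n_shuffles:
        Number of dinucleotide-preserving shuffles for the
        randomization p-value.
    rng_seed:
        Seed for every stochastic step.
    """

    mature_len_min: int = 18
    mature_len_max: int = 26
    read_len_min: int = 18
    read_len_max: int = 30
    hairpin_mfe_max: float = -18.0
    pseudo_mfe_max: float = -20.0
    pseudo_p_max: float = 0.05
    arm_gap_max: int = 35
    flank_len: int = 10
    cluster_gap: int = 10_000
    seed_start: int = 2
    seed_end: int = 8
    duplex_mfe_max: float = -25.0
    n_shuffles: int = 1000
    rng_seed: int = 1
    # operational knobs (not part of the published criteria)
    excise_window: int = 90
    excise_merge_gap: int = 35
    index_k: int = 12
    max_hits: int = 20
    duplex_context: int = 15
    max_edit: int = 4

    def __post_init__(self) -> None:
        if self.mature_len_min > self.mature_len_max:
            raise ConfigError("mature_len_min must be <= mature_len_max")
        if not (self.read_len_min <= self.mature_len_min
                and self.mature_len_max <= self.read_len_max):
            raise ConfigError("read window must contain the mature window")
        for name in ("hairpin_mfe_max", "pseudo_mfe_max", "duplex_mfe_max"):
            if getattr(self, name) >= 0:
                raise ConfigError(f"{name} must be negative")
        if not self.seed_start < self.seed_end:
            raise ConfigError("seed_start must be < seed_end")
        if self.n_shuffles < 1:
            raise ConfigError("n_shuffles must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from YAML (or JSON, a YAML subset)."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def setup_logging(verbose: bool = False) -> None:
    """Structured logging to stderr; -v raises the level to DEBUG."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
    )
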