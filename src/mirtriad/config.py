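"""Pipeline configuration: defaults, parsing, and domain validation.

A configuration is a flat key-value document (YAML or a plain dict).  Every
numeric threshold of the pipeline lives here with its documented default,
and the validated configuration is echoed verbatim into output provenance
so any run can be reproduced from its report alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-domain configuration values."""


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration.

    Numeric fields (all exposed in config files under the same names):

    - ``min_count`` — raw-count floor for the low-count gene filter.
    - ``low_count_mode`` — ``"each"`` (floor applies per library) or
      ``"total"`` (floor applies to the across-library sum).
    - ``fc_threshold`` — strict fold-change cutoff of the downregulation
      screen (0.5 = "more than 2-fold down").
    - ``pseudocount`` — added to normalized condition means before the ratio.
    - ``f`` — R_RC pseudocount.
    - ``q`` — calibration quantile of the control-context R_RC distribution.
    - ``min_votes`` — predictor-consensus vote floor.
    - ``k`` — number of highest technical replicates aggregated by the
      particle-counting helper.
    """

    # input/output paths (optional; in-memory use leaves them None)
    stable: str | None = None
    pulldown_normal: str | None = None
    pulldown_cancer: str | None = None
    predictions: str | None = None
    annotations: str | None = None
    out_dir: str | None = None
    # condition assignment for the stable-cell matrix; None = infer from
    # column-name prefixes "control"/"mir"
    control_samples: tuple[str, ...] | None = None
    mir_samples: tuple[str, ...] | None = None
    # thresholds
    min_count: int = 2
    low_count_mode: str = "each"
    fc_threshold: float = 0.5
    pseudocount: float = 1.0
    f: float = 0.5
    q: float = 0.95
    min_votes: int = 4
    k: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_count < 0:
            raise ConfigError("min_count must be >= 0")
        if self.low_count_mode not in ("each", "total"):
            raise ConfigError("low_count_mode must be 'each' or 'total'")
        if self.fc_threshold <= 0:
            raise ConfigError("fc_threshold must be positive")
        if self.pseudocount < 0:
            raise ConfigError("pseudocount must be >= 0")
        if self.f <= 0:
            raise ConfigError("f (R_RC pseudocount) must be positive")
        if not 0 < self.q < 1:
            raise ConfigError(f"q must lie strictly in (0, 1), got {self.q}")
        if self.min_votes < 1:
            raise ConfigError("min_votes must be >= 1")
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        for name in ("control_samples", "mir_samples"):
            value = getattr(self, name)
            if value is not None and not isinstance(value, tuple):
                object.__setattr__(self, name, tuple(value))

    def params(self) -> dict:
        """Threshold parameters only, for provenance records."""
        keep = (
            "min_count",
            "low_count_mode",
            "fc_threshold",
            "pseudocount",
            "f",
            "q",
            "min_votes",
            "k",
            "seed",
        )
        d = asdict(self)
        return {k: d[k] for k in keep}


_FIELD_NAMES = {f.name for f in fields(PipelineConfig)}


def validate_config(source: str | Path | dict | None) -> PipelineConfig:
    """Parse and validate a configuration document.

    ``source`` may be a mapping, a path to a YAML file, YAML text, or None
    (all defaults).  Unknown keys are rejected, as are values outside their
    documented domains.
    """
    if source is None:
        raw: dict = {}
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).is_file()
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("configuration must be a flat key-value mapping")
        raw = loaded

    unknown = set(raw) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    return PipelineConfig(**raw)
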