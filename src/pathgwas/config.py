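"""Run configuration: every analysis knob in one flat, serializable record.

The defaults are the source study's operating point: case/control trait
thresholds 10.4 / 7.4 mg/L, MAF floor 0.01, HWE exact-test floor 0.001,
+/-20 kb gene windows, enrichment weight p = 1, and 1000 phenotype-label
permutations.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path

from .errors import ConfigurationError

_MODES = ("binary", "quantitative")
_PHENO_MODES = ("raw", "log10", "covariate_adjusted")


@dataclass
class RunConfig:
    mode: str = "binary"
    phenotype_mode: str = "raw"
    case_min: float = 10.4
    control_max: float = 7.4
    outlier_sd: float = 3.0
    maf_min: float = 0.01
    hwe_min: float = 0.001
    window_bp: int = 20_000
    weight_p: float = 1.0
    n_permutations: int = 1000
    set_size_min: int = 10
    set_size_max: int = 200
    seed: int = 0
    genotypes: str = ""
    snp_map: str = ""
    phenotype: str = ""
    annotation: str = ""
    gmt: str = ""

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ConfigurationError(f"mode must be one of {_MODES}")
        if self.phenotype_mode not in _PHENO_MODES:
            raise ConfigurationError(f"phenotype_mode must be one of {_PHENO_MODES}")
        if not self.control_max < self.case_min:
            raise ConfigurationError("control_max must be below case_min")
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")
        if self.set_size_min < 1 or self.set_size_max < self.set_size_min:
            raise ConfigurationError("invalid set size bounds")
        if self.window_bp < 0:
            raise ConfigurationError("window_bp must be >= 0")

    # -- flat key=value (de)serialization ----------------------------------
    def to_file(self, path: str | Path) -> None:
        lines = [f"{k} = {v}" for k, v in sorted(asdict(self).items())]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        known = {f.name: f.type for f in fields(cls)}
        casts = {f.name: type(getattr(cls(), f.name)) for f in fields(cls)}
        kwargs = {}
        for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}:{ln}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in known:
                raise ConfigurationError(f"{path}:{ln}: unknown key {key!r}")
            kwargs[key] = casts[key](value)
        return cls(**kwargs)

    def digest(self) -> str:
        """Short stable hash of the resolved configuration, for report headers."""
        blob = ";".join(f"{k}={v}" for k, v in sorted(asdict(self).items()))
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
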