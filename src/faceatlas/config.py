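"""Run configuration (YAML), manifests, and run logging.

A config file holds flat sections mirroring the parameter dataclasses::

    seed: 7
    output_dir: runs
    registration: {pyramid_levels: 3, histogram_bins: 64, ...}
    fusion: {top_k: 8, lncc_sigma_mm: 2.0, ...}
    phantom: {grid_shape: [64, 64, 64], ...}
    thresholds: {good: 0.7, acceptable: 0.8}

Missing keys take the versioned defaults; unknown keys are errors.  CLI
flags override config values (flag > config > default).
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fusion import FusionParams
from .phantom import PhantomParams
from .registration import RegistrationParams

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "Manifest",
    "load_manifest",
    "write_run_log",
]


class ConfigError(ValueError):
    """Unparseable config, unknown key, or out-of-range value."""


@dataclass(frozen=True)
class Thresholds:
    good: float = 0.7
    acceptable: float = 0.8

    def __post_init__(self) -> None:
        if not (0 <= self.good <= 1 and 0 <= self.acceptable <= 1):
            raise ValueError("thresholds must lie in [0, 1]")


_SECTIONS = {
    "registration": RegistrationParams,
    "fusion": FusionParams,
    "phantom": PhantomParams,
    "thresholds": Thresholds,
}
_TUPLE_FIELDS = {"grid_shape", "spacing"}


@dataclass(frozen=True)
class RunConfig:
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    fusion: FusionParams = field(default_factory=FusionParams)
    phantom: PhantomParams = field(default_factory=PhantomParams)
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    output_dir: str = "."

    def to_dict(self) -> dict:
        doc: dict = {"seed": self.seed, "output_dir": self.output_dir}
        for name in _SECTIONS:
            section = dataclasses.asdict(getattr(self, name))
            doc[name] = {
                k: (list(v) if isinstance(v, tuple) else v) for k, v in section.items()
            }
        return doc

    def with_overrides(self, **sections) -> "RunConfig":
        """Replace individual section fields, e.g. ``registration={"histogram_bins": 32}``."""
        updates = {}
        for name, vals in sections.items():
            if name in ("seed", "output_dir"):
                updates[name] = vals
                continue
            if name not in _SECTIONS:
                raise ConfigError(f"unknown config section: {name!r}")
            updates[name] = dataclasses.replace(getattr(self, name), **vals)
        return dataclasses.replace(self, **updates)


def _build_section(cls, values: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in section {section!r}: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
        for k, v in values.items()
    }
    try:
        return cls(**coerced)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value in section {section!r}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load a YAML config; empty file means all defaults."""
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if doc is None:
        return RunConfig()
    if not isinstance(doc, dict):
        raise ConfigError(f"config root must be a mapping, got {type(doc).__name__}")
    unknown = set(doc) - set(_SECTIONS) - {"seed", "output_dir"}
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in doc:
            if not isinstance(doc[name], dict):
                raise ConfigError(f"section {name!r} must be a mapping")
            kwargs[name] = _build_section(cls, doc[name], name)
    if "seed" in doc:
        kwargs["seed"] = int(doc["seed"])
    if "output_dir" in doc:
        kwargs["output_dir"] = str(doc["output_dir"])
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# manifests


@dataclass
class Manifest:
    """Rows of (id, image path, mask path[, rater id]); paths resolved."""

    rows: list[dict]

    def __post_init__(self) -> None:
        seen = set()
        for row in self.rows:
            key = (row["id"], row.get("rater"))
            if key in seen:
                raise ValueError(f"duplicate manifest id {key}")
            seen.add(key)
            for col in ("image", "mask"):
                if row.get(col) and not Path(row[col]).exists():
                    raise FileNotFoundError(f"manifest references missing file: {row[col]}")

    def __len__(self) -> int:
        return len(self.rows)


def load_manifest(path) -> Manifest:
    """Tab-separated manifest with header ``id<TAB>image<TAB>mask[<TAB>rater]``;
    paths are relative to the manifest's directory."""
    path = Path(path)
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    if not lines:
        raise ValueError(f"empty manifest: {path}")
    header = lines[0].split("\t")
    if header[:3] != ["id", "image", "mask"]:
        raise ValueError(f"manifest header must start with id/image/mask, got {header}")
    rows = []
    for line in lines[1:]:
        parts = line.split("\t")
        row = dict(zip(header, parts))
        for col in ("image", "mask"):
            row[col] = str((path.parent / row[col]).resolve())
        rows.append(row)
    return Manifest(rows)


def write_run_log(out_dir, cfg: RunConfig, command: str, timings: dict | None = None) -> Path:
    """Config snapshot + seed + versions + stage timings, for reproducibility."""
    import numpy
    import scipy

    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = {
        "command": command,
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
        "versions": {
            "faceatlas": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
        },
        "config": cfg.to_dict(),
        "timings_s": timings or {},
    }
    log_path = out_dir / "run_log.yaml"
    log_path.write_text(yaml.safe_dump(log, sort_keys=False))
    return log_path
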