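"""Layered run configuration (defaults < YAML file < CLI flags) + manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger("zoomotion")

#: Every key a run may consume, with its default.  The motion defaults
#: (window, pixel threshold, SD floor, A threshold) are deliberately
#: surfaced here rather than buried in code.
DEFAULTS: dict = {
    "window_size": 28,
    "pixel_threshold_k": 3.0,
    "sd_floor": 2.0,
    "a_threshold": 0.01,
    "bin_minutes": 10,
    "coverage_min": 0.5,
    "timezone_offset_hours": 1.0,
    "fps": 14.0,
    "latitude": 50.30,
    "longitude": 18.95,
    "utc_offset": 1.0,
    "periods": {
        "prenatal": ["2016-03-04", "2016-03-13"],
        "postnatal": ["2016-03-17", "2016-04-29"],
        "standard_time": ["2016-03-01", "2016-03-26"],
        "dst": ["2016-03-27", "2016-04-29"],
        "excluded_days": ["2016-03-14", "2016-03-15"],
    },
    "pressure_csv": {
        "date_column": "date",
        "pressure_column": "pressure",
        "delimiter": ",",
        "decimal": ".",
        "pressure_unit": "hPa",
    },
}


@dataclass
class RunConfig:
    """Validated, merged configuration for one run."""

    values: dict
    seed: int = 0
    out_dir: Path = Path("out")
    run_id: str = "run"

    def __getitem__(self, key: str):
        return self.values[key]

    def config_hash(self) -> str:
        blob = json.dumps(self.values, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _merge(base: dict, extra: dict, prefix: str = "") -> dict:
    merged = dict(base)
    for key, value in extra.items():
        if key not in base:
            logger.warning("unknown config key %r ignored", prefix + key)
            continue
        if isinstance(base[key], dict) and isinstance(value, dict):
            merged[key] = _merge(base[key], value, prefix + key + ".")
        else:
            merged[key] = value
    return merged


def load_config(
    path: str | Path | None = None,
    overrides: dict | None = None,
    seed: int = 0,
    out_dir: str | Path = "out",
    run_id: str = "run",
) -> RunConfig:
    """Merge defaults, an optional YAML file, then explicit overrides."""
    values = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        values = _merge(values, loaded)
    if overrides:
        values = _merge(values, {k: v for k, v in overrides.items() if v is not None})
    return RunConfig(values=values, seed=seed, out_dir=Path(out_dir), run_id=run_id)


def show_config() -> str:
    """The full default configuration, as YAML."""
    return yaml.safe_dump(DEFAULTS, sort_keys=False)


def write_manifest(config: RunConfig, extra: dict | None = None) -> Path:
    """Write a provenance manifest next to a run's outputs."""
    import numpy
    import pandas
    import scipy

    from zoomotion import __version__

    manifest = {
        "run_id": config.run_id,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": json.loads(json.dumps(config.values, default=str)),
        "versions": {
            "zoomotion": __version__,
            "python": sys.version.split()[0],
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    config.out_dir.mkdir(parents=True, exist_ok=True)
    path = config.out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def setup_logging(out_dir: Path | None = None, level: int = logging.INFO) -> None:
    """Log to stderr and, when an output directory is given, to a run log."""
    root = logging.getLogger("zoomotion")
    root.setLevel(level)
    have_stderr = any(
        isinstance(h, logging.StreamHandler) and getattr(h, "stream", None) is sys.stderr
        for h in root.handlers
    )
    if not have_stderr:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        root.addHandler(handler)
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(out_dir / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s: %(message)s"))
        root.addHandler(fh)
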