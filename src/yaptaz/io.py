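"""Parameter files, run manifests and deterministic seed expansion."""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .model import PARAM_NAMES, ParameterSet

logger = logging.getLogger(__name__)

__all__ = [
    "standard_parameters",
    "load_parameters",
    "save_parameters",
    "write_manifest",
    "spawn_seeds",
]


def standard_parameters() -> ParameterSet:
    """The packaged standard parameter set."""
    ref = resources.files("yaptaz").joinpath("data/standard_parameters.yaml")
    with ref.open("r") as fh:
        return _from_mapping(yaml.safe_load(fh))


def _from_mapping(raw: dict) -> ParameterSet:
    if not isinstance(raw, dict):
        raise ValueError("parameter file must be a flat key: value mapping")
    unknown = sorted(set(raw) - set(PARAM_NAMES))
    if unknown:
        raise KeyError(f"unknown parameter key(s): {unknown}")
    missing = sorted(set(PARAM_NAMES) - set(raw))
    if missing:
        raise KeyError(f"missing parameter key(s): {missing}")
    vals = {}
    for k, v in raw.items():
        try:
            vals[k] = float(v)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"parameter {k} is not numeric: {v!r}") from exc
    return ParameterSet(**vals)


def load_parameters(path: str | Path) -> ParameterSet:
    """Read a flat YAML parameter file; every key is validated by name."""
    with open(path) as fh:
        return _from_mapping(yaml.safe_load(fh))


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {k: float(getattr(params, k)) for k in PARAM_NAMES},
            fh,
            sort_keys=False,
        )


def write_manifest(out_dir: str | Path, config: dict) -> Path:
    """Record the resolved configuration of a run next to its outputs."""
    from importlib.metadata import version

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "yaptaz",
        "version": version("yaptaz"),
        **config,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Expand one global seed into ``n`` independent child seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
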