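"""File I/O: TSV tables, YAML/JSON configuration, run manifests, NIfTI maps."""

from __future__ import annotations

import json
import time
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError

__all__ = ["write_events", "read_events", "write_estimates", "write_scores",
           "write_matrix", "read_matrix", "load_config", "apply_overrides",
           "write_manifest", "write_stat_map"]


def _pkg_version() -> str:
    try:
        return version("probcode")
    except PackageNotFoundError:
        return "unknown"


def write_events(seq, path) -> Path:
    from .task import sequence_to_events
    path = Path(path)
    sequence_to_events(seq).to_csv(path, sep="\t", index=False)
    return path


def read_events(path, config=None, session_id: int = 0):
    from .task import sequence_from_events
    return sequence_from_events(pd.read_csv(path, sep="\t"), config, session_id)


def write_estimates(est, path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "trial_index": np.arange(est.p_hat.size),
        "p_hat": est.p_hat,
        "confidence": est.confidence,
        "surprise": est.surprise,
        "entropy": est.entropy,
    }).to_csv(path, sep="\t", index=False)
    return path


def write_scores(score, path, unit_ids=None) -> Path:
    """Per-unit cross-validated scores as TSV (unit_id, r2, z_r2)."""
    path = Path(path)
    n = score.z_r2.size
    pd.DataFrame({
        "unit_id": unit_ids if unit_ids is not None else np.arange(n),
        "r2": score.r2.mean(axis=1),
        "z_r2": score.z_r2,
    }).to_csv(path, sep="\t", index=False)
    return path


def write_matrix(M: np.ndarray, path, row_labels, col_labels) -> Path:
    path = Path(path)
    pd.DataFrame(M, index=row_labels, columns=col_labels).to_csv(path, sep="\t")
    return path


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    elif path.suffix == ".json":
        cfg = json.loads(text)
    else:
        raise ConfigurationError(f"unsupported config format: {path.suffix}")
    if not isinstance(cfg, dict):
        raise ConfigurationError("config file must define a mapping")
    return cfg


def apply_overrides(cfg: dict, overrides: dict) -> dict:
    """Apply dotted-key overrides (e.g. ``task.hazard``) to a nested dict."""
    out = json.loads(json.dumps(cfg))
    for key, value in overrides.items():
        node = out
        parts = key.split(".")
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value
    return out


def write_manifest(path, config: dict, seed, outputs: list[str]) -> Path:
    path = Path(path)
    manifest = {
        "config": config,
        "seed": seed,
        "version": _pkg_version(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": sorted(str(o) for o in outputs),
    }
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def write_stat_map(values: np.ndarray, voxel_indices: np.ndarray,
                   shape: tuple[int, int, int], path,
                   affine: np.ndarray | None = None) -> Path:
    """Write per-unit values into a NIfTI-1 volume at flat voxel indices."""
    import nibabel as nib
    vol = np.full(np.prod(shape), np.nan)
    vol[np.asarray(voxel_indices, dtype=int)] = values
    img = nib.Nifti1Image(vol.reshape(shape).astype(np.float32),
                          affine if affine is not None else np.eye(4))
    path = Path(path)
    nib.save(img, path)
    return path
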