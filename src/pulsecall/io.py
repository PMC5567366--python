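"""WAV and config I/O plus spec (de)serialization.

Waveforms travel as mono WAV (float32 or PCM16); model specs and scene
truths travel as JSON sidecars; run configurations are strict-schema YAML
(unknown keys are rejected, round-trips are lossless).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml
from scipy.io import wavfile

from .scene import SceneConfig
from .sinusoid import SinusoidModelParams
from .train import IntervalSchedule, PulseTrainSpec
from .wavelet import PulseShape
from .waveform import Waveform

__all__ = [
    "read_wav",
    "write_wav",
    "spec_to_dict",
    "spec_from_dict",
    "write_sidecar",
    "read_sidecar",
    "save_config",
    "load_config",
]


def read_wav(path) -> Waveform:
    """Read a mono float32 or PCM16 WAV file.

    PCM16 samples are scaled to [-1, 1); float32 samples pass through
    unchanged.  Multichannel or other encodings are rejected.
    """
    sr, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got {data.shape[1]} channels")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV encoding {data.dtype}")
    return Waveform(samples, float(sr))


def write_wav(w: Waveform, path) -> None:
    """Write a mono float32 WAV file (read/write round-trips bit-exactly
    at float32 precision)."""
    wavfile.write(str(path), int(round(w.sample_rate)), w.samples.astype(np.float32))


# --- spec serialization ------------------------------------------------------

_KINDS = {
    "pulse_shape": PulseShape,
    "pulse_train": PulseTrainSpec,
    "sinusoid": SinusoidModelParams,
    "scene": SceneConfig,
}


def _plain(value: Any) -> Any:
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, (tuple, list)):
        return [_plain(v) for v in value]
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        return spec_to_dict(value)
    return value


def spec_to_dict(spec) -> dict:
    """Serialize a model/scene spec to a plain, JSON/YAML-safe dict with a
    ``kind`` tag."""
    kind = next((k for k, cls in _KINDS.items() if type(spec) is cls), None)
    if kind is None:
        raise TypeError(f"cannot serialize {type(spec).__name__}")
    out: dict[str, Any] = {"kind": kind}
    for f in dataclasses.fields(spec):
        value = getattr(spec, f.name)
        if isinstance(value, IntervalSchedule):
            out[f.name] = {"onsets": value.onsets.tolist()}
        else:
            out[f.name] = _plain(value)
    return out


def spec_from_dict(data: dict):
    """Inverse of :func:`spec_to_dict`; unknown kinds or keys are rejected."""
    data = dict(data)
    kind = data.pop("kind", None)
    if kind not in _KINDS:
        raise ValueError(f"unknown spec kind {kind!r}")
    cls = _KINDS[kind]
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys for {kind}: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for name, value in data.items():
        if isinstance(value, dict) and "kind" in value:
            value = spec_from_dict(value)
        elif isinstance(value, dict) and set(value) == {"onsets"}:
            value = IntervalSchedule(np.asarray(value["onsets"]))
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    return cls(**kwargs)


def write_sidecar(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())


# --- run configuration -------------------------------------------------------


def save_config(path, blocks: dict) -> None:
    """Write a run configuration: a mapping of named blocks, each a
    spec dict (with ``kind``) or a plain scalar mapping."""
    Path(path).write_text(yaml.safe_dump(blocks, sort_keys=True))


def load_config(path) -> dict:
    """Read and validate a run configuration.

    Every block carrying a ``kind`` tag is round-tripped through the
    corresponding spec class, so unknown keys and invalid values fail
    loudly here instead of deep inside a run.
    """
    blocks = yaml.safe_load(Path(path).read_text())
    if not isinstance(blocks, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    for name, block in blocks.items():
        if isinstance(block, dict) and "kind" in block:
            blocks[name] = spec_to_dict(spec_from_dict(block))
    return blocks
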