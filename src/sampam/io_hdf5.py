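"""HDF5 layout for paired SAM/PAM A-scan volumes.

A volume-pair file holds one group per modality (``/sam``, ``/pam``), each
with a 3-D ``data`` dataset indexed ``[x, y, t]`` (time fastest-varying,
chunked per A-line) and the acquisition attributes ``sampling_rate``,
``trigger_delay``, ``pixel_pitch`` and ``repeats``.  Root attributes carry
``schema_version`` and a free-text ``description``.  Samples are stored as
32-bit floats; raw integer digitizer counts may instead be stored with a
``scale``/``offset`` attribute pair, which readers apply on load.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np

SCHEMA_VERSION = "1"

_MODALITIES = ("SAM", "PAM")
_REQUIRED_ATTRS = ("sampling_rate", "trigger_delay", "pixel_pitch", "repeats")


class SchemaError(ValueError):
    """A file does not conform to the volume-pair layout."""


@dataclass
class AScanVolume:
    """Raster-scanned stack of time-resolved signals plus acquisition metadata.

    ``data[x, y, t]`` is the signal trace recorded at lateral grid position
    (x, y); ``trigger_delay`` anchors the time axis (time of sample 0
    relative to the excitation trigger).  ``modality`` distinguishes
    pulse-echo ("SAM", round-trip times) from one-way detection ("PAM").
    """

    data: np.ndarray
    sampling_rate: float
    trigger_delay: float
    pixel_pitch: float
    modality: str
    repeats: int = 1
    report: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D [x, y, t], got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all data dimensions must be >= 1, got {self.data.shape}")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be positive")
        if self.modality not in _MODALITIES:
            raise ValueError(f"modality must be one of {_MODALITIES}, got {self.modality!r}")
        if int(self.repeats) < 1:
            raise ValueError("repeats must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def time_axis(self) -> np.ndarray:
        """Absolute time of each sample (s), including the trigger delay."""
        return self.trigger_delay + np.arange(self.n_samples) / self.sampling_rate


def write_volume(volume: AScanVolume, path: str | os.PathLike) -> None:
    """Write (or replace) one modality group of a volume-pair file.

    Only the group addressed by ``volume.modality`` is touched; the other
    modality, if present, is preserved.
    """
    group_name = volume.modality.lower()
    with h5py.File(path, "a") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs.setdefault("description", "SAM/PAM A-scan volume pair")
        if group_name in f:
            del f[group_name]
        g = f.create_group(group_name)
        nt = volume.data.shape[2]
        g.create_dataset(
            "data",
            data=volume.data.astype(np.float32),
            chunks=(1, 1, nt),
        )
        g.attrs["sampling_rate"] = float(volume.sampling_rate)
        g.attrs["trigger_delay"] = float(volume.trigger_delay)
        g.attrs["pixel_pitch"] = float(volume.pixel_pitch)
        g.attrs["repeats"] = int(volume.repeats)


def read_volume(path: str | os.PathLike, modality: str) -> AScanVolume:
    """Read one modality from a volume-pair file.

    Raises :class:`SchemaError` naming the missing element when the file
    does not conform, and rejects files with an unknown major
    ``schema_version``.
    """
    if modality not in _MODALITIES:
        raise ValueError(f"modality must be one of {_MODALITIES}, got {modality!r}")
    group_name = modality.lower()
    with h5py.File(path, "r") as f:
        version = str(f.attrs.get("schema_version", ""))
        if not version:
            raise SchemaError("missing root attribute 'schema_version'")
        if version.split(".")[0] != SCHEMA_VERSION:
            raise SchemaError(f"unsupported schema_version {version!r}")
        if group_name not in f:
            raise SchemaError(f"missing group '/{group_name}'")
        g = f[group_name]
        if "data" not in g:
            raise SchemaError(f"missing dataset '/{group_name}/data'")
        for attr in _REQUIRED_ATTRS:
            if attr not in g.attrs:
                raise SchemaError(f"missing attribute '/{group_name}@{attr}'")
        data = np.asarray(g["data"])
        if "scale" in g.attrs or "offset" in g.attrs:
            scale = float(g.attrs.get("scale", 1.0))
            offset = float(g.attrs.get("offset", 0.0))
            data = data.astype(np.float32) * scale + offset
        return AScanVolume(
            data=data,
            sampling_rate=float(g.attrs["sampling_rate"]),
            trigger_delay=float(g.attrs["trigger_delay"]),
            pixel_pitch=float(g.attrs["pixel_pitch"]),
            modality=modality,
            repeats=int(g.attrs["repeats"]),
        )


def validate_layout(path: str | os.PathLike) -> list[str]:
    """Check a file against the volume-pair layout; return a list of problems.

    An empty list means the file fully conforms.  Problems are reported,
    never raised, so a single pass surfaces every issue at once.
    """
    problems: list[str] = []
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        return [f"unreadable file: {exc}"]
    with f:
        if "schema_version" not in f.attrs:
            problems.append("missing root attribute 'schema_version'")
        lateral: dict[str, tuple] = {}
        present = [m for m in ("sam", "pam") if m in f]
        if not present:
            problems.append("no modality group present (need '/sam' and/or '/pam')")
        for name in present:
            g = f[name]
            if "data" not in g:
                problems.append(f"missing dataset '/{name}/data'")
            else:
                shape = g["data"].shape
                if len(shape) != 3:
                    problems.append(
                        f"'/{name}/data' must be 3-D [x, y, t], got {len(shape)}-D"
                    )
                else:
                    lateral[name] = shape[:2]
            for attr in _REQUIRED_ATTRS:
                if attr not in g.attrs:
                    problems.append(f"missing attribute '/{name}@{attr}'")
            if "sampling_rate" in g.attrs and not float(g.attrs["sampling_rate"]) > 0:
                problems.append(f"'/{name}@sampling_rate' must be positive")
            if "pixel_pitch" in g.attrs and not float(g.attrs["pixel_pitch"]) > 0:
                problems.append(f"'/{name}@pixel_pitch' must be positive")
        if len(lateral) == 2 and lateral["sam"] != lateral["pam"]:
            problems.append(
                "lateral grids differ between groups: "
                f"sam {lateral['sam']} vs pam {lateral['pam']}"
            )
        if len(present) == 2:
            pitches = [float(f[m].attrs["pixel_pitch"]) for m in present
                       if "pixel_pitch" in f[m].attrs]
            if len(pitches) == 2 and pitches[0] != pitches[1]:
                problems.append("pixel_pitch differs between '/sam' and '/pam'")
    return problems
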