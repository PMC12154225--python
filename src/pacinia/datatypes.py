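"""Shared containers: labeled voxel volumes, spike trains, vibration epochs.

Conventions used throughout the package:

* voxel arrays are indexed ``(z, y, x)`` with 0-based indices; ``z`` is the
  serial-sectioning axis,
* physical voxel sizes are given in nanometres as ``(dx, dy, dz)`` and may be
  anisotropic (``dz`` typically much larger than ``dx = dy``),
* derived lengths and areas are reported in micrometres,
* spike times are in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

#: roles a segmentation label may play in a corpuscle volume
ROLES = ("axon", "axon_protrusion", "LSC", "nucleus", "other")

NM_PER_UM = 1000.0


@dataclass(frozen=True)
class LabeledVolume:
    """Integer-labeled voxel grid with anisotropic physical voxel size.

    Parameters
    ----------
    labels
        ``(nz, ny, nx)`` array of non-negative integer labels; 0 is background.
    voxel_size_nm
        Physical voxel pitch ``(dx, dy, dz)`` in nanometres.
    label_table
        Mapping from label id to its role (one of :data:`ROLES`).
    """

    labels: np.ndarray
    voxel_size_nm: tuple[float, float, float]
    label_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"labels must be 3-D (z, y, x), got ndim={labels.ndim}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if labels.size and labels.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        object.__setattr__(self, "labels", labels)
        dx, dy, dz = self.voxel_size_nm
        if dx <= 0 or dy <= 0 or dz <= 0:
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_nm}")
        present = set(np.unique(labels).tolist()) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from label_table")
        for lbl, role in self.label_table.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} for label {lbl}")

    # -- convenience accessors -------------------------------------------------
    @property
    def n_slices(self) -> int:
        return self.labels.shape[0]

    @property
    def dx_nm(self) -> float:
        return float(self.voxel_size_nm[0])

    @property
    def dy_nm(self) -> float:
        return float(self.voxel_size_nm[1])

    @property
    def dz_nm(self) -> float:
        return float(self.voxel_size_nm[2])

    @property
    def dz_um(self) -> float:
        return float(self.voxel_size_nm[2]) / NM_PER_UM

    def mask(self, label: int) -> np.ndarray:
        """Boolean mask of one label (does not validate membership)."""
        return self.labels == label

    def labels_of_role(self, role: str) -> list[int]:
        return sorted(l for l, r in self.label_table.items() if r == role)


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (seconds) of one recorded or simulated unit."""

    times: np.ndarray
    unit_id: int | str = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float).ravel()
        if times.size and not np.all(np.isfinite(times)):
            raise ValueError("spike times must be finite")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("spike times must be strictly increasing")
        object.__setattr__(self, "times", times)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def in_window(self, start: float, stop: float) -> np.ndarray:
        """Spike times t with ``start <= t <= stop``."""
        t = self.times
        return t[(t >= start) & (t <= stop)]


@dataclass(frozen=True)
class VibrationEpoch:
    """A sinusoidal vibration epoch with a constant or linearly ramped amplitude.

    ``amplitude_um`` is the constant displacement amplitude for a ``constant``
    profile and the final (peak) amplitude for a ``ramp`` profile, which rises
    linearly from 0 at ``onset_s`` to the peak at ``onset_s + duration_s``.
    """

    onset_s: float
    duration_s: float
    frequency_hz: float
    profile: Literal["constant", "ramp"] = "constant"
    amplitude_um: float = 1.0

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.profile not in ("constant", "ramp"):
            raise ValueError(f"unknown amplitude profile {self.profile!r}")
        if self.amplitude_um < 0:
            raise ValueError("amplitude must be non-negative")

    @property
    def period_s(self) -> float:
        """Stimulus period T = 1/frequency in seconds."""
        return 1.0 / self.frequency_hz

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s

    def amplitude_at(self, t: float | np.ndarray) -> np.ndarray:
        """Instantaneous displacement amplitude (um) at time(s) ``t``.

        Zero outside the epoch window.
        """
        t = np.asarray(t, dtype=float)
        inside = (t >= self.onset_s) & (t <= self.end_s)
        if self.profile == "constant":
            amp = np.full_like(t, self.amplitude_um, dtype=float)
        else:
            amp = self.amplitude_um * (t - self.onset_s) / self.duration_s
        return np.where(inside, amp, 0.0)
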