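"""Channel layout of a multi-IMU recording.

A segment carries one column per (sensor site, modality, axis) triple.  The
reference configuration is five IMUs — both wrists, both upper arms and the
trunk — each streaming a tri-axial accelerometer and a tri-axial gyroscope,
i.e. 5 x 2 x 3 = 30 channels.  Columns are ordered sensor-major, then
modality (accelerometer before gyroscope), then axis (x, y, z), so sensor
``s`` occupies columns ``6*s .. 6*s+5``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ACCEL = "accel"
GYRO = "gyro"
AXES = ("x", "y", "z")

DEFAULT_SITES = ("left_wrist", "right_wrist", "left_arm", "right_arm", "trunk")


@dataclass(frozen=True)
class Triad:
    """Three consecutive channels forming one 3-vector stream."""

    sensor: str
    modality: str  # ACCEL or GYRO
    channels: tuple[int, int, int]


@dataclass(frozen=True)
class SensorLayout:
    """Maps the flat channel index space to (sensor, modality, axis) triads."""

    sites: tuple[str, ...] = DEFAULT_SITES

    @property
    def n_sensors(self) -> int:
        return len(self.sites)

    @property
    def n_channels(self) -> int:
        return 6 * self.n_sensors

    @property
    def triads(self) -> tuple[Triad, ...]:
        out = []
        for s, site in enumerate(self.sites):
            base = 6 * s
            out.append(Triad(site, ACCEL, (base, base + 1, base + 2)))
            out.append(Triad(site, GYRO, (base + 3, base + 4, base + 5)))
        return tuple(out)

    def channels_of(self, modality: str) -> list[int]:
        """All channel indices of one modality, in column order."""
        return [c for t in self.triads if t.modality == modality for c in t.channels]

    def channels_of_side(self, side: str) -> list[int]:
        """Channels of sensors whose site name starts with ``side`` ('left'/'right')."""
        out = []
        for t in self.triads:
            if t.sensor.startswith(side):
                out.extend(t.channels)
        return sorted(out)

    def describe(self) -> list[tuple[int, str, str, str]]:
        """(channel, sensor, modality, axis) rows for all channels."""
        rows = []
        for t in self.triads:
            for ax, c in zip(AXES, t.channels):
                rows.append((c, t.sensor, t.modality, ax))
        rows.sort()
        return rows
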