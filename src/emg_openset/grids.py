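"""Electrode-grid geometry for high-density sEMG arrays.

The default layout models two stacked 6 x 8 monopolar arrays (one over the
forearm extensors, one over the flexors) forming a single 12 x 8 matrix of
96 channels with 15 mm inter-electrode distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field


def _row_major_order(rows: int, cols: int) -> dict[tuple[int, int], int]:
    return {(r, c): r * cols + c for r in range(rows) for c in range(cols)}


@dataclass
class GridSpec:
    """Geometry and channel mapping of a 2-D electrode array.

    Parameters
    ----------
    rows, cols
        Grid dimensions; ``rows * cols`` must equal the channel count.
    inter_electrode_mm
        Centre-to-centre electrode spacing in millimetres.
    channel_order
        Bijection ``(row, col) -> channel index``. Defaults to row-major.
    """

    rows: int = 12
    cols: int = 8
    inter_electrode_mm: float = 15.0
    channel_order: dict[tuple[int, int], int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.channel_order is None:
            self.channel_order = _row_major_order(self.rows, self.cols)
        positions = set(self.channel_order)
        channels = set(self.channel_order.values())
        expected = {(r, c) for r in range(self.rows) for c in range(self.cols)}
        if positions != expected or channels != set(range(self.n_channels)):
            raise ValueError("channel_order must be a bijection grid position -> channel")

    @property
    def n_channels(self) -> int:
        return self.rows * self.cols

    def channel_of(self, row: int, col: int) -> int:
        return self.channel_order[(row, col)]

    def position_of(self, channel: int) -> tuple[int, int]:
        if not hasattr(self, "_inverse"):
            self._inverse = {v: k for k, v in self.channel_order.items()}
        return self._inverse[channel]

    def to_grid(self, per_channel):
        """Reshape a ``(..., n_channels)`` array onto the ``(rows, cols)`` grid."""
        import numpy as np

        per_channel = np.asarray(per_channel)
        out = np.empty(per_channel.shape[:-1] + (self.rows, self.cols), dtype=per_channel.dtype)
        for (r, c), ch in self.channel_order.items():
            out[..., r, c] = per_channel[..., ch]
        return out
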