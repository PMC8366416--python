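"""Electrode-sleeve channel layout.

The 32-channel bipolar multi-array sleeve has two faces wrapped around the
forearm: one over the wrist flexor muscles and one over the wrist extensors.
Each face is a 4x4 grid. Channel numbering interleaves the two faces:

    flexor rows:   ch5-8,  ch13-16, ch21-24, ch29-32
    extensor rows: ch1-4,  ch9-12,  ch17-20, ch25-28

Within a row, channel number increases left to right. The geometry plots and
the synthetic day-shift model (electrode sleeve slipping by whole columns)
both depend on this mapping, so it lives in its own module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

FLEXOR_ROWS = ((5, 6, 7, 8), (13, 14, 15, 16), (21, 22, 23, 24), (29, 30, 31, 32))
EXTENSOR_ROWS = ((1, 2, 3, 4), (9, 10, 11, 12), (17, 18, 19, 20), (25, 26, 27, 28))

N_CHANNELS = 32
GRID_SIZE = 4


@dataclass(frozen=True)
class ChannelLayout:
    """Bijective map channel id (1-32) -> (side, row, col) on the sleeve."""

    flexor_rows: tuple = FLEXOR_ROWS
    extensor_rows: tuple = EXTENSOR_ROWS
    _pos: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        pos = {}
        for side, rows in (("flexor", self.flexor_rows), ("extensor", self.extensor_rows)):
            for r, row in enumerate(rows):
                for c, ch in enumerate(row):
                    if ch in pos:
                        raise ConfigurationError(f"channel {ch} assigned twice")
                    pos[ch] = (side, r, c)
        if sorted(pos) != list(range(1, N_CHANNELS + 1)):
            raise ConfigurationError("layout must cover channels 1..32 exactly once")
        object.__setattr__(self, "_pos", pos)

    def position(self, channel_id: int) -> tuple:
        """Return (side, row, col) for a 1-based channel id."""
        return self._pos[channel_id]

    def side_of(self, channel_id: int) -> str:
        return self._pos[channel_id][0]

    def channels_on(self, side: str) -> list:
        return sorted(ch for ch, (s, _, _) in self._pos.items() if s == side)

    def grid(self, side: str) -> np.ndarray:
        """4x4 array of channel ids for one face of the sleeve."""
        rows = self.flexor_rows if side == "flexor" else self.extensor_rows
        return np.asarray(rows, dtype=int)

    def channel_at(self, side: str, row: int, col: int) -> int:
        return int(self.grid(side)[row, col])

    def column_rotation_permutation(self, shift: int) -> np.ndarray:
        """0-based source index per output channel for a column rotation.

        After the sleeve slips by ``shift`` columns, the electrode sitting at
        (side, row, col) picks up the signal previously seen at
        (side, row, (col - shift) mod 4). Returns ``perm`` such that
        ``shifted[:, i] = original[:, perm[i]]`` for 0-based channel index i.
        """
        if abs(shift) >= GRID_SIZE:
            raise ConfigurationError(f"|layout_shift| must be < {GRID_SIZE}, got {shift}")
        perm = np.empty(N_CHANNELS, dtype=int)
        for ch, (side, r, c) in self._pos.items():
            src = self.channel_at(side, r, (c - shift) % GRID_SIZE)
            perm[ch - 1] = src - 1
        return perm


DEFAULT_LAYOUT = ChannelLayout()
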