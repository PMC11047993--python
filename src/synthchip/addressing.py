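"""DRAM-like row/column addressing fabric for the electrode array.

The chip selects electrodes the way a DRAM selects cells: a single row
decoder (12 address bits -> one of 3163 word lines) and a bank of 128
block decoders that share a 5-bit within-block offset.  Raising block
``b`` with offset ``o`` drives column ``b * cols_per_block + o``, so one
*instance* (one charge interval) can energise at most 128 electrodes,
all in one row and all at the same within-block offset.

An arbitrary activation pattern over the array is executed as an ordered
:class:`Schedule` of such instances; scanning the full array takes
``n_rows * cols_per_block`` instances (79,075 for the default geometry,
6.3 ms at 80 ns per instance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "AddressingError",
    "ArrayGeometry",
    "PinVector",
    "UnitAddress",
    "Instance",
    "Schedule",
    "decode_row",
    "decode_columns",
    "select_units",
    "encode_instance",
    "schedule_mask",
    "scan_time",
    "full_scan_schedule",
    "group_lower_bound",
    "cols_per_block_required",
    "unit_density",
    "round_sig",
]


class AddressingError(ValueError):
    """Raised for illegal decoder inputs (out-of-range row or offset)."""


def cols_per_block_required(n_cols: int, n_blocks: int) -> int:
    """Columns each block decoder must serve: ``ceil(n_cols / n_blocks)``.

    For the default array this is ceil(3163 / 128) = 25, hence the
    5-to-25 block decoders.
    """
    if n_cols < 1 or n_blocks < 1:
        raise ValueError("n_cols and n_blocks must be >= 1")
    return -(-n_cols // n_blocks)


def group_lower_bound(n_active: int, width: int = 128) -> int:
    """Minimum number of <=``width``-unit instances covering ``n_active`` units."""
    if width <= 0:
        raise ValueError("width must be positive")
    if n_active < 0:
        raise ValueError("n_active must be >= 0")
    return -(-n_active // width)


def unit_density(pitch_um: float) -> float:
    """Electrode density in units/cm^2 for a square unit of the given pitch (µm)."""
    if pitch_um <= 0:
        raise ValueError("pitch must be positive")
    return (1e4 / pitch_um) ** 2


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (used for reported scan times)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass(frozen=True)
class ArrayGeometry:
    """Dimensions of the electrode array and its decoder fabric.

    ``cols_per_block`` defaults to the ceiling division the hardware
    uses; small test geometries exercise identical code paths.
    """

    n_rows: int = 3163
    n_cols: int = 3163
    n_blocks: int = 128
    cols_per_block: int | None = None
    pitch_um: float = 3.16

    def __post_init__(self) -> None:
        if self.cols_per_block is None:
            object.__setattr__(
                self, "cols_per_block", cols_per_block_required(self.n_cols, self.n_blocks)
            )
        if self.n_rows < 1 or self.n_cols < 1 or self.n_blocks < 1:
            raise ValueError("array dimensions must be positive")
        if self.n_blocks * self.cols_per_block < self.n_cols:
            raise ValueError("decoder fabric cannot reach every column")
        if self.pitch_um <= 0:
            raise ValueError("pitch must be positive")

    @property
    def row_bit_width(self) -> int:
        return max(1, math.ceil(math.log2(self.n_rows)) or 1)

    @property
    def offset_bit_width(self) -> int:
        return max(1, math.ceil(math.log2(self.cols_per_block)) or 1)

    @property
    def pin_count(self) -> int:
        """External input pins: row bits + per-block enables + shared offset bits."""
        return self.row_bit_width + self.n_blocks + self.offset_bit_width

    @property
    def n_units(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def density_per_cm2(self) -> float:
        return unit_density(self.pitch_um)


class UnitAddress(NamedTuple):
    row: int
    col: int


@dataclass(frozen=True)
class PinVector:
    """State of the external input pins.

    ``row_code`` is the binary value on the row-address bits,
    ``block_enable`` one boolean per block decoder, ``offset_code`` the
    shared value on the offset bits of every block decoder.
    """

    row_code: int
    block_enable: tuple[bool, ...]
    offset_code: int

    def validate(self, geometry: ArrayGeometry) -> None:
        if not 0 <= self.row_code < 2**geometry.row_bit_width:
            raise AddressingError(
                f"row code {self.row_code} does not fit in {geometry.row_bit_width} bits"
            )
        if len(self.block_enable) != geometry.n_blocks:
            raise AddressingError(
                f"expected {geometry.n_blocks} block enables, got {len(self.block_enable)}"
            )
        if not 0 <= self.offset_code < 2**geometry.offset_bit_width:
            raise AddressingError(
                f"offset code {self.offset_code} does not fit in "
                f"{geometry.offset_bit_width} bits"
            )


def decode_row(row_code: int, geometry: ArrayGeometry = ArrayGeometry()) -> int:
    """Row selected by the row-address bits (their plain binary value).

    Codes >= ``n_rows`` address no word line and are an error: the
    default 12-bit bus spans 0..4095 but only 3163 outputs exist.
    """
    if not 0 <= row_code < 2**geometry.row_bit_width:
        raise AddressingError(
            f"row code {row_code} outside {geometry.row_bit_width}-bit range"
        )
    if row_code >= geometry.n_rows:
        raise AddressingError(f"row {row_code} >= n_rows {geometry.n_rows}")
    return row_code


def decode_columns(
    block_enable: Sequence[bool],
    offset_code: int,
    geometry: ArrayGeometry = ArrayGeometry(),
) -> set[int]:
    """Columns driven for a given block-enable pattern and shared offset.

    Block ``b`` drives column ``b * cols_per_block + offset``.  The
    decode space (128 x 25 = 3200) exceeds the 3163 physical columns;
    surplus outputs are unconnected, so enabling them is a silent no-op.
    """
    if len(block_enable) != geometry.n_blocks:
        raise AddressingError(
            f"expected {geometry.n_blocks} block enables, got {len(block_enable)}"
        )
    if not 0 <= offset_code < geometry.cols_per_block:
        raise AddressingError(
            f"offset {offset_code} >= cols_per_block {geometry.cols_per_block}"
        )
    cpb = geometry.cols_per_block
    return {
        b * cpb + offset_code
        for b, enabled in enumerate(block_enable)
        if enabled and b * cpb + offset_code < geometry.n_cols
    }


def select_units(
    pins: PinVector, geometry: ArrayGeometry = ArrayGeometry()
) -> set[UnitAddress]:
    """Electrodes charged by one pin state: the decoded row crossed with
    the decoded columns (at most one unit per block, <= n_blocks total)."""
    pins.validate(geometry)
    row = decode_row(pins.row_code, geometry)
    cols = decode_columns(pins.block_enable, pins.offset_code, geometry)
    return {UnitAddress(row, c) for c in cols}


@dataclass(frozen=True)
class Instance:
    """One timed activation: a row, a shared offset, and the enabled blocks."""

    row: int
    offset: int
    blocks: frozenset[int]
    t_charge_ns: float = 80.0

    def units(self, geometry: ArrayGeometry) -> set[UnitAddress]:
        cpb = geometry.cols_per_block
        return {
            UnitAddress(self.row, b * cpb + self.offset)
            for b in self.blocks
            if b * cpb + self.offset < geometry.n_cols
        }

    def validate(self, geometry: ArrayGeometry) -> None:
        if not 0 <= self.row < geometry.n_rows:
            raise AddressingError(f"row {self.row} out of range")
        if not 0 <= self.offset < geometry.cols_per_block:
            raise AddressingError(f"offset {self.offset} out of range")
        if len(self.blocks) > geometry.n_blocks:
            raise AddressingError("more blocks than decoders")
        for b in self.blocks:
            if not 0 <= b < geometry.n_blocks:
                raise AddressingError(f"block {b} out of range")
            if b * geometry.cols_per_block + self.offset >= geometry.n_cols:
                raise AddressingError(
                    f"block {b} at offset {self.offset} implies a column beyond the array"
                )
        if self.t_charge_ns <= 0:
            raise AddressingError("t_charge must be positive")


def encode_instance(
    instance: Instance, geometry: ArrayGeometry = ArrayGeometry()
) -> PinVector:
    """Pin state realising one instance (inverse of :func:`select_units`).

    Raises for instances that no single pin state can produce (a block
    whose implied column does not exist).
    """
    instance.validate(geometry)
    enable = tuple(b in instance.blocks for b in range(geometry.n_blocks))
    return PinVector(
        row_code=instance.row, block_enable=enable, offset_code=instance.offset
    )


@dataclass
class Schedule:
    """Ordered list of instances executed sequentially, first to last."""

    instances: list[Instance] = field(default_factory=list)
    t_charge_default_ns: float = 80.0

    def __len__(self) -> int:
        return len(self.instances)

    def units(self, geometry: ArrayGeometry) -> set[UnitAddress]:
        out: set[UnitAddress] = set()
        for inst in self.instances:
            out |= inst.units(geometry)
        return out


def schedule_mask(
    mask: np.ndarray,
    t_charge_ns: float = 80.0,
    geometry: ArrayGeometry = ArrayGeometry(),
) -> Schedule:
    """Compile a boolean activation mask into a legal instance schedule.

    Iterates (row, offset) lexicographically; each pair with at least one
    active unit yields one instance enabling exactly the blocks whose
    unit at ``(row, block * cols_per_block + offset)`` is active.  The
    union of all instances equals the mask exactly and no unit is
    selected twice, because every column belongs to a unique
    (block, offset) pair.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (geometry.n_rows, geometry.n_cols):
        raise ValueError(
            f"mask shape {mask.shape} != ({geometry.n_rows}, {geometry.n_cols})"
        )
    cpb = geometry.cols_per_block
    width = geometry.n_blocks * cpb
    padded = np.zeros((geometry.n_rows, width), dtype=bool)
    padded[:, : geometry.n_cols] = mask
    # blocks axis 1, offsets axis 2
    cube = padded.reshape(geometry.n_rows, geometry.n_blocks, cpb)
    instances: list[Instance] = []
    active_rows = np.flatnonzero(cube.any(axis=(1, 2)))
    # Identical block patterns recur massively (e.g. a full-array mask has
    # only 25 distinct patterns); intern the frozensets to keep large
    # schedules compact.
    pattern_cache: dict[bytes, frozenset[int]] = {}
    for row in active_rows:
        for offset in range(cpb):
            col_pattern = cube[row, :, offset]
            if col_pattern.any():
                key = col_pattern.tobytes()
                blocks = pattern_cache.get(key)
                if blocks is None:
                    blocks = frozenset(int(b) for b in np.flatnonzero(col_pattern))
                    pattern_cache[key] = blocks
                instances.append(
                    Instance(
                        row=int(row),
                        offset=int(offset),
                        blocks=blocks,
                        t_charge_ns=t_charge_ns,
                    )
                )
    return Schedule(instances=instances, t_charge_default_ns=t_charge_ns)


def full_scan_schedule(
    t_charge_ns: float = 80.0, geometry: ArrayGeometry = ArrayGeometry()
) -> Schedule:
    """Schedule refreshing the whole array: one instance per (row, offset)."""
    all_blocks = frozenset(range(geometry.n_blocks))
    valid_blocks = [
        frozenset(
            b
            for b in all_blocks
            if b * geometry.cols_per_block + off < geometry.n_cols
        )
        for off in range(geometry.cols_per_block)
    ]
    instances = [
        Instance(row=r, offset=off, blocks=valid_blocks[off], t_charge_ns=t_charge_ns)
        for r in range(geometry.n_rows)
        for off in range(geometry.cols_per_block)
    ]
    return Schedule(instances=instances, t_charge_default_ns=t_charge_ns)


def scan_time(schedule: Schedule) -> float:
    """Total schedule duration in seconds (sum of per-instance charge times)."""
    return sum(inst.t_charge_ns for inst in schedule.instances) * 1e-9


def scan_time_reported(schedule: Schedule) -> float:
    """Scan time rounded to 2 significant figures, the design-sheet convention
    (the exact full-array value 6.326 ms reports as 6.3 ms)."""
    return round_sig(scan_time(schedule), 2)
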