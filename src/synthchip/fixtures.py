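"""Seeded synthetic inputs: random activation masks, random oligo sets,
and droplet-census fixtures.

All generators are pure functions of (spec, seed): the same arguments
always reproduce byte-identical output.  Seeds are split per purpose
from a single master seed via ``numpy.random.SeedSequence`` so that a
full-platform run is reproducible end to end.
"""

from __future__ import annotations

import numpy as np

from .addressing import UnitAddress

__all__ = [
    "split_seed",
    "gen_random_mask",
    "gen_random_oligos",
    "gen_census_fixture",
]


def split_seed(seed: int, stream: int) -> int:
    """Derive an independent child seed (< 2**31) for a named stream."""
    child = np.random.SeedSequence(seed, spawn_key=(stream,))
    return int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))


def gen_random_mask(
    n_rows: int, n_cols: int, fraction: float, seed: int
) -> np.ndarray:
    """Bernoulli(fraction) activation mask.

    ``fraction = 0.25`` emulates one base sub-step of a synthesis cycle,
    where on average a quarter of the sites need the incoming base.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return rng.random((n_rows, n_cols)) < fraction


def gen_random_oligos(n: int, length: int, seed: int) -> str:
    """FASTA text with ``n`` uniform-random A/C/G/T records of ``length``."""
    if n < 1 or length < 1:
        raise ValueError("n and length must be >= 1")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    lines = []
    for i in range(n):
        seq = b"".join(rng.choice(bases, size=length)).decode()
        lines.append(f">oligo_{i}")
        lines.append(seq)
    return "\n".join(lines) + "\n"


def gen_census_fixture(
    n_rows: int,
    n_cols: int,
    seed: int,
    mean_area_um2: float = 1.74,
    rel_spread: float = 0.05,
    dropout: float = 0.0,
    chamber_area_um2: float = 3.16,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic per-chamber droplet census (areas, confined flags).

    A stand-in for a full droplet-flow run when only the orchestrator is
    under test: chamber areas scatter around ``mean_area_um2`` and a
    ``dropout`` fraction of chambers fail to hold a droplet.
    """
    rng = np.random.default_rng(seed)
    areas = mean_area_um2 * (1 + rel_spread * rng.standard_normal((n_rows, n_cols)))
    areas = np.clip(areas, 0.0, chamber_area_um2)
    empty = rng.random((n_rows, n_cols)) < dropout
    areas[empty] = 0.0
    confined = ~empty
    return areas, confined


def sites_row_major(n: int, n_cols: int) -> list[UnitAddress]:
    """First ``n`` sites in row-major order (the default FASTA assignment)."""
    return [UnitAddress(i // n_cols, i % n_cols) for i in range(n)]
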