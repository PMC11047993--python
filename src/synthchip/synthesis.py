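"""Phosphoramidite synthesis-cycle orchestration.

Electrochemical DNA synthesis extends every site's oligonucleotide one
base per cycle.  Within a cycle the four nucleotides are coupled in four
sub-steps; before each sub-step the chip deprotects exactly the sites
whose *next* required base is the one about to flow, by energising their
electrodes.  This module turns per-site target sequences into those
per-cycle, per-base activation masks, drives the addressing scheduler,
and audits which activations actually deprotect (a site reacts only if
its chamber holds a reaction-medium droplet).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .addressing import ArrayGeometry, Schedule, UnitAddress, scan_time, schedule_mask
from .dynamics import RCParams, steady_state_ripple

__all__ = [
    "BASES",
    "OligoJob",
    "CycleState",
    "SynthesisReport",
    "load_jobs",
    "cycle_plan",
    "run_synthesis",
    "confinement_audit",
]

BASES = "ACGT"


@dataclass(frozen=True)
class OligoJob:
    """Mapping from electrode sites to target A/C/G/T sequences."""

    targets: Mapping[UnitAddress, str]
    geometry: ArrayGeometry = ArrayGeometry()

    def __post_init__(self) -> None:
        for site, seq in self.targets.items():
            if not seq:
                raise ValueError(f"empty target sequence at site {site}")
            if set(seq) - set(BASES):
                bad = sorted(set(seq) - set(BASES))
                raise ValueError(f"non-ACGT characters {bad} at site {site}")
            if not (
                0 <= site.row < self.geometry.n_rows
                and 0 <= site.col < self.geometry.n_cols
            ):
                raise ValueError(f"site {site} outside the array")

    @property
    def max_length(self) -> int:
        return max(len(s) for s in self.targets.values())


@dataclass
class CycleState:
    """Per-site synthesized prefix length and the cycle counter."""

    lengths: dict[UnitAddress, int]
    cycle: int = 0

    @classmethod
    def fresh(cls, job: OligoJob) -> "CycleState":
        return cls(lengths={site: 0 for site in job.targets}, cycle=0)

    def finished(self, job: OligoJob) -> bool:
        return all(
            self.lengths[site] >= len(seq) for site, seq in job.targets.items()
        )


@dataclass
class SynthesisReport:
    """Aggregate outcome of a synthesis run."""

    n_cycles: int
    base_counts: list[dict[str, int]]  # per cycle: base -> sites activated
    n_instances: int
    addressing_time_s: float
    total_time_s: float
    t_hold_s: float
    refresh_droop_percent: float
    products: dict[UnitAddress, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_cycles": self.n_cycles,
            "base_counts": self.base_counts,
            "n_instances": self.n_instances,
            "addressing_time_s": self.addressing_time_s,
            "total_time_s": self.total_time_s,
            "t_hold_s": self.t_hold_s,
            "refresh_droop_percent": self.refresh_droop_percent,
        }


def load_jobs(
    fasta_path,
    geometry: ArrayGeometry = ArrayGeometry(),
) -> OligoJob:
    """Read target oligos from FASTA and assign them to electrode sites.

    Records are placed row-major starting at (0, 0) unless a record
    header carries an explicit ``site=row,col`` annotation.  Non-ACGT
    residues and duplicate site assignments are errors.
    """
    from .io import read_fasta_records

    records = read_fasta_records(fasta_path)
    if len(records) > geometry.n_units:
        raise ValueError(
            f"{len(records)} records exceed the {geometry.n_units}-unit array"
        )
    targets: dict[UnitAddress, str] = {}
    cursor = 0
    for name, seq in records:
        site = None
        for token in name.replace(";", " ").split():
            if token.startswith("site="):
                r, c = token[len("site=") :].split(",")
                site = UnitAddress(int(r), int(c))
        if site is None:
            site = UnitAddress(cursor // geometry.n_cols, cursor % geometry.n_cols)
            cursor += 1
        if site in targets:
            raise ValueError(f"duplicate site assignment {site}")
        targets[site] = seq.upper()
    return OligoJob(targets=targets, geometry=geometry)


def cycle_plan(
    state: CycleState, job: OligoJob
) -> dict[str, np.ndarray]:
    """Activation masks for one cycle, one per base.

    Each unfinished site appears in exactly the mask of its next
    required base; finished sites appear in none, so the four masks are
    pairwise disjoint and their union is the unfinished-site set.
    """
    geom = job.geometry
    masks = {b: np.zeros((geom.n_rows, geom.n_cols), dtype=bool) for b in BASES}
    for site, seq in job.targets.items():
        done = state.lengths[site]
        if done < len(seq):
            masks[seq[done]][site.row, site.col] = True
    return masks


def run_synthesis(
    job: OligoJob,
    rc: RCParams | None = None,
    t_charge_ns: float = 80.0,
    t_hold_s: float = 60.0,
    collect_products: bool = True,
) -> SynthesisReport:
    """Run the full cycle loop until every site reaches its target.

    Each cycle issues four base sub-steps (fixed A->C->G->T order); each
    sub-step compiles its mask into an instance schedule, which refreshes
    the selected electrodes for the whole electrochemical hold time
    ``t_hold_s``.  The cycle count equals the longest target; short sites
    idle after completion.
    """
    rc = rc or RCParams()
    geom = job.geometry
    state = CycleState.fresh(job)
    base_counts: list[dict[str, int]] = []
    n_instances = 0
    addressing_time = 0.0
    n_substeps = 0
    synthesized: dict[UnitAddress, list[str]] = {s: [] for s in job.targets}

    while not state.finished(job):
        masks = cycle_plan(state, job)
        counts = {}
        for base in BASES:
            mask = masks[base]
            n_active = int(mask.sum())
            counts[base] = n_active
            if n_active == 0:
                continue
            sched: Schedule = schedule_mask(mask, t_charge_ns, geom)
            n_instances += len(sched)
            t_pass = scan_time(sched)
            # the schedule loops as a refresh for the whole hold time
            n_passes = max(1, int(np.ceil(t_hold_s / t_pass))) if t_pass else 1
            addressing_time += t_pass * n_passes
            n_substeps += 1
            for inst in sched.instances:
                for unit in inst.units(geom):
                    synthesized[unit].append(base)
            state.lengths = {
                site: done + (1 if mask[site.row, site.col] else 0)
                for site, done in state.lengths.items()
            }
        state.cycle += 1
        base_counts.append(counts)

    _, _, droop = steady_state_ripple(t_charge_ns * 1e-9, params=rc)
    return SynthesisReport(
        n_cycles=state.cycle,
        base_counts=base_counts,
        n_instances=n_instances,
        addressing_time_s=addressing_time,
        total_time_s=n_substeps * t_hold_s,
        t_hold_s=t_hold_s,
        refresh_droop_percent=droop,
        products={s: "".join(v) for s, v in synthesized.items()}
        if collect_products
        else {},
    )


def confinement_audit(
    active_mask: np.ndarray,
    chamber_areas_um2: np.ndarray,
    confined: np.ndarray,
    mode: str = "confined",
    area_threshold_um2: float = 1e-3,
) -> dict[str, set[UnitAddress]]:
    """Which activated sites actually deprotect, given the droplet state.

    ``chamber_areas_um2`` / ``confined`` are per-chamber droplet areas
    and confinement flags on the same grid as ``active_mask`` (from a
    droplet-flow census or a fixture).

    confined mode: a site deprotects iff it is activated AND its chamber
    holds a confined droplet (protons stay inside the droplet, so no
    neighbour is ever at risk — the platform's headline property).

    unconfined mode: activation additionally flags the 4-neighbour sites
    as at-risk, a qualitative crosstalk indicator for a chip run without
    the droplet array.
    """
    active = np.asarray(active_mask, dtype=bool)
    areas = np.asarray(chamber_areas_um2, dtype=float)
    conf = np.asarray(confined, dtype=bool)
    if active.shape != areas.shape or active.shape != conf.shape:
        raise ValueError("mask, areas and confinement grids must share a shape")
    if mode not in ("confined", "unconfined"):
        raise ValueError("mode must be 'confined' or 'unconfined'")

    has_medium = areas > area_threshold_um2
    deprotected = {
        UnitAddress(int(r), int(c))
        for r, c in zip(*np.nonzero(active & has_medium & conf))
    }
    if mode == "unconfined":
        # without droplets, an activated site with any medium reacts ...
        deprotected = {
            UnitAddress(int(r), int(c))
            for r, c in zip(*np.nonzero(active & has_medium))
        }
        # ... and its protons can reach the 4-neighbours
        at_risk: set[UnitAddress] = set()
        nr, nc = active.shape
        for r, c in zip(*np.nonzero(active)):
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = int(r) + dr, int(c) + dc
                if 0 <= rr < nr and 0 <= cc < nc:
                    at_risk.add(UnitAddress(rr, cc))
        at_risk -= {UnitAddress(int(r), int(c)) for r, c in zip(*np.nonzero(active))}
    else:
        at_risk = set()
    return {"deprotected": deprotected, "at_risk": at_risk}
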