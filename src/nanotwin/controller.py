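"""Automated sense-then-extract protocol against the simulated world.

The state machine mirrors the robotic workflow: plan an insertion point in
each cell's cytoplasm band away from the nucleus, order targets as a
nearest-neighbour tour, then per cell: contact, penetrate (a loosely
adherent cell may escape), sense the intracellular current for the
configured window at the sensor rate, apply the detection threshold, and
on detection switch the tip to nanotweezer mode (DEP on for the dwell,
retraction with the drive held on).  Failed detections reposition to a new
feasible point at least 2 um from previous attempts, up to the attempt
cap.  Everything is logged: per-sample current/pose channels per sensing
interval plus one event record per attempt.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from .electrochem import SensorCalibration, detect_mitochondrion
from .synthetic_world import VirtualCell, VirtualDish, make_trace

__all__ = [
    "StagePose",
    "ProtocolConfig",
    "EventLog",
    "BiopsyRecord",
    "NoFeasiblePointError",
    "plan_insertion_point",
    "order_targets",
    "run_protocol",
    "survival_report",
]


class NoFeasiblePointError(RuntimeError):
    pass


@dataclass
class StagePose:
    chamber_xyz: tuple          # um
    probe_xyzd: tuple           # um; d = axis along the tip (45 deg)
    timestamp: float            # s


@dataclass
class ProtocolConfig:
    insertion_speed: float = 200.0     # um/s
    sense_window: float = 1.0          # s
    current_threshold: float = 8.0     # pA
    dep_voltage_pp: float = 7.0        # V
    dep_frequency: float = 1.0e6       # Hz
    dep_dwell: float = 60.0            # s
    max_attempts_per_cell: int = 7
    seed: int = 0
    sample_rate: float = 1000.0        # Hz
    noise_sd: float = 0.5              # pA
    reposition_min_spacing: float = 2.0  # um

    def __post_init__(self) -> None:
        for name in ("insertion_speed", "sense_window", "current_threshold",
                     "dep_voltage_pp", "dep_frequency", "dep_dwell", "sample_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.max_attempts_per_cell < 1:
            raise ValueError("max_attempts_per_cell must be >= 1")


@dataclass
class BiopsyRecord:
    cell_id: int
    attempts: int
    penetrated: bool
    detected: bool
    extracted: bool
    trapped_count: int = 0
    retraction_retained: bool = False

    def __post_init__(self) -> None:
        if self.extracted and not self.detected:
            raise ValueError("extracted implies detected")
        if self.detected and not self.penetrated:
            raise ValueError("detected implies penetrated")


@dataclass
class EventLog:
    """Synchronized channels plus per-attempt event records."""

    sample_rate: float
    times: list = field(default_factory=list)        # np arrays per interval
    currents: list = field(default_factory=list)
    positions: list = field(default_factory=list)
    events: list = field(default_factory=list)       # dicts

    def add_interval(self, t0: float, current: np.ndarray, position: np.ndarray) -> None:
        t = t0 + np.arange(len(current)) / self.sample_rate
        self.times.append(t)
        self.currents.append(np.asarray(current))
        self.positions.append(np.asarray(position))

    def add_event(self, **kwargs) -> None:
        self.events.append(dict(kwargs))

    def audit(self) -> bool:
        """Every sensing interval sampled at exactly the sensor rate, no gaps."""
        for t in self.times:
            if len(t) > 1:
                dt = np.diff(t)
                if not np.allclose(dt, 1.0 / self.sample_rate, rtol=1e-9, atol=1e-12):
                    return False
        return True

    def save(self, rundir) -> None:
        rundir = Path(rundir)
        rundir.mkdir(parents=True, exist_ok=True)
        if self.times:
            arr = np.column_stack([
                np.concatenate(self.times),
                np.concatenate(self.currents),
                np.concatenate(self.positions),
            ])
        else:
            arr = np.zeros((0, 3))
        np.savetxt(rundir / "channels.tsv", arr, delimiter="\t",
                   header="time_s\tcurrent_pA\tposition_um", comments="")
        (rundir / "events.json").write_text(json.dumps(self.events, indent=1))


def _polygon_mask(poly: np.ndarray, shape: tuple, origin: tuple, scale: float) -> np.ndarray:
    """Rasterize a closed polygon (um coords) onto a boolean grid."""
    from skimage.draw import polygon as sk_polygon
    cols = (poly[:, 0] - origin[0]) / scale
    rows = (poly[:, 1] - origin[1]) / scale
    mask = np.zeros(shape, dtype=bool)
    rr, cc = sk_polygon(rows, cols, shape=shape)
    mask[rr, cc] = True
    return mask


def plan_insertion_point(cell: VirtualCell, margin: float = 1.0,
                         exclude: Optional[list] = None,
                         min_spacing: float = 2.0,
                         grid_um: float = 0.5) -> tuple:
    """Cytoplasm-band point: inside the cell, outside the nucleus, medial.

    The cell and nucleus contours are rasterized; the feasible band is the
    cell eroded by ``margin`` minus the nucleus dilated by ``margin``, with
    optional exclusion disks of ``min_spacing`` around previous attempts.
    The returned point (um) maximizes the distance to both boundaries.
    """
    poly = cell.contour
    x0, y0 = poly.min(axis=0) - 2 * margin - grid_um
    x1, y1 = poly.max(axis=0) + 2 * margin + grid_um
    shape = (int(math.ceil((y1 - y0) / grid_um)) + 1,
             int(math.ceil((x1 - x0) / grid_um)) + 1)
    cell_mask = _polygon_mask(poly, shape, (x0, y0), grid_um)
    nuc_mask = _polygon_mask(cell.nucleus_contour, shape, (x0, y0), grid_um)

    m = max(1, int(round(margin / grid_um)))
    cell_er = ndimage.binary_erosion(cell_mask, iterations=m)
    nuc_dil = ndimage.binary_dilation(nuc_mask, iterations=m)
    feasible = cell_er & ~nuc_dil
    if exclude:
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        px = x0 + xx * grid_um
        py = y0 + yy * grid_um
        for (ex, ey) in exclude:
            feasible &= (px - ex) ** 2 + (py - ey) ** 2 >= min_spacing**2
    if not feasible.any():
        raise NoFeasiblePointError("no feasible cytoplasm point")

    d_out = ndimage.distance_transform_edt(cell_mask)
    d_nuc = ndimage.distance_transform_edt(~nuc_mask)
    score = np.where(feasible, np.minimum(d_out, d_nuc), -1.0)
    r, c = np.unravel_index(int(np.argmax(score)), shape)
    return (x0 + c * grid_um, y0 + r * grid_um)


def order_targets(points, start=(0.0, 0.0)) -> list:
    """Nearest-neighbour tour over target points; returns visiting indices."""
    pts = [tuple(p) for p in points]
    if not pts:
        raise ValueError("need at least one point")
    remaining = list(range(len(pts)))
    order = []
    cur = tuple(start)
    while remaining:
        nxt = min(remaining, key=lambda i: (pts[i][0] - cur[0]) ** 2 + (pts[i][1] - cur[1]) ** 2)
        remaining.remove(nxt)
        order.append(nxt)
        cur = pts[nxt]
    return order


def _expected_trapped(cell: VirtualCell, config: ProtocolConfig,
                      rng: np.random.Generator) -> int:
    """Capture count over the DEP dwell: Poisson flux from the local
    mitochondrial density, conditioned to be >= 1 (detection implies
    mitochondria near the tip)."""
    rate = 0.05 * cell.mito_density * (config.dep_voltage_pp / 7.0) ** 2
    n = rng.poisson(rate * config.dep_dwell)
    return max(1, int(n))


def run_protocol(dish: VirtualDish, config: ProtocolConfig,
                 cal: Optional[SensorCalibration] = None):
    """Execute the full protocol; returns ``(EventLog, [BiopsyRecord])``.

    All randomness flows from ``config.seed``; failures are recorded
    outcomes, never exceptions.
    """
    cal = cal or SensorCalibration()
    rng = np.random.default_rng(config.seed)
    log = EventLog(sample_rate=config.sample_rate)
    records = []
    if not dish.cells:
        return log, records

    points = []
    for cell in dish.cells:
        try:
            points.append(plan_insertion_point(cell))
        except NoFeasiblePointError:
            points.append(cell.cytoplasm_point)
    order = order_targets(points)

    sim_t = 0.0
    for cell_id in order:
        cell = dish.cells[cell_id]
        tried = []
        penetrated = detected = extracted = False
        trapped_count = 0
        retained = False
        attempts = 0
        point = points[cell_id]
        for attempt in range(config.max_attempts_per_cell):
            attempts += 1
            log.add_event(kind="approach", cell=cell_id, attempt=attempt,
                          target_um=list(point), t=sim_t)
            # contact is deterministic in simulation; penetration may fail
            # when the cell escapes (poor adhesion)
            escaped = rng.random() < cell.escape_probability
            if escaped:
                log.add_event(kind="penetration_failed", cell=cell_id,
                              attempt=attempt, t=sim_t)
                sim_t += 1.0
                tried.append(point)
                point = _next_point(cell, tried, config, point)
                continue
            penetrated = True
            trace = make_trace(
                cell, t_contact=0.2, hold=config.sense_window, cal=cal,
                noise_sd=config.noise_sd, seed=int(rng.integers(2**31)),
                insertion_speed=config.insertion_speed,
                sample_rate=config.sample_rate, post=0.2,
                insertion_point=point)
            log.add_interval(sim_t, trace.current, trace.position)
            hit, t_detect = detect_mitochondrion(
                trace, threshold=config.current_threshold)
            log.add_event(kind="sense", cell=cell_id, attempt=attempt,
                          detected=bool(hit),
                          t_detect=(sim_t + t_detect) if hit else None, t=sim_t)
            sim_t += trace.duration
            if hit:
                detected = True
                trapped_count = _expected_trapped(cell, config, rng)
                # retraction with the drive on: retention at the slow
                # retraction speed is assured by the contact-force margin
                retained = trapped_count > 0
                extracted = retained
                log.add_event(kind="biopsy", cell=cell_id, attempt=attempt,
                              dep_voltage_pp=config.dep_voltage_pp,
                              dep_frequency=config.dep_frequency,
                              dwell_s=config.dep_dwell,
                              trapped=trapped_count, t=sim_t)
                sim_t += config.dep_dwell
                break
            tried.append(point)
            point = _next_point(cell, tried, config, point)
        log.add_event(kind="cell_done", cell=cell_id, attempts=attempts,
                      penetrated=penetrated, detected=detected,
                      extracted=extracted, t=sim_t)
        records.append(BiopsyRecord(
            cell_id=cell_id, attempts=attempts, penetrated=penetrated,
            detected=detected, extracted=extracted,
            trapped_count=trapped_count, retraction_retained=retained))
    return log, records


def _next_point(cell, tried, config, fallback):
    try:
        return plan_insertion_point(
            cell, exclude=tried, min_spacing=config.reposition_min_spacing)
    except NoFeasiblePointError:
        return fallback


def survival_report(records, dish: VirtualDish, seed: int = 0,
                    max_attempts: Optional[int] = None) -> dict:
    """Simulated per-attempt viability aggregated over the run's cells.

    Death is drawn per attempt from each cell's per-penetration death
    probability; the report gives the survival fraction after k attempts,
    which is monotone nonincreasing in k.
    """
    rng = np.random.default_rng(seed)
    kmax = max_attempts or max((r.attempts for r in records), default=0)
    alive = {r.cell_id: True for r in records}
    survival = []
    for _ in range(kmax):
        for r in records:
            if alive[r.cell_id]:
                cell = dish.cells[r.cell_id]
                if rng.random() < cell.death_probability_per_attempt:
                    alive[r.cell_id] = False
        survival.append(sum(alive.values()) / len(alive) if alive else 1.0)
    return {"attempts": list(range(1, kmax + 1)), "survival_fraction": survival}


def save_records(records, path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=[
            "cell_id", "attempts", "penetrated", "detected", "extracted",
            "trapped_count", "retraction_retained"])
        writer.writeheader()
        for r in records:
            writer.writerow(asdict(r))
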