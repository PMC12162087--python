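"""Block schedules and frame-accurate stimulus descriptions.

Four experiment types are covered:

* a 2D-motion localizer — limited-lifetime random dots alternating between
  moving (radial in/out, clockwise/counterclockwise rotation) and static
  blocks, with eccentricity-scaled dot speeds;
* a 3D-motion (changing-disparity stereomotion) localizer — two
  disparity-defined surfaces (central disk and surrounding annulus) moving
  in antiphase through depth, against a temporally scrambled control;
* an opponent-motion stimulus — leftward/rightward dots presented either
  as counterphase pairs or spatially unpaired;
* population-receptive-field mapping apertures — translating bars,
  rotating wedges and expanding/contracting rings rasterized on a
  visual-field grid.

All geometry is expressed in degrees of visual angle: x rightward
positive, y upward positive, origin at fixation. Stimuli are generated at
display frame resolution (default 120 Hz) but consumed by the BOLD
simulator at TR resolution through the block labels only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Block",
    "BlockSchedule",
    "DotFieldMovie",
    "DisparityTrajectory",
    "ApertureMovie",
    "build_2d_schedule",
    "build_3d_schedule",
    "build_opponent_schedule",
    "gen_2d_dot_movie",
    "gen_opponent_movie",
    "gen_disparity_trajectory",
    "gen_prf_apertures",
    "MOTION_2D_LABELS",
]

#: the four moving-dot conditions of the 2D localizer, in block order
MOTION_2D_LABELS = ("radial_in", "radial_out", "cw", "ccw")

DEFAULT_FRAME_RATE = 120.0  # Hz, display refresh


@dataclass(frozen=True)
class Block:
    """One condition block: label, onset and duration in seconds."""

    label: str
    onset: float
    duration: float


@dataclass
class BlockSchedule:
    """Ordered, non-overlapping condition blocks defining one run."""

    blocks: list[Block]
    total_duration: float
    tr: float = 1.0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        prev_end = 0.0
        for b in self.blocks:
            if b.duration <= 0:
                raise ValueError(f"block {b.label!r} has non-positive duration")
            if b.onset < prev_end - 1e-9:
                raise ValueError("blocks overlap or are unsorted")
            for v in (b.onset, b.duration):
                if abs(v / self.tr - round(v / self.tr)) > 1e-9:
                    raise ValueError(
                        f"block {b.label!r}: onset/duration must be TR multiples"
                    )
            prev_end = b.onset + b.duration
        if self.blocks and self.total_duration < prev_end - 1e-9:
            raise ValueError("total_duration shorter than the last block")

    @property
    def n_timepoints(self) -> int:
        return int(np.ceil(self.total_duration / self.tr - 1e-9))

    def labels(self) -> list[str]:
        return [b.label for b in self.blocks]

    def condition_names(self, exclude: tuple[str, ...] = ("blank",)) -> list[str]:
        """Unique condition labels in order of first appearance."""
        seen: list[str] = []
        for b in self.blocks:
            if b.label not in seen and b.label not in exclude:
                seen.append(b.label)
        return seen

    def labels_per_tr(self, baseline: str = "blank") -> np.ndarray:
        """Condition label of each TR; gaps get the baseline label."""
        out = np.array([baseline] * self.n_timepoints, dtype=object)
        for b in self.blocks:
            i0 = int(round(b.onset / self.tr))
            i1 = int(round((b.onset + b.duration) / self.tr))
            out[i0:i1] = b.label
        return out

    def label_at(self, t: float) -> str:
        for b in self.blocks:
            if b.onset - 1e-9 <= t < b.onset + b.duration - 1e-9:
                return b.label
        return "blank"

    def to_events(self):
        """BIDS-style events table (onset, duration, trial_type)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "onset": [b.onset for b in self.blocks],
                "duration": [b.duration for b in self.blocks],
                "trial_type": [b.label for b in self.blocks],
            }
        )


@dataclass
class DotFieldMovie:
    """Frame-accurate dot kinematics.

    ``xy`` has shape (frames, dots, 2); ``age`` (frames, dots) in seconds.
    ``eye`` is 'both' for binocularly identical displays. ``pair_id`` maps
    each dot slot to a pair index (or -1 when unpaired). ``frame_labels``
    records the block condition each frame belongs to.
    """

    frame_rate: float
    xy: np.ndarray
    age: np.ndarray
    aperture_radius: float
    eye: np.ndarray | None = None
    pair_id: np.ndarray | None = None
    frame_labels: np.ndarray | None = None
    lifetime: float = 0.5

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def n_dots(self) -> int:
        return self.xy.shape[1]

    def eccentricity(self) -> np.ndarray:
        return np.hypot(self.xy[..., 0], self.xy[..., 1])

    def speeds(self) -> np.ndarray:
        """Instantaneous speed (deg/s) from frame-to-frame displacement.

        Steps that end in a respawn (age reset) are NaN: the jump back into
        the aperture is not stimulus motion.
        """
        disp = np.linalg.norm(np.diff(self.xy.astype(np.float64), axis=0), axis=-1)
        speeds = disp * self.frame_rate
        # a surviving dot's age advances by exactly one frame; anything less
        # (including back-to-back respawns at age 0) is a respawn jump
        half_frame = 0.5 / self.frame_rate
        respawned = self.age[1:] < self.age[:-1] + half_frame
        speeds[respawned] = np.nan
        return speeds

    def max_speed(self) -> float:
        return float(np.nanmax(self.speeds()))

    def to_frame(self):
        """Long-format per-frame dot table for inspection/export."""
        import pandas as pd

        f, n = self.n_frames, self.n_dots
        frame_idx = np.repeat(np.arange(f), n)
        return pd.DataFrame(
            {
                "frame": frame_idx,
                "dot": np.tile(np.arange(n), f),
                "x": self.xy[..., 0].ravel(),
                "y": self.xy[..., 1].ravel(),
                "age": self.age.ravel(),
            }
        )


@dataclass
class DisparityTrajectory:
    """Framewise binocular disparity (arcmin) of the two stereo surfaces."""

    frame_rate: float
    center_disparity: np.ndarray
    surround_disparity: np.ndarray
    condition: str

    @property
    def n_frames(self) -> int:
        return self.center_disparity.size


@dataclass
class ApertureMovie:
    """Binary visual-field masks over time on an S x S raster.

    The raster spans [-radius, +radius] in both axes; cell centers are at
    ``coords``. One mask per timepoint (TR resolution).
    """

    grid: np.ndarray  # (T, S, S) bool
    radius: float
    kind: str
    tr: float = 1.0

    @property
    def n_timepoints(self) -> int:
        return self.grid.shape[0]

    @property
    def grid_size(self) -> int:
        return self.grid.shape[1]

    @property
    def cell_size(self) -> float:
        return 2.0 * self.radius / self.grid_size

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinates (x, y) as 2D arrays, deg."""
        s = self.grid_size
        c = (np.arange(s) + 0.5) * self.cell_size - self.radius
        x, y = np.meshgrid(c, c)
        return x, y

    def field_mask(self) -> np.ndarray:
        x, y = self.coords()
        return x * x + y * y <= self.radius**2

    def area(self) -> np.ndarray:
        """Stimulated area per timepoint in deg^2."""
        return self.grid.reshape(self.n_timepoints, -1).sum(axis=1) * self.cell_size**2


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------


def build_2d_schedule(
    block_s: float = 15.0,
    reps_per_direction: int = 3,
    tr: float = 1.0,
    blank_s: float = 15.0,
) -> BlockSchedule:
    """2D-motion localizer: moving/static alternation plus a final blank.

    Each of the four motion directions appears ``reps_per_direction`` times,
    every moving block followed by a static block; the run ends with a blank
    block. Defaults give 24 blocks of 15 s (6 min of stimulus) plus 15 s of
    blank.
    """
    if block_s <= 0:
        raise ValueError("block_s must be positive")
    if reps_per_direction < 1:
        raise ValueError("reps_per_direction must be >= 1")
    blocks: list[Block] = []
    t = 0.0
    for _ in range(reps_per_direction):
        for direction in MOTION_2D_LABELS:
            blocks.append(Block(direction, t, block_s))
            t += block_s
            blocks.append(Block("static", t, block_s))
            t += block_s
    blocks.append(Block("blank", t, blank_s))
    t += blank_s
    return BlockSchedule(blocks, total_duration=t, tr=tr)


def build_3d_schedule(
    block_s: float = 10.0,
    reps: int = 15,
    tr: float = 1.0,
    blank_s: float = 15.0,
) -> BlockSchedule:
    """3D-motion localizer: coherent/scrambled alternation every block.

    Defaults give 15 repetitions of each condition in 10 s blocks (5 min of
    stimulus) followed by 15 s of blank.
    """
    if block_s <= 0:
        raise ValueError("block_s must be positive")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    blocks: list[Block] = []
    t = 0.0
    for _ in range(reps):
        for cond in ("coherent", "scrambled"):
            blocks.append(Block(cond, t, block_s))
            t += block_s
    blocks.append(Block("blank", t, blank_s))
    t += blank_s
    return BlockSchedule(blocks, total_duration=t, tr=tr)


def build_opponent_schedule(
    block_s: float = 15.0,
    n_blocks: int = 21,
    tr: float = 1.0,
    start: str = "unpaired",
) -> BlockSchedule:
    """Opponent-motion scan: strict paired/unpaired alternation.

    Defaults give 21 blocks of 15 s, i.e. a 315 s (5 m 15 s) scan.
    """
    if block_s <= 0:
        raise ValueError("block_s must be positive")
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if start not in ("unpaired", "paired"):
        raise ValueError(f"unknown start condition {start!r}")
    other = "paired" if start == "unpaired" else "unpaired"
    blocks = [
        Block(start if i % 2 == 0 else other, i * block_s, block_s)
        for i in range(n_blocks)
    ]
    return BlockSchedule(blocks, total_duration=n_blocks * block_s, tr=tr)


# ---------------------------------------------------------------------------
# dot movies
# ---------------------------------------------------------------------------


def _uniform_disk(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    phi = rng.uniform(0.0, 2 * np.pi, size=n)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def gen_2d_dot_movie(
    schedule: BlockSchedule,
    seed: int,
    frame_rate: float = DEFAULT_FRAME_RATE,
    n_dots: int = 250,
    lifetime: float = 0.5,
    aperture_radius: float = 10.0,
    max_speed: float = 12.0,
) -> DotFieldMovie:
    """Limited-lifetime random-dot movie for a 2D-motion localizer run.

    Radial blocks scale dot speed with the square root of eccentricity,
    ``v = max_speed * sqrt(ecc / R)``; rotational blocks use one-eighth power
    scaling, ``v = max_speed * (ecc / R)**(1/8)``, so motion remains visible
    near the fovea. Both profiles reach ``max_speed`` at the aperture edge.
    Static (and blank) blocks freeze positions. Dots respawn uniformly in
    the aperture when their lifetime expires or they leave the field.
    """
    known = set(MOTION_2D_LABELS) | {"static", "blank"}
    unknown = set(schedule.labels()) - known
    if unknown:
        raise ValueError(f"unknown condition label(s) in schedule: {sorted(unknown)}")

    dt = 1.0 / frame_rate
    n_frames = int(round(schedule.total_duration * frame_rate))
    rng = np.random.default_rng(seed)

    pos = _uniform_disk(rng, n_dots, aperture_radius)
    age = rng.uniform(0.0, lifetime, size=n_dots)

    # per-frame condition labels, resolved once
    frame_labels = np.empty(n_frames, dtype=object)
    for b in schedule.blocks:
        f0 = int(round(b.onset * frame_rate))
        f1 = int(round((b.onset + b.duration) * frame_rate))
        frame_labels[f0:f1] = b.label
    frame_labels[frame_labels == None] = "blank"  # noqa: E711  (object array)

    xy = np.empty((n_frames, n_dots, 2), dtype=np.float32)
    ages = np.empty((n_frames, n_dots), dtype=np.float32)

    for f in range(n_frames):
        xy[f] = pos
        ages[f] = age
        label = frame_labels[f]

        crossed_center = np.zeros(n_dots, dtype=bool)
        if label in MOTION_2D_LABELS:
            ecc = np.hypot(pos[:, 0], pos[:, 1])
            moving = ecc > 0
            with np.errstate(divide="ignore", invalid="ignore"):
                ux = np.where(moving, pos[:, 0] / ecc, 0.0)
                uy = np.where(moving, pos[:, 1] / ecc, 0.0)
            if label in ("radial_in", "radial_out"):
                speed = max_speed * np.sqrt(ecc / aperture_radius)
                sign = 1.0 if label == "radial_out" else -1.0
                step = sign * speed * dt
                if label == "radial_in":
                    crossed_center = ecc + step < 0
                pos = pos + np.column_stack([ux * step, uy * step])
            else:  # cw / ccw: rotate about fixation, tangential speed profile
                speed = max_speed * (ecc / aperture_radius) ** 0.125
                with np.errstate(divide="ignore", invalid="ignore"):
                    dphi = np.where(moving, speed * dt / ecc, 0.0)
                if label == "cw":
                    dphi = -dphi
                c, s = np.cos(dphi), np.sin(dphi)
                pos = np.column_stack(
                    [c * pos[:, 0] - s * pos[:, 1], s * pos[:, 0] + c * pos[:, 1]]
                )

        age = age + dt
        dead = (
            (age >= lifetime - 1e-12)
            | (np.hypot(pos[:, 0], pos[:, 1]) > aperture_radius)
            | crossed_center
        )
        n_dead = int(dead.sum())
        if n_dead:
            pos[dead] = _uniform_disk(rng, n_dead, aperture_radius)
            age[dead] = 0.0

    return DotFieldMovie(
        frame_rate=frame_rate,
        xy=xy,
        age=ages,
        aperture_radius=aperture_radius,
        eye=np.array(["both"] * n_dots),
        pair_id=None,
        frame_labels=frame_labels,
        lifetime=lifetime,
    )


def gen_opponent_movie(
    condition: str,
    duration: float,
    seed: int,
    frame_rate: float = DEFAULT_FRAME_RATE,
    n_dots: int = 300,
    speed: float = 5.0,
    max_separation: float = 0.5,
    aperture_radius: float = 10.0,
) -> DotFieldMovie:
    """Opponent-motion dot movie: 'paired' or 'unpaired' condition.

    Half the dots move leftward, half rightward, all at ``speed`` deg/s.
    In the paired condition dots come in counterphase pairs sharing a
    y-coordinate: members start ``max_separation`` apart, cross once at
    mid-life, and annihilate at ``max_separation`` on the other side, so
    the lifetime is ``2 * (max_separation/2) / speed`` (0.1 s at defaults).
    Unpaired dots follow the same kinematics with independent positions.
    """
    if condition not in ("paired", "unpaired"):
        raise ValueError(f"unknown condition {condition!r}")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if n_dots % 2:
        raise ValueError("n_dots must be even (half left, half right)")

    dt = 1.0 / frame_rate
    lifetime = max_separation / speed  # relative speed is 2*speed
    n_frames = int(round(duration * frame_rate))
    rng = np.random.default_rng(seed)
    half_span = max_separation / 2.0
    spawn_radius = aperture_radius - half_span - speed * dt

    # even slots move rightward, odd slots leftward -> 150/150 marginals
    direction = np.where(np.arange(n_dots) % 2 == 0, 1.0, -1.0)

    if condition == "paired":
        n_pairs = n_dots // 2
        pair_id = np.repeat(np.arange(n_pairs), 2)
        centers = _uniform_disk(rng, n_pairs, spawn_radius)
        phase = rng.uniform(0.0, lifetime, size=n_pairs)
    else:
        pair_id = np.full(n_dots, -1)
        centers = _uniform_disk(rng, n_dots, spawn_radius)
        phase = rng.uniform(0.0, lifetime, size=n_dots)

    xy = np.empty((n_frames, n_dots, 2), dtype=np.float32)
    ages = np.empty((n_frames, n_dots), dtype=np.float32)

    for f in range(n_frames):
        if condition == "paired":
            # offset runs from -half_span to +half_span over one lifetime
            off = (phase - lifetime / 2.0) * speed
            x = np.empty(n_dots)
            y = np.empty(n_dots)
            x[0::2] = centers[:, 0] + off  # rightward member
            x[1::2] = centers[:, 0] - off  # leftward member
            y[0::2] = centers[:, 1]
            y[1::2] = centers[:, 1]
            xy[f, :, 0] = x
            xy[f, :, 1] = y
            ages[f] = np.repeat(phase, 2)
            phase = phase + dt
            expired = phase >= lifetime - 1e-12
            n_exp = int(expired.sum())
            if n_exp:
                centers[expired] = _uniform_disk(rng, n_exp, spawn_radius)
                phase[expired] = 0.0
        else:
            off = (phase - lifetime / 2.0) * speed * direction
            xy[f, :, 0] = centers[:, 0] + off
            xy[f, :, 1] = centers[:, 1]
            ages[f] = phase
            phase = phase + dt
            expired = phase >= lifetime - 1e-12
            n_exp = int(expired.sum())
            if n_exp:
                centers[expired] = _uniform_disk(rng, n_exp, spawn_radius)
                phase[expired] = 0.0

    return DotFieldMovie(
        frame_rate=frame_rate,
        xy=xy,
        age=ages,
        aperture_radius=aperture_radius,
        eye=np.array(["both"] * n_dots),
        pair_id=pair_id,
        frame_labels=np.array([condition] * n_frames, dtype=object),
        lifetime=lifetime,
    )


# ---------------------------------------------------------------------------
# disparity trajectories
# ---------------------------------------------------------------------------


def gen_disparity_trajectory(
    condition: str,
    frame_rate: float = DEFAULT_FRAME_RATE,
    duration: float = 10.0,
    seed: int = 0,
    amplitude: float = 18.0,
    period: float = 2.0,
) -> DisparityTrajectory:
    """Framewise disparity of the center/surround stereo surfaces.

    The coherent condition is a triangle wave: the center surface sweeps
    from -amplitude to +amplitude arcmin and back over one ``period`` (a
    direction reversal every period/2 = 1 s), while the surround is its
    negation, so the two surfaces always move oppositely in depth. The
    scrambled control permutes whole stereo frame pairs within each
    half-period segment, which preserves the disparity multiset overall and
    keeps every relative disparity level of the cycle on screen once per
    second — only the temporal coherence of the disparity change is lost.
    """
    if condition not in ("coherent", "scrambled"):
        raise ValueError(f"unknown condition {condition!r}")
    n_cycles = duration / period
    if abs(n_cycles - round(n_cycles)) > 1e-9 or duration <= 0:
        raise ValueError("duration must be a positive multiple of the cycle period")

    n_frames = int(round(duration * frame_rate))
    t = np.arange(n_frames) / frame_rate
    tm = np.mod(t, period)
    half = period / 2.0
    center = np.where(
        tm < half,
        -amplitude + 2 * amplitude * tm / half,
        amplitude - 2 * amplitude * (tm - half) / half,
    )

    if condition == "scrambled":
        rng = np.random.default_rng(seed)
        seg = int(round(half * frame_rate))  # frames per half cycle (1 s)
        order = np.arange(n_frames)
        for s0 in range(0, n_frames, seg):
            idx = order[s0 : s0 + seg]
            if idx.size > 1:
                perm = rng.permutation(idx.size)
                while np.all(perm == np.arange(idx.size)):
                    perm = rng.permutation(idx.size)
                order[s0 : s0 + seg] = idx[perm]
        center = center[order]

    return DisparityTrajectory(
        frame_rate=frame_rate,
        center_disparity=center,
        surround_disparity=-center,
        condition=condition,
    )


# ---------------------------------------------------------------------------
# pRF mapping apertures
# ---------------------------------------------------------------------------


def gen_prf_apertures(
    kind: str = "bar",
    radius: float = 12.2,
    grid_size: int = 101,
    n_steps: int = 8,
    tr: float = 1.0,
    step_trs: int = 3,
    bar_width: float | None = None,
    directions: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0),
    wedge_width: float = 45.0,
    ring_rel_width: float = 0.25,
) -> ApertureMovie:
    """Binary aperture masks for pRF mapping.

    bar: a bar of width ``bar_width`` (default 2*radius/n_steps, which tiles
    the field) sweeps across the field in ``n_steps`` positions, once per
    motion direction in ``directions`` (degrees; the bar is perpendicular
    to its motion). wedge: an angular sector of ``wedge_width`` deg rotating
    through ``n_steps`` angles, one clockwise and one counterclockwise
    rotation. ring: an annulus of relative width ``ring_rel_width`` stepping
    through ``n_steps`` radii, expanding then contracting. Each position is
    held for ``step_trs`` TRs; all masks are clipped to the circular field.
    """
    if kind not in ("bar", "wedge", "ring"):
        raise ValueError(f"unknown aperture kind {kind!r}")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if grid_size < 32:
        raise ValueError("grid_size must be >= 32")
    if n_steps < 4:
        raise ValueError("n_steps must be >= 4")

    s = grid_size
    c = (np.arange(s) + 0.5) * (2 * radius / s) - radius
    x, y = np.meshgrid(c, c)
    field = x * x + y * y <= radius**2

    masks: list[np.ndarray] = []
    if kind == "bar":
        width = 2 * radius / n_steps if bar_width is None else bar_width
        centers = -radius + (np.arange(n_steps) + 0.5) * (2 * radius / n_steps)
        for ang in directions:
            a = np.deg2rad(ang)
            u = x * np.cos(a) + y * np.sin(a)
            for ctr in centers:
                masks.append((np.abs(u - ctr) <= width / 2) & field)
    elif kind == "wedge":
        theta = np.rad2deg(np.arctan2(y, x)) % 360.0
        angles = np.arange(n_steps) * 360.0 / n_steps
        for ctr in list(angles) + list(angles[::-1]):
            d = np.abs((theta - ctr + 180.0) % 360.0 - 180.0)
            masks.append((d <= wedge_width / 2) & field)
    else:  # ring
        ecc = np.hypot(x, y)
        inner = np.arange(n_steps) * radius / n_steps
        width = ring_rel_width * radius
        seq = list(inner) + list(inner[::-1])
        for r0 in seq:
            masks.append((ecc >= r0) & (ecc <= r0 + width) & field)

    grid = np.repeat(np.stack(masks, axis=0), step_trs, axis=0)
    return ApertureMovie(grid=grid, radius=radius, kind=kind, tr=tr)
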