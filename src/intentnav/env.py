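"""Continuous 2-D T-maze with a 360-degree raycast RGB camera.

The maze is the union of two axis-aligned rectangles: a vertical bottom arm
and a horizontal top bar.  Exits sit at the two ends of the bar; the left
end walls are red and the right end walls are blue so that color goals
("see red", "avoid blue") are well-posed and observations discriminate
position.  The agent is a point with no heading — the camera covers 360
degrees, one azimuthal ray per image column, so pose = position only.

Reward contract per step: the configured exit reward on entering an exit
region (episode ends), the collision reward (default -1) when the commanded
move was truncated by a wall, otherwise 0.  Episodes are force-terminated
after ``max_steps`` (default 60) steps.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml


class ConfigurationError(ValueError):
    pass


_DEFAULT_WALL_COLORS = {
    "bottom": (0.50, 0.45, 0.40),
    "arm_right": (0.40, 0.50, 0.35),
    "arm_left": (0.45, 0.40, 0.55),
    "bar_bottom_right": (0.55, 0.55, 0.30),
    "bar_bottom_left": (0.30, 0.55, 0.50),
    "end_left": (0.90, 0.10, 0.10),   # red landmark at the left exit
    "end_right": (0.10, 0.10, 0.90),  # blue landmark at the right exit
    "top_left": (0.90, 0.10, 0.10),
    "top_mid": (0.60, 0.60, 0.55),
    "top_right": (0.10, 0.10, 0.90),
}


@dataclass
class MazeConfig:
    """Geometry, rewards and sensor parameters of the T-maze."""

    width: float = 3.0            # total span of the top bar (world units)
    arm_width: float = 1.0        # width of the vertical bottom arm
    arm_height: float = 2.0       # length of the bottom arm
    bar_height: float = 1.0       # corridor width of the top bar
    exit_depth: float = 0.4       # exit zones: terminal slabs of the bar
    start: tuple = None           # default: bottom-arm center, near the base
    reward_left: float = 1000.0
    reward_right: float = 500.0
    collision_reward: float = -1.0
    max_steps: int = 60
    max_speed: float = None       # default: arm_width / 8
    image_height: int = 16
    image_width: int = 64
    wall_scale: float = 0.4       # wall fills the image at this distance
    floor_color: tuple = (0.25, 0.20, 0.15)
    ceiling_color: tuple = (0.08, 0.08, 0.10)
    wall_colors: dict = field(default_factory=lambda: dict(_DEFAULT_WALL_COLORS))

    def __post_init__(self):
        if self.max_speed is None:
            self.max_speed = self.arm_width / 8.0
        if self.start is None:
            self.start = (self.width / 2.0, self.arm_height * 0.15)
        self.start = tuple(float(v) for v in self.start)
        for name, v in (("width", self.width), ("arm_width", self.arm_width),
                        ("arm_height", self.arm_height), ("bar_height", self.bar_height),
                        ("exit_depth", self.exit_depth), ("max_speed", self.max_speed)):
            if v <= 0:
                raise ConfigurationError(f"{name} must be positive, got {v}")
        if self.arm_width > self.width:
            raise ConfigurationError("bottom arm wider than the top bar")
        if 2 * self.exit_depth >= self.width:
            raise ConfigurationError("exit regions overlap")
        if self.max_steps < 1:
            raise ConfigurationError("max_steps must be >= 1")
        for r in (self.reward_left, self.reward_right, self.collision_reward):
            if not np.isfinite(r):
                raise ConfigurationError("rewards must be finite")
        if not self._in_free_space(*self.start):
            raise ConfigurationError("start position outside free space")

    # -- geometry helpers -----------------------------------------------------
    @property
    def arm_x0(self):
        return self.width / 2.0 - self.arm_width / 2.0

    @property
    def arm_x1(self):
        return self.width / 2.0 + self.arm_width / 2.0

    @property
    def top_y(self):
        return self.arm_height + self.bar_height

    def _in_free_space(self, x, y):
        in_arm = self.arm_x0 < x < self.arm_x1 and 0 < y < self.arm_height
        in_bar = 0 < x < self.width and self.arm_height < y < self.top_y
        on_seam = (self.arm_x0 < x < self.arm_x1 and y == self.arm_height)
        return in_arm or in_bar or on_seam

    def exit_at(self, x, y):
        """'left'/'right' if (x, y) lies in an exit zone, else None."""
        if y > self.arm_height:
            if x < self.exit_depth:
                return "left"
            if x > self.width - self.exit_depth:
                return "right"
        return None

    def wall_segments(self):
        """Boundary segments (p0, p1, color) of the free-space polygon."""
        ax0, ax1, ah, w, ty, ed = (self.arm_x0, self.arm_x1, self.arm_height,
                                   self.width, self.top_y, self.exit_depth)
        c = self.wall_colors
        return [
            ((ax0, 0.0), (ax1, 0.0), c["bottom"]),
            ((ax1, 0.0), (ax1, ah), c["arm_right"]),
            ((ax1, ah), (w, ah), c["bar_bottom_right"]),
            ((w, ah), (w, ty), c["end_right"]),
            ((w, ty), (w - ed, ty), c["top_right"]),
            ((w - ed, ty), (ed, ty), c["top_mid"]),
            ((ed, ty), (0.0, ty), c["top_left"]),
            ((0.0, ty), (0.0, ah), c["end_left"]),
            ((0.0, ah), (ax0, ah), c["bar_bottom_left"]),
            ((ax0, ah), (ax0, 0.0), c["arm_left"]),
        ]

    # -- serialization --------------------------------------------------------
    def to_yaml(self, path):
        d = asdict(self)
        d["wall_colors"] = {k: list(v) for k, v in self.wall_colors.items()}
        for key in ("start", "floor_color", "ceiling_color"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("start", "floor_color", "ceiling_color"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "wall_colors" in d:
            d["wall_colors"] = {k: tuple(v) for k, v in d["wall_colors"].items()}
        return cls(**d)


@dataclass
class StepResult:
    obs: np.ndarray
    reward: float
    done: bool
    info: dict


class TMazeEnv:
    """Episodic point-navigation environment with panoramic RGB observations."""

    def __init__(self, config: MazeConfig | None = None):
        self.config = config or MazeConfig()
        self._pos = None
        self._step_count = 0
        self._done = True
        self._ray_dirs = self._make_ray_dirs()

    def _make_ray_dirs(self):
        n = self.config.image_width
        angles = 2.0 * np.pi * (np.arange(n) + 0.5) / n
        return np.stack([np.cos(angles), np.sin(angles)], axis=1)

    # -- episode control ------------------------------------------------------
    @property
    def position(self):
        return None if self._pos is None else tuple(self._pos)

    def reset(self, seed: int | None = None) -> np.ndarray:
        # the environment itself is deterministic; the seed is accepted for
        # interface uniformity and future stochastic variants
        del seed
        self._pos = np.array(self.config.start, dtype=np.float64)
        self._step_count = 0
        self._done = False
        return self.render_camera()

    def step(self, action) -> StepResult:
        if self._done:
            raise RuntimeError("step() called on a finished episode; call reset()")
        action = np.clip(np.asarray(action, dtype=np.float64), -1.0, 1.0)
        if action.shape != (2,):
            raise ValueError("action must be a 2-vector")
        cfg = self.config
        delta = action * cfg.max_speed
        collision = self._move(delta)
        self._step_count += 1

        exit_id = cfg.exit_at(*self._pos)
        truncated = False
        if exit_id == "left":
            reward, done = cfg.reward_left, True
        elif exit_id == "right":
            reward, done = cfg.reward_right, True
        else:
            reward = cfg.collision_reward if collision else 0.0
            done = self._step_count >= cfg.max_steps
            truncated = done
        self._done = done
        return StepResult(
            obs=self.render_camera(),
            reward=float(reward),
            done=done,
            info={
                "collision": collision,
                "step": self._step_count,
                "position": tuple(self._pos),
                "exit": exit_id,
                "truncated": truncated,
            },
        )

    def _move(self, delta) -> bool:
        """Axis-separable displacement truncated at walls; returns collision flag."""
        cfg = self.config
        m = 1e-9
        x, y = self._pos
        collision = False
        # x axis: the free x-interval at height y
        if y < cfg.arm_height:
            lo, hi = cfg.arm_x0, cfg.arm_x1
        else:
            lo, hi = 0.0, cfg.width
        nx = x + delta[0]
        cx = min(max(nx, lo + m), hi - m)
        if abs(cx - nx) > 1e-12:
            collision = True
        # y axis: the free y-interval at the (updated) x
        if cfg.arm_x0 < cx < cfg.arm_x1:
            lo, hi = 0.0, cfg.top_y
        else:
            lo, hi = cfg.arm_height, cfg.top_y
        ny = y + delta[1]
        cy = min(max(ny, lo + m), hi - m)
        if abs(cy - ny) > 1e-12:
            collision = True
        self._pos = np.array([cx, cy])
        return collision

    # -- rendering ------------------------------------------------------------
    def render_camera(self, position=None) -> np.ndarray:
        """Panoramic image: one azimuthal ray per column, 360-degree sweep.

        Nearest wall hit per ray sets the column's color and apparent height
        (nearer walls fill more rows); rows above/below are ceiling/floor.
        """
        cfg = self.config
        pos = np.asarray(position if position is not None else self._pos, dtype=np.float64)
        h, w = cfg.image_height, cfg.image_width
        img = np.empty((h, w, 3))
        img[: h // 2] = cfg.ceiling_color
        img[h // 2 :] = cfg.floor_color
        segments = cfg.wall_segments()
        for col, d in enumerate(self._ray_dirs):
            dist, color = self._cast_ray(pos, d, segments)
            shade = min(max(1.0 / (1.0 + 0.3 * dist), 0.35), 1.0)
            wall_h = int(round(h * cfg.wall_scale / max(dist, 1e-9)))
            wall_h = min(max(wall_h, 1), h)
            top = (h - wall_h) // 2
            img[top : top + wall_h, col] = np.asarray(color) * shade
        return np.clip(img, 0.0, 1.0)

    @staticmethod
    def _cast_ray(origin, direction, segments):
        best_t, best_color = np.inf, (0.0, 0.0, 0.0)
        ox, oy = origin
        dx, dy = direction
        for (x0, y0), (x1, y1), color in segments:
            ex, ey = x1 - x0, y1 - y0
            denom = dx * ey - dy * ex
            if abs(denom) < 1e-14:
                continue
            # solve origin + t*d = p0 + u*e
            t = ((x0 - ox) * ey - (y0 - oy) * ex) / denom
            u = ((x0 - ox) * dy - (y0 - oy) * dx) / denom
            if t > 1e-9 and -1e-12 <= u <= 1.0 + 1e-12 and t < best_t:
                best_t, best_color = t, color
        return best_t, best_color

    def render_aerial(self, trajectories=(), path=None, ax=None):
        """Aerial-view plot of the maze outline and agent trajectories."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        cfg = self.config
        own_fig = ax is None
        if own_fig:
            fig, ax = plt.subplots(figsize=(4, 4))
        for (x0, y0), (x1, y1), color in cfg.wall_segments():
            ax.plot([x0, x1], [y0, y1], color=color, lw=2)
        for zone_x in (0.0, cfg.width - cfg.exit_depth):
            ax.add_patch(
                __import__("matplotlib.patches", fromlist=["Rectangle"]).Rectangle(
                    (zone_x, cfg.arm_height), cfg.exit_depth, cfg.bar_height,
                    alpha=0.15, color="green"))
        for i, traj in enumerate(trajectories):
            pts = np.asarray(traj)
            if len(pts):
                ax.plot(pts[:, 0], pts[:, 1], lw=1.2, label=f"trial {i}")
        ax.set_aspect("equal")
        ax.set_xlim(-0.2, cfg.width + 0.2)
        ax.set_ylim(-0.2, cfg.top_y + 0.2)
        if own_fig:
            if path is not None:
                fig.savefig(path, dpi=120)
                plt.close(fig)
            return fig
        return ax


def save_trajectories_csv(trajectories, path):
    """Write trajectories as rows of (trial, step, x, y)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["trial", "step", "x", "y"])
        for trial, traj in enumerate(trajectories):
            for step, (x, y) in enumerate(traj):
                writer.writerow([trial, step, float(x), float(y)])
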