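"""Render the T-maze: panoramic agent views and an aerial sketch.

Builds the default maze, shows what the 360-degree camera sees from the
start and from near the red (left) exit, and writes an aerial view with a
hand-made trajectory.  The printed pixel counts show how the red landmark
grows as the agent approaches it — the signal color goals rely on.
"""

import numpy as np

from intentnav import MazeConfig, TMazeEnv

env = TMazeEnv(MazeConfig())
obs_start = env.reset()
cfg = env.config

near_left = (cfg.exit_depth + 0.1, cfg.arm_height + cfg.bar_height / 2)
obs_near = env.render_camera(position=near_left)


def red_pixels(img):
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    return int(((r > 2 * g) & (r > 2 * b)).sum())


print(f"observation shape: {obs_start.shape}, values in "
      f"[{obs_start.min():.2f}, {obs_start.max():.2f}]")
print(f"red-landmark pixels from start:        {red_pixels(obs_start)}")
print(f"red-landmark pixels near the left exit: {red_pixels(obs_near)}")
print("-> the left-exit wall is red; its pixel share encodes proximity")

trajectory = [(cfg.start[0], cfg.start[1] + 0.1 * i) for i in range(15)]
env.render_aerial([trajectory], path="maze_aerial.png")
print("aerial view with one trajectory written to maze_aerial.png")
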