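"""Staged experiment protocols and their summary metrics.

Three protocols, all built from the same staged driver:

* habitization — random exploration, then learning with a large left-exit
  reward, then re-learning after the left reward is extinguished;
* devaluation — habitization with a variable stage-2 budget, recording the
  trials immediately around the reward switch and the re-adaptation course;
* novel goal — learning with equal exit rewards, then a frozen-model test of
  goal-directed planning for full-observation and color goals against a
  purely habitual baseline.

Budgets, maze size and network width are configurable; the desk preset runs
on one CPU in minutes, the full-scale preset keeps the published sizes.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .active_inference import AIfConfig, GoalMemory, GoalSpec
from .behaving import BehaveMode, act, pink_noise
from .env import MazeConfig, TMazeEnv
from .learning import LearnConfig, ReplayBuffer, Trainer, Transition
from .networks import AgentModel, NetworkConfig


@dataclass
class Stage:
    name: str
    budget: int
    reward_left: float
    reward_right: float
    learning: bool
    mode: str  # "random" | "synergized" | "habitual_only" | "goal_directed_only"

    def __post_init__(self):
        if self.budget <= 0:
            raise ValueError("stage budget must be positive")


@dataclass
class ExperimentConfig:
    maze: MazeConfig
    network: NetworkConfig
    learn: LearnConfig
    aif: AIfConfig
    stages: list
    seed: int = 0

    def digest(self) -> str:
        blob = json.dumps({
            "maze": {k: str(v) for k, v in asdict(self.maze).items()},
            "network": {k: str(v) for k, v in asdict(self.network).items()},
            "learn": {k: str(v) for k, v in asdict(self.learn).items()},
            "aif": {k: str(v) for k, v in asdict(self.aif).items()},
            "stages": [asdict(s) for s in self.stages],
            "seed": self.seed,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class MetricsLog:
    """Per-step, per-episode and per-update records of one run."""

    def __init__(self):
        self.steps: list[dict] = []
        self.episodes: list[dict] = []
        self.losses: list[dict] = []
        self.stage_bounds: dict[str, tuple] = {}
        self.stage_rewards: dict[str, tuple] = {}

    def step_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)

    def episode_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.episodes)

    def loss_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.losses)

    def save(self, out_dir):
        os.makedirs(out_dir, exist_ok=True)
        self.step_frame().to_csv(os.path.join(out_dir, "steps.csv"), index=False)
        self.episode_frame().to_csv(os.path.join(out_dir, "episodes.csv"), index=False)
        self.loss_frame().to_csv(os.path.join(out_dir, "losses.csv"), index=False)
        with open(os.path.join(out_dir, "losses.jsonl"), "w") as fh:
            for rec in self.losses:
                fh.write(json.dumps(rec) + "\n")
        with open(os.path.join(out_dir, "stages.json"), "w") as fh:
            json.dump({"bounds": self.stage_bounds, "rewards": self.stage_rewards}, fh)


def moving_average(x, window: int):
    """Centered moving average; shorter windows at the borders."""
    x = np.asarray(x, dtype=np.float64)
    if window <= 1 or len(x) == 0:
        return x.copy()
    half = window // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


@dataclass
class ReadaptationResult:
    steps: int
    reached: bool


def compute_readaptation_steps(log: MetricsLog, criterion: float = 0.8,
                               stage: str = "stage3", window: int = 5) -> ReadaptationResult:
    """Env steps into the re-adaptation stage until the smoothed episodic
    reward reaches ``criterion`` x the optimal stage reward."""
    if stage not in log.stage_bounds:
        raise ValueError(f"stage {stage!r} absent from log")
    start, end = log.stage_bounds[stage]
    optimal = max(log.stage_rewards[stage])
    episodes = [e for e in log.episodes if e["stage"] == stage]
    if not episodes:
        return ReadaptationResult(steps=end - start, reached=False)
    rewards = moving_average([e["reward"] for e in episodes], window)
    for e, r in zip(episodes, rewards):
        if r >= criterion * optimal:
            return ReadaptationResult(steps=max(e["end_step"] - start, 0), reached=True)
    return ReadaptationResult(steps=end - start, reached=False)


class ExperimentDriver:
    """Runs a staged schedule: acting, experience storage, training, logging."""

    def __init__(self, config: ExperimentConfig):
        self.config = config
        self.env = TMazeEnv(config.maze)
        self.model = AgentModel(config.network, seed=config.seed)
        self.trainer = Trainer(self.model, config.learn)
        self.buffer = ReplayBuffer(config.learn.buffer_capacity,
                                   max_len=config.maze.max_steps)
        self.memory = GoalMemory()
        root = np.random.default_rng(config.seed)
        self.noise_rng = np.random.default_rng(root.integers(2**31))
        self.cem_rng = np.random.default_rng(root.integers(2**31))
        self.goal_rng = np.random.default_rng(root.integers(2**31))
        self.log = MetricsLog()
        self.global_step = 0
        self.learn_step = 0  # annealing clock: steps inside learning stages

    def run(self) -> MetricsLog:
        for stage in self.config.stages:
            self._run_stage(stage)
        return self.log

    # -- stages ---------------------------------------------------------------
    def _run_stage(self, stage: Stage):
        cfg = self.env.config
        cfg.reward_left = stage.reward_left
        cfg.reward_right = stage.reward_right
        self.memory.revalue({"left": stage.reward_left, "right": stage.reward_right})
        start = self.global_step
        self.log.stage_rewards[stage.name] = (stage.reward_left, stage.reward_right)
        while self.global_step - start < stage.budget:
            self._run_episode(stage)
        self.log.stage_bounds[stage.name] = (start, self.global_step)

    def _run_episode(self, stage: Stage):
        env, model = self.env, self.model
        obs = env.reset()
        context = model.init_context(1)
        noise = pink_noise(self.noise_rng, model.cfg.action_dim, env.config.max_steps)
        goal_obs, goal_exit = None, None
        mode = BehaveMode(stage.mode) if stage.mode != "random" else None
        if mode in (BehaveMode.SYNERGIZED, BehaveMode.GOAL_DIRECTED_ONLY) and len(self.memory):
            goal_obs, goal_exit = self.memory.select_goal(self.goal_rng)
        goal = GoalSpec(kind="full", observation=goal_obs) if goal_obs is not None else None

        total_reward, steps, done = 0.0, 0, False
        while not done:
            if stage.mode == "random":
                action = self.noise_rng.uniform(-1.0, 1.0, size=model.cfg.action_dim)
                diag = None
            else:
                step_mode = mode if goal is not None or mode == BehaveMode.HABITUAL_ONLY \
                    else BehaveMode.HABITUAL_ONLY
                action, context, diag = act(model, context, obs, noise[steps],
                                            step_mode, goal=goal,
                                            aif_config=self.config.aif,
                                            rng=self.cem_rng)
            result = env.step(action)
            self.buffer.store(Transition(
                obs=obs, next_obs=result.obs, action=np.asarray(action),
                reward=result.reward, done=result.done,
                terminal=result.done and not result.info["truncated"]))
            if result.info["exit"] is not None:
                self.memory.add(result.obs, result.reward, result.info["exit"])
            self._log_step(stage, result, diag)
            self.global_step += 1
            if stage.learning:
                self.learn_step += 1
                if self.global_step % self.config.learn.update_interval == 0:
                    breakdown = self.trainer.train_step(self.buffer, env_step=self.learn_step)
                    if breakdown is not None:
                        rec = breakdown.as_dict()
                        rec["step"] = self.global_step
                        self.log.losses.append(rec)
            total_reward += result.reward
            obs = result.obs
            steps += 1
            done = result.done
        self.log.episodes.append({
            "stage": stage.name, "reward": total_reward, "steps": steps,
            "exit": result.info["exit"] or "timeout",
            "end_step": self.global_step,
            "goal_exit": goal_exit,
        })

    def _log_step(self, stage, result, diag):
        rec = {
            "step": self.global_step, "stage": stage.name,
            "reward": result.reward, "collision": int(result.info["collision"]),
        }
        if diag is not None:
            rec["sigma_p"] = float(np.mean(diag.prior.sigma))
            if diag.posterior is not None:
                rec["sigma_q"] = float(np.mean(diag.posterior.sigma))
                rec["habitual_ratio"] = diag.habitual_ratio
            rec["generations"] = diag.generations_used
        self.log.steps.append(rec)


# -- presets -------------------------------------------------------------------

def desk_maze() -> MazeConfig:
    from .fixtures import tiny_maze_config

    return tiny_maze_config()


def desk_config(seed: int = 0, stage_budgets=(400, 900, 900),
                protocol: str = "habitization") -> ExperimentConfig:
    """Desk-scale study conditions: tiny maze and nets, budgets in the
    hundreds of steps, CEM 32/8/8 for per-step inference.

    The loss weights beta_a and beta_z are scaled by the pixel-count ratio
    of the small retina to the full one, preserving the balance between the
    pixel-summed prediction errors and the RL/complexity terms at the
    reduced resolution (the published weights assume 16x64x3 observations).
    """
    maze = desk_maze()
    px_ratio = (maze.image_height * maze.image_width) / (16 * 64)
    # buffer capacity scales with the stage budgets (the full-scale ring of
    # 2^13 sequences also holds a few stages' worth of experience)
    learn = LearnConfig(batch_sequences=6, buffer_capacity=64,
                        beta_a=1e5 * px_ratio, beta_z=0.1 * px_ratio,
                        anneal_steps=sum(stage_budgets[1:]), seed=seed)
    aif = AIfConfig(population=32, elites=8, max_generations=8,
                    beta_z=learn.beta_z)
    stages = _protocol_stages(protocol, stage_budgets)
    return ExperimentConfig(maze=maze, network=NetworkConfig.tiny(),
                            learn=learn, aif=aif, stages=stages, seed=seed)


def fullscale_config(seed: int = 0, stage_budgets=(100_000, 80_000, 80_000),
                 protocol: str = "habitization") -> ExperimentConfig:
    learn = LearnConfig(anneal_steps=sum(stage_budgets[1:]), seed=seed)
    stages = _protocol_stages(protocol, stage_budgets)
    return ExperimentConfig(maze=MazeConfig(), network=NetworkConfig.default(),
                            learn=learn, aif=AIfConfig(), stages=stages, seed=seed)


def _protocol_stages(protocol: str, budgets) -> list:
    b1, b2, b3 = budgets
    if protocol == "habitization" or protocol == "devaluation":
        return [
            Stage("stage1", b1, 1000.0, 500.0, learning=False, mode="random"),
            Stage("stage2", b2, 1000.0, 500.0, learning=True, mode="synergized"),
            Stage("stage3", b3, 0.0, 500.0, learning=True, mode="synergized"),
        ]
    if protocol == "novel-goal":
        return [
            Stage("stage1", b1, 1000.0, 1000.0, learning=False, mode="random"),
            Stage("stage2", b2, 1000.0, 1000.0, learning=True, mode="synergized"),
        ]
    raise ValueError(f"unknown protocol {protocol!r}")


# -- protocols -----------------------------------------------------------------

def run_habitization(config: ExperimentConfig) -> MetricsLog:
    """Exploration, adaptation to the large-reward left exit, re-adaptation
    to the right after left-reward extinction."""
    return ExperimentDriver(config).run()


def run_devaluation(config: ExperimentConfig, devalue: str = "left"):
    """Habitization with the configured stage-2 budget; additionally reports
    the exit choices of the last 2 trials before and first 2 after the
    reward devaluation.

    ``devalue`` selects which outcome loses its reward at the stage-2 ->
    stage-3 boundary: "left" (the fixed protocol) or "committed" — the exit
    the agent actually habitized, read from its late stage-2 trials.  The
    adaptive form keeps the devaluation probe meaningful at desk scale,
    where short training may habitize either side; the devalued outcome is
    always the trained one, as in the behavioral paradigm.
    """
    if devalue not in ("left", "committed"):
        raise ValueError(f"unknown devaluation target {devalue!r}")
    driver = ExperimentDriver(config)
    s1, s2, s3 = config.stages
    driver._run_stage(s1)
    driver._run_stage(s2)
    stage2 = [e for e in driver.log.episodes if e["stage"] == s2.name]
    tail = stage2[-max(len(stage2) // 3, 1):]
    lefts = sum(e["exit"] == "left" for e in tail)
    rights = sum(e["exit"] == "right" for e in tail)
    committed = "left" if lefts >= rights else "right"
    if devalue == "committed" and committed == "right":
        s3.reward_left, s3.reward_right = 500.0, 0.0
    valued = "right" if (devalue == "left" or committed == "left") else "left"
    driver._run_stage(s3)
    log = driver.log
    readapt = compute_readaptation_steps(log, stage=s3.name)
    if not readapt.reached:
        readapt.steps = s3.budget  # the full budget, free of episode overrun
    pre = stage2[-2:]
    post = [e for e in log.episodes if e["stage"] == s3.name][:2]
    outcomes = {
        "committed_exit": committed,
        "valued_exit": valued,
        "pre_exits": [e["exit"] for e in pre],
        "post_exits": [e["exit"] for e in post],
        "post_switch_rate": float(np.mean([e["exit"] == valued for e in post])),
        "readaptation": asdict(readapt),
    }
    return log, outcomes


def run_novel_goal(config: ExperimentConfig, eval_trials: int = 10,
                   waypoints=None, target_radius: float = None,
                   eval_aif: AIfConfig = None) -> pd.DataFrame:
    """Equal-reward training, then frozen-model planning tests.

    For every goal kind the table reports successes over ``eval_trials``
    trials: full-observation goals succeed on reaching the goal region,
    color goals on reaching the matching exit (red = left walls, blue =
    right).  The habitual baseline receives the same exit targets but acts
    purely habitually, so with a two-sided habit it succeeds about half the
    time.  Evaluation planning uses ``eval_aif`` (default: the same planner
    configuration the agent behaved with during training).
    """
    driver = ExperimentDriver(config)
    log = driver.run()
    env, model = driver.env, driver.model
    rng = np.random.default_rng(config.seed + 1)
    if eval_aif is None:
        eval_aif = config.aif
    if target_radius is None:
        target_radius = env.config.bar_height / 2.0
    red = env.config.wall_colors["end_left"]
    blue = env.config.wall_colors["end_right"]

    def run_trial(mode, goal, success_fn):
        traj, reward, steps, diags = _frozen_episode(env, model, mode, goal,
                                                     eval_aif, rng)
        return success_fn(traj)

    def reaches_exit(side):
        return lambda traj: env.config.exit_at(*traj[-1]) == side

    def reaches_region(point):
        pt = np.asarray(point)
        return lambda traj: bool(np.any(
            np.linalg.norm(np.asarray(traj) - pt[None], axis=1) <= target_radius))

    exit_goal = {}
    for side in ("left", "right"):
        entries = [e for e in driver.memory.entries if e["exit"] == side]
        if entries:
            exit_goal[side] = entries[-1]["obs"]
    if waypoints is None:
        c = env.config
        waypoints = [(c.width / 2.0, c.arm_height + c.bar_height / 2.0)]

    rows = []

    def record(kind, mode, goal, success_fn):
        wins = sum(run_trial(mode, goal, success_fn) for _ in range(eval_trials))
        rows.append({"goal": kind, "mode": mode.value,
                     "successes": int(wins), "trials": eval_trials,
                     "rate": wins / eval_trials})

    # habitual baseline: same alternating exit targets, goal-blind behavior
    sides = [("left", "right")[i % 2] if "left" in exit_goal and "right" in exit_goal
             else ("left" if "left" in exit_goal else "right")
             for i in range(eval_trials)]
    wins = sum(run_trial(BehaveMode.HABITUAL_ONLY, None, reaches_exit(s))
               for s in sides)
    rows.append({"goal": "habitual_baseline", "mode": "habitual_only",
                 "successes": int(wins), "trials": eval_trials,
                 "rate": wins / eval_trials})
    for side in ("left", "right"):
        if side in exit_goal:
            record(f"full_obs_{side}", BehaveMode.GOAL_DIRECTED_ONLY,
                   GoalSpec(kind="full", observation=exit_goal[side]),
                   reaches_exit(side))
    for i, wp in enumerate(waypoints):
        goal_obs = env.render_camera(position=wp)
        record(f"full_obs_waypoint{i}", BehaveMode.GOAL_DIRECTED_ONLY,
               GoalSpec(kind="full", observation=goal_obs), reaches_region(wp))
    record("see_red", BehaveMode.GOAL_DIRECTED_ONLY,
           GoalSpec(kind="color", color=red, mode="pursue"), reaches_exit("left"))
    record("see_blue", BehaveMode.GOAL_DIRECTED_ONLY,
           GoalSpec(kind="color", color=blue, mode="pursue"), reaches_exit("right"))
    record("avoid_red", BehaveMode.GOAL_DIRECTED_ONLY,
           GoalSpec(kind="color", color=red, mode="avoid"), reaches_exit("right"))
    record("avoid_blue", BehaveMode.GOAL_DIRECTED_ONLY,
           GoalSpec(kind="color", color=blue, mode="avoid"), reaches_exit("left"))

    # habitual two-sidedness: exit sides under pure habit
    habit_sides = []
    for _ in range(eval_trials):
        traj, *_ = _frozen_episode(env, model, BehaveMode.HABITUAL_ONLY, None,
                                   config.aif, rng)
        habit_sides.append(env.config.exit_at(*traj[-1]) or "timeout")
    table = pd.DataFrame(rows)
    table.attrs["habitual_exits"] = habit_sides
    table.attrs["log"] = log
    return table


def _frozen_episode(env, model, mode, goal, aif_config, rng):
    obs = env.reset()
    context = model.init_context(1)
    noise = pink_noise(rng, model.cfg.action_dim, env.config.max_steps)
    traj = [env.position]
    total, steps, done = 0.0, 0, False
    diags = []
    while not done:
        action, context, diag = act(model, context, obs, noise[steps], mode,
                                    goal=goal, aif_config=aif_config, rng=rng)
        result = env.step(action)
        diags.append(diag)
        traj.append(result.info["position"])
        total += result.reward
        obs = result.obs
        steps += 1
        done = result.done
    return traj, total, steps, diags


def aggregate_seeds(logs: list, frame: str = "steps") -> pd.DataFrame:
    """Mean +/- standard error of aligned numeric series across seed runs."""
    if not logs:
        raise ValueError("need at least one log")
    frames = [getattr(lg, f"{frame.rstrip('s')}_frame")() for lg in logs]
    n_rows = {len(f) for f in frames}
    if len(n_rows) != 1:
        raise ValueError("misaligned budgets: runs have different lengths")
    out = {}
    numeric = frames[0].select_dtypes(include=[np.number]).columns
    for col in numeric:
        stack = np.stack([f[col].to_numpy(dtype=np.float64) for f in frames])
        out[f"{col}_mean"] = np.nanmean(stack, axis=0)
        out[f"{col}_sem"] = (np.nanstd(stack, axis=0, ddof=0)
                             / np.sqrt(stack.shape[0]))
    return pd.DataFrame(out)


def write_manifest(config: ExperimentConfig, out_dir, extra=None):
    os.makedirs(out_dir, exist_ok=True)
    manifest = {"config_digest": config.digest(), "seed": config.seed,
                "package_version": "0.1.0"}
    if extra:
        manifest.update(extra)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
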