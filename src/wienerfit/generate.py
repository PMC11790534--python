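"""Synthetic trial-table generation for the two penalty-anticipation experiments.

Both experiments are two-alternative forced-choice tasks: a participant
watches a video of a handball penalty throw and indicates the anticipated
throw direction (left/right) by pointing or swiping on a touch screen.
Experiment 1 manipulates only the response modality (pointing vs swiping,
alternating between blocks).  Experiment 2 adds contextual probability
cues in blocks 3–4: a "75/25" cue advertises a 75% probability of a throw
to the left, "25/75" one to the right, switching halfway through each cued
block.  A trial whose actual throw direction matches the cued majority side
is *congruent*, a mismatch is *incongruent*; uncued trials are *baseline*.

The generator draws per-subject diffusion parameters from group-level
distributions (see :class:`GroundTruth`), assembles per-trial parameters
from the design cell of each trial, and simulates choices and response
times with the Euler–Maruyama forward simulator of the diffusion core.
Everything is deterministic under the configured seed, so the full
fit-and-test pipeline can be validated by parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _wfpt

__all__ = [
    "DesignConfig",
    "GroundTruth",
    "exp1_design",
    "exp2_design",
    "generate_experiment1",
    "generate_experiment2",
    "write_trials",
    "read_trials",
    "validate_trials",
]

MODALITIES = ("point", "swipe")
CUES = ("none", "75/25", "25/75")
CONGRUENCIES = ("baseline", "congruent", "incongruent")

#: majority stimulus side advertised by each cue
CUE_MAJORITY = {"75/25": "left", "25/75": "right"}

REQUIRED_COLUMNS = [
    "subject",
    "experiment",
    "block",
    "modality",
    "cue",
    "stimulus",
    "congruency",
    "response",
    "correct",
    "rt",
]


@dataclass(frozen=True)
class DesignConfig:
    """Block/trial structure of one experiment.

    ``cue_schedule`` labels each block ``"none"`` or ``"cued"``; cued blocks
    show one probability cue up to ``switch_position`` (fraction of the
    block) and the opposite cue afterwards, with the first cue
    counterbalanced between blocks and participants.  ``stimulus_mix`` is
    the fraction of left-direction stimuli per cue segment (the clip set is
    balanced); set ``match_cue_frequencies`` to make cued segments follow
    the advertised 75/25 split instead.
    """

    n_subjects: int
    trials_per_block: int
    n_blocks: int = 4
    modality_order: str = "counterbalanced"  # point_first | swipe_first | counterbalanced
    cue_schedule: tuple[str, ...] = ("none", "none", "none", "none")
    switch_position: float = 0.5
    stimulus_mix: float = 0.5
    match_cue_frequencies: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.trials_per_block < 2 or self.trials_per_block % 2:
            raise ValueError("trials_per_block must be even and >= 2")
        if len(self.cue_schedule) != self.n_blocks:
            raise ValueError("cue_schedule must list one entry per block")
        if not all(c in ("none", "cued") for c in self.cue_schedule):
            raise ValueError("cue_schedule entries must be 'none' or 'cued'")
        if not (0.0 < self.switch_position < 1.0):
            raise ValueError("switch_position must lie within the block")
        if self.modality_order not in ("point_first", "swipe_first", "counterbalanced"):
            raise ValueError(f"unknown modality_order {self.modality_order!r}")


def exp1_design(n_subjects: int = 27, trials_per_block: int = 100, seed: int = 0, **kw) -> DesignConfig:
    """Default Experiment 1 design: 4 uncued blocks, modality alternating."""
    return DesignConfig(
        n_subjects=n_subjects,
        trials_per_block=trials_per_block,
        cue_schedule=("none",) * kw.pop("n_blocks", 4),
        seed=seed,
        **kw,
    )


def exp2_design(n_subjects: int = 30, trials_per_block: int = 96, seed: int = 0, **kw) -> DesignConfig:
    """Default Experiment 2 design: 2 baseline blocks, then 2 cued blocks."""
    return DesignConfig(
        n_subjects=n_subjects,
        trials_per_block=trials_per_block,
        cue_schedule=("none", "none", "cued", "cued"),
        seed=seed,
        **kw,
    )


@dataclass(frozen=True)
class GroundTruth:
    """Group-level generative parameters.

    Means are given on the natural scale; subject-level values are sampled
    on transformed scales (drift: identity, boundary and non-decision time:
    log, starting point: logit) so every draw respects the parameter
    domains without rejection.  ``rho_subject`` is the correlation of a
    subject's deviations across the cells of one parameter (e.g. the two
    modalities): 1.0 means a subject who is slow when pointing is equally
    slow when swiping.

    Effects: ``dv_congruency`` is added to (subtracted from) the drift
    magnitude on congruent (incongruent) trials; ``dz_cue`` shifts the
    starting point toward the cued majority side from the uncued baseline
    ``z0`` (> 0.5 encodes the rightward bias seen in this task);
    ``dv_modality`` splits the drift magnitude between pointing and swiping
    (zero by default — modality affects non-decision time, not drift).
    """

    v: float = 1.5
    dv_congruency: float = 0.3
    dv_modality: float = 0.0
    a: float = 2.0
    z0: float = 0.55
    dz_cue: float = 0.05
    t_point: float = 0.55
    t_swipe: float = 0.45
    sd_v: float = 0.3
    sd_log_a: float = 0.2
    sd_log_t: float = 0.2
    sd_logit_z: float = 0.2
    rho_subject: float = 0.6

    def __post_init__(self) -> None:
        if self.a <= 0 or self.t_point < 0 or self.t_swipe < 0:
            raise ValueError("boundary separation must be > 0 and non-decision times >= 0")
        for zval in (self.z0, self.z0 - self.dz_cue, self.z0 + self.dz_cue):
            if not (0.0 < zval < 1.0):
                raise ValueError("starting points implied by z0 and dz_cue must lie in (0, 1)")
        if not (0.0 <= self.rho_subject <= 1.0):
            raise ValueError("rho_subject must be in [0, 1]")

    # --- cell means -------------------------------------------------------
    def v_mean(self, modality: str, congruency: str) -> float:
        val = self.v + 0.5 * self.dv_modality * (1.0 if modality == "point" else -1.0)
        if congruency == "congruent":
            val += self.dv_congruency
        elif congruency == "incongruent":
            val -= self.dv_congruency
        return val

    def t_mean(self, modality: str) -> float:
        return self.t_point if modality == "point" else self.t_swipe

    def z_mean(self, cue: str) -> float:
        if cue == "none":
            return self.z0
        return self.z0 - self.dz_cue if CUE_MAJORITY[cue] == "left" else self.z0 + self.dz_cue

    def sample_subjects(self, n_subjects: int, rng: np.random.Generator) -> list[dict]:
        """Draw per-subject parameter values for every design cell."""

        def effects(n_cells: int, sd: float) -> np.ndarray:
            # exchangeable correlation rho_subject across cells of a parameter
            shared = rng.standard_normal()
            own = rng.standard_normal(n_cells)
            r = self.rho_subject
            return sd * (np.sqrt(r) * shared + np.sqrt(1.0 - r) * own)

        subjects = []
        v_cells = [(m, c) for m in MODALITIES for c in CONGRUENCIES]
        for _ in range(n_subjects):
            ev = effects(len(v_cells), self.sd_v)
            ea = effects(1, self.sd_log_a)
            et = effects(len(MODALITIES), self.sd_log_t)
            ez = effects(len(CUES), self.sd_logit_z)
            subj = {
                "v": {cell: self.v_mean(*cell) + ev[i] for i, cell in enumerate(v_cells)},
                "a": float(np.exp(np.log(self.a) + ea[0])),
                "t": {m: float(np.exp(np.log(self.t_mean(m)) + et[i])) for i, m in enumerate(MODALITIES)},
                "z": {
                    cue: float(_invlogit(_logit(self.z_mean(cue)) + ez[i]))
                    for i, cue in enumerate(CUES)
                },
            }
            subjects.append(subj)
        return subjects


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _invlogit(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def _subject_modalities(config: DesignConfig, subj_index: int) -> list[str]:
    if config.modality_order == "point_first":
        first = "point"
    elif config.modality_order == "swipe_first":
        first = "swipe"
    else:
        first = MODALITIES[subj_index % 2]
    other = "swipe" if first == "point" else "point"
    return [first if b % 2 == 0 else other for b in range(config.n_blocks)]


def _block_segments(config: DesignConfig, subj_index: int, block: int) -> list[tuple[str, int]]:
    """(cue label, n_trials) segments of one block, in presentation order."""
    n = config.trials_per_block
    if config.cue_schedule[block] == "none":
        return [("none", n)]
    switch = int(round(config.switch_position * n))
    # first cue alternates between participants and between cued blocks
    cued_rank = sum(1 for b in range(block) if config.cue_schedule[b] == "cued")
    first = ("75/25", "25/75")[(subj_index + cued_rank) % 2]
    second = "25/75" if first == "75/25" else "75/25"
    return [(first, switch), (second, n - switch)]


def _segment_stimuli(config: DesignConfig, cue: str, n: int, rng: np.random.Generator) -> np.ndarray:
    frac_left = config.stimulus_mix
    if cue != "none" and config.match_cue_frequencies:
        frac_left = 0.75 if CUE_MAJORITY[cue] == "left" else 0.25
    n_left = int(round(frac_left * n))
    stim = np.array(["left"] * n_left + ["right"] * (n - n_left))
    rng.shuffle(stim)
    return stim


def _generate(config: DesignConfig, truth: GroundTruth, experiment: int, dt: float, max_decision_time: float) -> pd.DataFrame:
    rng = np.random.default_rng(config.seed)
    subjects = truth.sample_subjects(config.n_subjects, rng)

    rows: dict[str, list] = {c: [] for c in REQUIRED_COLUMNS if c not in ("response", "correct", "rt")}
    pv, pa, pz, pt = [], [], [], []
    for si, subj in enumerate(subjects):
        modalities = _subject_modalities(config, si)
        for b in range(config.n_blocks):
            for cue, n_seg in _block_segments(config, si, b):
                stim = _segment_stimuli(config, cue, n_seg, rng)
                for s in stim:
                    if cue == "none":
                        cong = "baseline"
                    else:
                        cong = "congruent" if s == CUE_MAJORITY[cue] else "incongruent"
                    rows["subject"].append(f"s{si:02d}")
                    rows["experiment"].append(experiment)
                    rows["block"].append(b + 1)
                    rows["modality"].append(modalities[b])
                    rows["cue"].append(cue)
                    rows["stimulus"].append(s)
                    rows["congruency"].append(cong)
                    sign = 1.0 if s == "right" else -1.0
                    pv.append(sign * subj["v"][(modalities[b], cong)])
                    pa.append(subj["a"])
                    pz.append(subj["z"][cue])
                    pt.append(subj["t"][modalities[b]])

    sim_seed = int(rng.integers(0, 2**31 - 1))
    rt, hit_upper, truncated = _wfpt.simulate_many(
        np.asarray(pv), np.asarray(pa), np.asarray(pz), np.asarray(pt),
        dt, 1.0, max_decision_time, sim_seed,
    )
    df = pd.DataFrame(rows)
    df["response"] = np.where(hit_upper, "right", "left")
    df["correct"] = df["response"] == df["stimulus"]
    df["rt"] = rt
    df["truncated"] = truncated
    df = df[REQUIRED_COLUMNS + ["truncated"]]
    df.attrs["meta"] = {
        "rt_unit": "s",
        "seed": config.seed,
        "experiment": experiment,
        "design": dataclasses.asdict(config),
        "truth": dataclasses.asdict(truth),
    }
    return df


def generate_experiment1(
    config: DesignConfig | None = None,
    truth: GroundTruth | None = None,
    dt: float = 1e-4,
    max_decision_time: float = 20.0,
) -> pd.DataFrame:
    """Simulate an Experiment 1 table (uncued, modality alternating)."""
    config = config or exp1_design()
    if any(c != "none" for c in config.cue_schedule):
        raise ValueError("experiment 1 has no cued blocks")
    truth = truth or GroundTruth()
    return _generate(config, truth, experiment=1, dt=dt, max_decision_time=max_decision_time)


def generate_experiment2(
    config: DesignConfig | None = None,
    truth: GroundTruth | None = None,
    dt: float = 1e-4,
    max_decision_time: float = 20.0,
) -> pd.DataFrame:
    """Simulate an Experiment 2 table (baseline blocks then cued blocks)."""
    config = config or exp2_design()
    if not any(c == "cued" for c in config.cue_schedule):
        raise ValueError("experiment 2 requires cued blocks")
    truth = truth or GroundTruth()
    return _generate(config, truth, experiment=2, dt=dt, max_decision_time=max_decision_time)


# --- validation and I/O ---------------------------------------------------

def validate_trials(df: pd.DataFrame) -> None:
    """Raise ``ValueError`` (listing offending rows) on schema violations."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    problems = []

    def check(mask: pd.Series, what: str) -> None:
        if mask.any():
            idx = list(df.index[mask][:10])
            problems.append(f"{what} (rows {idx}{', ...' if mask.sum() > 10 else ''})")

    check(~df["modality"].isin(MODALITIES), "modality not in {point, swipe}")
    check(~df["cue"].isin(CUES), "cue not in {none, 75/25, 25/75}")
    check(~df["stimulus"].isin(("left", "right")), "stimulus not in {left, right}")
    check(~df["response"].isin(("left", "right")), "response not in {left, right}")
    check(~df["congruency"].isin(CONGRUENCIES), "congruency label unknown")
    check(~(df["rt"] > 0), "rt must be positive")
    check((df["cue"] == "none") != (df["congruency"] == "baseline"),
          "congruency must be 'baseline' exactly when cue is 'none'")
    cued = df["cue"] != "none"
    majority = df.loc[cued, "cue"].map(CUE_MAJORITY)
    expect = np.where(df.loc[cued, "stimulus"] == majority, "congruent", "incongruent")
    bad = pd.Series(False, index=df.index)
    bad.loc[cued] = df.loc[cued, "congruency"].to_numpy() != expect
    check(bad, "congruency inconsistent with cue majority side")
    check(df["correct"] != (df["response"] == df["stimulus"]),
          "correct flag inconsistent with response and stimulus")
    if problems:
        raise ValueError("invalid trial table: " + "; ".join(problems))


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial table as CSV with a ``#``-prefixed JSON metadata header."""
    meta = dict(df.attrs.get("meta", {"rt_unit": "s"}))
    with open(path, "w") as fh:
        fh.write("# wienerfit trial table\n")
        fh.write("# meta: " + json.dumps(meta) + "\n")
        df.to_csv(fh, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table written by :func:`write_trials`."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# meta:"):
                meta = json.loads(line[len("# meta:"):])
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    df["correct"] = df["correct"].astype(bool)
    if "truncated" in df.columns:
        df["truncated"] = df["truncated"].astype(bool)
    validate_trials(df)
    if meta.get("rt_unit", "s") == "ms":
        df["rt"] = df["rt"] / 1000.0
        meta["rt_unit"] = "s"
    df.attrs["meta"] = meta
    return df
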