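"""Experiment designs for the audiovisual Ternus paradigm.

Four designs are supported:

* ``E1`` — fully randomized Ternus task: 7 SOAs x 2 sound conditions x 24
  trials (336 total, two blocks of 168), order fully randomized.
* ``E2`` — sound blocked: 4 blocks of 84 trials, two all-sound and two
  no-sound blocks in a Latin-square order; 12 trials per SOA per block.
* ``E3`` — SOA blocked: one block per SOA (fixed SOA within block).
* ``E4`` — visual localization control: identical timeline to E1 but with
  no Ternus frames; beep anchor times mark where the frames would be.

Times are milliseconds from trial start.  The SOA (frame-onset to
frame-onset) always equals ISI + 30 ms because each frame lasts 30 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ISI_LEVELS_MS = (50, 80, 110, 140, 170, 200, 230)
FRAME_DURATION_MS = 30.0
SOA_LEVELS_MS = tuple(isi + FRAME_DURATION_MS for isi in ISI_LEVELS_MS)

#: delay from trial start (end of the 3-5 s central fixation) to frame1:
#: peripheral fixation 200 ms + blank 100 ms + central fixation 200 ms +
#: blank 300 ms.
_PRE_FRAME1_MS = 200.0 + 100.0 + 200.0 + 300.0
_PROBE_DELAY_MS = 300.0  # blank between frame2 offset and the question mark

EXPERIMENT_IDS = ("E1", "E2", "E3", "E4")


@dataclass(frozen=True)
class TrialSpec:
    """One trial: condition labels plus the event timeline.

    ``timeline`` maps event name -> onset in ms from trial start.  E1-E3
    trials always have ``frame1``/``frame2``; ``beep1``/``beep2`` are present
    when ``sound`` is true (onsets equal to the frame onsets).  E4 trials
    have no frame events; instead ``beep1``/``beep2`` mark the nominal frame
    times for every trial (the beeps are audible only on sound trials).
    """

    trial_id: int
    soa_ms: float
    sound: bool
    direction: str  # "left" | "right"
    block: int
    timeline: dict = field(compare=False)

    @property
    def isi_ms(self) -> float:
        return self.soa_ms - FRAME_DURATION_MS

    def anchor(self, name: str) -> float:
        """Onset of a timeline event; ``frame1``/``frame2`` fall back to
        ``beep1``/``beep2`` on frame-less (E4) trials."""
        if name in self.timeline:
            return self.timeline[name]
        fallback = {"frame1": "beep1", "frame2": "beep2"}.get(name)
        if fallback is not None and fallback in self.timeline:
            return self.timeline[fallback]
        raise KeyError(f"trial {self.trial_id} has no timeline event {name!r}")


@dataclass
class ExperimentDesign:
    experiment_id: str
    trials: list[TrialSpec]
    block_structure: list[tuple[int, str]]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        """Flat trial table with one timeline column per event."""
        rows = []
        for t in self.trials:
            row = {
                "trial_id": t.trial_id,
                "soa_ms": t.soa_ms,
                "sound": t.sound,
                "direction": t.direction,
                "block": t.block,
            }
            for ev in ("fixation", "peripheral_fixation", "central_fixation",
                       "frame1", "frame2", "beep1", "beep2", "probe"):
                row[ev + "_ms"] = t.timeline.get(ev, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)


def subset_per_cell(design: ExperimentDesign, per_cell: int) -> ExperimentDesign:
    """Keep the first ``per_cell`` trials of every SOA x sound cell (in
    presentation order); used to scale simulated datasets down."""
    counts: dict = {}
    trials = []
    for t in design.trials:
        key = (t.soa_ms, t.sound)
        if counts.get(key, 0) < per_cell:
            counts[key] = counts.get(key, 0) + 1
            trials.append(t)
    return ExperimentDesign(design.experiment_id, trials, design.block_structure)


def _make_cells(trials_per_cell: int) -> list[tuple[float, bool, str]]:
    """(soa, sound, direction) labels, balanced left/right within each cell."""
    cells = []
    half = trials_per_cell // 2
    for soa in SOA_LEVELS_MS:
        for sound in (False, True):
            cells += [(soa, sound, "left")] * half
            cells += [(soa, sound, "right")] * (trials_per_cell - half)
    return cells


def _timeline(rng: np.random.Generator, soa: float, sound: bool,
              with_frames: bool) -> dict:
    fix = float(np.round(rng.uniform(3000.0, 5000.0), 1))
    f1 = fix + _PRE_FRAME1_MS
    f2 = f1 + soa
    tl = {
        "fixation": 0.0,
        "peripheral_fixation": fix,
        "central_fixation": fix + 300.0,
        "probe": f2 + FRAME_DURATION_MS + _PROBE_DELAY_MS,
    }
    if with_frames:
        tl["frame1"] = f1
        tl["frame2"] = f2
        if sound:
            tl["beep1"] = f1
            tl["beep2"] = f2
    else:
        # E4: no visual frames; anchors present on every trial.
        tl["beep1"] = f1
        tl["beep2"] = f2
    return tl


def build_design(experiment_id: str, seed: int, *,
                 e3_trials_per_block: int = 24) -> ExperimentDesign:
    """Construct a seeded, counterbalanced trial table for one experiment.

    Parameters
    ----------
    experiment_id
        One of ``E1``-``E4``.
    seed
        Controls both the trial permutation and the per-trial fixation
        durations; identical seeds give identical designs.
    e3_trials_per_block
        Trials per fixed-SOA block in E3 (default 24, i.e. 12 sound +
        12 no-sound, 168 trials total).
    """
    if experiment_id not in EXPERIMENT_IDS:
        raise ValueError(f"unknown experiment id {experiment_id!r}")
    rng = np.random.default_rng([int(seed), EXPERIMENT_IDS.index(experiment_id)])
    with_frames = experiment_id != "E4"

    labels: list[tuple[float, bool, str]]
    block_of: list[int]
    block_structure: list[tuple[int, str]]

    if experiment_id in ("E1", "E4"):
        labels = _make_cells(24)
        order = rng.permutation(len(labels))
        labels = [labels[i] for i in order]
        block_of = [0] * 168 + [1] * 168
        block_structure = [(0, "mixed"), (1, "mixed")]
    elif experiment_id == "E2":
        # Latin-square order over the two sound conditions (ABAB or BABA).
        first_sound = bool(rng.integers(2))
        block_sound = [first_sound, not first_sound, first_sound, not first_sound]
        labels, block_of, block_structure = [], [], []
        for b, snd in enumerate(block_sound):
            blk = []
            for soa in SOA_LEVELS_MS:
                blk += [(soa, snd, "left")] * 6 + [(soa, snd, "right")] * 6
            order = rng.permutation(len(blk))
            labels += [blk[i] for i in order]
            block_of += [b] * len(blk)
            block_structure.append((b, "sound" if snd else "no_sound"))
    else:  # E3: one block per SOA
        per_block = int(e3_trials_per_block)
        if per_block % 4:
            raise ValueError("e3_trials_per_block must be divisible by 4")
        q = per_block // 4
        soa_order = rng.permutation(len(SOA_LEVELS_MS))
        labels, block_of, block_structure = [], [], []
        for b, si in enumerate(soa_order):
            soa = SOA_LEVELS_MS[si]
            blk = []
            for snd in (False, True):
                blk += [(soa, snd, "left")] * q + [(soa, snd, "right")] * q
            order = rng.permutation(len(blk))
            labels += [blk[i] for i in order]
            block_of += [b] * len(blk)
            block_structure.append((b, f"soa_{int(soa)}"))

    trials = []
    for i, ((soa, sound, direction), blk) in enumerate(zip(labels, block_of)):
        tl = _timeline(rng, soa, sound, with_frames)
        trials.append(TrialSpec(trial_id=i, soa_ms=float(soa), sound=bool(sound),
                                direction=direction, block=blk, timeline=tl))
    return ExperimentDesign(experiment_id, trials, block_structure)
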