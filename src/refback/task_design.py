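"""Reference-back trial sequences: generation, classification, events I/O.

The reference-back task presents letters (X or O) inside a red or a blue
frame.  Red-framed trials are *reference* trials: the letter shown becomes
the new referent held in working memory.  Blue-framed trials are
*comparison* trials: the letter is only matched against the most recent
referent.  Crossing trial type with whether the frame colour changed from
the previous trial (gate switch) and with the required same/different
response yields the eight conditions the subprocess contrasts are built
from.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REFERENCE",
    "COMPARISON",
    "SWITCH",
    "NO_SWITCH",
    "SAME",
    "DIFFERENT",
    "ConditionLabel",
    "ALL_LABELS",
    "TrialRecord",
    "SessionDesign",
    "InvalidDesignError",
    "BalanceConstraintError",
    "generate_session",
    "classify_trials",
    "trials_to_frame",
    "frame_to_trials",
    "write_events_tsv",
    "read_events_tsv",
]

REFERENCE = "reference"
COMPARISON = "comparison"
SWITCH = "switch"
NO_SWITCH = "no_switch"
SAME = "same"
DIFFERENT = "different"

#: discrete display-refresh step used for all timing jitter (ms)
REFRESH_MS = 16.6


class InvalidDesignError(ValueError):
    """Raised when a SessionDesign cannot describe a valid session."""


class BalanceConstraintError(RuntimeError):
    """Raised when the balance constraints cannot be satisfied."""


@dataclass(frozen=True)
class ConditionLabel:
    """One of the 8 analysable cells: trial type x gate switch x response."""

    trial_type: str
    gate_switch: str
    response: str

    def __post_init__(self) -> None:
        if self.trial_type not in (REFERENCE, COMPARISON):
            raise ValueError(f"bad trial_type {self.trial_type!r}")
        if self.gate_switch not in (SWITCH, NO_SWITCH):
            raise ValueError(f"bad gate_switch {self.gate_switch!r}")
        if self.response not in (SAME, DIFFERENT):
            raise ValueError(f"bad response {self.response!r}")

    def __str__(self) -> str:  # compact, used in HDF5 label datasets
        return f"{self.trial_type}/{self.gate_switch}/{self.response}"

    @classmethod
    def parse(cls, s: str) -> "ConditionLabel":
        t, g, r = s.split("/")
        return cls(t, g, r)


#: the 8 possible condition labels, in a fixed canonical order
ALL_LABELS: tuple[ConditionLabel, ...] = tuple(
    ConditionLabel(t, g, r)
    for t, g, r in itertools.product(
        (REFERENCE, COMPARISON), (NO_SWITCH, SWITCH), (SAME, DIFFERENT)
    )
)


@dataclass
class TrialRecord:
    """A single reference-back trial.

    ``gate_switch`` and ``required_response`` are ``None`` ("undefined")
    when the trial has no usable predecessor: gate status is undefined for
    the first trial of each block, and the required response is undefined
    until a reference trial has occurred.
    """

    block_index: int  # 1-based
    trial_index_in_block: int  # 1-based
    frame: str  # REFERENCE or COMPARISON
    letter: str  # "X" or "O"
    gate_switch: str | None = None
    required_response: str | None = None
    stimulus_duration: float = 500.0
    isi_duration: float = 1400.0
    onset: float = 0.0

    @property
    def classifiable(self) -> bool:
        return self.gate_switch is not None and self.required_response is not None

    @property
    def label(self) -> ConditionLabel | None:
        if not self.classifiable:
            return None
        return ConditionLabel(self.frame, self.gate_switch, self.required_response)

    @property
    def response_deadline(self) -> float:
        """Time available to respond: stimulus plus following fixation (ms)."""
        return self.stimulus_duration + self.isi_duration


@dataclass
class SessionDesign:
    """Parameters of one reference-back session (defaults follow the study
    design: 9 blocks of 80 trials, p(reference)=.5, p(switch)=.25,
    balanced same/different responses)."""

    n_blocks: int = 9
    trials_per_block: int = 80
    p_reference: float = 0.5
    p_switch: float = 0.25
    p_same: float = 0.5
    balance_tolerance: float = 1.5
    seed: int = 0
    stimulus_base: float = 500.0
    stimulus_jitter: float = 50.0
    isi_base: float = 1400.0
    isi_jitter: float = 100.0

    def validate(self) -> None:
        if self.trials_per_block < 4:
            raise InvalidDesignError("trials_per_block must be at least 4")
        if self.n_blocks < 1:
            raise InvalidDesignError("n_blocks must be at least 1")
        for name in ("p_reference", "p_switch", "p_same"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise InvalidDesignError(f"{name} must lie in (0, 1), got {p}")
        if self.balance_tolerance < 0.5:
            raise BalanceConstraintError(
                "balance_tolerance below half a trial is infeasible for "
                "integer trial counts"
            )

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


def _jitter_grid(base: float, halfwidth: float) -> np.ndarray:
    """Discrete jitter values base + k*16.6 ms inside [base-hw, base+hw]."""
    kmax = int(np.floor(halfwidth / REFRESH_MS))
    return base + REFRESH_MS * np.arange(-kmax, kmax + 1)


def _block_frames(
    rng: np.random.Generator, design: SessionDesign
) -> tuple[list[str], int]:
    """Frame sequence of one block with controlled switch and reference counts.

    The first trial is forced to be a reference trial (it is unanalysable
    anyway: no gate status, and at session start no prior referent).  The
    sequence is parameterised by its switch positions: with the first frame
    fixed, choosing which of the T-1 transitions switch determines every
    frame.  Switch count is drawn within +-1 of p_switch*(T-1) and switch
    positions are resampled until the reference count lands within
    balance_tolerance of p_reference*T.
    """
    T = design.trials_per_block
    n_trans = T - 1
    target_switch = design.p_switch * n_trans
    target_ref = design.p_reference * T
    # randomise the fractional part so the long-run mean equals the target,
    # and hold the count fixed across balance resamples (redrawing it inside
    # the rejection loop would bias the switch rate upward)
    n_switch = int(np.floor(target_switch)) + int(
        rng.random() < target_switch - np.floor(target_switch)
    )
    n_switch = max(0, min(n_trans, n_switch))
    for _ in range(10_000):
        is_switch = np.zeros(n_trans, dtype=bool)
        is_switch[rng.choice(n_trans, size=n_switch, replace=False)] = True
        frames = [REFERENCE]
        for s in is_switch:
            prev = frames[-1]
            frames.append(
                (COMPARISON if prev == REFERENCE else REFERENCE) if s else prev
            )
        n_ref = sum(f == REFERENCE for f in frames)
        if abs(n_ref - target_ref) <= design.balance_tolerance:
            return frames, n_switch
    raise BalanceConstraintError(
        "could not satisfy reference/switch balance; relax balance_tolerance"
    )


def _assign_responses(
    rng: np.random.Generator, frames: Sequence[str]
) -> list[str | None]:
    """Required responses, balanced within trial-type x gate-switch cells.

    Trial 1 gets None (no gate status / possibly no referent).  Cells with
    an odd trial count get their extra member assigned so that the running
    block total stays as close to half/half as possible.
    """
    T = len(frames)
    cells: dict[tuple[str, str], list[int]] = {}
    for i in range(1, T):
        gate = SWITCH if frames[i] != frames[i - 1] else NO_SWITCH
        cells.setdefault((frames[i], gate), []).append(i)
    responses: list[str | None] = [None] * T
    imbalance = 0  # (#same - #different) assigned so far
    for key in sorted(cells):
        idx = cells[key]
        rng.shuffle(idx)
        half = len(idx) // 2
        if len(idx) % 2 == 0:
            n_same = half
        else:
            # give the odd trial to whichever response restores balance
            n_same = half + (1 if imbalance <= 0 else 0)
        for j, i in enumerate(idx):
            responses[i] = SAME if j < n_same else DIFFERENT
        imbalance += 2 * n_same - len(idx)
    return responses


def _letters_for(
    rng: np.random.Generator,
    frames: Sequence[str],
    responses: Sequence[str | None],
    ref_letter: str | None,
) -> tuple[list[str], str]:
    """Choose letters realising the required responses.

    A trial's required response is "same" iff its letter equals the current
    referent; the referent is then updated on reference trials.  Returns
    the letters and the referent carried out of the block.
    """
    letters: list[str] = []
    for frame, resp in zip(frames, responses):
        if resp is None or ref_letter is None:
            letter = "X" if rng.random() < 0.5 else "O"
        elif resp == SAME:
            letter = ref_letter
        else:
            letter = "O" if ref_letter == "X" else "X"
        letters.append(letter)
        if frame == REFERENCE:
            ref_letter = letter
    return letters, ref_letter


def generate_session(design: SessionDesign) -> list[TrialRecord]:
    """Generate one full session of classified trials.

    Deterministic given ``design.seed``.  Within each block the
    reference/comparison split, the switch rate among gate-classifiable
    trials, and the same/different response split are balanced to the
    design tolerances by constrained resampling of the switch positions.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    stim_grid = _jitter_grid(design.stimulus_base, design.stimulus_jitter)
    isi_grid = _jitter_grid(design.isi_base, design.isi_jitter)

    trials: list[TrialRecord] = []
    ref_letter: str | None = None
    clock = 0.0
    for b in range(1, design.n_blocks + 1):
        frames, _ = _block_frames(rng, design)
        responses = _assign_responses(rng, frames)
        # required_response is undefined only while no referent exists; with
        # the forced-reference first trial that is just the session's trial 1.
        # Block-initial trials of later blocks do have a referent: give them
        # a coin-flip response (they are unanalysable regardless: no gate).
        responses[0] = (
            None if ref_letter is None else (SAME if rng.random() < 0.5 else DIFFERENT)
        )
        letters, ref_letter = _letters_for(rng, frames, responses, ref_letter)
        for i, (frame, letter, resp) in enumerate(zip(frames, letters, responses)):
            stim = float(rng.choice(stim_grid))
            isi = float(rng.choice(isi_grid))
            clock += isi  # fixation precedes the stimulus
            gate: str | None
            if i == 0:
                gate = None
            else:
                gate = SWITCH if frame != frames[i - 1] else NO_SWITCH
            trials.append(
                TrialRecord(
                    block_index=b,
                    trial_index_in_block=i + 1,
                    frame=frame,
                    letter=letter,
                    gate_switch=gate,
                    required_response=resp,
                    stimulus_duration=stim,
                    isi_duration=isi,
                    onset=clock,
                )
            )
            clock += stim
    return trials


def classify_trials(trials: Sequence[TrialRecord]) -> list[ConditionLabel | None]:
    """(Re)derive the condition label of each trial from the raw sequence.

    Walks the sequence in onset order, maintaining the current referent:
    the required response is "same" iff the letter matches the most recent
    preceding reference letter, and the referent is updated only *after*
    the comparison on reference trials.  Gate status is undefined for the
    first trial of each block.  Returns one label per trial, ``None``
    where either attribute is undefined.
    """
    labels: list[ConditionLabel | None] = []
    ref_letter: str | None = None
    prev: TrialRecord | None = None
    for t in trials:
        first_of_block = prev is None or t.block_index != prev.block_index
        gate = None if first_of_block else (
            SWITCH if t.frame != prev.frame else NO_SWITCH
        )
        resp = None if ref_letter is None else (
            SAME if t.letter == ref_letter else DIFFERENT
        )
        labels.append(
            ConditionLabel(t.frame, gate, resp)
            if gate is not None and resp is not None
            else None
        )
        if t.frame == REFERENCE:
            ref_letter = t.letter
        prev = t
    return labels


# ---------------------------------------------------------------------------
# events table I/O (BIDS-events-like TSV dialect)

_EVENT_COLUMNS = [
    "block",
    "trial",
    "onset_ms",
    "frame",
    "letter",
    "gate_switch",
    "required_response",
    "stim_dur_ms",
    "isi_ms",
]


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = [
        {
            "block": t.block_index,
            "trial": t.trial_index_in_block,
            "onset_ms": t.onset,
            "frame": t.frame,
            "letter": t.letter,
            "gate_switch": t.gate_switch if t.gate_switch is not None else "n/a",
            "required_response": (
                t.required_response if t.required_response is not None else "n/a"
            ),
            "stim_dur_ms": t.stimulus_duration,
            "isi_ms": t.isi_duration,
        }
        for t in trials
    ]
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    trials = []
    for row in df.itertuples(index=False):
        trials.append(
            TrialRecord(
                block_index=int(row.block),
                trial_index_in_block=int(row.trial),
                frame=str(row.frame),
                letter=str(row.letter),
                gate_switch=None if row.gate_switch == "n/a" else str(row.gate_switch),
                required_response=(
                    None
                    if row.required_response == "n/a"
                    else str(row.required_response)
                ),
                stimulus_duration=float(row.stim_dur_ms),
                isi_duration=float(row.isi_ms),
                onset=float(row.onset_ms),
            )
        )
    return trials


def write_events_tsv(path, trials: Iterable[TrialRecord] | pd.DataFrame) -> None:
    df = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
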