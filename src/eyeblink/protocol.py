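"""Trial scheduling for the delay eyeblink-conditioning protocol.

A training session consists of 22 blocks of 10 trials.  During acquisition
(and reacquisition) each block holds 9 paired CS-US trials and 1 unpaired
CS-only probe, placed pseudorandomly within the block; during extinction each
block holds 5 CS-only and 5 US-only trials, again in pseudorandom order.
Trials are separated by an adaptive intertrial interval of at least 12 s
(see :mod:`eyeblink.preprocess` for the baseline-stability rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np


class Phase(str, Enum):
    HABITUATION = "habituation"
    ACQUISITION = "acquisition"
    EXTINCTION = "extinction"
    REACQUISITION = "reacquisition"


class TrialKind(str, Enum):
    PAIRED = "paired"
    CS_ONLY = "cs_only"
    US_ONLY = "us_only"


class ConfigurationError(ValueError):
    """Raised for inconsistent protocol or simulation configuration."""


@dataclass(frozen=True)
class ProtocolConfig:
    """Stimulus timing and session structure of the conditioning protocol.

    Defaults reproduce the standard head-fixed mouse protocol: a 280 ms light
    CS co-terminating with a 30 ms airpuff US (US onset 250 ms after CS
    onset), 22 blocks of 10 trials per session, 12 acquisition / 4 extinction
    / 3 reacquisition daily sessions, and a >= 12 s intertrial interval.
    """

    blocks_per_session: int = 22
    trials_per_block: int = 10
    paired_per_block: int = 9
    unpaired_cs_per_block: int = 1
    cs_duration_ms: float = 280.0
    us_duration_ms: float = 30.0
    us_onset_ms: float = 250.0  # from CS onset; co-terminates with the CS
    min_iti_s: float = 12.0
    n_acquisition_sessions: int = 12
    n_extinction_sessions: int = 4
    n_reacquisition_sessions: int = 3
    extinction_cs_per_block: int = 5
    extinction_us_per_block: int = 5

    def __post_init__(self) -> None:
        if self.paired_per_block + self.unpaired_cs_per_block != self.trials_per_block:
            raise ConfigurationError(
                "paired_per_block + unpaired_cs_per_block must equal trials_per_block "
                f"({self.paired_per_block} + {self.unpaired_cs_per_block} != "
                f"{self.trials_per_block})"
            )
        if self.extinction_cs_per_block + self.extinction_us_per_block != self.trials_per_block:
            raise ConfigurationError(
                "extinction block composition must fill the block"
            )
        if not np.isclose(self.us_onset_ms + self.us_duration_ms, self.cs_duration_ms):
            raise ConfigurationError(
                "US must co-terminate with the CS (us_onset + us_duration == cs_duration)"
            )
        for name in ("cs_duration_ms", "us_duration_ms", "us_onset_ms", "min_iti_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("blocks_per_session", "trials_per_block", "paired_per_block"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")


@dataclass(frozen=True)
class TrialPlan:
    """One scheduled trial: position within the session and stimulus kind."""

    session_index: int
    phase: Phase
    block_index: int
    trial_index: int  # within block
    kind: TrialKind

    def __post_init__(self) -> None:
        allowed = {
            Phase.ACQUISITION: {TrialKind.PAIRED, TrialKind.CS_ONLY},
            Phase.REACQUISITION: {TrialKind.PAIRED, TrialKind.CS_ONLY},
            Phase.EXTINCTION: {TrialKind.CS_ONLY, TrialKind.US_ONLY},
            Phase.HABITUATION: set(TrialKind),
        }[self.phase]
        if self.kind not in allowed:
            raise ConfigurationError(
                f"trial kind {self.kind.value!r} not allowed in phase {self.phase.value!r}"
            )


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def build_acquisition_schedule(
    cfg: ProtocolConfig,
    seed: int | np.random.Generator,
    session_index: int = 0,
    phase: Phase = Phase.ACQUISITION,
) -> list[TrialPlan]:
    """Schedule one acquisition (or reacquisition) session.

    Each block contains ``paired_per_block`` paired trials and
    ``unpaired_cs_per_block`` CS-only probes; the probe slots are drawn
    uniformly within each block from the seeded generator, so the same seed
    always yields the same schedule.
    """
    rng = _as_rng(seed)
    plans: list[TrialPlan] = []
    for b in range(cfg.blocks_per_session):
        slots = rng.choice(
            cfg.trials_per_block, size=cfg.unpaired_cs_per_block, replace=False
        )
        cs_slots = set(int(s) for s in slots)
        for t in range(cfg.trials_per_block):
            kind = TrialKind.CS_ONLY if t in cs_slots else TrialKind.PAIRED
            plans.append(TrialPlan(session_index, phase, b, t, kind))
    return plans


def build_extinction_schedule(
    cfg: ProtocolConfig,
    seed: int | np.random.Generator,
    session_index: int = 0,
) -> list[TrialPlan]:
    """Schedule one extinction session: per block, ``extinction_cs_per_block``
    CS-only and ``extinction_us_per_block`` US-only trials in pseudorandom
    order."""
    rng = _as_rng(seed)
    plans: list[TrialPlan] = []
    base = [TrialKind.CS_ONLY] * cfg.extinction_cs_per_block + [
        TrialKind.US_ONLY
    ] * cfg.extinction_us_per_block
    for b in range(cfg.blocks_per_session):
        order = rng.permutation(len(base))
        for t, j in enumerate(order):
            plans.append(TrialPlan(session_index, Phase.EXTINCTION, b, t, base[j]))
    return plans


def schedule_counts(plans: Sequence[TrialPlan]) -> dict[str, int]:
    """Count trials of each kind in a schedule."""
    out = {k.value: 0 for k in TrialKind}
    for p in plans:
        out[p.kind.value] += 1
    return out
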