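"""Stimulus arrangements: how pedestal/target/masker modulations map to ears.

Psychophysics (2AFC increment discrimination; all modulations at 40 Hz):

===========  ========================  ==========================
condition    standard interval (L, R)  signal interval (L, R)
===========  ========================  ==========================
mon          (P, 0)                    (P + T, 0)
bin          (P, P)                    (P + T, P + T)
dich         (P, 0)                    (P, T)
half_bin     (P, P)                    (P + T, P)
===========  ========================  ==========================

P is the pedestal depth, T the target increment (percent modulation).
The ear labelled L is nominal; arrangements are counterbalanced in the
real experiment and the models are symmetric.  With P = 0 the mon, dich
and half_bin conditions resolve to the identical stimulus (target in one
ear, plain carrier in the other), which licenses pooling their detection
data.

Steady-state EEG (signal depth m; masker fixed at 50 percent):

===========  ==========================
condition    (left ear, right ear)
===========  ==========================
mon          (m @ 40 Hz, carrier)
bin          (m @ 40 Hz, m @ 40 Hz)
dich         (m @ 40 Hz, 50 @ 40 Hz)
cross_mon    (m @ 35 Hz, carrier)
cross_bin    (m @ 40 Hz, m @ 35 Hz)
cross_dich   (m @ 40 Hz, 50 @ 35 Hz)
===========  ==========================

An unmodulated carrier is represented as depth 0 with no frequency tag;
the carrier itself is not represented in the models.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

__all__ = [
    "F40",
    "F35",
    "PsychCondition",
    "EEGCondition",
    "EarSignal",
    "psych_intervals",
    "psych_increment_spec",
    "eeg_arrangement",
    "PSYCH_CONDITIONS",
    "EEG_CONDITIONS",
    "MASKER_DEPTH",
]

F40 = 40.0
F35 = 35.0
MASKER_DEPTH = 50.0


class PsychCondition(str, Enum):
    MON = "mon"
    BIN = "bin"
    DICH = "dich"
    HALF_BIN = "half_bin"


class EEGCondition(str, Enum):
    MON = "mon"
    BIN = "bin"
    DICH = "dich"
    CROSS_MON = "cross_mon"
    CROSS_BIN = "cross_bin"
    CROSS_DICH = "cross_dich"


PSYCH_CONDITIONS = tuple(PsychCondition)
EEG_CONDITIONS = tuple(EEGCondition)


@dataclass(frozen=True)
class EarSignal:
    """Modulation presented to one ear: depth in percent plus frequency tag.

    ``tag`` is ``None`` for an unmodulated carrier (depth 0).
    """

    depth: float
    tag: Optional[float] = F40

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")
        if self.depth > 0 and self.tag is None:
            raise ValueError("a modulated ear needs a frequency tag")


def psych_intervals(
    condition: PsychCondition | str, pedestal: float, target: float
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Ear depths for the standard and signal intervals of a 2AFC trial.

    Returns ``((L_std, R_std), (L_sig, R_sig))`` in percent modulation.
    All modulations carry the 40 Hz tag.
    """
    condition = PsychCondition(condition)
    if pedestal < 0 or target < 0:
        raise ValueError("pedestal and target must be >= 0")
    P, T = float(pedestal), float(target)
    if condition is PsychCondition.MON:
        return (P, 0.0), (P + T, 0.0)
    if condition is PsychCondition.BIN:
        return (P, P), (P + T, P + T)
    if condition is PsychCondition.DICH:
        return (P, 0.0), (P, T)
    return (P, P), (P + T, P)  # half_bin


def psych_increment_spec(
    condition: PsychCondition | str, pedestal: float
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Standard-interval depths and the per-ear target-increment mask.

    Returns ``((L0, R0), (aL, aR))`` such that the signal interval is
    ``(L0 + aL*T, R0 + aR*T)`` for target increment T.  Convenience for
    vectorized threshold solving.
    """
    condition = PsychCondition(condition)
    P = float(pedestal)
    if P < 0:
        raise ValueError("pedestal must be >= 0")
    if condition is PsychCondition.MON:
        return (P, 0.0), (1.0, 0.0)
    if condition is PsychCondition.BIN:
        return (P, P), (1.0, 1.0)
    if condition is PsychCondition.DICH:
        return (P, 0.0), (0.0, 1.0)
    return (P, P), (1.0, 0.0)  # half_bin


def eeg_arrangement(
    condition: EEGCondition | str, depth: float, masker: float = MASKER_DEPTH
) -> tuple[EarSignal, EarSignal]:
    """Left/right ear signals for one steady-state EEG condition."""
    condition = EEGCondition(condition)
    if depth < 0:
        raise ValueError("depth must be >= 0")
    m = float(depth)
    carrier = EarSignal(0.0, None)
    if condition is EEGCondition.MON:
        return EarSignal(m, F40), carrier
    if condition is EEGCondition.BIN:
        return EarSignal(m, F40), EarSignal(m, F40)
    if condition is EEGCondition.DICH:
        return EarSignal(m, F40), EarSignal(masker, F40)
    if condition is EEGCondition.CROSS_MON:
        return EarSignal(m, F35), carrier
    if condition is EEGCondition.CROSS_BIN:
        return EarSignal(m, F40), EarSignal(m, F35)
    return EarSignal(m, F40), EarSignal(masker, F35)  # cross_dich
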