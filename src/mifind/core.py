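"""Shared vocabulary for the finger-individuation pipeline.

Three right-hand finger muscles carry the motor-evoked-potential (MEP)
readout: abductor pollicis brevis (thumb), first dorsal interosseus
(index) and abductor digiti minimi (little finger).  Background EMG is
monitored on both hands, six muscles in total.
"""

from __future__ import annotations

FINGERS: tuple[str, ...] = ("thumb", "index", "little")
REST: str = "rest"

#: muscle acronym per instructed finger (right hand)
MUSCLE_OF_FINGER: dict[str, str] = {
    "thumb": "apb",
    "index": "fdi",
    "little": "adm",
}

#: bgEMG channels: right hand first, then left hand
BG_MUSCLES: tuple[str, ...] = (
    "r_apb", "r_fdi", "r_adm", "l_apb", "l_fdi", "l_adm",
)

SESSIONS: tuple[str, str] = ("pre", "post")


def check_finger(name: str) -> str:
    if name not in FINGERS:
        raise ValueError(f"unknown finger {name!r}; expected one of {FINGERS}")
    return name


def check_cue(name: str) -> str:
    if name != REST and name not in FINGERS:
        raise ValueError(f"unknown cue {name!r}; expected {FINGERS + (REST,)}")
    return name


def nontargets(target: str) -> tuple[str, str]:
    """The two fingers that are not the cued target."""
    check_finger(target)
    return tuple(f for f in FINGERS if f != target)  # type: ignore[return-value]
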