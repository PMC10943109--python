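"""Bit-coded disability states over nine activities of daily living (ADLs).

Each of the nine ADLs — feeding (F), transferring (S), grooming (G), toilet
use (T), bathing (B), walking (W), dressing (D), bowel continence (L) and
urinary continence (U) — is dichotomized as completely dependent (1) versus
independent or only partially dependent (0).  A *disability state* is a
combination of dependent ADLs, one of 2^9 = 512 possibilities, encoded as an
integer in [0, 511] by summing fixed per-ADL bit weights.

The canonical display order of the letters is F, S, G, T, B, W, D, L, U.
State 0 (no disability) is named ``"O"`` and state 511 (all nine) ``"All"``;
every other state is named by its letters in display order, e.g. code 476 is
``"GTBDLU"``.  The severity of a state is its number of dependent ADLs
(the popcount of the code), giving the preference order used to classify
transitions as recoveries or declines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

__all__ = [
    "ADL_ORDER",
    "ADL_FUNCTIONS",
    "BIT_WEIGHTS",
    "N_STATES",
    "ADLProfile",
    "DisabilityState",
    "encode_state",
    "decode_state",
    "state_name",
    "severity",
    "severity_norm",
    "bit_weights_json",
]

#: Canonical display order of the ADL letters.
ADL_ORDER: tuple[str, ...] = ("F", "S", "G", "T", "B", "W", "D", "L", "U")

#: Letter -> physiological function.
ADL_FUNCTIONS: dict[str, str] = {
    "F": "feeding",
    "S": "transferring",
    "G": "grooming",
    "T": "toilet_use",
    "B": "bathing",
    "W": "walking",
    "D": "dressing",
    "L": "bowel",
    "U": "urinary",
}

#: Per-ADL bit weight; a state code is the sum of the weights of its
#: dependent ADLs.  Kept as a single constant table so the coding can be
#: swapped wholesale if a different convention is ever needed.
BIT_WEIGHTS: dict[str, int] = {
    "F": 1,
    "S": 2,
    "G": 4,
    "D": 8,
    "B": 16,
    "W": 32,
    "T": 64,
    "L": 128,
    "U": 256,
}

N_STATES: int = 512

_FIELD_BY_LETTER = {k: v for k, v in ADL_FUNCTIONS.items()}


def _check_code(code: int) -> int:
    code = int(code)
    if not 0 <= code < N_STATES:
        raise ValueError(f"state code must be in [0, {N_STATES - 1}], got {code}")
    return code


@dataclass(frozen=True)
class ADLProfile:
    """Nine boolean dependence flags, one per ADL."""

    feeding: bool = False
    transferring: bool = False
    grooming: bool = False
    toilet_use: bool = False
    bathing: bool = False
    walking: bool = False
    dressing: bool = False
    bowel: bool = False
    urinary: bool = False

    @classmethod
    def from_letters(cls, letters: str) -> "ADLProfile":
        """Build a profile from a string of canonical letters, e.g. ``"GTBD"``."""
        kwargs = {}
        for ch in letters:
            if ch not in _FIELD_BY_LETTER:
                raise ValueError(f"unknown ADL letter {ch!r}")
            kwargs[_FIELD_BY_LETTER[ch]] = True
        return cls(**kwargs)

    @property
    def letters(self) -> str:
        """Dependent-ADL letters in canonical display order."""
        return "".join(ch for ch in ADL_ORDER if getattr(self, _FIELD_BY_LETTER[ch]))


def encode_state(profile: ADLProfile) -> int:
    """Encode an :class:`ADLProfile` as an integer state code in [0, 511]."""
    return sum(BIT_WEIGHTS[ch] for ch in profile.letters)


def decode_state(code: int) -> ADLProfile:
    """Inverse of :func:`encode_state`."""
    code = _check_code(code)
    kwargs = {
        _FIELD_BY_LETTER[ch]: bool(code & BIT_WEIGHTS[ch]) for ch in ADL_ORDER
    }
    return ADLProfile(**kwargs)


def state_name(code: int) -> str:
    """Human-readable state name: ``"O"`` for 0, ``"All"`` for 511, letters otherwise."""
    code = _check_code(code)
    if code == 0:
        return "O"
    if code == N_STATES - 1:
        return "All"
    return decode_state(code).letters


def severity(code: int) -> int:
    """Number of dependent ADLs in the state (the popcount of the code)."""
    return _check_code(code).bit_count()


def severity_norm(code: int) -> float:
    """Severity rescaled to [0, 1] (severity / 9)."""
    return severity(code) / len(ADL_ORDER)


@dataclass(frozen=True)
class DisabilityState:
    """A disability state with its code, name and severity."""

    code: int
    name: str
    severity: int
    severity_norm: float

    @classmethod
    def from_code(cls, code: int) -> "DisabilityState":
        code = _check_code(code)
        return cls(
            code=code,
            name=state_name(code),
            severity=severity(code),
            severity_norm=severity_norm(code),
        )

    @classmethod
    def from_letters(cls, letters: str) -> "DisabilityState":
        return cls.from_code(encode_state(ADLProfile.from_letters(letters)))


def bit_weights_json() -> str:
    """The bit-weight table in machine-readable form, for documentation."""
    payload = {
        "display_order": list(ADL_ORDER),
        "functions": ADL_FUNCTIONS,
        "bit_weights": BIT_WEIGHTS,
        "n_states": N_STATES,
    }
    return json.dumps(payload, indent=2, sort_keys=False)
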