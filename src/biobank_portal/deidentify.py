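"""Coded limited-dataset de-identification.

A *coded* limited dataset (LDS) strips direct identifiers but keeps a
re-linkable pseudonymous key so the dataset can be refreshed as the
source records grow. Three obfuscations are applied on export:

* stable pseudonymous patient codes (keyed one-way HMAC of the id),
* per-patient date shifting by a constant, nonzero offset drawn
  deterministically from a keyed hash (default window +/-182 days), and
* zip-code truncation to the first three digits.

Because the code and the offset are pure functions of (patient_id, key),
re-running de-identification after a store update assigns previously
seen patients the same code and the same shift — the "coded, updatable"
contract. No crosswalk table is ever persisted. Within a patient, every
date moves by the same offset, so intervals between events are exactly
preserved.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import hmac
from dataclasses import dataclass

DEFAULT_MAX_SHIFT_DAYS = 182


@dataclass(frozen=True)
class DeidConfig:
    """De-identification settings: secret key and shift window."""

    secret_key: str
    max_shift_days: int = DEFAULT_MAX_SHIFT_DAYS

    def __post_init__(self):
        if not self.secret_key:
            raise ValueError("secret_key must be non-empty")
        if self.max_shift_days < 1:
            raise ValueError("max_shift_days must be >= 1")


def _mac(key: str, message: bytes) -> bytes:
    return hmac.new(key.encode("utf-8"), message, hashlib.sha256).digest()


def patient_code(patient_id: str, key: str) -> str:
    """Deterministic keyed one-way pseudonymous code for a patient id.

    Same (id, key) always yields the same 32-hex-character code;
    distinct ids collide only with negligible probability. An empty key
    is an error (codes must never be an unkeyed hash of the id).
    """
    if not key:
        raise ValueError("de-identification key must be non-empty")
    return _mac(key, b"patient-code|" + patient_id.encode("utf-8")).hex()[:32]


def date_shift_offset(
    patient_id: str, key: str, max_shift_days: int = DEFAULT_MAX_SHIFT_DAYS
) -> int:
    """Per-patient constant date-shift offset, in days.

    Uniform over {-max .. -1, +1 .. +max} (zero excluded: every date is
    guaranteed to move) under a keyed hash of the patient id, hence
    deterministic across runs and store refreshes.
    """
    if not key:
        raise ValueError("de-identification key must be non-empty")
    if max_shift_days < 1:
        raise ValueError("max_shift_days must be >= 1")
    digest = _mac(key, b"date-shift|" + patient_id.encode("utf-8"))
    v = int.from_bytes(digest[:8], "big") % (2 * max_shift_days)
    offset = v - max_shift_days
    return offset if offset < 0 else offset + 1


def shift_date(date: dt.date, offset: int) -> dt.date:
    """Shift a calendar date by *offset* days (plain calendar arithmetic)."""
    return date + dt.timedelta(days=offset)


def truncate_zip(zip_code: str) -> str:
    """Truncate a zip code to its first three digits.

    Anything that is not a digit string of length >= 3 truncates to the
    empty string rather than leaking a partial value.
    """
    z = str(zip_code).strip()
    if len(z) >= 3 and z.isdigit():
        return z[:3]
    return ""
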