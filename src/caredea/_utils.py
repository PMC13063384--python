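"""Shared numeric helpers."""

from __future__ import annotations

import decimal

import numpy as np

from .exceptions import InvalidInputError


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at the given decimal place.

    Python's built-in ``round`` uses banker's rounding, which turns the
    reported coefficient (0.94 + 0.85) / 2 = 0.895 into 0.89; conventional
    reporting in this field rounds it up to 0.90.  Going through the
    shortest decimal repr avoids binary-float artefacts such as
    ``0.895 -> 0.89499999...``.
    """
    if not np.isfinite(x):
        return float(x)
    q = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def validate_positive_matrix(arr: np.ndarray, name: str) -> np.ndarray:
    """Return ``arr`` as a 2-D float array, rejecting non-finite or <= 0 cells."""
    out = np.asarray(arr, dtype=float)
    if out.ndim == 1:
        out = out.reshape(-1, 1)
    if out.ndim != 2:
        raise InvalidInputError(f"{name} must be 2-dimensional, got ndim={out.ndim}")
    if not np.all(np.isfinite(out)):
        i, j = np.argwhere(~np.isfinite(out))[0]
        raise InvalidInputError(f"{name} has a non-finite value at row {i}, column {j}")
    if np.any(out <= 0):
        i, j = np.argwhere(out <= 0)[0]
        raise InvalidInputError(
            f"{name} must be strictly positive; found {out[i, j]!r} at row {i}, column {j}"
        )
    return out
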